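"""Time-dependent stimulation protocols.

A protocol is a list of rectangular MHC pulses (start, duration, amplitude
in units of the nominal stimulus strength), an optional constant calcineurin
inhibitor (CnI) dose applied from t = 0, and two half-open response windows
bracketing the primary and secondary responses for AUC bookkeeping. Times
are hours at this interface; the simulation engine converts to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class Pulse:
    start: float  # h
    duration: float  # h
    amplitude: float  # x nominal MHC strength

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError("pulse duration must be > 0")
        if self.amplitude < 0:
            raise ProtocolError("pulse amplitude must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    pulses: tuple[Pulse, ...]
    horizon: float  # h
    cni_dose: float = 0.0  # nM, constant from t=0
    response_windows: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.cni_dose < 0:
            raise ProtocolError("CnI dose must be >= 0")
        starts = [p.start for p in self.pulses]
        if starts != sorted(starts):
            raise ProtocolError("pulses must be sorted by start time")
        for a, b in zip(self.pulses, self.pulses[1:]):
            if b.start < a.end:
                raise ProtocolError("pulses must not overlap")
        for lo, hi in self.response_windows:
            if not (0 <= lo < hi <= self.horizon):
                raise ProtocolError("response windows must be within [0, horizon]")
        for (_, hi), (lo2, _) in zip(self.response_windows, self.response_windows[1:]):
            if lo2 < hi:
                raise ProtocolError("response windows must be disjoint")

    def amplitude_at(self, t: float) -> float:
        """Piecewise-constant input; zero outside pulses."""
        for p in self.pulses:
            if p.start <= t < p.end:
                return p.amplitude
        return 0.0

    def segment_edges(self) -> list[float]:
        edges = {0.0, self.horizon}
        for p in self.pulses:
            if p.start < self.horizon:
                edges.add(p.start)
            if p.end < self.horizon:
                edges.add(p.end)
        return sorted(edges)

    def shifted(self, dt: float) -> "StimulusProtocol":
        return replace(
            self,
            pulses=tuple(replace(p, start=p.start + dt) for p in self.pulses),
            horizon=self.horizon + dt,
            response_windows=tuple((a + dt, b + dt) for a, b in self.response_windows),
        )


def make_sequential_pulses(
    amp1: float,
    amp2: float,
    interval: float = 48.0,
    duration: float = 1.0,
    horizon: float = 96.0,
) -> StimulusProtocol:
    """Two rectangular TCR pulses at t = 0 and t = ``interval`` (hours).

    Window defaults: primary [0, interval), secondary [interval, horizon).
    """
    if amp1 <= 0:
        raise ProtocolError("primary amplitude must be > 0")
    if amp2 < 0:
        raise ProtocolError("secondary amplitude must be >= 0")
    if duration <= 0 or interval <= duration:
        raise ProtocolError("need 0 < duration < interval")
    if horizon <= interval:
        raise ProtocolError("horizon must exceed the interval")
    pulses = (Pulse(0.0, duration, amp1), Pulse(interval, duration, amp2))
    return StimulusProtocol(
        pulses=pulses,
        horizon=horizon,
        response_windows=((0.0, interval), (interval, horizon)),
    )


def make_cni_protocol(base: StimulusProtocol, dose: float) -> StimulusProtocol:
    """Copy of ``base`` with a constant CnI dose (nM) applied from t = 0."""
    if dose < 0:
        raise ProtocolError("CnI dose must be >= 0")
    return replace(base, cni_dose=float(dose))
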