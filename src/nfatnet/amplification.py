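"""AUC-based amplification indices and response classification.

Under two sequential TCR pulses every species' response is summarized by
the baseline-subtracted area under its time course within the primary (A1)
and secondary (A2) response windows. The amplification index is carried in
two forms: the percentage change AI% = (A2 - A1)/A1 * 100 used for the
three-way classification (amplification at AI% >= 10, depletion below -10,
no change in between), and the plain AUC ratio A2/A1 used by the
robustness and ensemble analyses. AUC is preferred over peak height
because it integrates the signalling flux of abrupt, transient responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .engine import Trajectory, find_baseline, simulate
from .network import NetworkModel
from .parameters import ParameterSet
from .stimulation import make_sequential_pulses

AMPLIFICATION_THRESHOLD_PCT = 10.0


class ResponseGroup(str, Enum):
    AMPLIFICATION = "amplification"
    DEPLETION = "depletion"
    NO_CHANGE = "no_change"
    UNDEFINED = "undefined"  # A1 = 0: index not computable


@dataclass(frozen=True)
class AmplificationResult:
    species: str
    A1: float
    A2: float
    AI_pct: float  # (A2-A1)/A1 * 100; nan when undefined
    AI_ratio: float  # A2/A1; nan when undefined
    group: ResponseGroup

    @property
    def defined(self) -> bool:
        return self.group is not ResponseGroup.UNDEFINED


def classify_ai_pct(ai_pct: float) -> ResponseGroup:
    if not math.isfinite(ai_pct):
        return ResponseGroup.UNDEFINED
    if ai_pct >= AMPLIFICATION_THRESHOLD_PCT:
        return ResponseGroup.AMPLIFICATION
    if ai_pct < -AMPLIFICATION_THRESHOLD_PCT:
        return ResponseGroup.DEPLETION
    return ResponseGroup.NO_CHANGE


def window_auc(traj: Trajectory, species: str, window: tuple[float, float]) -> float:
    """Trapezoidal AUC (nM h) of the baseline-subtracted response in a window.

    The pre-stimulus steady-state value is subtracted and the excess floored
    at zero, so the integral measures response, not abundance.
    """
    lo, hi = window
    t = traj.time_h
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}) outside trajectory grid")
    mask = (t >= lo) & (t < hi)
    excess = np.maximum(traj.series(species)[mask] - traj.baseline_of(species), 0.0)
    return float(np.trapezoid(excess, t[mask]))


def amplification_index(
    traj: Trajectory,
    species: str,
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> AmplificationResult:
    """AI of one species over the primary/secondary windows."""
    if windows is None:
        windows = traj.protocol.response_windows
    if len(windows) != 2:
        raise ValueError("need exactly a primary and a secondary response window")
    a1 = window_auc(traj, species, windows[0])
    a2 = window_auc(traj, species, windows[1])
    if a1 <= 0.0:
        return AmplificationResult(species, a1, a2, float("nan"), float("nan"),
                                   ResponseGroup.UNDEFINED)
    ai_pct = (a2 - a1) / a1 * 100.0
    return AmplificationResult(species, a1, a2, ai_pct, a2 / a1, classify_ai_pct(ai_pct))


def network_response_map(
    traj: Trajectory, species: list[str] | None = None
) -> dict[str, AmplificationResult]:
    """Amplification result for every (or each requested) species."""
    names = species if species is not None else list(traj.species_names)
    return {sp: amplification_index(traj, sp) for sp in names}


def response_map_frame(results: dict[str, AmplificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "A1": r.A1,
                "A2": r.A2,
                "AI_pct": r.AI_pct,
                "AI_ratio": r.AI_ratio,
                "group": r.group.value,
            }
            for r in results.values()
        ]
    )


def weakened_secondary_scan(
    model: NetworkModel,
    params: ParameterSet,
    fold_reductions: list[float] = (1.0, 10.0, 100.0, 1000.0),
    readouts: tuple[str, ...] = ("NFATnuc", "FasL"),
    amp1: float = 1.0,
    duration: float = 1.0,
    baseline: np.ndarray | None = None,
) -> dict[float, dict[str, AmplificationResult]]:
    """AI of the readouts as the secondary pulse is weakened ``fold``-fold.

    fold = 1 reproduces the equal-pulse protocol; amp2 = amp1 / fold.
    """
    if any(f < 1 for f in fold_reductions):
        raise ValueError("fold reductions must be >= 1")
    if baseline is None:
        baseline = find_baseline(model, params)
    out: dict[float, dict[str, AmplificationResult]] = {}
    for fold in fold_reductions:
        proto = make_sequential_pulses(amp1, amp1 / fold, duration=duration)
        traj = simulate(model, params, proto, baseline=baseline)
        out[fold] = {sp: amplification_index(traj, sp) for sp in readouts}
    return out
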