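"""Feedback perturbation, strength scans, sensitivity and CnI dosing.

The feedback studies all operate on the annotated links of a network:

* ``perturbation_study`` — each link is strengthened/weakened by 30% on top
  of randomized parameter backgrounds (every constant jittered within
  +/-30%), and the paired NFAT amplification indices are compared against
  matched no-perturbation controls with a two-sided Wilcoxon signed-rank
  test (pairing on the shared backgrounds).
* ``strength_scan`` — the link's controlled parameters are scaled over
  [1e-2, 1e2] and the resulting NFAT AI curve is classified as monotonic,
  flat, biphasic (interior maximum) or reverse-biphasic (interior minimum).
* ``lsf_sensitivity`` — the logarithmic sensitivity L = (dx/x)/(dp/p)
  evaluated with the one-sided finite difference at a stated fractional
  parameter change.
* ``cni_dose_response`` / ``optimal_window`` — primary/secondary response
  AUCs across a CnI dose grid, and the largest contiguous dose interval
  that suppresses primary IL-2 while keeping secondary FasL near its
  dose-curve maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .amplification import amplification_index, window_auc
from .engine import BaselineError, SimulationError, find_baseline, simulate
from .network import FeedbackLink, NetworkModel, apply_link_perturbation
from .parameters import ParameterSet
from .stimulation import StimulusProtocol, make_cni_protocol, make_sequential_pulses


class ScanPattern(str, Enum):
    MONOTONIC_INCREASE = "monotonic_increase"
    MONOTONIC_DECREASE = "monotonic_decrease"
    NO_CHANGE = "no_change"
    BIPHASIC = "biphasic"
    REVERSE_BIPHASIC = "reverse_biphasic"


class ImmunePhenotype(str, Enum):
    AICD = "AICD"
    ID = "ID"  # immune deficiency: strong primary FasL induction
    AU = "AU"  # autoimmunity: FasL silent in both responses
    OTHER = "other"


@dataclass(frozen=True)
class PerturbationResult:
    link: str
    direction: str  # "up30" | "down30"
    ai_samples: np.ndarray
    control_samples: np.ndarray
    p_value: float
    significance_band: str  # ns | p<0.05 | p<0.01 | p<0.001
    n_failed: int = 0
    reliable: bool = True


@dataclass(frozen=True)
class ScanResult:
    link: str
    strengths: np.ndarray
    outputs: np.ndarray
    pattern: ScanPattern


@dataclass(frozen=True)
class PhenotypeCall:
    fasl_primary: float
    fasl_secondary: float
    phenotype: ImmunePhenotype


@dataclass(frozen=True)
class SensitivityScore:
    output_name: str
    parameter_name: str
    delta_fraction: float
    score: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.score)


def significance_band(p: float) -> str:
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


#: marker rendering used in the tabular outputs, matching common figure legends
BAND_MARKERS = {"ns": "ns", "p<0.05": "*", "p<0.01": "**", "p<0.001": "#"}

DEFAULT_STRENGTH_GRID = np.logspace(-2, 2, 9)


def _nfat_ai_ratio(model, params, protocol, baseline=None, rtol=1e-6, atol=1e-9):
    traj = simulate(model, params, protocol, rtol=rtol, atol=atol, baseline=baseline)
    res = amplification_index(traj, "NFATnuc")
    return res.AI_ratio


def perturbation_study(
    model: NetworkModel,
    fitted: ParameterSet,
    links: Sequence[FeedbackLink | str] | None = None,
    delta: float = 0.30,
    n: int = 300,
    background_spread: float = 0.30,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> list[PerturbationResult]:
    """Paired 30%-perturbation study of every feedback link.

    For each of ``n`` randomized backgrounds the control AI and the AI with
    one link scaled by (1 +/- delta) are computed from the same background,
    and the paired samples are tested per link and direction. An arm with
    more than 10% failed integrations is flagged unreliable.
    """
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if links is None:
        links = list(model.feedback_links)
    links = [model.link(l) if isinstance(l, str) else l for l in links]
    rng = np.random.default_rng(seed)
    backgrounds = [fitted.jittered(background_spread, rng) for _ in range(n)]

    control = np.full(n, np.nan)
    for i, bg in enumerate(backgrounds):
        try:
            control[i] = _nfat_ai_ratio(model, bg, protocol, rtol=rtol, atol=atol)
        except (SimulationError, BaselineError):
            pass

    results = []
    for link in links:
        for direction, factor in (("up30", 1 + delta), ("down30", 1 - delta)):
            perturbed = np.full(n, np.nan)
            for i, bg in enumerate(backgrounds):
                ps = apply_link_perturbation(model, link, factor, params=bg) \
                    if factor != 1.0 else bg
                try:
                    perturbed[i] = _nfat_ai_ratio(model, ps, protocol, rtol=rtol, atol=atol)
                except (SimulationError, BaselineError):
                    pass
            ok = np.isfinite(control) & np.isfinite(perturbed)
            n_failed = int(n - ok.sum())
            diffs = perturbed[ok] - control[ok]
            if ok.sum() == 0 or np.allclose(diffs, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
            results.append(
                PerturbationResult(
                    link=link.name,
                    direction=direction,
                    ai_samples=perturbed[ok],
                    control_samples=control[ok],
                    p_value=p,
                    significance_band=significance_band(p),
                    n_failed=n_failed,
                    reliable=n_failed <= 0.1 * n,
                )
            )
    return results


def classify_scan_pattern(
    strengths: np.ndarray,
    outputs: np.ndarray,
    flat_tol: float = 0.10,
    interior_margin: float = 0.05,
) -> ScanPattern:
    """Label a strength-scan response curve.

    ``no_change`` when the total relative variation is below ``flat_tol``;
    ``biphasic``/``reverse_biphasic`` when the extremum is interior and
    clears both endpoints by ``interior_margin`` (relative); otherwise
    monotonic by endpoint comparison. Invariant under positive rescaling of
    the outputs.
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(outputs, dtype=float)
    if len(s) < 5 or len(s) != len(y):
        raise ValueError("need >= 5 grid points with matching outputs")
    if np.any(np.diff(s) <= 0):
        raise ValueError("strength grid must be strictly increasing")
    scale = float(np.mean(np.abs(y)))
    if scale == 0 or (y.max() - y.min()) / scale < flat_tol:
        return ScanPattern.NO_CHANGE
    i_max, i_min = int(np.argmax(y)), int(np.argmin(y))
    lo, hi = y[0], y[-1]
    if 0 < i_max < len(y) - 1 and y[i_max] > (1 + interior_margin) * max(lo, hi):
        return ScanPattern.BIPHASIC
    if 0 < i_min < len(y) - 1 and y[i_min] < (1 - interior_margin) * min(lo, hi):
        return ScanPattern.REVERSE_BIPHASIC
    return ScanPattern.MONOTONIC_INCREASE if hi >= lo else ScanPattern.MONOTONIC_DECREASE


def strength_scan(
    model: NetworkModel,
    fitted: ParameterSet,
    link: FeedbackLink | str,
    grid: np.ndarray = DEFAULT_STRENGTH_GRID,
    protocol: StimulusProtocol | None = None,
) -> ScanResult:
    """NFAT AI across multiplicative link strengths in [1e-2, 1e2]."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 1e-2 - 1e-12 or grid.max() > 1e2 + 1e-10 or not np.any(np.isclose(grid, 1.0)):
        raise ValueError("grid must lie within [1e-2, 1e2] and include 1.0")
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    link = model.link(link) if isinstance(link, str) else link
    outputs = []
    for g in grid:
        ps = apply_link_perturbation(model, link, float(g), params=fitted)
        outputs.append(_nfat_ai_ratio(model, ps, protocol))
    outputs = np.array(outputs)
    return ScanResult(link.name, grid, outputs, classify_scan_pattern(grid, outputs))


def classify_immune_phenotype(
    fasl_primary: float,
    fasl_secondary: float,
    silence_threshold: float,
    induction_threshold: float,
) -> PhenotypeCall:
    """Map FasL induction AUCs to an immune phenotype.

    AICD: silenced primary with strongly induced secondary; ID (immune
    deficiency): strong primary induction regardless of the secondary;
    AU (autoimmunity): both silenced.
    """
    if not (0 < silence_threshold < induction_threshold):
        raise ValueError("need 0 < silence_threshold < induction_threshold")
    if fasl_primary < 0 or fasl_secondary < 0:
        raise ValueError("FasL AUCs must be >= 0")
    if fasl_primary >= induction_threshold:
        ph = ImmunePhenotype.ID
    elif fasl_primary < silence_threshold and fasl_secondary >= induction_threshold:
        ph = ImmunePhenotype.AICD
    elif fasl_primary < silence_threshold and fasl_secondary < silence_threshold:
        ph = ImmunePhenotype.AU
    else:
        ph = ImmunePhenotype.OTHER
    return PhenotypeCall(fasl_primary, fasl_secondary, ph)


def secondary_auc_output(species: str = "NFATnuc") -> Callable:
    """Summary functional: baseline-subtracted secondary-window AUC."""

    def output(model: NetworkModel, params: ParameterSet,
               protocol: StimulusProtocol) -> float:
        traj = simulate(model, params, protocol)
        return window_auc(traj, species, protocol.response_windows[1])

    return output


def lsf_sensitivity(
    model: NetworkModel,
    params: ParameterSet,
    output: Callable,
    parameter_names: Sequence[str],
    delta_fraction: float = 0.01,
    protocol: StimulusProtocol | None = None,
    output_name: str = "output",
) -> list[SensitivityScore]:
    """Logarithmic sensitivity scores by one-sided finite difference.

    score = [(x(p + dp) - x(p)) / x(p)] / (dp / p) with dp = delta * p;
    an undefined score (x(p) = 0) is reported as a NaN sentinel.
    """
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    x0 = output(model, params, protocol)
    scores = []
    for pname in parameter_names:
        if delta_fraction == 0.0:
            scores.append(SensitivityScore(output_name, pname, 0.0, 0.0))
            continue
        if x0 == 0:
            scores.append(SensitivityScore(output_name, pname, delta_fraction, float("nan")))
            continue
        x1 = output(model, params.scaled({pname: 1.0 + delta_fraction}), protocol)
        scores.append(
            SensitivityScore(
                output_name, pname, delta_fraction,
                ((x1 - x0) / x0) / delta_fraction,
            )
        )
    return scores


def link_sensitivity(
    model: NetworkModel,
    params: ParameterSet,
    link: FeedbackLink | str,
    output: Callable,
    delta_fraction: float = -0.5,
    protocol: StimulusProtocol | None = None,
    output_name: str = "output",
) -> SensitivityScore:
    """LSF of a summary output w.r.t. a link's common strength factor."""
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    link = model.link(link) if isinstance(link, str) else link
    x0 = output(model, params, protocol)
    if delta_fraction == 0.0:
        return SensitivityScore(output_name, link.name, 0.0, 0.0)
    if x0 == 0:
        return SensitivityScore(output_name, link.name, delta_fraction, float("nan"))
    ps = apply_link_perturbation(model, link, 1.0 + delta_fraction, params=params)
    x1 = output(model, ps, protocol)
    return SensitivityScore(output_name, link.name, delta_fraction,
                            ((x1 - x0) / x0) / delta_fraction)


@dataclass(frozen=True)
class DoseResponse:
    doses: np.ndarray
    primary: dict[str, np.ndarray]
    secondary: dict[str, np.ndarray]


def cni_dose_response(
    model: NetworkModel,
    fitted: ParameterSet,
    dose_grid: np.ndarray,
    readouts: tuple[str, ...] = ("IL2", "FasL", "NFATnuc"),
    protocol: StimulusProtocol | None = None,
    baseline: np.ndarray | None = None,
) -> DoseResponse:
    """Primary/secondary response AUCs of the readouts across CnI doses."""
    doses = np.asarray(dose_grid, dtype=float)
    if doses.min() < 0 or 0.0 not in doses:
        raise ValueError("dose grid must be non-negative and include 0")
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if baseline is None:
        baseline = find_baseline(model, fitted)
    primary = {sp: np.empty(len(doses)) for sp in readouts}
    secondary = {sp: np.empty(len(doses)) for sp in readouts}
    for i, dose in enumerate(doses):
        traj = simulate(model, fitted, make_cni_protocol(protocol, float(dose)),
                        baseline=baseline)
        for sp in readouts:
            primary[sp][i] = window_auc(traj, sp, protocol.response_windows[0])
            secondary[sp][i] = window_auc(traj, sp, protocol.response_windows[1])
    return DoseResponse(doses, primary, secondary)


def optimal_window(
    doses: np.ndarray,
    il2_primary: np.ndarray,
    fasl_secondary: np.ndarray,
    il2_suppression_fraction: float = 0.5,
    fasl_induction_fraction: float = 0.8,
) -> tuple[float, float] | None:
    """Largest contiguous dose interval suppressing IL-2 yet inducing FasL.

    A dose qualifies when primary IL-2 is below ``il2_suppression_fraction``
    of its zero-dose value and secondary FasL exceeds
    ``fasl_induction_fraction`` of its dose-curve maximum. Returns
    (dose_lo, dose_hi) or None when no dose qualifies.
    """
    doses = np.asarray(doses, dtype=float)
    il2 = np.asarray(il2_primary, dtype=float)
    fasl = np.asarray(fasl_secondary, dtype=float)
    if not (len(doses) == len(il2) == len(fasl)):
        raise ValueError("curves must share the dose grid")
    ok = (il2 < il2_suppression_fraction * il2[0]) & (
        fasl > fasl_induction_fraction * fasl.max()
    )
    best: tuple[int, int] | None = None
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if best is None or doses[j] - doses[i] > doses[best[1]] - doses[best[0]]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return float(doses[best[0]]), float(doses[best[1]])


def dose_curve_feedback_sensitivity(
    model: NetworkModel,
    fitted: ParameterSet,
    links: Sequence[FeedbackLink | str] | None = None,
    dose_grid: np.ndarray | None = None,
    delta: float = 0.30,
    readout: str = "FasL",
    protocol: StimulusProtocol | None = None,
) -> dict[str, float]:
    """LSF of the secondary dose-curve AUC with respect to each link strength.

    The summary output is the integral over the dose grid of the secondary
    ``readout`` response AUC — a scalar measure of the whole drug-response
    curve; the score is its logarithmic sensitivity to scaling the link's
    controlled parameters by (1 + delta).
    """
    if links is None:
        links = list(model.feedback_links)
    if dose_grid is None:
        dose_grid = np.array([0.0, 50.0, 100.0, 200.0, 400.0, 800.0])
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)

    def curve_auc(params: ParameterSet) -> float:
        dr = cni_dose_response(model, params, dose_grid, readouts=(readout,),
                               protocol=protocol)
        return float(np.trapezoid(dr.secondary[readout], dr.doses))

    x0 = curve_auc(fitted)
    out: dict[str, float] = {}
    for link in links:
        link = model.link(link) if isinstance(link, str) else link
        if delta == 0.0:
            out[link.name] = 0.0
            continue
        ps = apply_link_perturbation(model, link, 1.0 + delta, params=fitted)
        out[link.name] = ((curve_auc(ps) - x0) / x0) / delta if x0 else float("nan")
    return out
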