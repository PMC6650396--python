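"""Ensemble modelling: many parameter sets satisfying qualitative constraints.

Instead of a single best-fit parameterization, an ensemble of models is
generated by drawing a random starting point (each constant log10-uniform
in [-4, 4], clipped to its biological range), refining it with the GA until
the qualitative dynamic constraints hold — the secondary NFAT peak exceeds
the primary by at least 2-fold, the response is macroscopic, and NFAT is
transient in both windows — and retaining the refined set. Members that
fail within the generation cap are discarded and redrawn (the discard
count is reported).

Ensemble-wide feedback function is assessed by suppressing each link by
50% in every member and scoring the logarithmic sensitivity of the NFAT
amplification index (AUC ratio); per-link tallies count the members in
which a link exerts a strong enhancing or inhibiting effect (sensitivity
beyond the upper/lower quartile of the pooled score distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .amplification import amplification_index
from .calibration import (
    GAConfig,
    QualitativeConstraints,
    check_qualitative_constraints,
    fit_ga,
)
from .engine import BaselineError, SimulationError, simulate
from .network import NetworkModel, apply_link_perturbation
from .parameters import ParameterSet
from .stimulation import StimulusProtocol, make_sequential_pulses

#: qualitative constraints the ensemble enforces (no FasL fold: the screen
#: follows the two NFAT conditions; a 1 nM floor keeps responses macroscopic)
ENSEMBLE_CONSTRAINTS = QualitativeConstraints(
    nfat_fold_min=2.0, fasl_fold_min=None, min_response_nm=1.0
)

ENSEMBLE_RHS_BUDGET = 15_000


def ensemble_grid(protocol: StimulusProtocol) -> np.ndarray:
    """Coarse output grid resolving both response windows cheaply."""
    pts = []
    for p in protocol.pulses:
        pts.append(np.arange(p.start, min(p.start + 2.0, protocol.horizon), 1 / 6))
    pts.append(np.arange(0.0, protocol.horizon + 1e-9, 1.0))
    return np.unique(np.concatenate(pts))


@dataclass
class EnsembleModel:
    id: int
    params: ParameterSet
    ai_ratio: float
    constraint_report: dict[str, bool]


@dataclass
class EnsembleResult:
    members: list[EnsembleModel]
    n_discarded: int
    seed: int

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ai_ratios(self) -> np.ndarray:
        return np.array([m.ai_ratio for m in self.members])


def _random_start(reference: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Each constant log10-uniform over [-4, 4] within its biological range.

    Drawing within the intersection (rather than clipping draws onto the
    range boundary) keeps constants with narrower admissible ranges, such
    as degradation rates, uniformly spread instead of piled on a bound.
    """
    values = {}
    for name in reference.names:
        lo, hi = reference.ranges[name]
        llo, lhi = max(np.log10(lo), -4.0), min(np.log10(hi), 4.0)
        if llo >= lhi:
            llo, lhi = np.log10(lo), np.log10(hi)
        values[name] = float(10.0 ** rng.uniform(llo, lhi))
    return ParameterSet(values, dict(reference.ranges), "sampled")


def build_ensemble(
    model: NetworkModel,
    n: int = 100,
    seed: int = 0,
    ga_config: GAConfig | None = None,
    protocol: StimulusProtocol | None = None,
    reference: ParameterSet | None = None,
    constraints: QualitativeConstraints = ENSEMBLE_CONSTRAINTS,
    max_redraws_per_member: int = 24,
    rtol: float = 1e-5,
    atol: float = 1e-8,
    ga_rtol: float = 1e-4,
    ga_atol: float = 1e-7,
) -> EnsembleResult:
    """GA-refine random starting points until the constraints pass, n times.

    The GA phase integrates at coarser tolerances than the final validation
    (``ga_rtol``/``ga_atol`` vs ``rtol``/``atol``): candidate screening does
    not need the full precision, and every retained member is re-simulated
    and re-checked at the stricter setting before acceptance.
    """
    if n < 1:
        raise ValueError("need n >= 1 members")
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if reference is None:
        from .fullmodel import nominal_parameters

        reference = nominal_parameters()
    if ga_config is None:
        ga_config = GAConfig(population=10, generations=24, mutation_sigma=0.45,
                             mutation_rate=0.3, init_jitter=0.5,
                             abandon_after=10, abandon_above=20.0, abandon_stall=8)
    rng = np.random.default_rng(seed)
    grid = ensemble_grid(protocol)
    from .calibration import PENALTY_CEILING, objective as _objective

    # stage-1 screen: single primary pulse over the first window only. Most
    # candidates already fail there (no macroscopic or no transient primary
    # response), at roughly half the integration cost of the full protocol.
    w1_end = protocol.response_windows[0][1]
    stage1_protocol = StimulusProtocol(
        pulses=protocol.pulses[:1], horizon=w1_end, cni_dose=protocol.cni_dose,
        response_windows=((0.0, w1_end),),
    )
    stage1_grid = grid[grid <= w1_end + 1e-9]
    floor = constraints.min_response_nm or 1.0

    def stage1_penalty(ps: ParameterSet) -> float | None:
        """Shaped penalty if the primary response alone disqualifies; None if OK."""
        try:
            traj = simulate(model, ps, stage1_protocol, grid=stage1_grid,
                            rtol=ga_rtol, atol=ga_atol,
                            max_rhs_evals=ENSEMBLE_RHS_BUDGET)
        except (SimulationError, BaselineError):
            return PENALTY_CEILING
        s = traj.series(constraints.nfat_species) - traj.baseline_of(constraints.nfat_species)
        if not np.all(np.isfinite(s)):
            return PENALTY_CEILING
        i = int(np.argmax(s))
        peak, t_peak = float(s[i]), float(traj.time_h[i])
        pen = 0.0
        if peak < floor:
            pen += max(0.0, -np.log10(max(peak, 1e-15) / floor)) / 15.0
        lo_w, hi_w = constraints.transient_peak_window
        if peak > 0:
            pen += max(0.0, t_peak - hi_w) / w1_end + max(0.0, lo_w - t_peak) / w1_end
            pen += max(0.0, float(s[-1]) / peak - constraints.transient_decay_fraction)
        else:
            pen += 1.0
        # an un-amplified fold counts 1 toward the full objective; add it so
        # stage-1 costs upper-bound their stage-2 counterparts
        return 100.0 * pen + 100.0 if pen > 0 else None

    def cost_of(ps: ParameterSet) -> float:
        early = stage1_penalty(ps)
        if early is not None:
            return early
        return _objective(ps, model, [], constraints, protocol, rtol=ga_rtol,
                          atol=ga_atol, grid=grid, max_rhs_evals=ENSEMBLE_RHS_BUDGET)

    members: list[EnsembleModel] = []
    n_discarded = 0
    while len(members) < n:
        attempts = 0
        member = None
        continue_from = None
        was_continuation = False
        thorough = False
        while member is None:
            if attempts >= max_redraws_per_member:
                if thorough:
                    raise RuntimeError(
                        f"member {len(members)}: no constraint-satisfying set "
                        f"within {2 * max_redraws_per_member} redraws"
                    )
                # escalate: thorough attempts with a doubled generation
                # budget and no early abandonment
                thorough = True
                attempts = 0
            overrides = {"seed": int(rng.integers(2**31))}
            if thorough:
                overrides |= {"generations": 2 * ga_config.generations,
                              "abandon_after": None, "abandon_stall": None}
            cfg = GAConfig(**{**ga_config.__dict__, **overrides})
            if continue_from is not None:
                # near miss: keep refining the same random start instead of
                # discarding the progress already made (one extra round)
                start, init_pop = continue_from, None
                continue_from = None
                was_continuation = True
            else:
                was_continuation = False
                # prescreen random draws; seed the GA population with the
                # most promising ones (cheap, one simulation each)
                starts = [_random_start(reference, rng) for _ in range(30)]
                ranked = sorted(starts, key=cost_of)
                start, init_pop = ranked[0], ranked[:8]
            res = fit_ga(model, targets=[], constraints=constraints, config=cfg,
                         protocol=protocol, start=start, rtol=ga_rtol, atol=ga_atol,
                         grid=grid, initial_population=init_pop,
                         objective_fn=cost_of)
            member = _validate_member(model, res.best, protocol, constraints,
                                      rtol=rtol, atol=atol)
            if member is None:
                n_discarded += 1
                attempts += 1
                if res.cost < 30.0 and not was_continuation:
                    continue_from = res.best
        report, ai = member
        members.append(EnsembleModel(len(members), res.best, ai, report))
    return EnsembleResult(members, n_discarded, seed)


def _validate_member(model, params, protocol, constraints, rtol, atol):
    """Re-simulate and re-check every constraint; returns (report, AI) or None."""
    try:
        traj = simulate(model, params, protocol, grid=ensemble_grid(protocol),
                        rtol=rtol, atol=atol,
                        max_rhs_evals=10 * ENSEMBLE_RHS_BUDGET)
    except (SimulationError, BaselineError):
        return None
    if not np.all(np.isfinite(traj.states)):
        return None
    report = check_qualitative_constraints(traj, constraints)
    if not all(report.values()):
        return None
    res = amplification_index(traj, constraints.nfat_species)
    if not res.defined:
        return None
    # the amplification screen applies to the AI statistic (AUC ratio) as
    # well as the peak ratio: retained members have AI >= the fold cut-off
    if res.AI_ratio < constraints.nfat_fold_min:
        return None
    return report, float(res.AI_ratio)


def _member_ai(model, params, protocol, rtol, atol) -> float:
    try:
        traj = simulate(model, params, protocol, grid=ensemble_grid(protocol),
                        rtol=rtol, atol=atol,
                        max_rhs_evals=10 * ENSEMBLE_RHS_BUDGET)
    except (SimulationError, BaselineError):
        return float("nan")
    res = amplification_index(traj, "NFATnuc")
    return float(res.AI_ratio) if res.defined else float("nan")


def ensemble_sensitivity(
    ensemble: EnsembleResult,
    model: NetworkModel,
    links: list[str] | None = None,
    suppression: float = 0.5,
    protocol: StimulusProtocol | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> "SensitivityMatrix":
    """LSF of every member's AI under fractional suppression of each link.

    Entry (m, l) = [(AI_suppressed - AI)/AI] / (-suppression); positive
    scores mean the link enhances amplification. Undefined entries (failed
    integration or AI = 0) are NaN sentinels, excluded from tallies.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if links is None:
        links = [l.name for l in model.feedback_links]
    scores = np.full((len(ensemble), len(links)), np.nan)
    for i, member in enumerate(ensemble):
        ai0 = _member_ai(model, member.params, protocol, rtol, atol)
        if not np.isfinite(ai0) or ai0 == 0:
            continue
        for j, link in enumerate(links):
            ps = apply_link_perturbation(model, link, 1.0 - suppression,
                                         params=member.params)
            ai1 = _member_ai(model, ps, protocol, rtol, atol)
            if np.isfinite(ai1):
                scores[i, j] = ((ai1 - ai0) / ai0) / (-suppression)
    return SensitivityMatrix(scores=scores, links=list(links),
                             member_ids=[m.id for m in ensemble])


@dataclass
class SensitivityMatrix:
    scores: np.ndarray  # (n_members, n_links), NaN = undefined sentinel
    links: list[str]
    member_ids: list[int] = field(default_factory=list)

    def cluster_order(self) -> np.ndarray:
        """Row order from hierarchical clustering (Euclidean, average linkage)."""
        rows = np.nan_to_num(self.scores, nan=0.0)
        if len(rows) < 3:
            return np.arange(len(rows))
        return np.asarray(leaves_list(linkage(rows, method="average",
                                              metric="euclidean")))


@dataclass(frozen=True)
class StrongEffectTally:
    link: str
    n_enhancing: int
    n_inhibiting: int
    n_scored: int

    @property
    def enhancing_fraction(self) -> float:
        return self.n_enhancing / self.n_scored if self.n_scored else 0.0

    @property
    def inhibiting_fraction(self) -> float:
        return self.n_inhibiting / self.n_scored if self.n_scored else 0.0


def tally_strong_effects(
    matrix: SensitivityMatrix,
    upper_q: float = 0.75,
    lower_q: float = 0.25,
    quantile_axis: str = "pooled",
) -> dict[str, StrongEffectTally]:
    """Count members where each link has a strong enhancing/inhibiting effect.

    Strong-enhancing: score strictly above the upper quantile and positive;
    strong-inhibiting: strictly below the lower quantile and negative. With
    ``quantile_axis="pooled"`` (default) the quantiles come from all finite
    scores of the whole matrix, so a uniformly influential link can be
    strong in most members; ``"per_link"`` uses each link's own column.
    """
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    scores = matrix.scores
    finite_all = scores[np.isfinite(scores)]
    if finite_all.size == 0:
        raise ValueError("sensitivity matrix contains no finite scores")
    out: dict[str, StrongEffectTally] = {}
    if quantile_axis == "pooled":
        hi = float(np.quantile(finite_all, upper_q))
        lo = float(np.quantile(finite_all, lower_q))
    for j, link in enumerate(matrix.links):
        col = scores[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0:
            continue  # all-sentinel column: excluded
        if quantile_axis == "per_link":
            hi = float(np.quantile(finite, upper_q))
            lo = float(np.quantile(finite, lower_q))
        n_enh = int(np.sum((finite > hi) & (finite > 0)))
        n_inh = int(np.sum((finite < lo) & (finite < 0)))
        out[link] = StrongEffectTally(link, n_enh, n_inh, int(finite.size))
    return out
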