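"""Model calibration: objective, qualitative constraints and the GA.

Calibration fits kinetic constants to normalized time-course targets while
enforcing the qualitative dynamic constraints the model must reproduce
under equal sequential TCR pulses: at least a 2-fold secondary/primary
increase of nuclear NFAT and a 10-fold increase of FasL (peak amplitudes
within the response windows), with a transient NFAT response in both
windows (early peak, decayed at the far end of the window).

The optimizer is a generational genetic algorithm searching log10 parameter
space within the biological ranges: tournament selection, uniform
crossover, Gaussian mutation in log space, elitism, fully seeded. An
optional early stop ends the run once the best individual satisfies all
qualitative constraints (and, when targets are present, improves slower
than the configured tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import BaselineError, SimulationError, default_grid, find_baseline, simulate
from .network import NetworkModel
from .parameters import ParameterSet
from .stimulation import StimulusProtocol, make_sequential_pulses

PENALTY_CEILING = 1e6
CONSTRAINT_WEIGHT = 100.0


@dataclass(frozen=True)
class CalibrationTarget:
    """One normalized time-course constraint: a species sampled at times (h)."""

    species: str
    times: np.ndarray
    values: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-d arrays")
        if not np.all(np.isfinite(v)):
            raise ValueError("target values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class QualitativeConstraints:
    nfat_fold_min: float = 2.0
    fasl_fold_min: float | None = 10.0
    #: window (hours after each pulse start) in which the NFAT peak must lie
    transient_peak_window: tuple[float, float] = (0.0, 6.0)
    #: terminal window value must drop below this fraction of the peak
    transient_decay_fraction: float = 0.5
    #: minimal primary peak (nM) for the response to count at all; None
    #: disables the magnitude check (quantitative targets already pin scale)
    min_response_nm: float | None = None
    nfat_species: str = "NFATnuc"
    fasl_species: str = "FasL"

    def __post_init__(self) -> None:
        if self.nfat_fold_min <= 0 or self.transient_decay_fraction <= 0:
            raise ValueError("constraint thresholds must be > 0")
        if self.fasl_fold_min is not None and self.fasl_fold_min <= 0:
            raise ValueError("constraint thresholds must be > 0")


def _window_peaks(traj, species, windows):
    """Baseline-subtracted peak value and time within each response window."""
    t = traj.time_h
    s = traj.series(species) - traj.baseline_of(species)
    peaks = []
    for lo, hi in windows:
        m = (t >= lo) & (t < hi)
        i = int(np.argmax(s[m]))
        peaks.append((float(s[m][i]), float(t[m][i])))
    return peaks


def check_qualitative_constraints(
    traj, constraints: QualitativeConstraints = QualitativeConstraints()
) -> dict[str, bool]:
    """Per-constraint pass record for a sequential-pulse trajectory."""
    windows = traj.protocol.response_windows
    if len(windows) != 2:
        raise ValueError("trajectory must cover a primary and a secondary window")
    pulses = traj.protocol.pulses
    (p1, t1), (p2, t2) = _window_peaks(traj, constraints.nfat_species, windows)
    out: dict[str, bool] = {}
    out["nfat_fold"] = p1 > 0 and p2 / p1 >= constraints.nfat_fold_min
    if constraints.min_response_nm is not None:
        out["min_response"] = p1 >= constraints.min_response_nm
    if constraints.fasl_fold_min is not None:
        (f1, _), (f2, _) = _window_peaks(traj, constraints.fasl_species, windows)
        out["fasl_fold"] = f1 > 0 and f2 / f1 >= constraints.fasl_fold_min
    lo_w, hi_w = constraints.transient_peak_window
    s = traj.series(constraints.nfat_species) - traj.baseline_of(constraints.nfat_species)
    t = traj.time_h
    for label, (peak, t_peak), pulse, (wlo, whi) in zip(
        ("transient_primary", "transient_secondary"), [(p1, t1), (p2, t2)], pulses, windows
    ):
        in_window = pulse.start + lo_w <= t_peak <= pulse.start + hi_w
        terminal = float(s[np.searchsorted(t, whi - 1e-9) - 1])
        decayed = peak > 0 and terminal < constraints.transient_decay_fraction * peak
        out[label] = bool(in_window and decayed)
    return out


def constraint_penalty(traj, constraints: QualitativeConstraints) -> float:
    """Smooth hinge penalty, zero iff all qualitative constraints hold."""
    windows = traj.protocol.response_windows
    pulses = traj.protocol.pulses
    pen = 0.0
    (p1, t1), (p2, t2) = _window_peaks(traj, constraints.nfat_species, windows)
    fold = p2 / p1 if p1 > 0 else 0.0
    pen += max(0.0, 1.0 - fold / constraints.nfat_fold_min)
    if constraints.min_response_nm is not None:
        # log-scaled distance: informative across many decades of response
        # magnitude, zero iff the primary peak reaches the floor
        ratio = max(p1, 1e-15) / constraints.min_response_nm
        pen += max(0.0, -np.log10(ratio)) / 15.0 if ratio < 1 else 0.0
    if constraints.fasl_fold_min is not None:
        (f1, _), (f2, _) = _window_peaks(traj, constraints.fasl_species, windows)
        ffold = f2 / f1 if f1 > 0 else 0.0
        pen += max(0.0, 1.0 - ffold / constraints.fasl_fold_min)
    lo_w, hi_w = constraints.transient_peak_window
    s = traj.series(constraints.nfat_species) - traj.baseline_of(constraints.nfat_species)
    t = traj.time_h
    for (peak, t_peak), pulse, (wlo, whi) in zip([(p1, t1), (p2, t2)], pulses, windows):
        if peak <= 0:
            pen += 1.0
            continue
        rel = t_peak - pulse.start
        span = whi - wlo
        pen += max(0.0, rel - hi_w) / span + max(0.0, lo_w - rel) / span
        terminal = float(s[np.searchsorted(t, whi - 1e-9) - 1])
        pen += max(0.0, terminal / peak - constraints.transient_decay_fraction)
    return pen


def _objective_grid(protocol: StimulusProtocol, targets) -> np.ndarray:
    pts = [default_grid(protocol)]
    for tg in targets:
        pts.append(np.asarray(tg.times, dtype=float))
    return np.unique(np.concatenate(pts))


def objective(
    params: ParameterSet,
    model: NetworkModel,
    targets: list[CalibrationTarget],
    constraints: QualitativeConstraints | None,
    protocol: StimulusProtocol,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    grid: np.ndarray | None = None,
    max_rhs_evals: int | None = None,
) -> float:
    """Weighted SSE on max-normalized curves plus constraint hinge penalties.

    Integration failure yields the finite penalty ceiling (GA robustness),
    never an exception.
    """
    if grid is None:
        grid = _objective_grid(protocol, targets)
    try:
        traj = simulate(model, params, protocol, grid=grid, rtol=rtol, atol=atol,
                        max_rhs_evals=max_rhs_evals)
    except (SimulationError, BaselineError, FloatingPointError):
        return PENALTY_CEILING
    if not np.all(np.isfinite(traj.states)):
        return PENALTY_CEILING
    cost = 0.0
    for tg in targets:
        sim = np.interp(tg.times, traj.time_h, traj.series(tg.species))
        sim = sim - sim.min()
        smax = sim.max()
        data = tg.values / max(tg.values.max(), 1e-300)
        if smax <= 0:
            cost += tg.weight * float(np.sum(data**2))
            continue
        cost += tg.weight * float(np.sum((sim / smax - data) ** 2))
    if constraints is not None:
        cost += CONSTRAINT_WEIGHT * constraint_penalty(traj, constraints)
    return cost


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.7
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.3  # decades, log10 space
    tournament_k: int = 3
    elitism: int = 2
    seed: int = 0
    #: initial population: log-normal jitter (decades) around the start set;
    #: None draws log-uniform within the full ranges
    init_jitter: float | None = 0.2
    #: stop once all qualitative constraints are satisfied by the best
    #: individual and (with targets) the residual improves < rel_tol
    early_stop: bool = True
    rel_tol: float = 1e-3
    patience: int = 10
    #: abandon a hopeless run: after ``abandon_after`` generations with the
    #: best cost still above ``abandon_above`` (None disables), or after
    #: ``abandon_stall`` generations without improvement while infeasible
    abandon_after: int | None = None
    abandon_above: float | None = None
    abandon_stall: int | None = None


@dataclass
class GAResult:
    best: ParameterSet
    cost: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0


def fit_ga(
    model: NetworkModel,
    targets: list[CalibrationTarget],
    constraints: QualitativeConstraints | None,
    config: GAConfig = GAConfig(),
    protocol: StimulusProtocol | None = None,
    start: ParameterSet | None = None,
    free: list[str] | None = None,
    objective_fn=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    grid=None,
    initial_population: list[ParameterSet] | None = None,
) -> GAResult:
    """Seeded generational GA minimizing the calibration objective.

    Search is in log10 space over ``free`` parameters (default: all of the
    model's kinetic constants), clipped to the biological ranges. The cost
    history records the best-so-far per generation and is non-increasing.
    """
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if start is None:
        from .fullmodel import nominal_parameters

        start = nominal_parameters()
    if free is None:
        free = list(model.parameter_names)
    rng = np.random.default_rng(config.seed)
    lo, hi = start.log_bounds(free)
    if grid is None:
        grid = _objective_grid(protocol, targets)

    if objective_fn is None:
        def objective_fn(ps: ParameterSet) -> float:
            return objective(ps, model, targets, constraints, protocol,
                             rtol=rtol, atol=atol, grid=grid)

    def decode(x: np.ndarray) -> ParameterSet:
        return start.with_log_vector(free, x)

    x0 = start.to_log_vector(free)
    pop = np.empty((config.population, len(free)))
    if initial_population is not None:
        seeds = [ps.to_log_vector(free) for ps in initial_population]
        for i in range(config.population):
            base = seeds[i % len(seeds)]
            pop[i] = base if i < len(seeds) else base + rng.normal(
                0.0, config.init_jitter or 0.3, size=len(free))
    elif config.init_jitter is None:
        pop = rng.uniform(lo, hi, size=pop.shape)
    else:
        pop = x0 + rng.normal(0.0, config.init_jitter, size=pop.shape)
        pop[0] = x0  # keep the unperturbed start in the population
    pop = np.clip(pop, lo, hi)

    n_eval = 0

    def evaluate(rows: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += len(rows)
        return np.array([objective_fn(decode(x)) for x in rows])

    fitness = evaluate(pop)
    best_i = int(np.argmin(fitness))
    best_x, best_f = pop[best_i].copy(), float(fitness[best_i])
    history = [best_f]
    stall = 0

    def constraints_met(x: np.ndarray) -> bool:
        if constraints is None:
            return True
        try:
            traj = simulate(model, decode(x), protocol, grid=grid, rtol=rtol, atol=atol)
        except (SimulationError, BaselineError):
            return False
        return all(check_qualitative_constraints(traj, constraints).values())

    for gen in range(config.generations):
        if (config.abandon_after is not None and gen >= config.abandon_after
                and best_f > (config.abandon_above or 0.0)):
            break
        if (config.abandon_stall is not None and stall >= config.abandon_stall
                and best_f > 0.0):
            break
        if config.early_stop and best_f < PENALTY_CEILING:
            # without residual targets the cost is a pure constraint
            # penalty, so zero cost certifies satisfaction without an
            # extra simulation
            if not targets and best_f <= 0.0:
                break
            if targets and stall >= config.patience and constraints_met(best_x):
                break
        order = np.argsort(fitness)
        elite = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population - config.elitism:
            idx = rng.integers(0, config.population, size=(2, config.tournament_k))
            pa = pop[idx[0][np.argmin(fitness[idx[0]])]]
            pb = pop[idx[1][np.argmin(fitness[idx[1]])]]
            child = pa.copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(len(free)) < 0.5
                child[mask] = pb[mask]
            mut = rng.random(len(free)) < config.mutation_rate
            child[mut] += rng.normal(0.0, config.mutation_sigma, size=int(mut.sum()))
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elite, np.array(children)])
        fitness = evaluate(pop)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f - config.rel_tol * max(abs(best_f), 1e-12):
            stall = 0
        else:
            stall += 1
        if fitness[gen_best] < best_f:
            best_f = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        history.append(best_f)

    return GAResult(best=decode(best_x), cost=best_f, history=history, evaluations=n_eval)


def local_refinement_start(params: ParameterSet, decades: float = 0.2) -> ParameterSet:
    """Copy of ``params`` with ranges narrowed to +/- ``decades`` around each value.

    Used when the GA should polish an existing calibration against new
    targets rather than re-explore the full biological ranges: the search
    stays within measurement-scale uncertainty of the starting set.
    """
    ranges = {}
    for name, v in params.values.items():
        lo, hi = params.ranges[name]
        f = 10.0 ** decades
        ranges[name] = (max(v / f, lo), min(v * f, hi))
    return ParameterSet(dict(params.values), ranges, params.provenance)


def robustness_envelope(
    model: NetworkModel,
    fitted: ParameterSet,
    protocol: StimulusProtocol,
    n: int = 100,
    spread: float = 0.30,
    seed: int = 0,
    grid: np.ndarray | None = None,
    species: list[str] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean +/- sd envelope over n replicates with every parameter jittered.

    Each replicate multiplies every constant by an independent
    Uniform[1 - spread, 1 + spread] factor (clipped to ranges). Returns
    {species: (mean, sd)} on the output grid; failed replicates are skipped,
    and an error is raised if none integrate.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = default_grid(protocol)
    names = species if species is not None else list(model.species_names)
    samples = []
    for _ in range(n):
        ps = fitted.jittered(spread, rng)
        try:
            traj = simulate(model, ps, protocol, grid=grid)
        except (SimulationError, BaselineError):
            continue
        samples.append(np.stack([traj.series(sp) for sp in names]))
    if not samples:
        raise RuntimeError("all envelope replicates failed to integrate")
    arr = np.stack(samples)  # (reps, species, time)
    mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=1)
    return {sp: (mean[i], sd[i]) for i, sp in enumerate(names)} | {
        "_grid": (grid, np.zeros_like(grid))
    }
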