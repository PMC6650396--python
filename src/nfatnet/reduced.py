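"""Reduced four-feedback TCR-CN-NFAT model and robustness counting.

The reduced network keeps only the signalling backbone
(MHC -> pTCR -> Ca-activated calcineurin -> NFAT nuclear translocation ->
FasL output) and the four feedback loops found to dominate NFAT
amplification control:

* F1 — NFAT transcriptional auto-induction (positive)
* F2 — NFAT-induced RCAN, phosphorylated to pRCAN, which captures active
  calcineurin into a hyperactive complex (positive)
* F3 — NFAT-induced Carabin catalytically deactivating calcineurin
  (negative)
* F4 — NFAT-induced CTLA-4 desensitizing TCR activation (negative)

Removing a loop deletes its reactions entirely. Robustness of NFAT
amplification is quantified by counting, across log-uniform parameter
draws within the biological ranges, how many parameter sets still produce
an amplification index >= 10% under equal sequential pulses; configurations
are compared with a two-proportion z-test on matched draws (same sampled
parameter sets applied to every configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .amplification import AMPLIFICATION_THRESHOLD_PCT, amplification_index
from .engine import BaselineError, SimulationError, simulate
from .fullmodel import _Builder
from .network import CANONICAL_LINKS, FeedbackLink, NetworkModel, Species, SpeciesRole
from .parameters import ParameterSet
from .stimulation import StimulusProtocol, make_sequential_pulses

S = SpeciesRole.SIGNALLING
T = SpeciesRole.TRANSCRIPT
C = SpeciesRole.COMPLEX

LOOP_NAMES = {"F1": "NFAT/NFAT", "F2": "pRCAN/CN", "F3": "Carabin/CN", "F4": "CTLA4/TCR"}


@dataclass(frozen=True)
class ReducedConfig:
    f1: bool = True
    f2: bool = True
    f3: bool = True
    f4: bool = True

    @property
    def label(self) -> str:
        on = [n for n, flag in zip(("F1", "F2", "F3", "F4"),
                                   (self.f1, self.f2, self.f3, self.f4)) if flag]
        return "+".join(on) if on else "backbone"

    def without(self, loop: str) -> "ReducedConfig":
        loop = loop.lower()
        if loop not in {"f1", "f2", "f3", "f4"}:
            raise ValueError(f"unknown loop {loop!r}")
        kw = {"f1": self.f1, "f2": self.f2, "f3": self.f3, "f4": self.f4}
        kw[loop] = False
        return ReducedConfig(**kw)


@dataclass(frozen=True)
class RobustnessResult:
    config: ReducedConfig
    n_sampled: int
    n_amplifying: int
    n_failed: int
    comparison_p: float | None = None  # two-proportion test vs the control config

    @property
    def fraction(self) -> float:
        return self.n_amplifying / self.n_sampled


def _build_reduced(config: ReducedConfig) -> tuple[NetworkModel, dict[str, float]]:
    b = _Builder()
    # backbone: TCR activation (CTLA-4-inhibited only when F4 present); the
    # CN activation step carries the F2 enhancer and the F3 brake as
    # phenomenological modifiers, each loop reduced to induction + turnover
    inhibitors = (("CTLA4", "kI_r1"),) if config.f4 else ()
    inh_values = (0.3,) if config.f4 else ()
    b.mm("r1", "TCR", "pTCR", Vmax="V_r1", Vmax_value=3.0, Km="Km_r1", Km_value=50.0,
         inhibitors=inhibitors, inh_values=inh_values, inp=True)
    b.ma("r2", [("pTCR", 1)], [("TCR", 1)], "kd_r2", value=0.1)
    b.ma("r2b", [("pTCR", 1)], [("iTCR", 1)], "kc_r2b", value=0.15)
    b.ma("r2c", [("iTCR", 1)], [("TCR", 1)], "kd_r2c", value=0.0015)
    enhancers = (("pRCAN", "Ka_r17"),) if config.f2 else ()
    enh_values = (20.0,) if config.f2 else ()
    inhibitors3 = (("Carabin", "kI_r22"),) if config.f3 else ()
    inh3_values = (0.02,) if config.f3 else ()
    # Ca2+-driven CN activation requires ongoing antigen engagement (input
    # gate) on top of the TCR signal: calcium entry collapses once the
    # stimulus ends, so no signalling-level state carries memory between
    # pulses — inter-pulse memory lives in the induced protein pools only
    b.mm("r3", "CN", "CaCN", Vmax="V_r3", Vmax_value=60.0, Km="Km_r3", Km_value=300.0,
         activators=(("pTCR", "Ka_r3"),), act_values=(2e-4,),
         enhancers=enhancers, enh_values=enh_values,
         inhibitors=inhibitors3, inh_values=inh3_values, inp=True)
    b.ma("r4", [("CaCN", 1)], [("CN", 1)], "kd_r4", value=0.2)
    b.mm("r5", "NFATcyt", "NFATnuc", kc="kc_r5", kc_value=0.03, Km="Km_r5",
         Km_value=400.0, enzyme="CaCN")
    b.ma("r6", [("NFATnuc", 1)], [("NFATcyt", 1)], "kc_r6", value=0.004)
    b.ma("r7", [], [("NFATcyt", 1)], "basal_r7", value=0.02)
    b.ma("r8", [("NFATcyt", 1)], [], "kdeg_r8", value=2e-4)
    b.ma("r9", [("NFATnuc", 1)], [], "kdeg_r9", value=2e-4)
    b.hill("r10", "NFATnuc", "FasL", Vmax="V_r10", Vmax_value=0.3, Km="Km_r10",
           Km_value=175.0, n=4.0, basal="basal_r10", basal_value=1e-4)
    b.ma("r11", [("FasL", 1)], [], "kdeg_r11", value=1e-3)

    species = [
        Species("TCR", S, 100.0), Species("pTCR", S), Species("iTCR", S),
        Species("CN", S, 1000.0), Species("CaCN", S),
        Species("NFATcyt", S), Species("NFATnuc", S),
        Species("FasL", T),
    ]
    links: list[FeedbackLink] = []

    if config.f1:
        # protein-level memory: auto-induced NFAT decays on the slow
        # protein-degradation timescale of the backbone pool
        b.hill("r12", "NFATnuc", "NFATcyt", Vmax="V_r12", Vmax_value=3.0,
               Km="Km_r12", Km_value=20.0)
        links.append(FeedbackLink("NFAT/NFAT", CANONICAL_LINKS["NFAT/NFAT"],
                                  frozenset({"V_r12"})))
    if config.f2:
        # fast loop: the phospho-RCAN pool turns over by dephosphorylation
        # (kd timescale), so the loop amplifies within a response rather
        # than storing inter-pulse memory; the induction threshold sits
        # above the un-amplified primary peak, making the boost selective
        # for amplified (secondary) responses
        b.hill("r13", "NFATnuc", "pRCAN", Vmax="V_r13", Vmax_value=0.5,
               Km="Km_r13", Km_value=150.0)
        b.ma("r14", [("pRCAN", 1)], [], "kd_r14", value=0.02)
        species.append(Species("pRCAN", S))
        links.append(FeedbackLink("pRCAN/CN", CANONICAL_LINKS["pRCAN/CN"],
                                  frozenset({"V_r13"})))
    if config.f3:
        b.hill("r20", "NFATnuc", "Carabin", Vmax="V_r20", Vmax_value=2.5,
               Km="Km_r20", Km_value=85.0, n=4.0)
        b.ma("r21", [("Carabin", 1)], [], "kdeg_r21", value=3e-4)
        species.append(Species("Carabin", T))
        links.append(FeedbackLink("Carabin/CN", CANONICAL_LINKS["Carabin/CN"],
                                  frozenset({"V_r20"})))
    if config.f4:
        b.hill("r23", "NFATnuc", "CTLA4", Vmax="V_r23", Vmax_value=0.03,
               Km="Km_r23", Km_value=15.0)
        b.ma("r24", [("CTLA4", 1)], [], "kdeg_r24", value=1.5e-4)
        species.append(Species("CTLA4", T))
        links.append(FeedbackLink("CTLA4/TCR", CANONICAL_LINKS["CTLA4/TCR"],
                                  frozenset({"kI_r1"})))

    moieties = {"TCR_total": ("TCR", "pTCR", "iTCR"), "CN_total": ("CN", "CaCN")}

    model = NetworkModel(
        name=f"tcr-cn-nfat-reduced[{config.label}]",
        species=tuple(species),
        reactions=tuple(b.reactions),
        feedback_links=tuple(links),
        inputs=("MHC",),
        conserved_moieties=moieties,
    )
    return model, b.defaults


def build_reduced_network(config: ReducedConfig = ReducedConfig()) -> NetworkModel:
    """Backbone + present loops; loop removal deletes its reactions."""
    return _build_reduced(config)[0]


def reduced_nominal_parameters(config: ReducedConfig = ReducedConfig()) -> ParameterSet:
    """Default constants for a reduced configuration (subset of the full set).

    Each constant carries a biological range of one decade either side of
    its calibrated value, clipped to the generic bounds for its type: the
    sampling studies explore realistic cell-to-cell variation of a working
    network, not arbitrary rate combinations (almost none of which yield a
    measurable response at all).
    """
    from .parameters import default_range

    _, defaults = _build_reduced(ReducedConfig())
    model = build_reduced_network(config)
    values = {n: defaults[n] for n in model.parameter_names}
    ranges = {}
    for name, v in values.items():
        lo, hi = default_range(name)
        ranges[name] = (max(v / 10.0, lo), min(v * 10.0, hi))
    return ParameterSet(values, ranges, provenance="fitted")


def sample_parameter_sets(n: int, seed: int) -> list[ParameterSet]:
    """Matched log-uniform draws over the full reduced parameter space.

    The same draws are applied to every configuration (loops absent from a
    configuration simply ignore their constants), which pairs the counts
    between configurations.
    """
    reference = reduced_nominal_parameters(ReducedConfig())
    rng = np.random.default_rng(seed)
    return [reference.log_uniform_sample(rng) for _ in range(n)]


SAMPLE_RHS_BUDGET = 20_000
#: minimal primary-peak magnitude for a trajectory to count as responsive
MIN_RESPONSE_NM = 1.0


def _amplifies(model, params, protocol, rtol=1e-5, atol=1e-8) -> bool | None:
    """True/False for finite runs; None when integration fails.

    A sampled set counts as amplifying when the NFAT amplification index is
    >= 10%, the primary NFAT response reaches at least a minimal magnitude
    (1 nM, i.e. ~1% of the backbone concentration scale), and the NFAT
    response is transient in both windows (peak within a few hours of the
    pulse, decayed below half-peak at the window end). The magnitude floor
    excludes sub-noise responses whose index is integrator artefact; the
    transiency requirement excludes parameter sets whose apparent
    "amplification" is passive carry-over of an undecayed primary response
    rather than a stronger evoked secondary response.
    """
    try:
        traj = simulate(model, params, protocol, rtol=rtol, atol=atol,
                        max_rhs_evals=SAMPLE_RHS_BUDGET)
    except (SimulationError, BaselineError, OverflowError):
        return None
    if not np.all(np.isfinite(traj.states)):
        return None
    res = amplification_index(traj, "NFATnuc")
    if not (res.defined and res.AI_pct >= AMPLIFICATION_THRESHOLD_PCT):
        return False
    t = traj.time_h
    s = traj.series("NFATnuc") - traj.baseline_of("NFATnuc")
    for (lo, hi), pulse in zip(protocol.response_windows, protocol.pulses):
        m = (t >= lo) & (t < hi)
        i = int(np.argmax(s[m]))
        peak, t_peak = s[m][i], t[m][i]
        if peak < MIN_RESPONSE_NM or not (pulse.start <= t_peak <= pulse.start + 6.0):
            return False
        if s[np.searchsorted(t, hi - 1e-9) - 1] > 0.5 * peak:
            return False
    return True


def robustness_count(
    config: ReducedConfig,
    n_sampled: int = 400,
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    samples: list[ParameterSet] | None = None,
    control: RobustnessResult | None = None,
) -> RobustnessResult:
    """Count sampled parameter sets with NFAT amplification (AI% >= 10).

    Sampling is log-uniform within the biological ranges; failed
    integrations count as non-amplifying (and are reported separately).
    When a control result is given, a two-proportion z-test compares the
    amplifying fractions.
    """
    if n_sampled < 50 and samples is None:
        raise ValueError("need n_sampled >= 50 for a meaningful count")
    if protocol is None:
        protocol = make_sequential_pulses(1.0, 1.0)
    if samples is None:
        samples = sample_parameter_sets(n_sampled, seed)
    model = build_reduced_network(config)
    n_amp = n_fail = 0
    for ps in samples:
        outcome = _amplifies(model, ps, protocol)
        if outcome is None:
            n_fail += 1
        elif outcome:
            n_amp += 1
    p = None
    if control is not None:
        counts = np.array([n_amp, control.n_amplifying])
        nobs = np.array([len(samples), control.n_sampled])
        if counts.sum() > 0:
            p = float(proportions_ztest(counts, nobs)[1])
        else:
            p = 1.0
    return RobustnessResult(config, len(samples), n_amp, n_fail, p)


def removal_study(
    n_sampled: int = 400,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
) -> dict[str, RobustnessResult]:
    """Remove each loop from the full reduced model; compare vs control."""
    samples = sample_parameter_sets(n_sampled, seed)
    control = robustness_count(ReducedConfig(), samples=samples, protocol=protocol)
    out = {"control": control}
    for loop in ("f1", "f2", "f3", "f4"):
        cfg = ReducedConfig().without(loop)
        out[loop.upper()] = robustness_count(cfg, samples=samples, protocol=protocol,
                                             control=control)
    return out


def incremental_addition_study(
    n_sampled: int = 400,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
) -> dict[str, RobustnessResult]:
    """Add loops to the F1-only model; compare each configuration vs F1-only."""
    samples = sample_parameter_sets(n_sampled, seed)
    base = robustness_count(ReducedConfig(True, False, False, False),
                            samples=samples, protocol=protocol)
    out = {"F1": base}
    configs = {
        "F1+F2": ReducedConfig(True, True, False, False),
        "F1+F3": ReducedConfig(True, False, True, False),
        "F1+F4": ReducedConfig(True, False, False, True),
        "F1+F2+F3": ReducedConfig(True, True, True, False),
        "full": ReducedConfig(True, True, True, True),
    }
    for label, cfg in configs.items():
        out[label] = robustness_count(cfg, samples=samples, protocol=protocol,
                                      control=base)
    return out
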