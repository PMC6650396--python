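# Methods

## The model

`nfatnet` implements an ODE kinetic model of the signalling network
downstream of T-cell receptor (TCR) engagement, centred on the
calcineurin–NFAT axis. MHC engagement (the model input, a dimensionless
piecewise-constant multiplier `u(t)`) phosphorylates TCR; active TCR drives
Ca²⁺-dependent activation of calcineurin (CN → CaCN); active calcineurin
dephosphorylates cytoplasmic NFAT, which translocates to the nucleus
(NFATcyt → NFATnuc) and transcribes its target programme — IL-2 (via an
mRNA intermediate), FasL, TNFα, CTLA-4, RCAN and Carabin. The Ras/MEK/ERK
and PI3K/Akt/GSK3β branches run in parallel: Akt phosphorylates and
inactivates GSK3β, the kinase that re-phosphorylates nuclear NFAT and
drives its export, so PI3K signalling prolongs NFAT residence. Kinetic-law
assignment follows interaction type: Hill kinetics for transcription,
Michaelis–Menten for enzyme catalysis, mass action for
binding/conversion/decay steps. Units are nM and minutes internally; the
public API uses hours.

Eleven annotated feedback links shape the response (sign = net effect on
nuclear NFAT): NFAT/NFAT auto-induction, pRCAN/CN, TNFα/TAK1, PI3K/Akt,
Akt/GSK3 and PI3K/Rac1 positive; RCAN/CN, Carabin/CN, Carabin/Ras,
CTLA4/TCR and CTLA4/PP2A negative. A link's *strength* is operationalized
as a common multiplicative factor on its controlled kinetic constants, a
property of the `ParameterSet`, so perturbations never mutate the network
object.

### Mechanistic choices that matter

* **Amplification memory.** The secondary response (48 h after the primary)
  is amplified because the primary response leaves two long-lived protein
  memories: an enlarged NFAT pool (auto-induction with a ~58 h protein
  half-life) and an enlarged RCAN/pRCAN pool whose phosphorylated form
  captures active calcineurin into a *hyperactive* complex (CN·pRCAN,
  catalytically stronger than CaCN). The negative memories are Carabin
  (catalytic deactivation of CaCN, saturating at low CaCN so the brake is
  near zero-order — a threshold-like inhibition) and CTLA-4 (desensitizes
  TCR activation; also activates PP2A, the Akt phosphatase).
* **Ultrasensitive trigger.** CN activation saturates in phospho-TCR at a
  very low half-activation constant, so the *trigger* for the secondary
  response is almost independent of the secondary pulse amplitude over
  three orders of magnitude — this is what makes NFAT amplification robust
  to a 1000-fold weaker secondary stimulus while an absent stimulus
  produces no response at all.
* **Carabin resolves to inactive CN.** The CN·Carabin encounter complex
  turns over quickly, returning calcineurin to the *inactive* pool and the
  inhibitor to the free pool. Modelling Carabin as a consumable
  stoichiometric buffer instead makes the brake irrelevant (tens of nM of
  inhibitor against thousands of nM·min of activation flux).
* **CnI binds active calcineurin.** The generic calcineurin inhibitor is a
  reversible binder of the Ca²⁺-activated conformation; the complex
  resolves to inactive CN and free inhibitor. This competition acts where
  removal fluxes already crowd the secondary response (Carabin brake,
  pRCAN capture) but meets no competition during the primary response —
  the asymmetry that produces monotone suppression of the primary
  responses together with a biphasic secondary FasL/NFAT dose–response
  and a therapeutic window (primary IL-2 halved while secondary FasL stays
  within 80% of its dose-curve maximum). An earlier variant binding the
  *inactive* pool produced strictly monotone dose curves and no window.
* **TCR desensitization.** Phospho-TCR internalizes (fast) and recycles
  (hours), giving the 5-minute receptor-proximal peak during an hour-long
  pulse and contributing to the depletion group at the secondary response.

### Nominal parameterization

The package ships a nominal ("calibrated") parameter set constructed
during model development so that the documented qualitative behaviours
emerge simultaneously: ≥2-fold secondary/primary NFAT peak (nominal ≈
2.6), ≥10-fold FasL induction (nominal ≈ 20), transient NFAT (peak ≈ 1.9 h
after the pulse, fully decayed by the window end), the three-way response
classification (NFAT, FasL, CN·RCAN, RCAN, pRCAN, IL-2, Carabin amplified;
pTCR, CaCN, aRas, pERK, aPI3K, pAkt depleted), biphasic NFAT/NFAT and
monotone TNFα/TAK1 strength scans with a flat RCAN/CN scan, and the CnI
window. All constants respect the biologically plausible ranges used for
fitting and sampling (association 10⁻⁴–10⁴ nM⁻¹min⁻¹; first-order and
catalytic rates 10⁻⁴–10⁴/10⁵ min⁻¹; maximal velocities 10⁻⁴–10⁴
nM min⁻¹; Michaelis constants 10⁻⁴–10⁵ nM). Degradation constants, which
have no published range, are bounded to 10⁻⁴–10⁻² min⁻¹ (protein/mRNA
half-lives of roughly 1–115 h); Hill exponents are structural constants,
not fitted. One classification difference from the source analysis is
accepted: CTLA-4 (and other sustained species) classify as *amplified*
rather than *no change* under our baseline-subtracted AUC definition,
because their slowly decaying primary induction accumulates into the
secondary window; the memberships of the amplification and depletion
groups listed above are unaffected.

## Calibration

The objective is a weighted sum of squared residuals between
max-normalized simulated and target curves plus smooth hinge penalties for
the qualitative constraints (NFAT fold ≥ 2, FasL fold ≥ 10 — peak
amplitudes within each 48 h response window — and transiency: peak within
6 h of the pulse, terminal window value < 0.5 × peak). Integration
failures cost a finite penalty ceiling so the optimizer never throws. The
optimizer is a generational GA in log10 parameter space clipped to the
biological ranges: tournament selection (k = 3), uniform crossover (0.7),
Gaussian log-space mutation (default σ = 0.3 decades at rate 0.15),
2-elite, fully seeded; the default calibration run (population 32, ≤ 25
generations, early-stopped when the constraints hold and the residual
stalls) takes a few minutes on one core. Curves are normalized to their
own maximum because the emulated measurements are in arbitrary relative
units; target weights are equal by default.

When re-calibrating against the synthetic fixtures, the search is bounded
to ±0.2 decades around the shipped calibrated values
(``local_refinement_start``): max-normalized shape targets do not pin
absolute rates, so an unbounded refit can satisfy the fold constraints
while drifting out of the behaviour regime the calibration represents.
Fitting genuinely quantitative data would instead use the full biological
ranges.

## Synthetic fixture data

The fixture generator emulates the qualitative single-stimulation response
shapes of the measured components: pTCR/pMEK/pERK peak at 5 min and decay;
NFAT activity peaks around 1 h; IL-2 protein/mRNA are slow transients;
TNFα and CTLA-4 rise slowly and plateau. Curves are differences of
exponentials (plus a saturating plateau term weighted by the sustained
fraction), normalized to unit maximum, with seeded multiplicative Gaussian
noise (default 5%). They are deliberately smooth stand-ins: they carry the
peak times and shape classes of the real measurements but none of their
error structure, absolute scales, or replicate-to-replicate variation, so
a successful fit demonstrates that the pipeline recovers the stated
dynamic phenotype — not that the model quantitatively reproduces any
particular experiment.

## Amplification analysis

Responses are quantified by the baseline-subtracted area under the curve
(AUC, nM·h; trapezoidal, floored at zero) within the primary [0, 48) h and
secondary [48, 96) h windows. The amplification index is carried in two
forms: AI% = (A2 − A1)/A1·100, used for the three-way classification
(amplification ≥ +10%, depletion < −10%, no change between); and the plain
ratio A2/A1 used by the robustness and ensemble analyses. A1 = 0 yields an
explicit undefined sentinel, never an exception. Baseline subtraction uses
the pre-stimulus steady state; AUC is preferred over peak height because
several components respond abruptly and transiently.

## Feedback analyses

* **Perturbation study.** Each link is scaled by 1 ± 0.30 on top of n
  randomized backgrounds (every constant × Uniform[0.7, 1.3], clipped),
  paired with matched no-perturbation controls from the same backgrounds.
  Paired two-sided Wilcoxon signed-rank tests (pairing reflects the shared
  backgrounds and increases power); significance bands at 0.05/0.01/0.001.
  Arms with >10% failed integrations are flagged unreliable.
* **Strength scans.** Link strengths over ×10⁻² … ×10² (log grid including
  1). The response-pattern classifier labels a curve *no change* when the
  total relative variation is < 10% (reusing the ±10% convention),
  *biphasic*/*reverse biphasic* when the interior extremum clears both
  endpoints by ≥ 5%, else monotone by endpoint comparison; both
  tolerances are exposed.
* **Immune phenotypes.** FasL induction AUCs classify as AICD (primary
  silenced below 10% of the calibrated primary FasL AUC and secondary
  induced above 200%), immune deficiency (primary above 200%, regardless
  of the secondary), autoimmunity (both silenced), else other.
* **Logarithmic sensitivity.** L = [(x(p + Δp) − x(p))/x(p)]/(Δp/p), the
  one-sided finite difference at the stated fractional change (0.5 for
  feedback-suppression screens, 0.01 for derivative-like use); x = 0 gives
  a NaN sentinel. The identity L = 1 holds exactly for linear outputs at
  any Δ; power-law outputs approach their exponent as Δ → 0.
* **CnI dosing.** Constant inhibitor from t = 0; primary/secondary AUCs of
  IL-2, FasL and NFAT per dose; the therapeutic window is the largest
  contiguous dose interval with primary IL-2 below 50% of its zero-dose
  value and secondary FasL above 80% of its dose-curve maximum (both
  fractions configurable).

## Reduced four-feedback model

The reduced network keeps the backbone (MHC → pTCR → CaCN → NFAT cycle →
FasL, with TCR internalization/recycling) and phenomenological one-to-two-
reaction versions of the four dominant loops: F1 NFAT auto-induction
(positive, protein-level memory), F2 NFAT-induced phospho-RCAN enhancing
CN activation (positive; *fast* — the pRCAN pool turns over by
dephosphorylation, so the loop amplifies within a response rather than
storing inter-pulse memory; its induction threshold sits above the
un-amplified primary peak, making the boost selective for amplified
responses), F3 NFAT-induced Carabin inhibiting CN activation (negative,
protein-level memory), and F4 NFAT-induced CTLA-4 desensitizing TCR
(negative, protein-level memory). CN activation additionally requires the
stimulus itself (input-gated Ca²⁺ entry), so no signalling-level state can
ferry memory across the 48 h interval — inter-pulse memory lives in the
induced protein pools only, which is the design hypothesis the removal
study interrogates.

**Robustness counting.** Parameter sets are drawn log-uniformly within
per-parameter biological ranges of one decade either side of the
calibrated value (clipped to the generic bounds). Sampling the full
generic ranges instead (8–9 decades per constant, ~45 constants) leaves
essentially no draws with a macroscopic response — the overwhelming
majority of nominal "amplifiers" under such sampling are sub-nM integrator
artefacts — so the study explores realistic variation of a working network
rather than arbitrary rate combinations. A draw counts as amplifying when
AI% ≥ 10, the primary NFAT peak reaches ≥ 1 nM (≈1% of the backbone
concentration scale; excludes numerical noise), and the NFAT response is
transient in both windows (excludes passive carry-over of an undecayed
primary response masquerading as amplification). Configurations are
compared on *matched* draws with a two-proportion z-test (α = 0.05).

With these definitions (400 draws): removing F1 leaves < 10% of the
control's amplifying count (p ≈ 10⁻³⁰); removing F3 significantly
increases the count; removing F4 changes nothing; adding F3 to an F1-only
model significantly suppresses it. **Known limitation:** because F2 is
modelled memoryless (the property that keeps F1 the sole positive
inter-pulse store), its positive contribution to the sampled counts is
consistent in direction but not statistically significant, and the full
four-loop configuration is correspondingly below the F1-only count rather
than statistically indistinguishable from it. A reduction in which F2
carries enough memory to shift the counts significantly also amplifies
without F1, contradicting the dominant result; we keep the dominant
result.

## Ensemble modelling

Members are generated by drawing every constant log10-uniformly over
[−4, 4] within its biological range, prescreening a batch of draws by the
constraint objective (one cheap simulation each), seeding the GA
population with the most promising draws, and refining until the
constraints hold: secondary/primary NFAT peak ratio ≥ 2, primary peak ≥
1 nM, transient NFAT in both windows. The GA phase integrates at coarser
tolerances than the final validation, and evaluates candidates in two
stages — a single-pulse primary-window simulation rejects most candidates
(no macroscopic or no transient primary response) at roughly half the
integration cost before the full two-pulse objective runs; a GA run that
stalls while infeasible is abandoned, and a near-miss is given one
continuation round before its random start is discarded.
Refined sets are re-validated by an independent simulation before
retention, and retention additionally requires the AI statistic itself
(the AUC ratio A2/A1) to clear the 2-fold cut-off; failures are discarded
and redrawn (counts logged). Everything is driven by one seeded
generator.

Feedback function across the ensemble: each link suppressed by 50% in
every member, scored by the logarithmic sensitivity of the member's AI.
The strong-effect tally counts members whose score lies strictly beyond
the upper/lower quartile of the *pooled* score distribution with the
matching sign. Pooled (rather than per-link) quantiles are used because
per-link quantiles cap every link's strong fraction near 25% by
construction, which cannot express the observation that one link is
strongly influential in the majority of members; the per-link variant
remains available.

## Numerics

The reaction list compiles to a single flat ODE right-hand side (source
generation + numba JIT when available), with species concentrations
clamped at zero inside rate expressions so stiff-integrator undershoot
cannot produce negative rates or NaNs in fractional powers. Integration is
LSODA (`scipy.integrate.odeint`) segment-by-segment between pulse edges
(the input is piecewise constant, so no event handling is needed), with a
compiled finite-difference Jacobian supplied to the integrator — this
avoids one Python callback per state dimension per Jacobian update and
dominates the speed of stiff steps. Default tolerances rtol 10⁻⁶ / atol
10⁻⁹ (halving them changes NFAT/FasL AUCs by < 0.1%); the sampling-heavy
analyses use rtol 10⁻⁵ / atol 10⁻⁸ on coarser output grids. Randomly
sampled parameter sets can be arbitrarily stiff; every sampling analysis
therefore runs under a hard budget of right-hand-side evaluations per
integration (deterministic, unlike wall-clock cutoffs), and a budget
overrun counts as an ordinary failed draw. The default output grid
resolves 1-minute spacing for 2 h after each pulse and 10-minute spacing
elsewhere.

Problem sizes used by the shipped analyses: calibration GA population 32
with early stopping; perturbation study n = 300 backgrounds (scaled down
in the test suite); reduced-model robustness 400 draws; ensemble 100
members at full scale, 20 in the scaled-down reproduction runs; CnI dose
grids of ~10 points spanning 0–1600 nM.

## Limitations

* The network is built from the interactions named in the published
  description of the system; the full supplementary equation list was not
  available, so reaction granularity and all parameter values are this
  package's own reconstruction. Quantitative agreement with any specific
  measured time course is not claimed and not targeted.
* Spatial effects, stochastic (SSA) dynamics, receptor-level microcluster
  models, and downstream Fas/FasL apoptosis execution are out of scope.
* The fixture data are smooth emulations; passing calibration against them
  demonstrates pipeline correctness, not biological fit quality.
* The reduced model is a phenomenological abstraction; see the F2
  limitation above.
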