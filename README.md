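# nfatnet

Kinetic modelling and feedback analysis of the TCR–calcineurin–NFAT
signalling network in T cells.

Repeated T-cell receptor (TCR) stimulation drives activation-induced cell
death (AICD): the primary antigen encounter induces IL-2 and clonal
expansion, while re-stimulation a couple of days later induces FasL and
apoptosis. Central to this switch is a paradox — nuclear NFAT activity is
strongly *amplified* by the secondary stimulation even though the stimulus
itself is no stronger (often far weaker). `nfatnet` provides an ODE model
of the integrated TCR/CN/NFAT–IL-2/FasL network with eleven annotated
feedback links, plus the complete analysis pipeline used to dissect this
behaviour: stiff simulation of sequential-pulse protocols, genetic-
algorithm calibration against time-course data under qualitative dynamic
constraints, AUC-based amplification classification, feedback perturbation
and strength-scan analysis, calcineurin-inhibitor (CnI) dose–response with
therapeutic-window finding, a reduced four-feedback model with sampled
robustness counting, and constraint-filtered ensemble modelling. It is
aimed at systems biologists studying coupled positive–negative feedback
control of immune signalling.

## The core quantities

For a protocol of two rectangular MHC pulses at t = 0 and t = 48 h, every
species' response is summarized by the baseline-subtracted area under its
time course in the primary and secondary windows, A₁ and A₂. The
amplification index is

    AI% = (A₂ − A₁)/A₁ × 100        (classification: amplified ≥ +10%,
                                     depleted < −10%, no change between)
    AI  = A₂/A₁                     (robustness and ensemble statistic)

Calibration enforces the qualitative constraints that the secondary/primary
peak fold of nuclear NFAT is ≥ 2 and of FasL ≥ 10, with transient NFAT in
both windows. Feedback influence is scored by the logarithmic sensitivity
L = (Δx/x)/(Δp/p) at a stated fractional parameter change.

## Worked example

```python
import numpy as np
from nfatnet import (build_full_network, nominal_parameters,
                     make_sequential_pulses, simulate)
from nfatnet.amplification import network_response_map

model = build_full_network()
params = nominal_parameters()
traj = simulate(model, params, make_sequential_pulses(1.0, 1.0))

for name in ("NFATnuc", "FasL", "pTCR"):
    r = network_response_map(traj, [name])[name]
    print(f"{name:8s} A1={r.A1:9.1f}  A2={r.A2:9.1f}  "
          f"AI%={r.AI_pct:8.1f}  {r.group.value}")
```

prints

```
NFATnuc  A1=    413.4  A2=   1421.0  AI%=   243.7  amplification
FasL     A1=     39.8  A2=    861.3  AI%=  2062.3  amplification
pTCR     A1=      6.2  A2=      2.1  AI%=   -66.8  depletion
```

— the secondary NFAT response integrates to ~3.4× the primary and FasL to
~22×, while phospho-TCR itself is depleted: amplification is generated
downstream by the network's feedback structure, not by the input. The same
objects drive the higher-level analyses:

```python
from nfatnet.feedback import strength_scan, cni_dose_response, optimal_window

scan = strength_scan(model, params, "NFAT/NFAT")
print(scan.pattern.value)            # biphasic

doses = np.array([0., 50., 100., 150., 200., 300., 450., 700., 1000., 1600.])
dr = cni_dose_response(model, params, doses)
print(optimal_window(dr.doses, dr.primary["IL2"], dr.secondary["FasL"]))
# (300.0, 300.0)  -- the CnI dose that halves primary IL-2 while keeping
#                    secondary FasL near its dose-curve maximum
```

A command-line interface mirrors the library
(`nfatnet simulate|calibrate|analyze|perturb|scan|dose|reduced|ensemble|fixtures`),
writing tidy CSV artifacts and a reproducibility log per run.

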