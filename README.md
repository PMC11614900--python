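# sabrex

Simulation and analysis toolkit for **SABRE** (Signal Amplification By
Reversible Exchange) hyperpolarization experiments that read out at ¹⁵N:

* a density-matrix simulator for the broadband **phINEPT+** and
  **ESOTHERIC** spin-order-transfer (SOT) pulse sequences, which convert the
  antiphase order of the two parahydrogen-derived Ir hydrides into ¹⁵N
  polarization of the equatorially bound substrate;
* fitting machinery for hyperpolarized ¹⁵N **exchange kinetics** — the
  bound-substrate signal decays while the free-substrate signal rises as a
  function of the mixing time τₑ — yielding the complex dissociation rate
  constant k_d;
* **Eyring analysis** of k_d(T) to obtain the activation enthalpy ΔH‡ and
  entropy ΔS‡ of ligand loss;
* a **synthetic-data generator** so every fitting stage is testable against
  a known ground truth.

## The science in brief

Parahydrogen binds reversibly to an Ir–NHC catalyst together with the
substrate (pyridine, nicotinamide, acetonitrile, …).  Chemical exchange
averages the hydride singlet, leaving antiphase order
ρ ∝ E − 4 Î₁z Î₂z, which a pulse sequence can convert into ¹⁵N magnetization
through the scalar-coupling network (J_HH between the hydrides, J_NH between
each ¹⁵N and its *trans* hydride).  Exchange during the SOT block of duration
t_tot destroys a fraction of complexes, modeled as a survival factor
exp(−k_d·t_tot), with t_tot = 2(τ₁+τ₂) for phINEPT+ and 2(2τ₁+τ₂) for
ESOTHERIC.

After transfer, the bound (M_e) and free (M_f) ¹⁵N magnetizations exchange
and relax.  Globally fitting both curves with a shared biexponential

&nbsp;&nbsp;&nbsp;&nbsp;M(t) = A·e^(−Rt) + B·e^(−kt) + C

gives the slow effective relaxation rate R and the fast exchange eigenvalue
k, from which

&nbsp;&nbsp;&nbsp;&nbsp;k_d = k / (0.5 + [CsS₂]/[S])

(the complex lifetime is 1/k_d; a single chosen ligand leaves at k_d/2).
Alternatively the two-pool (CsS₂ ⇌ S₂) or three-pool (CsS₂ ⇌ CsS + S)
first-order models are fitted directly.  Temperature series of k_d are fitted
to the Eyring equation k_d = (k_B T/h)·exp(ΔS‡/R)·exp(−ΔH‡/RT).

## Worked example

```python
import numpy as np
from sabrex.exchange_kinetics import (ExchangeSystem, fit_biexp_global,
                                      kd_from_eigenvalue)
from sabrex.synthetic_data import gen_kinetics
from sabrex.spin_dynamics import preset_system, optimize_sot

# exchange kinetics: generate a nicotinamide-like dataset and recover k_d
sys_ = ExchangeSystem(k_d=8.0, c_complex=1/12.24, c_free=1.0,
                      R_e=0.07, R_f=0.07)
data, truth = gen_kinetics("simplified", sys_, noise_sigma=0.01, seed=1)
fit = fit_biexp_global(data, fit_offset=False)
kd, skd = kd_from_eigenvalue(fit.k, sys_.ratio, fit.sigma_k)
print(f"R = {fit.R:.3f} s^-1, k = {fit.k:.2f} s^-1, "
      f"k_d = {kd:.2f} +/- {skd:.2f} s^-1")

# spin dynamics: best exchange-damped ESOTHERIC working point (three-spin)
t1, t2, P = optimize_sot(preset_system("threeSpin"), "esotheric", k_d=2.7)
print(f"tau1 = {1e3*t1:.1f} ms, tau2 = {1e3*t2:.1f} ms, P = {100*P:.1f} %")
```

prints

```
R = 0.068 s^-1, k = 4.81 s^-1, k_d = 8.26 +/- 0.14 s^-1
tau1 = 15.2 ms, tau2 = 12.4 ms, P = 59.2 %
```

The fitted fast rate k is the magnitude of the fast eigenvalue of the
two-pool rate matrix, R + k_d(0.5 + r); dividing by (0.5 + r) recovers the
generating k_d within its uncertainty.  The second line is the optimal
ESOTHERIC working point when exchange at k_d = 2.7 s⁻¹ damps the transfer.

The same workflows are scriptable from the shell:

```bash
sabrex synth-kinetics --kd 8 --noise 0.01 --seed 1 --out kin.csv
sabrex fit-kinetics --input kin.csv --model eigen --out fit.json
sabrex synth-eyring --dh 79 --ds 40 --seed 2 --out rates.csv
sabrex eyring --input rates.csv --out eyring.json
sabrex simulate-sot --sequence esotheric --system threeSpin --kd 2.7 \
       --tau-max 0.04 --grid 0.001 --out map.csv
```

Every command writes a JSON run manifest (parameters, checksums, seed,
conventions in effect) next to its outputs.

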