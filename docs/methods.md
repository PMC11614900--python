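# Methods

`sabrex` models one experimental workflow end to end: transfer of
parahydrogen-derived spin order to the `15N` nuclei of substrates bound to
an Ir(IMes) SABRE catalyst, measurement of bound/free exchange kinetics via
the hyperpolarized `15N` signals, and Eyring analysis of the resulting
dissociation rate constants. This note records the models, the conventions,
and the places where a design choice had to be made.

## Spin-order-transfer simulation (`sabrex.spin_dynamics`)

**Model.** Few-spin-1/2 density-matrix simulation in the doubly rotating
frame. The Hamiltonian is

    H/2pi = sum_i nu_i Iiz
          + sum_{same channel} J_ij (Ii . Ij)
          + sum_{cross channel} J_ij Iiz Ijz

with all offsets `nu_i = 0` by default (RF carriers on resonance with the
hydrides and the equatorial `15N`). Heteronuclear couplings are truncated
to their secular zz part, valid at 9.4 T where the Larmor frequency
difference dwarfs J; the hydride-hydride coupling is kept as the full
isotropic scalar term because the two hydrides are chemically equivalent
and hence strongly coupled at any field. Pulses are ideal instantaneous
collective rotations per channel (measured 90-degree pulse widths of
~10-20 us are negligible against 1/J ~ 50 ms); the rotation convention is
`U = exp(-i theta (Fx cos phi + Fy sin phi))`, so a +90x pulse takes
Iz to -Iy.

**Initial condition.** Chemical exchange of the chemically equivalent but
magnetically inequivalent hydrides averages the parahydrogen singlet,
leaving the observable antiphase order; the default initial state is the
zz-projected singlet `rho = 2^-n (E - 4 I1z I2z)`. The full singlet
`2^-n (E - 4 I1.I2)` is available for sensitivity checks — notably, with
zero offsets it transfers nothing (its deviation commutes with every
collective proton rotation), which is itself a useful control.

**Model systems.** `threeSpin` is two hydrides plus one `15N` with
J_HH = -8 Hz, J_NHt = -22 Hz (trans), J_NHc = 0 Hz (cis) — the effective
system when only one equatorial ligand carries `15N` (natural-abundance
substrate). `fourSpin` adds the second equatorial `15N`, each coupled only
to its trans hydride, mirror-symmetrically; both nitrogens provably end
with identical polarization.

**Sequences.** The package implements both broadband transfer sequences as
explicit event lists (pulse / delay / coherence filter):

* `phINEPT+`: 45x(H) excitation — tau1 echo (simultaneous 180 on both
  channels) — simultaneous 90x(H)+90x(N) transfer pulses — tau2 echo —
  90x(H) purge. Total duration `t_tot = 2(tau1 + tau2)`. The 45-degree
  excitation is essential for zz starting order: a 90-degree pulse converts
  it entirely into zero/double-quantum terms from which no net heteronuclear
  magnetization can be extracted (verified exactly in the simulator).
* `ESOTHERIC`: 90x(H) excitation — tau1 echo — 90x(H) relay pulse — second
  tau1 echo — 90x(H)+90x(N) — tau2 echo — purge; `t_tot = 2(2 tau1 + tau2)`.
  The doubled echo block with the relay pulse also converts two-spin order
  that the single INEPT-type step leaves behind, which is why it roughly
  doubles the attainable polarization.
* `SABRE-INEPT` / `SABRE-ESOTHERIC` append a coherence filter (see below),
  a 90(N) storage pulse, the exchange interval tau_e and a 90(N) read
  pulse.

Where published diagrams leave RF phases ambiguous, phases were fixed by
the rule "choose the set that maximizes three-spin transfer"; with ideal
pulses, common phase shifts of whole pulse groups change only the phase of
the final transverse magnetization, never its magnitude, so this choice is
unique up to irrelevant global phases. Exhaustive optimization over all
pulse phases (and flip angles) of the two-echo skeleton puts its transfer
ceiling at 0.487 for the three-spin system; the implemented phase set
reaches 0.462, and the relayed echo variant 0.906 — close to, but below,
the idealized 0.5/1.0 limits usually quoted for weakly coupled systems.
These figures are a property of the strongly coupled J set above, not of
the delay choice.

**Polarization metric.** `run_sot` reports per-`15N` polarization as
`P = 2 |<I+>|` (or `2 |<Iz>|` after a storage pulse, whichever is larger),
averaged over targets. Magnitude is reported because the sign merely tracks
the parahydrogen order sign convention.

**Exchange damping.** Chemical exchange during the transfer block is
modeled multiplicatively: every map entry is scaled by
`exp(-k_d t_tot)` — the fraction of complexes that survive the whole
block intact. Explicit coupled exchange/spin-evolution superoperators are
out of scope. Relaxation during the (tens of ms) transfer block is
neglected.

**Coherence filter.** The pulsed-field-gradient filter used to clean up
line shapes is emulated as a projection of the density operator onto the
identity plus longitudinal single-spin `15N` terms; it preserves `<Nz>`
exactly and discards everything else.

**Optimization.** `optimize_sot` scans a delay grid (default 1 ms raster
over 1-40 ms on both axes, matching the experimental raster) and refines
the best grid point with Nelder-Mead clipped to the bounds. Deterministic
for fixed bounds and grid. With propagator caching, a full 40x40 damped map
of the 16-dimensional four-spin system takes well under a second.

## Exchange kinetics (`sabrex.exchange_kinetics`)

**Pools and rates.** After the transfer block, the bound `15N`
magnetization `M_e` exchanges with the free pool `M_f` during the mixing
time tau_e. The rate convention: the complex loses *a* ligand at total rate
`k_d` (complex lifetime `1/k_d`); a chosen single ligand leaves at `k_d/2`
because the two equatorial sites dissociate at the same rate. This factor
of two matters when comparing rate constants across publications.

**Two-pool model** (`simplified`, overall CsS2 <-> S2):

    dM_e/dt = -(R_e + k_d/2) M_e + k_d r M_f
    dM_f/dt = +(k_d/2) M_e     - (R_f + k_d r) M_f

with `r = [CsS2]/[S]` the bound:free concentration ratio. Chemical
concentrations are at steady state (activated catalyst); only magnetization
moves. With `R_e = R_f = R` the eigenvalues are `-R` and
`-(R + k_d (0.5 + r))`, the origin of the eigenvalue relation below.

**Three-pool model** (`full`, CsS2 <-> CsS + S) adds the mono-substrate
intermediate: dissociation (flux `k_d [CsS2]`) parks one ligand on CsS and
frees the other; re-association at `k_assoc` (default `20 k_d`, fast)
merges an intermediate-bound and a free ligand back. Steady state fixes
`[CsS] = k_d [CsS2]/k_assoc`. As `k_assoc -> infinity` the model reduces
exactly to the two-pool model (tested). The default parameterization holds
`k_assoc` fixed; it is exposed for sensitivity analysis rather than fitting
because the two bound pools are spectroscopically indistinguishable here.

**Eigenvalue analysis.** Both curves are fitted globally with
`M(t) = A exp(-R t) + B exp(-k t) + C`, sharing the slow constant `R`
(effective relaxation) and the fast constant `k` (effective exchange)
between curves, amplitudes free per curve, inverse-variance weights when
uncertainties are present, five multi-starts log-spaced in k. The
dissociation rate then follows from

    k_d = k / (0.5 + r).

Note the ratio orientation: `r` is bound:free, typically ~1/12 (many free
ligands per complex). A printed ratio of 12.24 in this system is only
consistent with the accompanying k and k_d values when read as free:bound,
i.e. `r = 1/12.24`; the package adopts that internally consistent reading
everywhere and records it in every run manifest. Strictly, the fast
biexponential constant equals `R + k_d (0.5 + r)`; the relation above
ignores the small `R` offset exactly as the eigenvalue analysis convention
does (for the typical `R ~ 0.07 s^-1` against `k ~ 4.6 s^-1`, a 1.5%
effect). Tests that need exactness use the fitted gap `k - R`.

**Uncertainties** come from the Jacobian-based covariance at the optimum;
fit degeneracy (`|k - R|/k < 1e-3`) is flagged with a warning rather than
silently reported.

## Eyring analysis (`sabrex.thermo_analysis`)

`k_d(T) = (k_B T / h) exp(dS/R) exp(-dH/(R T))` with transmission
coefficient kappa = 1. Fitting is weighted linear regression of
`ln(k_d/T)` on `1/T`: slope `-dH/R`, intercept `ln(k_B/h) + dS/R`.
Measurement errors map onto the log scale as `sigma/k_d`, giving weights
`(k_d/sigma)^2`; the parameter covariance is the known-variance form
`(X' W X)^-1` (residual-scaled when no sigmas are supplied). The noiseless
round trip is exact to machine precision and the estimator is unbiased
over seeded replicates (tested). Rate constants from the different
analyses are combined by inverse-variance weighting:
`mean = sum(k_i/s_i^2)/sum(1/s_i^2)`, `sigma = (sum 1/s_i^2)^(-1/2)`.

Constants are CODATA 2018. Thermal polarization uses
`P_th = tanh(hbar |gamma| B0 / (2 k_B T))`; for `15N` at 9.4 T and 298 K
this gives 3.27e-6, so 1% polarization corresponds to an enhancement of
~3.1e3 under this convention (published enhancement factors may assume a
different temperature or convention; the package reports its own and does
not force agreement).

## Synthetic data (`sabrex.synthetic_data`)

Generators produce exchange-kinetics datasets and Eyring tables with
known ground truth, recorded in a `TruthRecord` sidecar (parameters, noise,
seed; regeneration with the same seed is bit-identical).

* Kinetics: mechanistic-model curves plus i.i.d. additive Gaussian noise
  (detection noise dominates); a signal-scaled heteroscedastic option
  exists. Defaults emulate the measured conditions: `k_d = 8 s^-1`,
  `R = 0.07 s^-1`, `r = 1/12.24`, 16 mixing times on [0, 20] s, denser at
  early times where the free-substrate rise (interior maximum near
  `ln(k/R)/(k - R)` ~ 1 s) lives.
* Eyring tables: rates from the Eyring equation with multiplicative
  log-normal scatter, default `dH = 79 kJ/mol`, `dS = 40 J/(mol K)` over
  278-308 K — the range and magnitudes typical of pyridine-family
  substrates on this catalyst.

What the generators do *not* emulate: spectral artifacts (phase errors,
baselines, line shapes), temperature drift, sample evaporation, and
multi-complex speciation. Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
every systematic error of a real spectrometer run.

## Numerical choices

* Propagators by eigendecomposition of the (cached) Hamiltonian; pulse
  propagators cached per (channel, flip, phase). Unitarity is preserved to
  < 1e-10 in trace and purity over full sequences.
* Kinetics ODEs solved by eigendecomposition of the rate matrix (exact),
  cross-checked against fine-step Euler integration.
* Fits: trust-region least squares (`lmfit`), 5 multi-starts log-spaced in
  the fast rate over [0.1, 100] s^-1, ties broken by SSE then by the
  smaller rate.
* Degenerate inputs: zero delays give zero transfer; `k_d = 0` decouples
  the pools; `R = k` biexponentials are flagged as degenerate.

## Known limitations

* The transfer-sequence event lists follow canonical published designs
  with phases fixed by the maximize-three-spin-transfer rule; other
  laboratories' variants of the same sequence names can differ at the
  event level (echo refocusing patterns, excitation flip), and such
  variants shift the polarization maxima by tens of percent. The map and
  optimizer machinery is agnostic: custom event lists can be simulated by
  constructing `PulseSequence` objects directly.
* No relaxation superoperators, finite pulses, field cycling, or explicit
  exchange-coupled spin evolution.
* The three-pool model's re-association rate is fixed, not fitted; the
  multi-complex speciation of substrates with several exchangeable sites is
  treated only phenomenologically (separate pools per resolved resonance).
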