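# Methods

## Scope and design

`evbscan` implements the computational Arrhenius-plot methodology for
decomposing reaction barriers into enthalpy and entropy: replicate EVB/FEP
umbrella-sampling free-energy profiles over a temperature scan, followed by
linear regression of ΔG/T on 1/T. The atomistic systems the methodology was
developed for (solvated ribosome complexes) are replaced by low-dimensional
surrogate systems constructed so that their *exact* thermodynamics — known
in closed form — equal prescribed targets. Passing tests therefore
demonstrate that the pipeline's estimators and regressions recover known
decompositions under realistic sampling noise; they do not demonstrate
anything about force fields, conformational sampling of macromolecules, or
electrostatics of real active sites, which the surrogates deliberately do
not model.

## Surrogate systems

**Solute.** One coordinate x (Å). Each diabatic state is a harmonic well
½a(x−x_i)² plus a gas-phase shift; both states share the curvature a. With
equal curvatures the energy gap X(x) = ε₁−ε₂ is linear in x, hence strictly
monotone (the binning coordinate is well defined, and the x→X Jacobian is
constant), and every mapping potential (1−λ)ε₁+λε₂ is itself a single
harmonic well, so no umbrella window is bistable and every window mixes on
the friction time scale. The well separation is fixed at 2 Å; the curvature
is sized per fixture as a = max(30, 2.5·(ΔG‡ + ½|ΔG⁰| + 8)) kcal·mol⁻¹·Å⁻²,
which keeps the calibrated coupling H₁₂ ≳ 5 kcal/mol — away from the
small-coupling cusp regime where the reweighting weights near the transition
state develop long tails.

**Bath.** n harmonic modes (default n = 12) with stiffness
k(x) = exp(log k₀ + g(x)) shared by both states; g(x) interpolates between
plateau values at the reactant, transition-state, and product positions with
quintic smoothsteps (C², zero slope at the nodes). Because k depends only on
x, the bath integrates out exactly:

    F(x;T) = E_g(x) + (n/2)·k_B T·ln(β k(x)/2π) + const.

The g-plateau differences therefore add an exactly T-linear term to the
barrier: ΔS‡ = −(n/2)·k_B·(g_TS − g_R), and likewise for the reaction
entropy via g_P. A softer transition-state environment (k_TS < k_R) gives
ΔS‡ > 0, mirroring the physical picture of an active site whose entropy
rises when it no longer needs to order itself around a localized charge.
With n = 12, the largest packaged entropy target (TΔS‡ = +7.3 kcal/mol at
298 K) needs ln(k_R/k_TS) ≈ 2.05 — a stiffness ratio of ~8, numerically
benign. A test verifies that doubling n while halving the log-ratio leaves
the decomposition unchanged.

**Fixture construction** (`surrogate.build_fixture`) alternates three exact
(oracle-based) solves until all constrained targets agree within 0.02
kcal/mol: (1) damped-Newton calibration of (α, H₁₂) against (ΔG‡, ΔG⁰);
(2) re-centering the bath nodes on the current stationary points; (3) secant
solution of (g_TS, g_P) against (TΔS‡, TΔS⁰). Because the bath nodes sit at
the stationary points and g′ vanishes there, the stationary points are
nearly T-independent and ΔG(T) is linear to better than 10⁻³ kcal/mol over
280–320 K (tested).

**Packaged fixtures.** Six systems, targets at 298 K:

| name | ΔG‡ | TΔS‡ | ΔG⁰ | TΔS⁰ | standard state |
|---|---|---|---|---|---|
| associative_water | 27.0 | −1.0 | −5.0* | 0 | 55 M |
| dissociative_water | 27.0 | +1.2 | −5.0* | 0 | 55 M |
| pt_water | 15.7 | 0* | 12.2 | 0* | 1 M |
| oh_attack_water | 17.5 | +5.9 | −5.0* | 0 | 1 M |
| pt_ribosome | 5.0* | 0* | 2.5* | −0.2 | 1 M |
| oh_attack_ribosome | 11.1 (=18.4−7.3) | +7.3 | −5.0* | 0 | 1 M |

Starred values are package defaults where no literature decomposition pins
them: hydrolysis steps default to a mildly exergonic ΔG⁰ = −5 kcal/mol
(phosphate-ester hydrolysis scale); the ribosomal proton transfer is low and
mainly enthalpic, with ΔG⁰ = 2.5 kcal/mol chosen (and configurable) so the
overall stepwise barrier ≈ 13.6 kcal/mol corresponds via Eyring to rates
above 500 s⁻¹. Standard-state labels are metadata; conversions
(−RT ln c₂/c₁) are applied downstream, never baked into potentials.

## Sampling protocol

BAOAB Langevin splitting, chosen because its stationary distribution is the
exact Boltzmann law for any stable time step and the pipeline only consumes
equilibrium averages; energy conservation is neither expected nor checked.
Units: kcal/mol, Å, K, k_B = 1.9872041×10⁻³ kcal·mol⁻¹·K⁻¹; masses 1 and
time in internal units (only configuration-space averages matter — a test
confirms barriers are invariant under mass rescaling).

Per replicate: Maxwell velocities at 1 K; 5 heating stages × 2,000 steps
from 1 K to the target temperature while a harmonic solute restraint decays
from 10 to 0 kcal·mol⁻¹·Å⁻²; 10,000 unrestrained equilibration steps; then
21 FEP windows, λ evenly spaced on [0,1], run sequentially with
configuration hand-off, each with 2,000 equilibration and 120,000 sampling
steps (dt = 0.01, friction 1.0, recording stride 10). A build-time check
enforces dt·ω_max < 0.5. All parameters are overridable via
`SamplingProtocol`.

Two protocol choices deserve explanation:

* **Sampling length.** 120,000 steps/window puts the per-replicate barrier
  noise at a few 0.01 kcal/mol. The entropy is the *intercept* of the
  regression of ΔG/T on 1/T over a narrow 1/T range — a long extrapolation
  that amplifies per-temperature noise by roughly a factor 19·σ(ΔG) — so
  recovering TΔS terms of order 0.2–7 kcal/mol to a few tenths requires
  per-temperature errors well below 0.1 kcal/mol. Shorter protocols
  reproduce the noisier regime (per-temperature s.e.m. of a few tenths of a
  kcal/mol) if that is what one wants to study.
* **Common random numbers.** Segment seeds derive from
  `SeedSequence(master, (replicate, segment))` — deliberately *without* the
  temperature — so a replicate sees the same noise realization at every
  temperature of the scan. Replicate estimator errors are then nearly
  constant across the 20 K window, and a T-constant error cancels exactly
  from the Arrhenius intercept (it perturbs only ΔH, by well under the
  quoted precision). Every window remains independently reproducible from
  the master seed.

## Free-energy estimators

* **Window offsets**: Zwanzig exponential averages, evaluated with
  log-sum-exp shifts. The default chain averages the forward and negated
  reverse estimate of each edge; one-sided chains carry a systematic
  exponential-averaging bias (measured at ~+0.12 kcal/mol over a full
  21-window ladder at short sampling) that the two-sided average cancels at
  no extra cost. The forward/reverse discrepancy doubles as the
  thermodynamic-cycle-closure diagnostic.
* **Profiles**: within each window, ground-state energies are reweighted
  onto 50 bins of the energy gap; where several windows populate a bin the
  one with the larger count owns it (the classic EVB umbrella-sampling
  assembly; no WHAM/MBAR). Bins whose owner contributes fewer than 10
  samples are flagged unusable, never interpolated. Profiles are anchored to
  zero at the reactant-side minimum; barriers and reaction free energies are
  read from stationary points refined by three-point quadratic fits.
  Profiles whose usable bins are monotone raise a "no barrier" error rather
  than reporting zero.
* **Replicate statistics**: per-temperature mean and s.e.m.
  (= sd/√n, n ≥ 2) over independent replicates — the across-replicate error
  model; no within-trajectory block averaging.
* **Residual bias**: the transition state is the *maximum* over noisy bins,
  so finite sampling biases ΔG‡ slightly upward; the effect decays as
  1/(sampling length) (measured: +0.055 → +0.010 kcal/mol from 60k to 240k
  steps/window) and is temperature-constant, so it cancels from recovered
  entropies.

## Regressions and conversions

ΔG/T against 1/T by ordinary least squares (slope ΔH, intercept −ΔS), with
R², rms residuals in entropy units (1 e.u. = 1 cal·mol⁻¹·K⁻¹ ≈ 0.3 kcal/mol
of TΔS at 298 K), and the 2×2 parameter covariance; inverse-variance
weighting is available behind a flag but off by default, matching the
convention that the regression rather than the per-point s.e.m. sets the
uncertainty. T_ref = 298 K throughout. Stepwise combination adds
(ΔH, ΔS, covariance) of a pre-equilibrium van't Hoff fit and an attack-step
Arrhenius fit. Eyring rates use CODATA k_B and h (prefactor 6.25×10¹² s⁻¹ at
300 K).

## Calibration

`calibrate` solves (α, H₁₂) — or α alone when no reaction target is given —
against oracle-evaluated (ΔG‡, ΔG⁰) at T_ref by damped Newton with
finite-difference Jacobian, 2 kcal/mol step cap, 0.01 kcal/mol tolerance,
100-iteration cap. Oracle-based calibration mirrors the practice of
calibrating EVB models once against known solution free energies; sampled
verification is a separate test (agreement within twice the replicate
s.e.m.). The same H₁₂ is kept when a model moves between environments.

## Numerical choices

Oracle curves are evaluated on 2,001-point grids (stationary points refined
quadratically; a 2× Richardson refinement bounds the residual error,
typically <10⁻⁵ kcal/mol). Exact entropies come from central differences of
the oracle barrier over T_ref ± 5 K plus a linearity audit over 280–320 K.
Degenerate inputs fail loudly: flat or monotone profiles, non-monotone gaps,
coverage holes between windows, unstable time steps, non-finite energies,
and unreachable calibration targets all raise diagnostic errors.

## Limitations

The surrogates encode thermodynamics only: no geometry, no Mg²⁺/histidine
chemistry, no solvent structure, no geometry-dependent coupling, at most two
states per step (the stepwise mechanism is two independent two-state
systems, combined additively). The bath is strictly separable given the
solute coordinate — exactness of the reference decomposition was valued over
physical literalism. Heat-capacity effects (ΔCp ≠ 0) are outside the model:
ΔG(T) is linear by construction and the fits are linear by design.
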