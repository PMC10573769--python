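# Methods

This note records the model conventions, numerical choices and known
limitations of `chronodose`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the package does not itself reproduce.

## Pharmacokinetic models

All three families share the oral chain: an impulsive dose `u` (mg) enters
the gut compartment as `F·u` (the bioavailability fraction `F` is folded
into the input, so the unabsorbed fraction never appears in the mass
balance), is absorbed into plasma at `ka` (1/min) and eliminated from plasma
at `ke` (1/min). States are masses (mg); concentrations are `yp = x2/Vp` and
`yb = x3/Vb` (mg/mL). Time is minutes everywhere; hour-denominated inputs
are converted at call boundaries.

Family-specific brain transfer:

| family | plasma→brain flux | notes |
|---|---|---|
| passive diffusion | `kbb·x2` | first-order, concentration-driven |
| carrier-mediated | `Vmax·yp/(km + yp)` | saturable, `km` a plasma concentration |
| nanoparticle transcytosis | `kbb·x2 − kebb·x3` | reversible endo-/exocytosis |

Two conventions deserve comment:

- **`km` as a concentration.** The published parameter table gives `km` in
  mg/mL while the accompanying text calls it a mass; the compartment diagram
  defines it as "the plasma concentration at half of `Vmax`", which is also
  the standard Michaelis–Menten usage. The package therefore evaluates the
  carrier flux against `yp`, equivalent to a half-saturation mass of
  `km·Vp`. This reading reproduces the amine (choline) validation row to
  ~5–10% where the mass reading is off by orders of magnitude.
  `PKParams(km_is_concentration=False)` selects the mass reading.
- **Nanoparticle plasma elimination.** The printed nanoparticle ODEs omit
  `−ke·x2`, but the model diagram states first-order plasma elimination is
  included; the package includes it by default and exposes
  `plasma_elimination=False` for the literal printed system (under which
  total mass is conserved after absorption — a property test covers this).

Doses at the same timestamp are summed; dose times must align with the
integration grid. The percent-of-dose brain profile divides `x3` by the
*effective* (bioavailable) dose `F·Σu` by default; the raw-dose denominator
is available and the validation report records which was used.

## Consistency of the published values

The packaged parameter table is the published one, verbatim. Several of the
published validation summaries cannot be produced from it, under any unit
convention we tested (rates per hour or per 5-min sample, mass vs
concentration `km`, raw vs effective dose, with/without nanoparticle plasma
elimination):

- The passive-diffusion plasma peak of 4.67×10⁻⁶ mg/mL would require a peak
  plasma mass of 0.84 mg, three times the entire bioavailable dose
  (0.14 × 2 mg); with the printed rates the model yields 4.6×10⁻⁷ mg/mL.
  (With `Vp = 1.8×10⁴ mL` instead of the printed 1.8×10⁵ the printed rates
  give 4.77×10⁻⁶ — suggestive of an exponent typo, but the package does not
  second-guess the printed table.)
- The T3 plasma peak of 3.81×10⁻⁶ mg/mL implies a plasma mass larger than
  the whole 0.05 mg dose.
- The passive-diffusion brain peak of 30.70% of dose exceeds the hard upper
  bound `kbb/(ke + kbb) = 29.17%` on the fraction of absorbed mass that can
  ever reach the brain with the printed rates.

The validation report therefore prints estimated and published values side
by side with relative errors and flags every gap above 10% instead of
absorbing it. The rows that are internally consistent (amine brain peak and
peak time, amine plasma Cmax, nanoparticle brain peak) are reproduced within
10%; the flagged rows fail by construction of the published table, not by a
property of the simulation (the integrator is verified against an adaptive
reference to 10⁻⁶ relative on all five parameter sets).

## Numerics

`simulate_pk` uses classical RK4 with a 0.5-min internal step and 5-min
output sampling. The half-minute step keeps the stiffest packaged set (the
passive model, fastest mode ≈ 0.155/min) within 2.2×10⁻⁷ relative of an
LSODA reference at rtol 10⁻¹²; a 1-min step gives 3.8×10⁻⁶. A forward-Euler
mode exists for consistency with the estimator's discretization. The
mass-balance oracle integrates the elimination flows with cumulative
Simpson quadrature; residuals stay below 10⁻⁴ of the effective dose on a
1-min grid (dominated by quadrature of the sharp post-dose transient, not by
integration error). The 5-min reporting grid resolves the sharp passive
plasma transient (peak ≈ 8 min post-dose) only to ~4%, which bounds how
reproducible AUC/Cmax are across reporting grids.

## Extended Kalman filter

The augmented state is `(x1, x2, x3, Vb)` under the forward-Euler map at
5-min sampling, with `Vb(k+1) = Vb(k)`. Measurement units: the published
covariances `R = diag(100, 100)`, `Q = diag(0, 0, 0, 10⁻⁴)` are physically
meaningless against outputs of order 10⁻⁷–10⁻⁶ mg/mL, but natural on the
pg/mL scale on which melatonin immunoassays report (≈10 pg/mL noise floor
against signals of hundreds of pg/mL). The filter therefore scales both
outputs by `output_scale = 10⁹` (mg/mL → pg/mL); synthetic CSF fixtures add
zero-mean Gaussian noise with covariance `R` on that scale.

Defaults and safeguards: the standard gain `P·Cᵀ(C·P·Cᵀ+R)⁻¹` (the published
typesetting premultiplies by `A`; selectable via `literal_gain=True`),
Joseph-form covariance update with symmetrization (`joseph_form=False` for
the literal `(I−KC)P` form), a positive floor on the `Vb` estimate so `1/Vb`
stays defined, and a default prior `P0` with a (50% of the initial guess)²
variance on `Vb`. The initial guess convention is `Vp·AUC(yp)/AUC(yb)` from
the measured record. On synthetic 12-h passive-diffusion records the median
terminal `Vb` error over 20 seeds is below 10% starting 50% off truth in
either direction (a test computes this).

## Circadian layer and the surrogate ipPRC

The clock is a phase oscillator `φ̇ = ω + B(φ)·v` with `ω = 2π/1440` rad/min
and no light input. The published ipPRC was derived in cited work from a
molecular clock model and is not reproduced here; `B` is a configuration
input (tabulated knots, periodic cubic interpolation) with a packaged
single-harmonic surrogate `B(φ) = A·sin(φ + ψ)`, defaults `A = 1`, `ψ = 0`.
Positive `B·v` advances phase.

The drug input is `v = min(gain·yb, v_cap)`:

- `v_cap = 3ω` stands in for the ceiling on the targeted clock process (the
  motivating compound cannot suppress cryptochrome degradation beyond a
  fixed fraction); at ceiling the clock can at most triple or invert its
  speed, consistent with the strong period lengthening such compounds show
  at saturating concentrations.
- `gain` is *ceiling-normalized per substrate*: a single dose at the
  published cumulative bound `u_max` drives the peak brain concentration
  exactly to `v_cap`. This mirrors the published rationale that `u_max` was
  chosen for each substrate so that the maximal brain level corresponds to
  the same saturating clock effect, and it avoids per-substrate hand tuning:
  with potency normalized, what differentiates the transport systems in
  closed loop is their kinetics (onset and clearance), which is the
  scientific comparison of interest.

Because the surrogate replaces the (unavailable) published ipPRC, closed-
loop results are reported as properties — full resets achieved, relative
ordering of transport systems — not as reproductions of the published reset
times. Under the surrogate the loop yields: passive diffusion 52 h / 50 h
(advance/delay; published 60/66), amine 6/36 (50/54), neutral amino acid
4/36 (30/48, fastest in both), T3 34/70 (published: advance never, delay
72), nanoparticle never/never (published: advance never, delay 84). The
published qualitative pattern — neutral amino acid fastest, nanoparticle
slowest and failing the advance, slow T3 kinetics causing dose build-up —
is reproduced; exact times are not expected to match.

## Controller

Sampling `τ = 120` min, horizon `Np = 3`, weights `w_φ = 1` and the
published per-substrate `w_u`, cumulative bound `0 ≤ Σu_ℓ ≤ u_max` per
horizon, dead zone `δ_φ = 0.1` rad (interpreted in radians: it thresholds a
phase distance). Doses are impulses at step starts. The predictor
co-simulates PK and phase with the same RK4/1-min scheme the surrogate
plant uses, so a matched plant is predicted exactly.

The horizon cost is nonconvex through `B(φ)`, so the solver is a
deterministic multistart — the lattice `{0, u_max/2, u_max}^Np` filtered by
the cumulative bound and always containing the all-zero sequence — followed
by Nelder-Mead refinement with bound handling by projection; the refined
point is accepted only if it improves the incumbent, so the reported cost
never exceeds the best lattice cost, and for `Np = 1` the solution is
verified against brute-force enumeration in the tests. A seed argument
controls optional extra random starts (none by default, so runs are
deterministic for a given configuration).

The gut-saturation guard zeroes the remaining horizon doses whenever the
predicted gut mass reaches `gi_cutoff_fraction·u_max` (default fraction 1),
bounding gut accumulation by one dose above `u_max`.

"Complete reset" (no published definition) is the first entry into the
dead zone after which the error stays inside for 24 consecutive hours,
truncated at the next shift event or the scenario end — without truncation
a reset occurring within a day of the next event (as the published passive
advance time does) could never be certified.

## Scenario conventions

The canonical scenario applies a 5-h advance at t = 0 and an 11-h delay at
t = 72 h, runs 10 days, and uses the published per-substrate `(u_max, w_u)`.
Reference phase shifts are instantaneous offsets of `φ_r(t) = ω·t + offset`.
Runs are deterministic: identical spec and seed give byte-identical CSV
logs (a test checks this).

## What the synthetic data does and does not show

The EKF fixtures share the generating discretization with the filter and
add white Gaussian noise at the filter's assumed covariance, so recovery
results certify the estimator under matched conditions; real CSF records
would add model mismatch, colored noise and sparse sampling. The closed-loop
plant is the same phase-reduction the controller uses (optionally perturbed
in `ω` and PRC scale), not a molecular clock model: convergence results
certify the dosing logic under bounded mismatch, not performance against
full clock dynamics. Amplitude effects near the oscillator's singularity,
light input, multi-compartment GI physiology, protein binding and toxicity
constraints are all out of scope.
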