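# chronodose

Model-based drug dosing for resetting a misaligned circadian clock.

Jet lag and shift work desynchronize the endogenous ~24-h clock from local
time. Small molecules that act on the core clock (the motivating example is
KL001, which slows nuclear cryptochrome degradation; melatonin is the
familiar passive-diffusion analogue) can shift circadian phase much faster
than light schedules — but only the fraction of an oral dose that crosses the
blood–brain barrier (BBB) acts on the clock. `chronodose` couples oral
pharmacokinetics of BBB transport to a phase-reduced circadian oscillator
and closes the loop with a receding-horizon dosing controller. It is aimed
at systems-pharmacology and control researchers studying the feasibility of
pharmacological re-entrainment.

## The models

**Pharmacokinetics.** Three-compartment mass-balance models (gut `x1`,
plasma `x2`, brain `x3`, all mg; oral doses enter as impulses of `F·u` with
bioavailability `F`), with three BBB transport mechanisms:

- *passive diffusion* — first-order transfer,
  `ẋ2 = ka·x1 − (ke + kbb)·x2`, `ẋ3 = kbb·x2 − kebb·x3`;
- *carrier-mediated transport* (amine, neutral amino acid, T3 systems) —
  saturable Michaelis–Menten flux `Vmax·yp/(km + yp)` with `yp = x2/Vp` the
  plasma concentration;
- *polymeric nanoparticle transcytosis* — first-order reversible exchange
  `kbb·x2 − kebb·x3` with plasma elimination.

Outputs are concentrations `yp = x2/Vp`, `yb = x3/Vb`. Five published
parameter sets (one per transport system) are packaged, together with the
published clinical validation doses and exposure summaries.

**Estimation.** The brain distribution volume `Vb` is not directly
measurable; it is estimated by an extended Kalman filter that appends `Vb`
as a constant fictitious state to the forward-Euler discretization
(5-min sampling) of the PK model and filters noisy plasma/CSF concentration
records (pg/mL scale, `R = diag(100, 100)`, `Q = diag(0, 0, 0, 10⁻⁴)`).

**Control.** The clock is phase-reduced: `φ̇ = ω + B(φ)·v`, `ω = 2π/24 h`,
where `B(φ)` is an infinitesimal parametric phase response curve (ipPRC) and
`v` the drug input at the brain, `v = min(gain·yb, v_cap)`. The controller
minimizes, over an `Np = 3` step horizon with sampling `τ = 2 h`,

```
Σ_ℓ  w_φ·g(h(χ̂_ℓ))² + w_u·u_ℓ²     s.t.  0 ≤ Σ u_ℓ ≤ u_max
```

with `h(χ) = min(χ, 2π−χ)` the circular phase distance to the reference
clock, `g` a dead zone (`δ_φ = 0.1` rad) that ignores small errors, and a
gut-saturation guard that suspends dosing when the GI compartment
approaches `u_max`. Only the first optimal dose is applied (receding
horizon). The published ipPRC is not available, so a single-harmonic
surrogate `B(φ) = sin φ` is packaged and all closed-loop results are
properties under that surrogate (see `docs/methods.md`).

## Worked example

Validate the amine-carrier model against its published choline study
(550 mg oral dose, 12-h horizon):

```sh
$ chronodose validate-pk --model carrier_amine
carrier_amine (dose 550 mg, percent-of-dose denominator: effective)
  plasma AUC  est 1.447e-01  reported 3.000e-01  rel.err -51.8%
  plasma Cmax est 2.529e-03  reported 2.300e-03  rel.err +10.0%
  brain peak  est 0.240%  reported 0.23%  rel.err +4.3%
  brain Tmax  est 45 min  reported 50 min
  ! exceeds 10% of the published value: plasma AUC (systematic; ...)
```

The brain exposure (0.240% of the bioavailable dose, peaking 45 min after
ingestion) and the plasma peak agree with the published study; the plasma
AUC does not, and the report flags rather than hides it — several published
summary values are mutually inconsistent with the published parameter table
(`docs/methods.md`, "Consistency of the published values").

Run the canonical jet-lag scenario (a 5-h phase advance at t = 0, an 11-h
delay three days later, 10 days total) for the neutral-amino-acid carrier:

```python
from chronodose import ScenarioSpec, run_jetlag_scenario
result = run_jetlag_scenario(ScenarioSpec(model="carrier_neutral_amino_acid"))
print(result.summary())
# 5-h advance at 0 h: reset in 4.0 h; 11-h delay at 72 h: reset in 36.0 h;
# total dosed mass 12.22 mg
```

A reset time is the first entry into the dead zone after which the phase
error stays inside for 24 h (truncated at the next shift event); under the
surrogate ipPRC the neutral-amino-acid system is the fastest of the five and
the nanoparticle system fails to re-entrain within 10 days, reproducing the
published ordering of transport mechanisms.

The same experiments are available from the shell:

```sh
chronodose simulate-pk --model passive_diffusion --dose 2 --out traj.csv
chronodose estimate-vb --model passive_diffusion --seed 1 --out ekf.csv
chronodose run-mpc --model carrier_amine --days 10 --out mpc_log.csv
```

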