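# Methods

`pklump` implements a three-model pharmacokinetic compatibility study: a
whole-body physiologically based (PBPK) model, its reduction to a lumped
model by proper lumping, and classical one/two-compartment models, with a
comparison layer that quantifies how far the three agree for a given drug.

## Whole-body PBPK model

The body is fourteen drug-holding compartments: eleven systemically
perfused tissues (adipose, bone, brain, gut, heart, kidney, liver, muscle,
skin, spleen, and a rest-of-body remainder), the lung, and separate
arterial and venous blood pools.  Distribution is perfusion-rate limited:
each tissue takes up drug at its blood flow `Q_T` and arterial
concentration `C_A`, and returns it at its emergent venous concentration
`C_T / (Kp_T / BP)`, where `Kp_T` is the tissue:plasma partition
coefficient and `BP` the blood:plasma ratio:

    V_T dC_T/dt = Q_T (C_A − C_T/(Kp_T/BP))                (non-eliminating)
    V_T dC_T/dt = Q_T (C_A − C_T/(Kp_T/BP)) − fu·CL_T·C_T/(Kp_T/BP)   (liver, kidney)

Venous blood collects the tissue returns, passes through the lung, and
re-enters the arterial pool.  Splanchnic wiring follows standard whole-body
topology: gut and spleen drain into the liver (portal vein), and the liver
receives a hepatic-arterial supply, so its total inflow is
`Q_li = Q_ha + Q_gut + Q_spleen`; gut and spleen are accordingly excluded
from the direct venous return.  This wiring is what produces hepatic
first-pass loss mechanistically for oral doses (first-order depot with rate
constant `Ka` emptying into the gut); no explicit bioavailability parameter
exists.

Elimination is restricted to liver and kidney.  Hepatic clearance may be
given directly or derived from an intrinsic clearance by the well-stirred
liver model `CL_hep = Q_li·fu·CL_int/(fu·CL_int + Q_li)`, which is bounded
by the hepatic blood flow.

**Units** are fixed package-wide — mg, L, h — so concentrations are mg/L
and clearances L/h; per-kilogram values (L/kg, L/h/kg) appear only in
report tables, divided by body weight.

**State variable and solver.** The integrator state is the *amount* per
compartment, which makes the whole system a constant-coefficient linear
ODE `dy/dt = A y` with an exact, constant Jacobian.  `scipy`'s BDF solver
is used at `rtol 1e-8 / atol 1e-10` (configurable): partition coefficients
spanning orders of magnitude make the rate matrix badly scaled, so a
stiff-capable method is the safe default.  A cumulative elimination sink is
carried as an extra state; because the matrix columns sum to zero, mass
balance (`Σ amounts + eliminated = dose`) is an exact structural property
and is verified to `< 1e-6` of the dose on every pipeline run (measured
`~1e-14`).

**Closed-form checks.** At the AUC level the model admits exact identities
used as oracles throughout the test suite: for an IV bolus the venous
`AUC(0,∞)` equals `dose / CL_b` with

    CL_b = fu·CL_hep·Q_li/(Q_li + fu·CL_hep) + fu·CL_ki·Q_ki/(Q_ki + fu·CL_ki)

and an oral dose scales this by the hepatic first-pass availability
`F = Q_li/(Q_li + fu·CL_hep)` (complete absorption assumed).

## Default physiology

A bundled 70-kg reference adult (cardiac output 390 L/h) compiled from
standard reference tables; every value is config-overridable.  The
rest-of-body compartment is derived by closure: its flow is the cardiac
output minus the named tissue flows, its volume the total body volume
(70 L at unit density) minus the named volumes.  After closure the
flow-sum identity `Σ Q_T = Q_lung` holds exactly and is enforced by the
`PhysiologySet` validator.

## Proper lumping

Tissues with similar kinetic behaviour are merged while conserving volume,
flow and Kp-weighted capacity:

    V_lump = Σ V_T,    Q_lump = Σ Q_T,    K_lump = Σ(V_T·Kp_T) / V_lump

The default scheme merges arterial blood, venous blood and lung into the
lumped central compartment (LCEN) and the seven non-eliminating tissues
into a single NET compartment; gut, spleen, liver and kidney are retained
un-lumped (the eliminating organs, plus the portal tract that feeds the
liver and receives the oral dose).  Two conventions make this concrete:

* **Blood compartments inside LCEN** enter the `K_lump` sum with an
  effective partition coefficient equal to `BP`, so the LCEN concentration
  is a *blood* concentration (`amount / (V_lcen·K_lcen/BP)`) and drives
  tissue uptake exactly as arterial/venous blood does in the full model.
* **LCEN flow** is the cardiac output, not the sum of member flows (which
  would double-count the blood pool).

Lumping a tissue group is exact when all members share the equilibration
rate `k_T = Q_T·BP/(V_T·Kp_T)`.  The synthetic-data module can construct
such a drug (`generate_matched_kinetics_drug`); in that limit the lumped
LCEN tracks the full model's venous concentration to ~0.2% pointwise.  The
agreement is asserted for t ≥ 1 h: during the first fraction of an hour
the full model carries a venous→lung→arterial transit delay that the
reduction removes by construction, so early pointwise ratios are not
informative (the first-hour deviation is instead bounded relative to the
peak).  Perturbing a single Kp tenfold breaks the agreement by two orders
of magnitude, which the tests use as a negative control.

**Peripheral and central volumes.** The peripheral distribution volume is
`Σ V_T·Kp_T / BW` over the NET tissues (full model) or `V_net·K_net / BW`
(lumped model); by the `K_lump` definition the two are algebraically
identical, which the tests check to machine precision.  The central volume
reported for the full and lumped models is the blood-like pool
`(V_arterial + V_venous + V_lung·Kp_lu/BP) / BW`.  This is an
interpretation: a volume "where the drug is rapidly and homogeneously
distributed" could also be read as the total tissue volume, and both
variants are computable from the public API.

## Compartment models

Standard 1- and 2-compartment models with first-order absorption,
parameterised by `CL`, `Vc` (plus `Vp`, `Q` for two compartments) and
`Ka`.  Oral literature parameters are apparent (`CL/F`, `V/F`); no
bioavailability correction is applied when comparing against the
mechanistic models — the comparison is between models as parameterised,
which is flagged in reports.  The 1-compartment oral model is evaluated in
closed form (with the removable `Ka = ke` singularity handled by its
limit); the 2-compartment model runs through the same linear-ODE path as
the PBPK model, with a tri-exponential closed form available for
cross-checks and fitting.

**Fitting.** When no literature compartment parameters are supplied, the
pipeline obtains them by least squares against the lumped model's central
profile: log-parameters, log-concentration residuals restricted to points
above 1e-4 of the peak (the analogue of an assay quantification limit —
without it the numerically tiny leading edge of the profile dominates the
cost), quadrature weights so that non-uniform grids do not bias the fit,
and a small set of heuristic starts because the absorption/distribution
split of an oral profile admits local minima.  On noise-free profiles this
recovers the apparent clearance `CL_b/F` to well under 5% across a
10-drug synthetic panel (typically < 1%).

## Non-compartmental analysis

Exposure is the linear trapezoidal `AUC_last`; on simulated grids of
≥ 1000 points the linear/log-linear choice is numerically immaterial.
`AUC(0,∞)` adds `C_last/λz` with `λz` from log-linear regression on the
terminal 10% of the grid; it is used for closed-form oracle comparisons
only, never in report tables.  Full-model "central" and "peripheral"
exposures are unweighted means of per-tissue `AUC_last` over
{lung, arterial, venous} and the NET tissues respectively.

## Simulation windows and grids

Each drug is followed over a window scaled to its own persistence —
7 effective half-lives, `t_half = ln2·Vss_blood/CL_b`, clipped to
[24, 1e5] h — mirroring study designs that follow fast and slow compounds
over different intervals; a fixed window can be forced via configuration.
The default grid is the union of a geometric and a uniform grid
(`hybrid_grid`), which resolves both the absorption/blood-mixing phase and
the terminal phase; pure IV-bolus AUC oracles use the geometric grid
(`graded_grid`), since a uniform grid under-samples the initial mixing
transient and biases the trapezoid by several percent.

## Compatibility metrics

* **2-fold criterion**: two positive values are compatible when their
  ratio lies in `[0.5, 2]`, *boundaries inclusive* — required so that a
  ratio of exactly 2.0 passes while 2.009 fails, which is how the packaged
  reference tables reproduce their printed counts.  Clearance is compared
  across all three models at once via the maximum pairwise ratio.
* **Accuracy of AUC**: the lumped central exposure is converted to a
  theoretical compartment exposure through the clearance ratio,
  `AUC_theory = AUC_lcen·CL_lumped/CL_cpt`, and the accuracy is
  `AUC_cpt_observed / AUC_theory`; values near 1 indicate compatibility.
  The statistic is invariant under a common rescaling of both AUCs.
* **Vd/fu**: `(Vc + Vp)/fu` per model (`Vp = 0` for one-compartment
  drugs); the relation between models is summarised by an ordinary
  least-squares power-law fit in log-log space (`y = a·x^b`), chosen over
  nonlinear fitting for determinism.
* **Tissue back-prediction**: a full-model tissue concentration is
  reconstructed from a compartment-model peripheral concentration as
  `C_T = C_p·(Vp_cpt/Vp_lump)·(Kp_T/K_lump)`.  The factors are supplied by
  the caller; the identity is mass-consistent when the volume ratio
  converts the compartment model's apparent peripheral amount to a
  concentration over the *physical* lumped volume, which is how the
  end-to-end test applies it.

## Synthetic drug panels

The supplementary per-drug parameterisations behind the packaged result
tables are not redistributable, so simulations run on synthetic drugs.
Draws are log-uniform within ranges spanning marketed small molecules:
fu 0.01–1, BP 0.55–2, Ka 0.2–3 /h, intrinsic clearance 1–10⁴ L/h
(restrictive through flow-limited), renal clearance 0.05–10 L/h, Kp
0.2–20 per tissue; dose 100 mg oral.  Panel generation stratifies the
intrinsic-clearance axis (shuffled stratified quantiles), mirroring a
study design that deliberately selects compounds across the clearance
spectrum, so a 20-drug panel always spans hepatic extraction ratios from
below 0.1 to above 10.  All draws are reproducible from a seed.

An optional Monte-Carlo mode applies median-preserving lognormal factors
(user CV) to fu, Ka, clearances and every Kp, with replicate AUCs
summarised by the median.  It is off by default: the deterministic run is
the primary analysis, and the perturbation model is this package's own
choice rather than a documented protocol.

What the synthetic panel does *not* emulate: correlations between
parameters (lipophilic drugs have correlated Kp across tissues),
nonlinear elimination, permeability-limited tissues, enterohepatic
recycling, and multiple dosing.  Passing tests therefore demonstrate the
internal consistency of the three models and the comparison arithmetic —
not predictive accuracy for any real compound.

## Packaged result tables

The per-compound reference tables (central AUC, peripheral AUC, clearance
for the three models, 20 compounds) are shipped as CSV fixtures and
exercise the comparison layer only; the simulation layer is tested
exclusively on synthetic drugs and analytic oracles, so the two testing
surfaces are independent.  Recomputing the 2-fold verdicts from these
tables yields the pass counts 18/20 (full vs lumped, central), 19/20
(peripheral), 17/20 (jointly), 14/20 (lumped vs compartment, central),
6 of 9 two-compartment drugs differing peripherally, 19/20 for clearance
across all three models, and 15/20 for the accuracy-of-AUC statistic —
`scripts/acceptance.py` recomputes all of them from scratch.

## Numerical choices and limitations

* Solver tolerances `rtol 1e-8 / atol 1e-10`; looser settings are safe for
  exploratory work but the mass-balance assertion assumes these.
* The 2-fold boundary is inclusive; ties at exactly 2.0 pass.
* `fit_power_law` requires ≥ 3 strictly positive pairs.
* Degenerate inputs: zero dose gives identically zero profiles; zero
  clearances give conserved mass and are rejected only where a statistic
  divides by clearance; single-point NCA returns 0.
* The lumped ODE builder supports the default two-lump scheme; parameter
  aggregation (`lump_parameters`) accepts arbitrary partitions, but
  arbitrary multi-lump circulation topologies are not wired.
* Single dose, linear kinetics, perfusion-limited tissues only.
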