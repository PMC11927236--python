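# Methods

## The model

`doxopkpd` simulates and identifies the action of doxorubicin (DOXO) on a
multiple-myeloma (MM1R) cell culture. It couples a three-compartment
pharmacokinetic (PK) description of the drug in a culture well to a logistic
pharmacodynamic (PD) law for the living-cell count.

**Drug kinetics.** Three concentrations (nM) are tracked: extracellular
`XE`, free intracellular `XF`, and DNA-bound `XB`:

    dXE/dt = k_EF(XB)·(VI/VE)·XF − k_FE·XE
    dXF/dt = k_FE·(VE/VI)·XE − k_EF(XB)·XF − k_BF·XF
    dXB/dt = k_BF·XF − γ·XB

with the saturable, bell-shaped efflux rate

    k_EF(XB) = Vmax·XB^1.31 / (kth^2.31 + XB^2.31),

reflecting P-glycoprotein induction by intracellular drug: efflux rises
from zero, peaks near `kth`, and decays as 1/XB (at `XB = kth` it equals
`Vmax/(2·kth)` exactly). The exponents 1.31/2.31 are structural constants.
The decay rate γ on the bound pool lumps dilution of intracellular drug
across cell divisions with chemical degradation; it is deliberately kept a
first-order sink on `XB` alone, and no dilution term appears elsewhere in
the PK equations. The compartment volumes `VE`, `VI` are fixed constants —
the PK subsystem does not depend on the cell count, which is what makes it
identifiable on drug-only data and lets the fitting code solve it once per
γ value.

**Dosing.** A bolus adds its concentration to `XE` instantaneously at the
event start; washout (medium replacement) resets `XE` to zero at the event
end, leaving the intracellular pools and the cells untouched. This
instantaneous-reset realization matches the experimental bolus/rinse
protocol and avoids stiff impulse forcing terms. After washout the model
lets effluxed drug accumulate in the fresh medium and re-enter, as the
equations dictate.

**Cell population.** The living-cell count obeys

    dN/dt = k_p·N·(1 − N/θ) − k_d(XB)·N,
    k_d(XB) = Kdmax·XB/(XBHS + XB),

a logistic law with a death rate that saturates in bound drug (the data
show little difference between high-dose arms, hence a maximal
rate-of-damage). The death rate acts on the shared per-arm PK state — a
population-level coupling, with no per-cell heterogeneity, resistant
subclones, or nutrient dynamics. The *efficacy threshold* is the bound-drug
level where death balances proliferation, `XB* = k_p·XBHS/(Kdmax − k_p)`;
when `Kdmax ≤ k_p` it is unreachable and reported as infinite rather than
as an error.

## Reference parameter values

PK constants (fixed, not re-estimated): `Vmax = 1.65e4 nM/h`,
`kth = 464 nM`, `k_FE = 5.63e-4 1/h`, `k_BF = 1.22 1/h`, `VE = 100 µL`,
`VI = 0.07 µL`. PD/decay reference values (defaults of `PDParams` /
`PKParams.gamma`, and the generating values of the synthetic study):
`k_p = 0.0198 1/h`, `θ = 262209 cells`, `Kdmax = 0.0435 1/h`,
`XBHS = 47.5 nM`, `γ = 0.0044 1/h`, with per-arm initial counts `N0`
between ~3.4e3 and ~2.0e4 cells.

## Time conventions

Each in vitro arm is exposed for 3 h; the PD clock starts at the end of
exposure (t = 0, the first sampling time), so the PK simulation for an arm
runs from t = −3 h with the bolus at −3 and washout at 0, while `N(0) = N0`.
The trial runner instead places boluses at arbitrary t ≥ 0 on a common
drug-free warm-up, which is the natural convention for regimen design.

## Numerics

- **Integration.** `simulate` uses LSODA with rtol 1e−8 / atol 1e−10,
  segmented at every dose boundary so bolus and washout resets are applied
  exactly. The system is only mildly stiff, but the post-washout tail makes
  implicit stepping worthwhile. States are clamped at zero only for
  round-off-scale negatives (|x| < 1e−6); anything larger raises, since it
  signals a misconfigured integration.
- **Fast PD evaluation.** Given `XB(t)`, the growth law is a Bernoulli
  equation; `1/N` obeys a linear ODE solved exactly by quadrature
  (`cell_counts_from_pk`). Fitting therefore solves the PK subsystem once
  per γ (all treated arms stacked into a single ODE system, cached per γ —
  finite-difference steps in the other parameters reuse it) and evaluates
  `N` by cumulative trapezoid on a grid that is 0.1 h fine over the
  post-washout transient and 0.5 h elsewhere. This path agrees with the
  fully coupled ODE to ~2e−5 relative, which the suite checks.
- **Optimizer.** Bounded trust-region least squares (`scipy`'s `trf`) on
  the stacked residual vector: data terms `√w·(y−ŷ)/σ_v`, prior terms
  `(p−μ)/σ_p`, so the squared norm is the MAP objective. Bounds:
  k_p, Kdmax, γ ∈ (0, 1]; XBHS ∈ (0, 1e4]; θ ∈ [1e4, 1e7]; N0 ∈ (0, 1e7].
  Multi-start (default 5): the first start sits at the prior means
  (physiological defaults for unprior'd parameters: Kdmax 0.05, XBHS 100,
  γ 0.01), the rest jitter it lognormally (σ = 0.3) with fixed seeds; the
  lowest-cost solution wins.

## Weighting, priors, degenerate inputs

- **Data covariance.** Residuals are weighted by the per-point SEM² of the
  averaged series (a diagonal covariance). Points with a single retained
  replicate — or zero spread, as in noise-free synthetic data — take the
  arm's median positive SEM², falling back to unit variance when the whole
  arm is degenerate. Control-arm squared residuals are multiplied by 3 (3×
  more control samples exist, and k_p/θ should be anchored by drug-free
  growth); the weight multiplies squared residuals and is configurable.
- **Priors.** k_p: mean 0.028 1/h from the cell line's documented 72 h
  doubling time, SD 50 % of the mean. (The documentation's own 0.028 h⁻¹
  figure is used verbatim as the prior mean even though ln 2/72 ≈ 0.0096;
  the prior is weak either way.) θ: mean 2.5e5 cells from prior capacity
  experiments, SD 20 %. N0 per arm: mean at the arm's first observed data
  point — the first sample is too unreliable to use as a hard initial
  condition, so N0 is estimated with this prior — SD = max(SEM at that
  point, 20 % of the mean); a missing t = 0 sample falls back to the
  earliest available point and is flagged. Kdmax, XBHS and γ carry flat
  priors.
- **Control-only data.** Without treated arms the drug parameters are
  structurally unidentifiable; `fit` holds Kdmax, XBHS and γ at their start
  values and flags them on the results instead of letting them wander.

## Uncertainty and validation

The bootstrap replaces each averaged point by one of the raw replicate
measurements behind it, refits from the point estimate (single start), and
summarizes: per-parameter SD and CV (% of the point estimate), and per-arm
2.5/97.5-percentile prediction bands. Default B = 200; refit failures are
dropped and more than 20 % of them raises.

`validate_holdout` fits on a subset of arms (default control, 20, 50, 200,
900 nM) and predicts the held-out arms (10, 40, 450 nM) forward from their
first observed data point, with N0 fixed to that measurement — emulating a
user who only has the initial count. It reports per-arm RMSE, optional
bootstrap-band coverage, and (optionally) the maximum relative gap between
reduced-fit and full-fit trajectories. Train and test arms must be
disjoint.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the design of the in vitro study: 8 arms at
0/10/20/40/50/200/450/900 nM, 3 h exposure, sampling every 24 h to 456 h,
~3× more control replicates (12 vs 4), the four (arm, time) cells missing
from the real campaign, and — optionally — "unrealistic" records (negative
counts and early zeros from low-fluorescence conversion) that exercise both
exclusion rules, bookkept so tests can check the exclusion report exactly.
Replicate noise is multiplicative lognormal with unit mean, cv 0.2 by
default (counts are positive with roughly scale-proportional spread), with
the t = 0 sample's cv inflated 2× to mimic the unreliable first
measurement (toggleable).

It does **not** emulate: medium-refreshment proliferation spikes (a known
feature of the real low-dose arms around t ≈ 300 h), nutrient depletion,
drug-resistant subpopulations, or the true heteroscedastic replicate
layout (4–28 per time). Passing recovery tests therefore demonstrate that
the estimator is consistent under the model's own noise assumptions — not
that the model captures every feature of real cultures.

## Problem sizes used by the test suite and acceptance script

Parameter recovery runs 10 datasets (20 for the median-bias property) at
the full 8-arm design with 2 optimizer starts each; bootstrap checks use
B = 16–40; the RK4 cross-check uses a 1e−3 h fixed step over 456 h. These
sizes give stable checks while keeping a full run in the minutes range.

## Known limitations

- γ conflates dilution-by-division with degradation; long-horizon PK data
  would be needed to separate them.
- The efficacy-threshold and trial metrics inherit the population-level
  coupling: they say nothing about heterogeneous or resistant
  subpopulations.
- RMSE-based holdout metrics pool arms of very different scales; per-arm
  values are reported for that reason.
- The bootstrap resamples replicates independently per time point, which
  ignores any within-well correlation over time.
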