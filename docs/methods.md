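# Methods

## The problem

A transdermal formulation is screened in vitro in Franz diffusion cells:
a gel sits in the donor chamber, a skin sample separates it from a
stirred receptor chamber, and the cumulative amount of drug that has
crossed into the receptor, per unit exposed area (Q_R, µg/cm²), is
measured over time. The scientific question this package addresses is
whether a kinetic constant estimated from such an *infinite-dose*
in vitro experiment can predict *in vivo* plasma concentrations after a
*finite* percutaneous dose — the nortriptyline-in-rats worked example
carried through the whole package.

## Models

### Fickian membrane diffusion (infinite dose)

Treating the skin as a pseudo-homogeneous membrane at constant donor
concentration C_D, Fick's second law gives the series solution

    Q_R(t) = K_p C_D t − K_p C_D T_lag
             − (12 K_p C_D T_lag / π²) Σ_{n≥1} (−1)ⁿ/n² · exp(−n²π² t / 6 T_lag)

with permeability coefficient K_p = K·D/h (cm/h) and lag time
T_lag = h²/6D (h). At late times the curve is the pseudo-steady-state
line with slope J_ss = K_p·C_D and t-intercept T_lag. Differentiating
term-by-term gives the flux-rise fraction

    J(t)/J_ss = 1 + 2 Σ_{n≥1} (−1)ⁿ exp(−n²π² (t/T_lag) / 6),

which reaches ≈97.5% of J_ss at t = 2.7·T_lag.

Numerics: the series is truncated at 200 terms by default with early
exit when a term falls below 1e-15 of the partial sum; this agrees with
a 10⁴-term sum to 1e-12 relative at all tested times. At t = 0 the
series equals −π²/12 analytically and cancels the lag term; the code
imposes that cancellation exactly instead of carrying ~1e-5 of
truncation residue. The flux fraction is clipped to [0, 1]; at
arguments below ~1e-4 lag times the alternating series converges slowly
and more terms should be requested.

### One-compartment skin transport

The skin is a single well-mixed compartment with first-order output
k_out (h⁻¹) to the receptor. Input from the donor is

* zero-order at rate R0 (µg/cm²/h) for an infinite dose, giving
  Q_M = (R0/k_out)(1 − e^{−k_out t}), Q_R = R0·t − Q_M, J = k_out·Q_M.
  R0 plays the role of J_ss and 1/k_out the role of T_lag (the
  pseudo-steady-state line of Q_R has slope R0 and t-intercept
  1/k_out); the flux reaches 97.5% of its plateau at 3.689/k_out.
* first-order at rate k_in (h⁻¹) for a finite dose Q0, giving
  Q_D = Q0 e^{−k_in t},
  Q_M = Q0 k_in/(k_in−k_out) (e^{−k_out t} − e^{−k_in t}),
  Q_R = Q0 − Q_D − Q_M, J = k_out Q_M, with peak flux at
  T_Jmax = ln(k_out/k_in)/(k_out−k_in).

k_out means the same thing in both regimens — that is the premise of
the in vitro → in vivo extrapolation: fit (R0, k_out) to an
infinite-dose experiment, obtain k_in separately, and simulate the
finite-dose case.

Degenerate case: the two-exponential formulas are singular at
k_in = k_out; the analytic limit Q_M = k_in Q0 t e^{−k_in t} and
T_Jmax = 1/k replace them when the rates agree to better than 1e-8
relative. An optional onset delay t0 substitutes (t − t0) clamped at
zero. Mass balance (Q_R + Q_M = R0·t infinite; Q_D + Q_M + Q_R = Q0
finite) holds to 1e-9 relative and is property-tested over 1000 random
parameter draws.

### Coupled skin–plasma simulation

For in vivo prediction the finite-dose skin stages feed a standard
two-compartment disposition model. States are amounts (µg):

    dA_vehicle/dt = −k_in A_vehicle
    dA_skin/dt    =  k_in A_vehicle − k_out A_skin
    dA_c/dt       =  k_out A_skin − (k10 + k12) A_c + k21 A_p
    dA_p/dt       =  k12 A_c − k21 A_p

with micro constants k10 = CL/V1, k12 = CLic/V1, k21 = CLic/V2,
V2 = VT − V1, and plasma concentration C_p = 1000·A_c/V1 (ng/mL).
Working in amounts makes the exposed area cancel; it is carried in the
configuration only for flux reporting.

Two solution routes cross-validate each other: LSODA integration at
rtol 1e-9 / atol 1e-12, and the analytic solution obtained by
eigendecomposition of the (linear, constant-coefficient) system —
a sum of exponentials with rates {0, k_in, k_out, α, β}, where α, β are
the usual hybrid disposition constants. When eigenvalues nearly
coincide the analytic route evaluates the matrix exponential per time
point instead, which is exact for the confluent case without perturbing
any parameter. Agreement is asserted to 1e-6 relative with an absolute
floor of 1e-6 of the profile peak — deep-tail values below that floor
are beyond the integrator's absolute tolerance and a pure relative
comparison there would test the tolerance, not the model.

The comparison model without the skin stage (first-order absorption
straight into the central compartment) is provided to show what is
lost: it peaks strictly earlier and higher than the three-compartment
prediction at the study parameters.

## Estimation

* Receptor sampling correction: withdrawing V_s and refilling at each
  sample removes drug that the cumulative amount must account for,
  Q_n = (C_n V_R + Σ_{i<n} C_i V_s)/A.
* Skin-model fits use `scipy.optimize.least_squares` with positivity
  bounds, xtol/ftol/gtol 1e-12. Infinite-dose starting values come from
  the pseudo-steady-state line through the last third of the points;
  finite-dose k_in starts from the residual-fraction inversion
  k_in = −ln(1 − Q_R(t_last)/Q0)/t_last. Standard errors are the
  residual-variance-scaled inverse of JᵀJ at the solution; a condition
  number above 1e12 means the parameters are not identifiable and no
  SEs are reported (for the finite-dose fit this doubles as the
  detector for instantaneous-transfer data, reported as non-converged
  rather than raised).
* Residual weighting defaults to unweighted (additive error);
  proportional weighting (1/|y|, floored at 1e-3 of the data maximum)
  is a switch. The pipeline's reproduce mode fits with proportional
  weighting because the synthetic generator's error model is
  proportional — the matched analysis.
* Flip-flop: the finite-dose cumulative and flux curves are exactly
  symmetric under k_in ↔ k_out, so the labelling is a convention. The
  primary result uses k_in ≤ k_out (matching the nortriptyline values);
  the swapped labelling is always reported alongside. No physical claim
  is attached to the convention.
* NCA: linear trapezoidal AUC; with extrapolation, λz from a log-linear
  regression on the last 3 (configurable) positive points and tail area
  C_last/λz. Extrapolation is refused, with the observed-range AUC
  returned flagged, when the tail is non-positive or non-decaying.
  CL_app = 1000·dose/AUC bridges µg to ng.
* IV disposition fit: least squares on the bi-exponential bolus
  solution, internally parameterised as (CL, V1, V2, CLic) so VT > V1
  by construction; a CLic estimate pinned at its lower bound signals
  one-compartment data. The VT standard error combines the V1 and V2
  SEs without their covariance — adequate for reporting, not for
  inference on VT alone.

## Synthetic data

The generator emulates the nortriptyline study conditions: the in vitro
design (schedule {3, 5, 7, 9, 24, 26, 28, 30} h, 4 cells, 9 mL receptor
sampled at 200 µL, 1.45 cm², donor refreshed at 9 h — a no-op for the
constant-C_D model, recorded in metadata) and the in vivo design
(schedule {8, 12, 24, 27, 30, 46, 48, 51, 54} h, 5 animals). Noise is
multiplicative by default — cv 5% in vitro and 15% in vivo, chosen as
plausible assay/biological variability scales; the study reports
mean ± SD figures but no error model, so these are this package's own
defaults. Noise is applied to receptor *concentrations* (so the
withdrawal correction propagates noisy values, as real analysis would)
and negative draws are truncated at zero and counted. Replicate streams
are spawned from a single seed (`numpy.random.SeedSequence`), giving
bit-identical datasets per seed and uncorrelated replicates.

What passing on synthetic data does *not* show: the generator contains
no between-animal parameter variability, no LOQ censoring, no assay
drift, and its truth curves come from the same model family being
fitted — round-trip and calibration results demonstrate correctness of
the machinery, not adequacy of the model for real skin.

## Problem sizes and verification

The dense simulation grid is 0–54 h at 0.1 h. Calibration uses 500
synthetic in vitro datasets (32 observations each): the empirical SD of
(R0, k_out) estimates matches the mean reported SE within 30% and the
±2 SE interval covers the truth in ≥90% of datasets. Route agreement is
checked over 200 random parameter draws spanning three orders of
magnitude in each rate. AUC∞ identities (AUC = 1000·dose/CL) hold to
1% on grids extending to ~25 disposition half-lives.

## Known limitations

Single homogeneous skin layer, no skin metabolism, no donor depletion
under the infinite-dose assumption, no nonlinear elimination, no
population variability. The finite-dose Fickian series solution is out
of scope (only the compartmental description covers that regimen). The
97.5%-of-plateau multiplier (3.689/k_out) and the 2.7·T_lag flux
fraction are model statements, not data.
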