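# Methods

## Scope and data model

The package consumes *annotated* thermal-transition tables — per-sample
rows of (solids fraction ws, temperature) for glass transitions (Tg) in
the unfreezable-water domain and freezing points (Tm) in the freezable
domain, plus replicated Tg′/Tm′ observations — not raw DSC heat-flow
thermograms. Transition picking (midpoint / half-height / peak
assignment) and annealing protocols are upstream of this package.

All temperatures are carried in °C. The Gordon–Taylor expression is a
weighted mean and hence affine-invariant, so evaluating it directly in
°C is exact (verified to 1e-9 against a Kelvin round trip in the test
suite). Fixed physical constants: Tgw = −135 °C (glass transition of
amorphous water), Tw = 0 °C (pure-water freezing point; never fitted),
β = 1860 kg·K/kgmol, λw = 18.015 kg/kgmol. E = λw/λs is fitted as a
single parameter; the solids molecular mass λs is never reconstructed
from it.

## Curve fitting

(Tgs, K) and (E, B) are estimated by unweighted nonlinear least squares
in °C (`scipy.optimize.least_squares`, trust-region reflective), with:

* initial values Tgs ← max observed Tg, K ← 4; E ← 0.05, B ← 0.15
  (mid-range of values observed across fruit-sugar systems);
* bounds Tgs ∈ (−50, 250) °C, K ∈ (0.1, 50), E ∈ (1e-4, 1),
  B ∈ [0, min(0.99, (1−ws_max_data)/ws_max_data)) — the B cap keeps the
  logarithm's argument positive at every data point throughout the
  search;
* termination at 1e-10 on the sum of squares, 500 evaluations; on
  failure, five jittered restarts before the result is flagged
  unconverged (flagged, never silent).

Both problems are two-parameter and well conditioned on realistic
grids; noiseless data are recovered to better than 1e-6 in all
parameters (a frozen test over the full bundled parameter table and 100
random draws). R² is reported as 1 − SSE/SST with SST about the
observation mean.

## Maximal-freeze-concentration condition

Tg′ and Tm′ vary little with initial moisture, so each is the
*unweighted* mean of its replicates (no replicate/moisture weighting is
attempted — the upstream counts are rarely known). ws′ is the root of
Tm(ws) = mean Tm′, bracketed on (0, 1/(1+B)) and solved by bisection
(xtol 1e-12; the curve is strictly decreasing so the root is unique).
Tg′ is *not* recomputed from the Gordon–Taylor curve at ws′: measured
Tg′ and the fitted glass curve disagree by several °C in real systems
(e.g. −55.9 °C measured vs ≈ −63 °C from the curve for pure fructose),
so consistency between them is deliberately not enforced. A missing
Tg′ (the transition can be masked by ice melting in high-polymer
samples) is carried as absent, not imputed.

One bundled reference row (experiment 5) fails the 0.001 round-trip
between its printed (E, B, Tm′) and printed ws′ by 0.004; its printed
inputs are internally inconsistent at their own rounding (the source
even prints two values of its Tm′ in different places). The loader
keeps the row verbatim; the self-test documents the discrepancy instead
of hiding it.

## Mixture models

Scheffé convention: no intercept anywhere; 6 linear blending terms and
up to 15 pairwise products; coefficients in raw mass-fraction units, so
a vertex prediction equals that component's linear coefficient. OLS is
delegated to statsmodels; coefficient p-values are two-sided t-tests
with n − p df.

ANOVA is computed about the response mean even though the model has no
intercept: sd = √(SSE/(n−p)), R² = 1 − SSE/SST, CV% = 100·sd/|mean|,
and the regression F-statistic uses df (p−1, n−p). Commercial
mixture-design software reports Scheffé fits this way, and the bundled
reference ANOVA values are only reproduced under the about-the-mean
convention (the uncentered alternative gives R² ≈ 0.999 for every
response and matches nothing).

Pruning is worst-first backward elimination: repeatedly drop the
interaction with the largest coefficient p-value above α = 0.10 and
refit; linear terms are never candidates (every published model of this
form retains all six). Two properties of this procedure on this design
are worth knowing (both measured by simulation in the test suite):
interaction columns are heavily collinear with linear columns
(condition number ≈ 2e4), so on purely linear truth some spurious
interactions survive — but they cancel against shifted linear
coefficients and the pruned model's *predictions* stay within a few
noise SDs of the truth surface; and a genuinely strong interaction
survives elimination far more reliably under worst-first stepwise
(19/20 seeds) than under single-pass omission (13/20), which is why
stepwise is used.

The bundled composition model for E is transcribed as printed but is
defective in the source: its fructose coefficient (0.946) is an order
of magnitude above the measured pure-fructose E (0.0954, a likely lost
leading zero), and its maltodextrin coefficient appears truncated
(an orphan "−0.0003"). It is retained for completeness and for the
qualitative maltodextrin trend, but its numeric predictions should not
be trusted.

## State-diagram prediction for blends

`predict_state_diagram` takes a maltodextrin-free base composition and
a target maltodextrin fraction XM, scales the base fractions by
(1 − XM) — the only convention that preserves the base solute ratios
while keeping the fractions on the simplex — and evaluates the seven
composition models. The resulting MFCC is a model prediction, not a
curve intersection, so exact consistency between the predicted Tm′ and
the predicted freezing curve is not imposed (each carries its own
regression error).

## Synthetic data generator

`GeneratorSpec` emulates the measurement structure of a moisture-series
DSC study: by default 6 solids levels on ws ∈ [0.81, 1.0] for the glass
curve (0–19% moisture), 6 levels on ws ∈ [0.10, min(0.80, 0.95/(1+B))]
for the freezing curve (10–90% moisture; annealed freezing-point
measurements reach 20% moisture, and the grid is always capped inside
the Chen domain), and 6 replicate observations of each of Tg′ and Tm′.
Noise is additive, homoscedastic and Gaussian in °C — defaults 1.0 °C
for curve points and 1.5 °C for the primes (prime replicates scatter by
a few °C across moisture levels in real thermograms) — with one
integer seed driving a single reproducible stream. Ground-truth Tg′ and
Tm′ are explicit fields (defaults −50 and −35 °C, mid-range for
fruit-sugar systems) since the primes are measured quantities, not
functions of the curve parameters.

What passing the pipeline tests does and does not show: with this
error model the generate→fit→intersect pipeline recovers ws′ within
0.01 in ≥95% of 200 seeded runs, demonstrating the estimator chain is
consistent and well conditioned under honest noise — not that real DSC
series (drift, heteroscedastic picking error, annealing sensitivity,
correlated replicates) would achieve the same accuracy.

## Problem sizes

Default test and acceptance runs use 6-point curve grids, 25-run
designs, and 20–200-seed Monte-Carlo loops; the whole suite completes
in a few seconds on one CPU, and each stage is O(n) or a 2-parameter
optimisation, so far larger studies pose no difficulty.

## Known limitations

* One plasticization model (Gordon–Taylor) and one freezing-point model
  (Chen); no Couchman–Karasz or alternative depression models.
* No confidence intervals on fitted curve parameters or model
  predictions (the reference workflow reports none).
* The intersection construction for ws′ inherits any bias in Tm′
  assignment; where the glass and melting transitions overlap, Tm′ (and
  hence ws′) can be systematically misplaced, and no correction is
  attempted.
* The D-optimal design is taken as given; design *generation* is out of
  scope.
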