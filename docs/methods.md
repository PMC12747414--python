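# Methods

## The mutational-response model

The package models the probability that a protein remains functional after
`n` nonsynonymous amino-acid substitutions as a hyper-exponential decay,

    P(n) = exp(-alpha*n - beta*n^2).

`alpha` (per substitution) is the initial log-linear decline; `beta`
(per substitution squared) is the acceleration of that decline and the
model's measure of negative epistasis: as mutations accumulate, each new
mutation is more likely to interact destructively with an existing one,
mostly through additive losses of thermodynamic stability crossing a
functional threshold. `beta = 0` recovers the ordinary exponential null
model, which is nested inside the hyper-exponential and is always fitted
alongside for comparison.

Assumptions worth stating plainly:

* `n` counts nonsynonymous substitutions only; synonymous changes are
  outside the model.
* The model is calibrated on data at small `n` (experiments reach n ≈ 8–14)
  and extrapolated far beyond; `beta` itself drifts with `n` in a way no
  experiment has measured. Everything downstream that depends on the far
  tail (the functional-density profile, the exact position of the
  distribution mode) is therefore *qualitative* — good for comparing
  proteins, not for tail probabilities. The quantitative bounds
  deliberately avoid the tail by clamping to calibrated target sizes.
* Negative epistasis must dominate for the target picture to hold; the
  epistasis criterion is `beta >= k*sigma_beta` with `k = 2` by default
  (configurable), applied by the decision router.

## Fitting

Fits are unweighted nonlinear least squares on the linear proportion scale
(`scipy.optimize.curve_fit`), initial guess `(alpha, beta) = (0.1, 0.01)`
(the order of magnitude of all published fits), both parameters
unconstrained — fitted `alpha` can legitimately be negative when the first
few mutations are nearly neutral while epistasis is strong. Parameter
uncertainties are one-standard-deviation errors from the fit covariance;
R² is `1 - SSres/SStot` against the mean of the included proportions.
Points with proportion 0 are retained (they inform the tail); a switch
drops them. To guarantee the nested-model invariant
`r2_hyper >= r2_exp` against optimizer non-convexity, the
hyper-exponential fit is restarted from the fitted exponential's
`(alpha_exp, 0)` and the better solution kept.

Two fitting options depart from the default: a log-scale fit (requires all
proportions positive) and a weighted fit that uses the known binomial
standard deviations `sqrt(p(1-p)/m)` from clone counts as *absolute*
errors, so its reported sigmas are on the z scale. The weighted fit is the
estimator matched to binomially sampled data and is what the
parameter-recovery tests exercise. A calibration caveat, measured with the
synthetic generator: at ~1000 clones per `n` the joint two-parameter
3-sigma coverage of the weighted fit is about 98.4–99.5% rather than the
asymptotic ~99.5%, because the curvature of the model inflates the
normalized errors by ~3–7%; the unweighted fit's residual-rescaled sigmas
under-cover further (~96–98.5%, a t-versus-z effect with few points).
Coverage approaches nominal as per-point noise shrinks.

## Reference point and tolerance

The tolerated-mutation fraction `Ptol` is the probability that one more
mutation is tolerated once the protein is past its stability threshold.
When not measured directly it is read from the model as
`P(n0+1)/P(n0) = exp(-alpha - beta*(2*n0+1))`. The reference `n0` is
chosen as the first `n` where this ratio approximates the target value:
the implementation scans `n` upward to the first sign change of
`(ratio - target)` and returns whichever neighbor deviates least,
erroring if nothing comes within 0.1. This is a model-ratio reading;
empirical plateau readings of tolerance-vs-round data are supported by
passing `(ptol, n0, p_n0)` explicitly, which always takes precedence. A
benchmark preset `Ptol = 1/3` (the measured plateau of a
well-characterized, mechanistically simple enzyme) is provided for
proteins whose function is at least as demanding.

## Target geometry and rarity bounds

Sequence-space counts use exactly `C(L,n) * 19^n` sequences at Hamming
distance `n` (fixed length, no indels). The in-target probability

    Pt = sum_{n=0..nb} C(L,n) 19^n / 20^L

is computed two ways: exact arbitrary-precision integer summation with a
single log10 at the end (the reference path — CPython's `math.log10`
accepts big integers), and a log-sum-exp path via `gammaln`; the two agree
to 1e-9 and the agreement is tested.

The target boundary from tolerance extrapolation is

    nb = log(Pmin / P(n0)) / log(Ptol) + n0,

rounded to the nearest integer (floor/ceil available). `Pmin` defaults to
the discoverability floor `Pth = 1e-40`, the reciprocal of roughly
`Tm = 1e38` distinct gene variants over Earth's history; a `1e-20` preset
reflects the much smaller effective trial count of multicellular
eukaryotes. An `nb` below the calibrated `c = 1/3` target (57% of
residues changed, the empirical limit for sharing a general function) is
clamped outward to it; between `1/3` and `1/2` (77%, the limit for
sharing a structure) it is clamped to the `1/2` boundary; beyond that it
is used directly with a warning, which is only defensible when `beta` and
`Ptol` are known with high confidence. Clamping outward can only be done
deliberately: it trades tightness for robustness against an
underestimated target.

The four estimators are `Pubt = Ptol^nb` (functional fraction inside the
target), the composite `Pub = Pt * Pubt`, the whole-sequence bound
`Pub = Ptol^L` (no target definable; always weaker than the composite),
and the stability proxy `Pub = Pnd^L`.

### Numeric conventions

All probabilities are carried as raw log10 reals; nothing this small
exists as a float. Two integer-exponent formats coexist because published
order-of-magnitude chains use both: *round* (nearest order of magnitude;
used for the epistatic pipeline, e.g. raw −73.59 → 10^−74) and *floor*
(scientific-notation exponent; used for tolerance/stability tables, e.g.
raw −123.2 = 6.0×10^−124 → 10^−124). A composite's formatted exponent is
the sum of its factors' formatted exponents, so printed chains stay
self-consistent; the raw sum is always reported alongside. Boundary
conversion `nb = floor(ca*L)` is the default, with round-to-nearest as an
override — published conversions are themselves inconsistent between the
two, so the choice is explicit and recorded in every report.

## Discovery mathematics

Expected discovery time for an undirected search follows `d = A * B^L`
with constants fitted to search simulations: `A = 2.21, B = 3.25` for
`c = 1/3` targets and `A = 5.36, B = 1.56` for `c = 1/2`. The success
probability within `Tm` trials is `Pdt = 1 - exp(-Tm/d)`, evaluated in
log space: for `Tm/d < 1e-8` the first-order form `log10(Tm) - log10(d)`
is exact to double precision and avoids catastrophic cancellation. The
multi-target generalization `dm = (1/m) exp(6L(3/4 - c)^2)` inverts to
the minimum discoverable target fraction
`cmin = 3/4 - sqrt(ln(m*d)/(6L))`, reported in whole percent.

Two published spot values (a `c = 1/3` discovery exponent of 133 at
L = 263 and a `c = 1/2` exponent of 48 at L = 254) are inconsistent with
these constants as printed (the formulas give 135 and 50); the package
implements the formulas and does not attempt to reproduce those two
numbers.

## Stability distributions

Mutational ddG distributions (kcal/mol, positive destabilizing) are
modelled as two-component Gaussian mixtures; the non-destabilizing
fraction is the mixture CDF at a cutoff `Gth`, and the cutoff itself can
be calibrated as the `Ptol`-quantile of a benchmark protein's mixture via
Brent root finding (tolerance 1e-6 kcal/mol) — the standard calibration
lands near 0.5 kcal/mol, and 0.5/1.0 kcal/mol are the conventional
presets. Empirical per-protein fractions count entries *strictly below*
the cutoff (ties at the cutoff count as destabilizing; the convention is
arbitrary but fixed), include stabilizing mutations in the
non-destabilizing tally, keep duplicate measurements as separate entries
(a mean-collapse option exists), and exclude proteins with fewer than 30
records by default.

## Synthetic data

The generator emulates the two data shapes the estimators consume:
survival curves with per-`n` functional counts drawn
`Binomial(clones, P(n))`, and ddG samples drawn from a specified mixture.
Defaults — `n = 0..14`, 1000 clones per `n` — mirror the deepest of the
published mutagenesis designs. A drift-rounds variant draws each clone's
mutation count `Poisson(lambda*round)` to mimic mutagenesis without
selection. One experiment seed expands into independent per-generator
streams via `SeedSequence` spawn keys, so adding a generator never
perturbs existing streams.

What the generator does *not* emulate: selection between rounds,
measurement error in classifying function, overdispersion from clone
relatedness, sequencing miscounts of `n`, and any sequence-level
structure (hotspots, site-specific tolerance). Passing recovery tests
therefore shows the estimators are correct for binomially sampled
hyper-exponential data, not that real experiments are free of these
effects.

## Problem sizes used in the test suite

Recovery and convergence checks run at 200 seeded replicates (survival
fitting), 1e5 draws (ddG convergence, 3-sigma binomial bound), and exact
integer checks up to L = 400; the whole suite completes in a few seconds
on one core.

## Known limitations

* The far tail of `P(n)` is an extrapolation; functional-density modes
  and FSH maps are comparative tools only.
* `Ptol` varies across proteins and with mutational load; a single scalar
  is a deliberate simplification, and the bounds inherit its uncertainty
  geometrically in `nb`.
* The stability proxy assumes destabilizing ≈ deleterious, which fails
  for intrinsically disordered or low-complexity regions; the router
  provides no special handling for them, and the tolerance-only bound is
  the recommended channel there.
* Functional specificity (low vs high) is a user-declared judgment, not
  inferred; the router records the declaration but cannot check it.
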