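# Methods

This note records the statistical models behind `npit`, the conventions
and tunable parameters of each estimator, what the synthetic benchmark
does and does not emulate, and the numerical choices made where more than
one defensible option existed.

## Quantities and units

All quantities are differential (continuous-variable) versions of entropy,
KL divergence and mutual information, in nats (natural logarithm
throughout; 1 bit = log 2 nats).  KL divergence D_KL(p‖q) is only defined
when the support of q covers the support of p; the reference engine
enforces this for the uniform family, the only bounded-support family with
a closed-form KL.  Mutual information between blocks of a d-dimensional
vector is always taken as I(X;Y) with X the leading `dx` dimensions and Y
the trailing d − dx; for the 4-D and 10-D normal cases the splits are 3|1
and 9|1.

## KDE plug-in estimators (`npit.kde`)

The density estimate places one multivariate Gaussian kernel on every
sample point.  The kernel covariance is h²Σ where Σ is the unbiased
(n−1 divisor) sample covariance and h = (n(d+2)/4)^(−1/(d+4)) is
Silverman's rule-of-thumb multiplier; this is identical to
`scipy.stats.gaussian_kde` with the `silverman` factor, which serves as an
independent cross-check in the test suite (the implementation itself is a
chunked Mahalanobis-distance kernel sum, so memory stays bounded at large
n).  The n−1 divisor is a convention choice: common KDE implementations
use it, and nothing else in the estimator pins it down.

*Resubstitution* estimates replace the defining integral by the sample
mean of log-densities at the observed points; *integral* estimates
integrate the estimated density by adaptive quadrature (QUADPACK, abs/rel
tolerance 1.49e−8).  Integration limits are per-dimension
[min − h, max + h]; this deliberately truncates the kernel tails on
bounded-support data and reproduces the known bias of the method there.
MI and KL integral modes share one box derived from the (joint or
p-) sample; marginal densities integrate over its projections.  Whether
separate per-model boxes would behave differently is untested — the
shared box was chosen because the quantities compare densities at common
points.

Cost ceilings fail loudly instead of truncating: resubstitution at
n > 25,000, integral mode at n > 10,000 or d > 2 (kernel-sum quadrature
cost grows exponentially with d).  Both ceilings are overridable per call
(`max_n`).

## Histogram estimators (`npit.binning`)

Bin widths are chosen per dimension: Sturges' rule fixes the bin *count*
at ⌈log₂ n⌉ + 1 (the conventional reading — the rule is a count rule even
though it is often written as if it produced a width) and derives the
width from the data range; Scott's rule (3.49 σ n^(−1/3)) and the
Freedman–Diaconis rule (2·IQR·n^(−1/3)) fix the width and derive the
count.  Grids span each column's min–max with half-open bins, the last
bin closed so the maximum is counted.  Bins are anchored at the sample
minimum; anchoring at a rounded origin would shift estimates by a
sub-bin-width amount and no convention is canonical.  Histograms are
stored sparsely (occupied bin index tuples and counts), which is what
makes the 10-dimensional cases tractable: the nominal Sturges grid there
has 18¹⁰ cells but at most n are occupied.

The entropy estimator is Ĥ = −Σ_b p̂_b log p̂_b + log ΠⱼΔⱼ with
p̂_b = c_b/n — the discrete entropy of the occupied-bin frequencies plus
the log bin volume.  This is the form that converges to differential
entropy as bins shrink, and it is the form consistent with the observed
convergence of histogram entropy to log(b−a) on the uniform case.  (The
alternative sign convention, −Σ p̂ log(p̂ Δ) with a *negative* volume
term, is the discrete entropy of the quantized variable and diverges as
Δ→0; it is not what a differential-entropy estimator needs.)  Empty bins
are excluded from every sum.

KL divergence bins both samples on the grid built from the p-sample (the
bin-volume factor cancels in the ratio).  p-points whose bin the q-sample
never occupies have ĝ = 0; by default they are excluded from the mean
and their count is reported, while `empty_bin="infinity"` returns +inf if
any such point exists.  Both behaviors occur in practice: exclusion keeps
low-dimensional estimates finite, the strict mode reproduces the
divergence-to-infinity seen in 10 dimensions where almost no q-bin is
shared.  The p-grid (rather than a pooled-sample grid) follows from
requiring "the same binning scheme" for both densities with p the
distribution of interest.

MI uses per-dimension marginal grids whose Cartesian product is the joint
grid, so the marginal histograms are exact projections of the joint one
and the estimate is the discrete MI of a proper contingency table —
non-negative up to floating error by construction.

### Quantile Spacing

The 1-D Quantile Spacing estimator models the density as piecewise
constant between NZ empirical quantiles and averages log(NZ·Δⱼ) over the
spacings.  Quantile locations are estimated by drawing Nk subsets of size
NZ−1 without replacement, sorting each, and averaging the order
statistics; endpoints are the full-sample min/max.  Defaults are
NZ = 0.25·n (rounded half away from zero, floored at 2) and Nk = 500, the
values reported as bias-minimizing by the method's authors.  Zero-width
spacings (possible under repeated sample values) are dropped like empty
bins.  The estimator is 1-D only and typically underestimates entropy
slightly.

## k-NN estimators (`npit.knn`)

Neighbor search is exact (scipy's k-d tree); a brute-force all-pairs
oracle in the tests confirms equality on small inputs.  Conventions:

- **Kozachenko–Leonenko entropy**: Euclidean norm, self-excluded k-th
  neighbor distances, Ĥ = ψ(N) − ψ(k) + log c₁(d) + (d/N) Σ log ρₖ(i)
  with c₁(d) = π^(d/2)/Γ(d/2+1).  The distance prefactor enters once —
  (d/N)·Σ log ρ and (1/N)·Σ log ρ^d are the same number, and applying the
  dimension twice is the error mode to avoid; the implementation is
  validated against the 1-D normal closed form.
- **Wang KL**: ρ from the p-sample (self-excluded), ν into the q-sample,
  D̂ = (d/n) Σ log(νₖ/ρₖ) + log(m/(n−1)).  The estimator is unbounded
  below and legitimately returns negative values.
- **Kraskov MI (algorithm 1)**: max-norm joint-space radii; the marginal
  counts use *strict* inequality at the radius, implemented by shrinking
  the ball-query radius to the previous representable float.  Strictness
  matters only on ties (measure zero for continuous data, decisive in
  hand-worked integer examples).  Raw negative values — common at small n
  and k = 1 on weakly dependent data — are clipped to 0.0 at the public
  API since MI is non-negative; the raw value is available via
  `return_raw=True` and is carried in benchmark records.

Coincident points give zero distances, which the log terms cannot absorb.
The estimators reject duplicates by default, naming the offending rows;
`jitter_duplicates=True` adds a uniform perturbation of amplitude
1e−10 × per-dimension range.  Jitter is opt-in because a silent
perturbation would invalidate the exact-value tests and surprise users
with integer-valued data.

k is the only hyperparameter.  Across the benchmark, k = 1 is most
accurate for entropy and KL, while MI benefits from aggregation and k = 15
performs best — small-k MI estimates at small n are frequently clipped at
zero.

## Benchmark distributions and references (`npit.distributions`)

Eight cases: U(0.5,2) vs U(0,2); N(−2.5,2.5²) vs N(0,3.15²); an equal
mixture of N(−2.5,2.5²) and N(2.5,1²) vs N(0,3.15²); a 2-D normal with
ρ = −0.5 vs an independent diag(5,1) normal; an equal mixture of two 2-D
normals (means ±(2,0), correlations ∓0.5) vs the same independent normal;
a gamma-exponential p(x₁,x₂) = x₁^θ e^(−x₁−x₁x₂)/Γ(θ) with θ = 3 vs
θ = 4; and 4-D / 10-D normals with equicorrelated covariances (off-diagonals
0.5 vs 0.1, and 0.9 vs 0.1).  The 1-D cases define entropy and KL only —
a scalar has no second variable for mutual information.

Closed forms: uniform H = log(b−a), KL = log((d−c)/(b−a)); normal
H = ½ln(2πσ²)+½ and the standard two-normal KL; multivariate normal
H = ½ln((2πe)^d det Σ), the trace-form KL, and block-split
MI = ½ln(det Σ_XX det Σ_YY / det Σ); gamma-exponential
H = 1 + θ − θψ(θ) + ln Γ(θ) and MI = ψ(θ) − ln θ + 1/θ.  Mixtures have no
closed form for any quantity (log of a sum of exponentials), nor does the
gamma-exponential KL; those references come from adaptive quadrature over
the true support at tolerance 1.49e−8, feasible for d ≤ 2.  Quadrature
integrands work in log-density space so that tail underflow of p or q
cannot poison the integral.  Reference values are carried at full float
precision; two-decimal rounding is applied only where published values
are quoted at that precision.

Sampler conventions the model family does not pin down: mixtures draw a
categorical component label first, then the component (one RNG stream,
fixed consumption order, so a seed fully determines the sample); the
gamma-exponential factorizes as x₁ ~ Gamma(θ, 1), x₂|x₁ ~ Exp(rate x₁),
which reproduces the joint density exactly (verified by the pdf-integral
and joint-vs-factorized likelihood tests).  Seed-for-seed streams
therefore need not match any other implementation of the same benchmark —
only the distributions do.

## Sweep harness (`npit.benchmark`)

Each cell is (case, quantity, estimator, hyperparameters, n, seed).  The
per-cell sample derives from SeedSequence(base, case, size-index, rep)
and is shared by every estimator in the cell, so methods are compared on
identical data; q-samples for KL use a separate spawn key.  Aggregation
reports the mean over seeds, the 2.5/97.5 percentile band (the sampling-
variability band), and the signed relative error of the mean,
(mean − ref)/|ref|; cells with a zero reference (e.g. independent-data
MI) report the absolute error instead, flagged in `error_kind`.
Estimator failures are isolated per cell and logged; documented cost
ceilings (KDE 25,000 resubstitution / 10,000 integral; k-NN 50,000 at
d = 10) clip the size ladder rather than erroring.

The full protocol repeats every cell over 300 seeds with sizes
100–100,000.  The packaged accuracy checks use 20 seeds (k-NN entropy
sweep over k ∈ {1,3,5,15} and the full size ladder) and 10 seeds (10-D
Sturges-rule entropy at n = 100,000) — sizes chosen so the checks
exercise the same conditions at a cost suitable for routine runs; the
percentile bands are correspondingly coarser but the mean-error
conclusions are unchanged.

## What the synthetic benchmark does not show

All test distributions are smooth, light- or exponential-tailed, and
either exactly normal, normal mixtures, uniform or gamma-exponential.
Passing accuracy checks on them says nothing about heavy-tailed data,
discrete or mixed-type variables, strongly clustered/manifold data (where
k-NN distances behave differently), or sample sizes outside 100–100,000.
KDE results in particular flatter the method: the benchmark's
higher-dimensional cases are multivariate normal, the Gaussian kernel's
best case.  The estimators themselves are general; the evidence is not.

## Known limitations

- No kernels besides Gaussian, no bandwidth selectors besides Silverman,
  no tree/FFT-accelerated KDE.
- No adaptive or MISE-optimal multi-dimensional binning; Quantile Spacing
  has no multi-dimensional extension.
- No approximate nearest-neighbor backends; exact k-d trees degrade in
  very high dimensions.
- Bootstrap confidence intervals for individual estimates are not
  provided; the benchmark quantifies sampling variability across repeated
  draws instead.
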