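# npit — non-parametric information-theoretic estimation

Differential entropy, Kullback–Leibler divergence and mutual information
are defined through integrals over probability densities,

- H(X) = −∫ p(x) log p(x) dx
- D_KL(p‖q) = ∫ p(x) log(p(x)/q(x)) dx
- I(X;Y) = ∫∫ p(x,y) log[p(x,y) / (p(x)p(y))] dx dy

(all in nats), but in practice one rarely has the densities — only an
n × d matrix of observations.  `npit` provides the three standard
non-parametric estimator families for these quantities, for researchers
who need them on continuous multi-dimensional samples (network inference
from expression data, model evaluation, dependence screening):

- **KDE plug-in** — a multivariate Gaussian kernel with Silverman's
  bandwidth h = (n(d+2)/4)^(−1/(d+4)); resubstitution
  (Ĥ = −(1/n) Σᵢ log p̂(xᵢ)) or numerical-integration variants.
- **Binning** — sparse multi-dimensional histograms with per-dimension
  Sturges, Scott or Freedman–Diaconis bin widths, plus the 1-D Quantile
  Spacing entropy estimator built from bootstrap-averaged empirical
  quantiles.
- **k-NN** — distance-based estimators that skip density estimation:
  Kozachenko–Leonenko entropy
  Ĥ = ψ(N) − ψ(k) + log c₁(d) + (d/N) Σᵢ log ρₖ(i),
  the Wang et al. two-sample KL estimator
  (d/n) Σᵢ log(νₖ(i)/ρₖ(i)) + log(m/(n−1)),
  and the Kraskov–Stögbauer–Grassberger mutual-information estimator
  ψ(k) + ψ(N) − ⟨ψ(nₓ+1) + ψ(n_y+1)⟩ under the max norm.

A registry of eight synthetic benchmark cases (1-D uniform/normal/normal
mixture, 2-D normal/normal mixture/gamma-exponential, 4-D and 10-D
multivariate normals) supplies seeded samplers, exact pdfs and analytic or
adaptive-quadrature reference values, and a sweep harness measures every
estimator's accuracy against them as a function of sample size,
hyperparameters and sampling variability.

## Worked example

Estimating the entropy of 10,000 draws from N(−2.5, 2.5²)
(`examples/01_entropy_from_samples.py`):

```
true entropy: 2.3352 nats
kde (resubstitution)   2.3324 nats  (error -0.12%)
binning (scott)        2.3318 nats  (error -0.15%)
binning (sturges)      2.3420 nats  (error +0.29%)
quantile spacing       2.3319 nats  (error -0.14%)
k-NN (k=1)             2.3593 nats  (error +1.03%)
```

Every estimator lands within ~1% of the closed form
½·ln(2πσ²) + ½ = 2.3352 nats at this sample size.  The other examples
cover KL divergence between two samples, mutual information of a
correlated bivariate normal, a seeded accuracy sweep, and the benchmark
case registry.  The same sweeps are scriptable from the shell:

```sh
npit list-cases
npit run --case 2 --quantity entropy --estimator knn --k 1,15 \
    --sizes 100,1000,10000 --seeds 20 --out records.csv
npit summarize records.csv
```

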