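"""Estimate the differential entropy of a 1-D normal sample four ways.

Draws 10,000 points from N(-2.5, 2.5^2) (true entropy 2.3352 nats) and
compares the KDE resubstitution estimate, two histogram rules, Quantile
Spacing and the Kozachenko-Leonenko k-NN estimate against the closed form.
"""

import numpy as np

from npit import bin_entropy, distributions, kde_entropy, kl_entropy, qs_entropy

case = distributions.get_case(2)  # 1-D normal benchmark case
truth = case.reference("entropy").value
x = distributions.sample(case.p, 10_000, seed=0)

estimates = {
    "kde (resubstitution)": kde_entropy(x),
    "binning (scott)": bin_entropy(x, "scott"),
    "binning (sturges)": bin_entropy(x, "sturges"),
    "quantile spacing": qs_entropy(x, seed=0),
    "k-NN (k=1)": kl_entropy(x, k=1),
}

print(f"true entropy: {truth:.4f} nats")
for name, value in estimates.items():
    print(f"{name:22s} {value:.4f} nats  (error {(value - truth) / truth:+.2%})")
# Every estimator lands within a few percent at this sample size; Sturges'
# coarser bins overshoot slightly, Quantile Spacing undershoots slightly.
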