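"""Paired model comparison with the signed-rank test and rank-biserial.

Reproduces the style of inference used for model-vs-model comparisons:
per-unit paired values (here, per-seed recall probabilities under two
architectures) -> Wilcoxon signed-rank W, p, and matched-pairs
rank-biserial effect size.
"""

import numpy as np

from memsearch import compare_paired_models
from memsearch.stats import rank_biserial, wilcoxon_p_from_statistic

# 13 paired runs where condition A beats condition B in every pair:
# W is the full rank sum 91 and the one-sided exact p is 1/2^13
a = np.linspace(0.55, 0.80, 13)
b = a - np.linspace(0.02, 0.10, 13)
report = compare_paired_models(a, b, alternative="greater")
print(f"all-positive pairs: W={report.W}, n={report.n}, "
      f"p={report.p:.3g} ({report.method}), r_rb={report.rank_biserial:+.3f}")

# from a reported (W, n) alone: the same machinery recovers the p-value
print("W=0,  n=171, two-sided normal p =",
      f"{wilcoxon_p_from_statistic(0, 171):.2e}")
print("W=2880, n=171, two-sided normal p =",
      f"{wilcoxon_p_from_statistic(2880, 171):.2e}")
print("rank-biserial(W=29, n=13)   =", f"{rank_biserial(29, 13):+.3f}")
print("rank-biserial(W=2880, n=171)=", f"{rank_biserial(2880, 171):+.3f}")
print("W counts the ranks of positive paired differences; the rank-biserial")
print("rescales it to [-1, +1] as an effect size.")
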