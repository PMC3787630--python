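"""Same-peak vs different-peak score separation in the dense regime.

For a dense biological-like run pair, compares how well each similarity
measure separates scores of true peak pairs from scores of unrelated peak
pairs, using the histogram overlap coefficient (lower = better separated).
This is the distributional explanation for why partial correlation aligns
dense data better than the classical dot product.
"""

import numpy as np

from peakalign import (
    SimilarityMeasureSpec,
    data2_like,
    generate_run_pair,
    overlap_coefficient,
    score_distributions,
)

cfg = data2_like(seed=3, n_compounds=150, extra_ref=10, extra_target=10)
R, T, truth = generate_run_pair(cfg)
print(f"dense pair: {len(R)} x {len(T)} peaks, {truth.s} true pairs\n")
print(f"{'measure':12s} {'same-peak med':>14s} {'diff-peak med':>14s} {'overlap':>8s}")
for kind, q in [("cosine", None), ("pearson", None), ("spearman", None),
                ("partial", 30), ("part", 30)]:
    spec = SimilarityMeasureSpec(kind, q=q)
    same, diff = score_distributions(R, T, truth, spec)
    print(f"{spec.describe():12s} {np.nanmedian(same):14.4f} "
          f"{np.nanmedian(diff):14.4f} {overlap_coefficient(same, diff):8.4f}")
print(
    "\nPartial correlation pushes different-peak scores toward zero while\n"
    "keeping same-peak scores high, giving the smallest overlap — the\n"
    "separation that similarity-only alignment exploits."
)
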