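"""ddCt fold-change analysis of a synthetic qPCR experiment.

Generates a Ct table for 40 non-diabetic and 40 diabetic samples with a
planted 1.2-cycle dCt difference (a 2.3-fold change) and two injected
outliers, then runs the full pipeline: dCt, pooled 3-SD outlier
exclusion, ddCt fold change and the group comparison.
"""

from mirseed import quantify
from mirseed.synthetic import gen_ct

table, truth = gen_ct(
    {"ND": (5.0, 0.2, 40), "T2D": (3.8, 0.2, 40)}, n_outliers=2, seed=42
)
res = quantify(table, "target", "housekeeper", reference="ND")

print(f"planted outliers: {list(truth.outlier_ids)}")
print(f"excluded by 3-SD rule: {sorted(res.excluded)}")
for g in ("ND", "T2D"):
    print(f"{g}: mean dCt {res.group_means[g]:.3f}  ddCt {res.ddct[g]:+.3f}"
          f"  fold change {res.fold_change[g]:.3f}")
print(f"{res.test}: p = {res.p_value:.3g}")
print(
    "\nA 1.2-cycle lower dCt in the diabetic group corresponds to"
    " 2**1.2 = 2.30-fold higher expression; the injected outliers are the"
    " only samples excluded."
)
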