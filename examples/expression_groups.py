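"""qPCR relative quantification and burden-group association.

Simulates a Ct table for one target gene (group 3 carries a true 2-fold
expression shift), runs the 2^ΔCt ladder with normal-median
normalization, and tests the shift with Kruskal-Wallis.
"""

import numpy as np
import pandas as pd

import palinsig as ps

groups = pd.Series(["G1"] * 39 + ["G2"] * 46 + ["G3"] * 18,
                   index=[f"T{i:03d}" for i in range(103)])
ct, truth = ps.simulate_expression(groups, ps.ExpressionSimSpec(seed=4, fold=2.0))
normals = set(truth.loc[truth.role == "normal", "sample_id"])

nfold = ps.expression_pipeline(ct, normals, reference_gene="TBP")
tumors = nfold[~nfold.sample_id.isin(normals)].set_index("sample_id")

print("median normalized expression (normal-tissue median scaled to 1):")
norm_med = np.median(nfold[nfold.sample_id.isin(normals)].nfold)
print(f"  normals: {norm_med:.2f}")
for g in ("G1", "G2", "G3"):
    med = tumors.loc[groups[groups == g].index, "nfold"].median()
    print(f"  {g}:      {med:.2f}")

stat, p, test = ps.rank_group_test(tumors["nfold"], groups.loc[tumors.index])
print(f"\n{test}: H = {stat:.2f}, p = {p:.4f}")
print("Group 3 (>=3 mutated loci) was generated 2-fold higher; the rank "
      "test detects that shift in most replicates at these group sizes.")
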