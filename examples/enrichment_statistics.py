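"""The susceptibility statistics on small constructed inputs.

Fold enrichment compares the hit fraction inside a selected set with the hit
fraction in its background (which contains the set); significance is a
two-sided Fisher exact test. The multiplicity comparison is a Mann-Whitney
test, computed exactly for small groups.
"""

import pandas as pd

from glycoshift import fisher_enrichment, multiplicity_enrichment, multiplicity_group_test

# 12 of 60 tested proteins decreased; 10 of those 12 are glycoproteins,
# versus 24 glycoproteins among all 60 tested.
res = fisher_enrichment(set_hits=10, set_total=12, bg_hits=24, bg_total=60)
print(
    f"glycoproteins among decreased proteins: fold={res.fold_enrichment:.2f} "
    f"odds_ratio={res.odds_ratio:.2f} p={res.p_value:.4f}"
)

# multiplicity thresholds on a small glycoproteome: decreased glycoproteins
# carry more sites, so enrichment grows with the threshold
profiles = pd.DataFrame(
    {"multiplicity": [6, 5, 4, 4, 1, 2, 1, 1, 2, 3, 1, 1, 2, 1, 4, 1]},
    index=[f"P{i}" for i in range(16)],
)
profiles.index.name = "protein_id"
decreased = ["P0", "P1", "P2", "P3"]
for k, r in multiplicity_enrichment(decreased, profiles, thresholds=(1, 2, 3, 4)).items():
    print(f"multiplicity >= {k}: fold={r.fold_enrichment:.2f} p={r.p_value:.4f}")

# group means and exact Mann-Whitney p (all C(8,4) labelings enumerated)
cmp = multiplicity_group_test([6, 5, 4, 4], [1, 2, 1, 2])
print(
    f"mean multiplicity {cmp.mean_a:.2f} vs {cmp.mean_b:.2f}: "
    f"p={cmp.p_value:.4f} ({cmp.method})"
)
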