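"""Beta-diversity statistics on the living portion of a synthetic experiment.

Computes Canberra distances between log10(1+x) absolute abundances of the
PMA-treated (living) communities, then runs pairwise PERMANOVA with
Benjamini-Hochberg adjustment and a multivariate dispersion analysis.
"""

import pandas as pd

import dustlight as dl
from dustlight.stats import permanova_table

exp = dl.generate_experiment(seed=42)
result = dl.run_pipeline(exp.counts, exp.qpcr, exp.controls,
                         depth=50_000, seed=7)

meta = result.rarefied.metadata
living = meta.index[meta.pma_treated]
table = result.transformed.data.loc[living]
groups = pd.Series(meta.loc[living, "treatment"].to_numpy(),
                   index=[str(i) for i in living])

dm = dl.canberra_matrix(table)
contrasts = dl.pairwise_permanova(dm, groups, n_perm=999, seed=8)
print("pairwise PERMANOVA on living communities (Canberra distances):")
print(permanova_table(contrasts).to_string(index=False))

dispersion = dl.dispersion_analysis(dm, groups)
print("\nmean distance to group centroid (dispersion):")
print(dispersion.group_means.round(1).to_string())
print(f"ANOVA on dispersions: F={dispersion.f_stat:.2f}, "
      f"p={dispersion.p_value:.2g}")
print()
print("Both dark-vs-light contrasts explain far more compositional variance")
print("(R2) than visible-vs-UV, and dark communities are the most variable -")
print("the dominance gradient among dark microcosms drives their dispersion.")
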