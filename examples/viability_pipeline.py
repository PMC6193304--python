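"""From raw counts and qPCR totals to viable fractions per light treatment.

Generates a default synthetic microcosm experiment (54 communities, paired
PMA/non-PMA aliquots), runs the processing chain (control subtraction,
rarefaction to 50,000 reads, absolute-abundance scaling, log transform) and
estimates per-treatment viable fractions from the paired qPCR totals.
"""

import dustlight as dl

exp = dl.generate_experiment(seed=42)
result = dl.run_pipeline(exp.counts, exp.qpcr, exp.controls,
                         depth=50_000, seed=7)

print(f"taxa removed by control subtraction: {result.removed_taxa}")
print(f"samples excluded by rarefaction:     {result.excluded_samples or 'none'}")

pma, total = dl.pair_qpcr_by_community(exp.qpcr, exp.counts.metadata)
fractions = dl.viable_fraction(pma, total)
groups = (exp.counts.metadata.drop_duplicates("community")
          .set_index("community")["treatment"])
means = fractions.group_means(groups)

print("\nestimated viable fraction (PMA qPCR / total qPCR):")
for treatment in ("dark", "visible", "ultraviolet"):
    print(f"  {treatment:12s} {means[treatment] * 100:5.1f} %")
print(f"  range across communities: "
      f"{fractions.fractions.min() * 100:.1f} - "
      f"{fractions.fractions.max() * 100:.1f} %")
print()
print("Dark dust retains the largest living share; both light treatments")
print("roughly halve it, with visible and UV glazing nearly equivalent.")
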