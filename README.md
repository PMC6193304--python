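# dustlight

Sampling-theory null models and viability statistics for light-exposed
dust microbiomes.

## The problem

Household dust harbours dense bacterial communities. When dust is exposed
to daylight — through ordinary (UV-blocking) or UV-transmitting window
glazing — the living fraction of those communities shrinks and a few
numerically dominant clades are lost. Amplicon surveys of such communities
face a subtle artefact: because sequencing libraries are sampled at a
fixed read depth, the *loss* of dominant taxa frees up reads for everyone
else, so very rare taxa can *appear* to increase in abundance without any
biological change. `dustlight` packages both sides of that story:

* a **null model** quantifying the apparent log10-fold change expected for
  every taxon after dominant-taxon loss, with no biology involved; and
* the **measurement pipeline and statistics** used to characterise such
  experiments: PMA-viability qPCR absolute abundances, Canberra
  β-diversity, PERMANOVA, and multivariate dispersion analysis.

It is a library for microbiome researchers and built-environment
scientists; a thin `dustlight` CLI is included for shell use.

## The model

A community is a sequence abundance distribution (SAD): per-taxon 16S
gene-copy abundances χᵢ (copies per mg dust), i = 1…S, drawn from
Lognormal(μ, σ). The fraction of each taxon's gene copies that come from
living cells follows a logistic curve in abundance,

```
α(χ) = (λ − φ) / (1 + exp(−k (χ − χ₀))) + φ ,
```

with minimum/maximum viabilities φ ≤ λ, steepness k and half-saturation
abundance χ₀, so (α(χᵢ) χᵢ) are living population sizes. Sequencing is
size-biased sampling: a multinomial draw of a fixed depth (50,000 reads)
with probabilities proportional to living abundance. Each model iteration
draws (S, μ, σ, φ, λ, k, χ₀) from uniform ranges, sequences the intact
community and its truncated twin (the 10–65 most abundant taxa removed),
and records each surviving taxon's apparent change
log₁₀((c_after + 1)/(c_before + 1)).

The downstream statistics are the field-standard chain: negative-control
subtraction, rarefaction, qPCR scaling to absolute abundance,
log₁₀(1+x) transform, Canberra distances, PERMANOVA
(R² = SS_between/SS_total with a label-permutation null), permdisp-style
dispersion, ANOVA with Tukey contrasts, and Benjamini-Hochberg adjustment.

Because no deposited dataset reproduces the original experiment at desk
scale, the package ships a mechanistic synthetic generator
(`generate_experiment`) that emulates the design — 6 replicate inocula ×
3 microcosms × 3 treatments (dark / visible / ultraviolet) = 54
communities, each with paired PMA and non-PMA aliquots — with planted,
recoverable treatment effects and a full ground-truth record.

## Worked example

`examples/viability_pipeline.py` generates a default synthetic experiment,
runs the processing chain and estimates viable fractions:

```
taxa removed by control subtraction: ['contam1', 'contam2', 'contam3', 'contam4']
samples excluded by rarefaction:     none

estimated viable fraction (PMA qPCR / total qPCR):
  dark          14.0 %
  visible        6.6 %
  ultraviolet    7.2 %
  range across communities: 2.4 - 26.2 %
```

Dark dust retains about twice the living share of either light treatment;
the four spiked contaminant taxa are the only ones eliminated by
negative-control subtraction. `examples/community_comparison.py` continues
with β-diversity statistics on the living communities:

```
           contrast       R2     p  p_adjusted
       dark-visible 0.147122 0.001      0.0015
   dark-ultraviolet 0.143068 0.001      0.0015
visible-ultraviolet 0.023834 0.711      0.7110

mean distance to group centroid (dispersion):
dark           208.6
ultraviolet    157.0
visible        156.9
```

Both dark-vs-light contrasts are strong and significant while
visible-vs-UV is weak, and dark communities are the most dispersed — the
planted dominance gradient across dark microcosms drives their
variability. `examples/sampling_artefacts.py` prints the null model's
headline numbers: the mean apparent change in the lowest abundance decile
is positive, and ~90% of taxa below 500 copies/mg show |change| < 0.5.

The same capabilities are available from the shell:

```bash
dustlight generate --out data --seed 0
dustlight pipeline --counts data/counts.tsv --qpcr data/qpcr.tsv \
    --metadata data/metadata.tsv --controls data/controls.tsv \
    --depth 50000 --seed 0 --out processed
dustlight stats --counts processed/log10_absolute.tsv \
    --metadata data/metadata.tsv --n-perm 10000 --seed 0 --out stats
dustlight simulate --out ensemble --seed 0 --n-iter 1000
```

## Layout

* `src/dustlight/sampling_model.py` — SAD draws, logistic viability,
  truncation, multinomial read sampling, ensembles, exhaustive oracle
* `src/dustlight/pipeline.py` — control subtraction, rarefaction,
  absolute-abundance scaling, log transform, viable fractions
* `src/dustlight/stats.py` — Canberra, PERMANOVA, dispersion, ANOVA/Tukey
* `src/dustlight/synthetic.py` — the synthetic experiment generator
* `src/dustlight/io.py`, `config.py`, `cli.py` — TSV/BIOM readers,
  flat YAML config, thin CLI
* `docs/methods.md` — modelling choices, defaults and limitations
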