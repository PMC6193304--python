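# Methods notes

This note records the modelling assumptions, default parameter choices and
numerical conventions behind `dustlight`, and what the synthetic-data tests
do and do not demonstrate about real data.

## The sampling-theory null model

**Model.** A community is a vector of per-taxon 16S gene-copy abundances
(χᵢ), i = 1…S — the sequence abundance distribution (SAD) — drawn i.i.d.
from Lognormal(μ, σ), where μ and σ are the mean and standard deviation of
the *natural log* of abundance (the standard parameterization). The viable
fraction of a taxon's gene copies is the logistic α(χ) = (λ−φ)/(1+e^(−k(χ−χ₀)))+φ,
so living abundances are α(χᵢ)χᵢ. The model's only behavioural assumption
is that viability is a function of abundance alone; the four parameters
(φ, λ, k, χ₀) span constant, increasing-saturating and near-step
relationships, so the ensemble averages over a wide family of community
structures rather than committing to one.

**Sequencing model.** Libraries pooled at equal amplicon concentration are
modelled as a single multinomial draw of a fixed depth (default 50,000
reads) with probabilities proportional to living abundance. No PCR bias,
chimeras or read errors are modelled. One read-sampling realization is
drawn per community per iteration; "expected" surfaces are ensemble
averages across iterations.

**Paired design.** Each iteration samples the intact community, removes
the n most abundant taxa (n uniform on 10–65) from the SAD — "sequences"
are interpreted as taxa, i.e. SAD entries — and re-samples the survivors
at the same depth. Apparent change per surviving taxon is
log₁₀((c_after + pc)/(c_before + pc)) with pseudocount pc = 1 read on both
sides (configurable). The pseudocount keeps the statistic finite through
the zero→nonzero detection transitions that create the rare-taxon artefact
while preserving its sign; the alternative (conditioning on detection) is
not used.

**Parameter ranges.** One iteration draws each parameter uniformly from
ranges exposed in `ParamRanges` and the flat YAML config. Defaults:
S ∈ [500, 5000], μ ∈ [0, 3], σ ∈ [1, 4], φ ∈ [0, 0.2], λ ∈ [0.2, 1]
(φ ≤ λ enforced by sorting the two draws), removal ∈ [10, 65], depth
50,000. Two parameters are drawn in community-relative units so they stay
meaningful across nine orders of magnitude of lognormal scales: χ₀ is a
quantile (level ∈ [0.05, 0.99]) of the realized SAD, and k is drawn from
[0.1, 10] in units of inverse SAD interquartile range (the IQR is robust
to the extreme tails produced by σ up to 4; if the IQR is zero the raw
draw is used). These ranges are stand-ins chosen to produce communities
resembling the dust experiment; any alternative table of ranges can be
substituted verbatim through the config file.

**Abundance axis.** The ensemble surface relates apparent change to "true"
abundance. Since read sampling acts on the living pool, the default axis
is living abundance α(χ)χ; total χ is available via
`abundance_axis="total"`. Records with zero living abundance are dropped
from summaries (they are unobservable and have no log abundance).

**Ties and determinism.** Top-n selection breaks abundance ties by taxon
index (lowest removed first), making truncation deterministic. Ensembles
spawn one child seed per iteration from a root seed, so identical seeds
give bit-identical ensembles.

**Oracle.** `enumerate_exact` computes exact per-taxon expected counts and
expected apparent change by brute-force enumeration of every multinomial
outcome (for ≤ ~2·10⁵ outcomes), using independence of the before/after
draws to separate the log-ratio expectation. It shares no code with the
Monte-Carlo path and anchors the simulation tests.

**What the surface shows.** Three regimes emerge under the defaults:
taxa far below one expected read are unobservable in both communities and
have exactly zero apparent change; taxa near the detection limit show a
positive mean apparent change (detection transitions are asymmetric — a
taxon can only newly *appear* after removal frees reads); well-sampled
taxa shift by the common renormalization factor log₁₀(L/L′) of their
iteration (L, L′ = living totals before/after truncation), which is pure
composition bookkeeping, not a detection artefact. The tests assert each
regime separately.

## The processing pipeline

Order is fixed and logged: control subtraction → rarefaction →
absolute-abundance scaling → log₁₀(1+x). Negative-control counts are
aggregated across control samples by **sum** (configurable to per-taxon
max) before subtraction, flooring at zero and dropping taxa zeroed
everywhere; the narrative order (subtract before rarefy) is used since no
other order is documented for this style of analysis. Rarefaction is a
single seed-controlled multivariate-hypergeometric draw (without
replacement) to exactly the target depth; shallower samples are excluded
and reported. Absolute abundance is (count / row total) × qPCR total, so
each row sums to its sample's qPCR total by construction. Viable fractions
are PMA-aliquot qPCR totals over non-PMA totals for the same community
(aliquots paired on identical community keys differing only in the PMA
flag); ratios above 1, possible through assay noise, are capped at 1 and
flagged, since fractions are proportions by definition.

## Community statistics

Canberra distances are computed coordinate-wise with 0/0 terms
contributing zero (scipy's convention); the triangle inequality is not
asserted for Canberra on log abundances and is out of scope. PERMANOVA
uses the distance-based sum-of-squares partition (Gower-centered, i.e.
SS from squared distances divided by group sizes), R² = SS_between/SS_total,
and a label-permutation null with the +1 convention — the observed
statistic counts as a permutation, so p ∈ [1/(n_perm+1), 1]. Samples are
permuted freely (no strata). An exact mode enumerates all N! label
permutations for N ≤ 9, where p is the frequency of permutations reaching
the observed F. Pairwise contrasts run one PERMANOVA per unordered pair
of levels (default 10,000 permutations) with Benjamini-Hochberg adjustment
across the contrast set.

Dispersion analysis embeds the distance matrix by principal coordinates,
keeping negative-eigenvalue axes as imaginary coordinates; a sample's
squared distance to its group centroid is the real-part squared distance
minus the imaginary-part squared distance, floored at zero — the standard
correction for semi-metric dissimilarities. Centroids are ordinary means
in that space (not spatial medians). Group differences in dispersion are
tested by one-way ANOVA with Tukey contrasts on the distances. A fully
degenerate embedding (all samples identical) warns and returns zero
dispersions. `anova_tukey` reports F = ∞ (p = 0) explicitly when every
group has zero internal variance but means differ, and F = 0 (p = 1) when
all values are identical.

## The synthetic experiment generator

The generator is mechanistic — viability acting on a shared SAD — rather
than a resampling of real data, so every generated count is traceable to a
ground-truth record (true abundances, viabilities, sensitive-taxon ids,
per-aliquot seeds), enabling parameter-recovery tests.

* **Homogenized pool.** One lognormal base SAD (1200 taxa, log-sd 2,
  total 10⁷ copies/mg) shared by all 54 communities; per-community
  multiplicative lognormal taxon noise (log-sd 0.3) keeps replicates
  "relatively similar". Community totals are an independent lognormal
  draw (log-sd 0.15) around the pool total.
* **Sensitive clades.** Two dominant clades (23 "Saccharopolyspora-like"
  and 12 "Staphylococcus-like" taxa) are boosted to 30% of pool gene
  copies. Under visible/UV they are suppressed in total abundance (×0.06 /
  ×0.05) and much more strongly in viability (×0.05 / ×0.04 of the
  community viable fraction). In dark microcosms they are instead scaled
  by a per-microcosm gradient (×0.2, ×1, ×8), creating the compositional
  dominance gradient that makes dark communities the most dispersed; the
  gradient is compositional only (totals are renormalized). Two 3-taxon
  minor clades ("Acidimicrobiales-like", "Cytophagales-like") are boosted
  (×8) under visible and UV respectively, giving the visible-vs-UV
  contrast a real but weak signal.
* **Viable fractions.** Each community's fraction is its treatment target
  (dark 12%, visible 6.8%, UV 6.1%) times a mean-one lognormal multiplier
  with log-sd 0.45, clipped to [0.4%, 73%]. Non-sensitive taxa share a
  common viability solved so the community fraction equals the drawn
  value exactly. The across-community spread is a free parameter: the
  chosen log-sd keeps 18-community group means identifiable to within ~2
  percentage points while spanning roughly a 2–40% fraction range —
  narrower than the full range the clipping bounds allow, a deliberate
  trade-off in favour of recoverable group means.
* **Measurements.** Non-PMA read counts are multinomial in total
  abundances, PMA counts in living abundances, at per-aliquot depths
  uniform in 65,000 ± 8,000 reads (so rarefaction to 50,000 keeps all
  samples). qPCR totals are true totals with lognormal noise (log-sd 0.1);
  the resulting ratio estimator carries a ≈1% multiplicative bias,
  negligible at the reported precision. Four contaminant taxa are spiked
  into every aliquot (Poisson, mean 8 reads) and into the negative
  controls (Poisson, mean 40 per control), so control subtraction
  eliminates exactly those four taxa in a default run.

**What passing tests show — and don't.** The generator realizes the
statistical structure the analysis assumes: exchangeable replicates from
one pool, treatment effects acting through clade suppression and
viability, independent lognormal measurement noise. Real dust data violate
parts of this (taxon-correlated PCR efficiencies, overdispersed counts,
shared extraction batches, temporal dynamics over the 90-day exposure),
so end-to-end recovery here demonstrates correctness of the computations
and sensitivity of the statistics under the assumed model, not robustness
to those violations.

## Problem sizes

Default test and acceptance runs use 10³ null-model iterations (the
surface is summarized from ~2.7M taxon records), 500 null simulations ×
999 permutations for PERMANOVA calibration, 999-permutation contrasts in
end-to-end checks, and 5 generator seeds (90 communities per treatment)
for viability recovery — sizes at which every Monte-Carlo tolerance in the
tests is comfortably resolved on a single CPU.
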