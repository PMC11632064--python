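# Methods

This note documents the statistical procedures implemented in
`mitoscreen`, the design choices made where several conventions exist,
what the synthetic-data generator does and does not emulate, and the
known limitations.

## The dependency–expression screen

**Inputs.** An expression matrix (cell lines × genes, log-scale
abundance, missing values allowed) and a perturbation-effect matrix
(cell lines × approaches). Effect scores follow the dependency-portal
polarity convention — Chronos-like CRISPR scores, DEMETER2-like RNAi
scores, and drug log2 fold-change of cell count all become *more
negative* the more the perturbation impairs proliferation, so a higher
score means a more resistant line. Loaders assert this orientation from
the effect matrix's JSON sidecar and refuse matrices declaring any other
convention; no re-orientation is ever applied.

**Correlation.** Spearman ρ is the Pearson correlation of mid-ranks
(average ranks on ties), computed per (gene, approach) over
pairwise-complete observations — the cell-line intersection is recomputed
against each approach's own missing pattern. The default two-sided P
value uses the t approximation t = ρ·√((n−2)/(1−ρ²)) with n−2 degrees of
freedom, which is standard and accurate for panels of tens to hundreds
of lines; |ρ| = 1 reports P = 0. An exact-permutation P (enumeration of
all n! orderings of one mid-rank vector, two-sided by |ρ|) is available
for n ≤ 9 and serves as the small-sample reference. Records with fewer
than `min_pairs` complete pairs (default 10, below which the t
approximation is unreliable) or a constant vector are flagged
insufficient rather than raising; flagged records never count as
selection evidence.

**Selection.** A gene is selected when at least `min_evidence = 2`
approaches reach raw P < α = 0.05. Direction is *resistance* when every
significant ρ is positive, *sensitizing* when every one is negative, and
*discordant* on a sign conflict; discordant genes are reported
separately rather than silently dropped, because sign conflicts carry
diagnostic value and are rare when the approaches genuinely share a
target. No multiple-testing correction is applied by default — the
evidence-count rule is itself the replication filter — but a
Benjamini–Hochberg mode (within-approach) is available. Outputs are
ordered deterministically by gene identifier.

**Null calibration.** With m independent approaches, the probability
that a null gene collects ≥ 2 significant records is
1 − (1−α)^m − mα(1−α)^(m−1) ≈ 0.0572 at α = 0.05, m = 8. The test suite
verifies the empirical selection fraction of an all-null panel against
this closed form within three Monte-Carlo standard errors. Note the
implication: a raw-P screen over hundreds of null genes *will* admit
false positives at roughly this rate — on the standard synthetic panel
(460 null genes, 40 planted) this yields an average false-discovery
proportion near 0.45, which is an inherent property of the published
selection rule, not an implementation artifact. Users wanting a
controlled FDR should enable the BH mode or raise `min_evidence`.

## Synthetic panels with planted signal

The generator emulates the statistical structure the screen assumes:
partially overlapping cell-line sets, approach effect scores with
missing values, planted resistance/sensitizing genes at a controlled
rank correlation, and exchangeable null genes.

**Mechanism.** Approaches targeting the same gene product are strongly
inter-correlated in real dependency panels, so effect scores share a
latent per-line dependency factor: effect_a = √b·f + √(1−b)·ε_a with
b = `approach_correlation` (default 0.45). A planted gene mixes the
standardized mean of its k signal approaches' effect scores into its
expression with weight w solved from w·√(b + (1−b)/k) = ρ_P, where
ρ_P = 2·sin(π·ρ_S/6) inverts the bivariate-normal relation
ρ_S = (6/π)·arcsin(ρ_P/2); the population Spearman correlation with each
signal approach then equals the requested ρ_S (sign flipped for
sensitizing genes). The shared factor is not optional: a gene cannot
correlate at ρ_P ≈ 0.62 with four mutually independent vectors
(Σρ² > 1 violates Cauchy–Schwarz), so any data-generating process
consistent with the target correlations must correlate the approaches.
Two consequences are documented rather than hidden: planted genes also
correlate (more weakly) with their non-signal approaches, and null
genes' per-approach P values are positively dependent whenever b > 0.
Tests of the independent-approach closed form therefore construct panels
with `approach_correlation = 0` and no planted genes.

**What is not emulated.** Realistic RNA-seq count noise, lineage
structure, copy-number confounding, and dose–response shapes. Effects
are already-summarized scores, as in the public dependency portals.
Passing recovery tests therefore demonstrates the selection machinery's
correctness, not robustness to confounding in real compendia.

**Other generators.** DE tables realize exact per-state up/down counts
(`round(fraction·n)` genes pushed past the thresholds per direction) so
polarization percentages round-trip exactly; flux runs realize the
five-phase injection schedule with per-well Gaussian noise; Ct tables
realize requested fold changes. Every generator is a pure function of
its parameters and seed.

## Mitochondrial annotation and essentiality

Annotation (mitochondrial membership, pathway labels, essentiality) is
consumed as input, mirroring curated resources; membership is never
re-derived. Pathway hierarchies are flat "A > B" strings, pipe-delimited
in files — sufficient for tallies and robust to hierarchy edits. A gene
with k labels contributes to k pathway rows; unduplicated per-direction
totals are reported alongside, and label-less genes pool under
"Unclassified".

Essentiality labels are consumed when provided. The fallback
score-based classifier uses the knockout-score distribution across
lines: *common_essential* when the median ≤ −1 (the −1 line is the
median of all common-essential gene scores in Chronos-scaled data);
*nonessential* when both the median and the lower quartile stay above
−0.5; *selective* otherwise, i.e. strong essentiality confined to a
minority of lines. Quantiles use linear interpolation; both thresholds
are parameters.

## Clustering

The gene × approach ρ matrix is clustered agglomeratively with Euclidean
distance and average linkage (UPGMA), on rows, columns or both.
Distances are computed on the raw correlation values — ρ is already
bounded, so no standardization is applied. Merge heights equal the
unweighted mean of all cross-cluster pairwise distances; the test suite
checks them against an exhaustive brute-force oracle to 1e-12. Leaf
order follows plain agglomeration order for determinism; an
optimal-leaf-ordering pass is available but off by default. Exact
distance ties are resolved by the linkage algorithm's deterministic scan
order. Missing values are a structural error: impute or drop before
clustering.

## Phenotype-switching readouts

DE calls are three-way: *up* iff log2FC > log2(fc_threshold) and
p_adj < padj_threshold (defaults 1.2 and 0.05, the common figure-legend
convention; a looser FDR < 0.1 screen is one parameter away — both
conventions appear in practice and the choice is left to the caller).
The polarization score reports, per phenotype state, the percentage of
its marker genes called up and down; the denominator is the state's
genes *detected* in the contrast, since undetected genes carry no
evidence either way. States with no detected gene are flagged
not-evaluable rather than scored 0. The seven state names ship as
editable GMT placeholders; real marker memberships are inputs.

The inflammation-correlation sum adds each query gene's pairwise
Spearman ρ against every member of an inflammation gene set (self-pairs
excluded; insufficient pairs contribute 0 and are counted), bounding the
score by ±|set|.

## Bioenergetics

Phase summaries collapse each phase's measurement cycles per well by
arithmetic mean (robust to cycle noise; a last-cycle mode is available).
Non-mitochondrial respiration — the rotenone/antimycin-phase OCR — is
subtracted from all OCR summaries; ECAR is not corrected (the correction
is defined for oxygen consumption only). Then per well: basal =
corrected baseline; proton leak = corrected post-oligomycin; ATP-linked
= basal − leak; maximal = corrected post-FCCP; spare capacity = maximal
− basal; maximal ECAR = post-monensin; glycolytic reserve = maximal −
basal ECAR. The coupling fraction, ATP-linked/basal, expresses the share
of mitochondrial respiration devoted to ATP synthesis; it is a standard
derived quantity, documented here as this package's chosen definition.
All rates are divided by the well's cell count, metrics are computed per
well and then averaged per group, and negative corrected OCR values are
retained but flagged. Percent-of-reference mode rescales OCR metrics by
the reference group's basal respiration and ECAR metrics by its basal
ECAR, pinning both reference basals at exactly 100%.

## qPCR quantification

Technical replicates are averaged per (sample, target) before any delta
is taken. ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the
*mean* ΔCt of the control samples (equivalently, the geometric mean of
control folds is exactly 1); fold = E^(−ΔΔCt) with amplification
efficiency E = 2 by default (perfect doubling; per-primer efficiencies
are a parameter). The mtDNA/gDNA ratio is E^(Ct_genomic − Ct_mito).
Samples missing a required Ct are flagged and excluded, never silently
dropped.

## Network statistics

Graphs are undirected, without self-loops or duplicate pairs; a declared
node list retains isolated (edge-less) nodes. Average node degree is
2|E|/|V| over *all* declared nodes, reported to two decimals. The local
clustering coefficient of a degree-<2 node is 0 and such nodes are
included in the clustering mean by default, so the denominator matches
the degree convention; an exclude-low-degree mode is provided because
published network statistics use either convention. Edge confidence
scores, when present, are thresholded at load time (default 0.400) and
then ignored.

## Problem sizes and determinism

The test suite and the acceptance script use the standard benchmark
panel (40 lines × 500 genes, 20 + 20 planted at |ρ| = 0.6 on 4 of 8
approaches, 10% missingness, 20 replicate seeds), a 2,000-gene all-null
panel at 100 lines for calibration, 200 small vector pairs for the
rank-correlation oracle, and matrices of ≤ 8 items for the clustering
oracle — sizes at which the brute-force oracles are exact and fast.
Every random quantity flows through a single seeded generator per run;
identical seeds reproduce outputs bit-for-bit, and the pipeline stamps
every output table with the hash of its resolved configuration.

## Known limitations

- The screen is correlational; no adjustment for lineage or other
  confounders is attempted, and no causal claims follow from selection.
- The raw-P evidence-count rule does not control the false-discovery
  rate (see the calibration analysis above).
- The t-approximation P is slightly conservative at small n; use the
  exact-permutation mode below ~10 informative lines.
- The flux module consumes the documented long-format CSV only; it does
  not parse instrument files, and it does not model proton production
  rate or glycolytic ATP.
- Annotation quality bounds the mitochondrial restriction: genes absent
  from the annotation are an error by default (or dropped under an
  explicit allow-missing flag), never guessed.
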