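# Methods

This note documents the models, parameter choices and limitations behind
`thermophos`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py` at run time.

## Quantitative proteome model

Protein abundances are label-free MS intensities over three conditions —
cold stress (22 °C), optimum (35 °C), heat stress (40 °C) — with ≥ 2
(by default 3) biological replicates each.

**Signal filter.** A measurement is kept iff intensity ≥ 3 × its noise
estimate; the comparison is strict on the low side ("lower than" is
removed, equality kept). Filtering is idempotent and the removed count is
logged. A present intensity without a noise estimate is an error naming
the measurement, not a silent drop.

**Differential testing.** For each stress s ∈ {22 °C, 40 °C} vs the
optimum:

* fold change FC = mean(stress replicates) / mean(optimal replicates) on
  *linear* intensities — the scale on which MS fold changes are
  conventionally reported;
* p-value from a two-sided **pooled-variance (Student) t-test on log₂
  intensities** — log-space testing is the standard for multiplicative MS
  noise, and the pooled variant is the classical default when the
  variance model is unspecified. Zero-variance degenerate inputs fall back
  to p = 1 (equal means) or p = 0 (distinct means);
* calls use **inclusive** thresholds: UP iff FC ≥ 1.5 and p ≤ 0.05, DOWN
  iff FC ≤ 1/1.5 and p ≤ 0.05. A protein with < 2 present replicates in
  either condition, or a non-positive optimal mean, is UNTESTABLE with a
  reason.

No multiple-testing correction is applied in the headline path (the
original workflow uses raw p ≤ 0.05); Benjamini–Hochberg is available via
`Thresholds(adjust_pvalues=True)` (scipy's `false_discovery_control`).
A one-group t-test against zero and a per-protein one-way ANOVA across the
three conditions are exposed as descriptive statistics; calls always
derive from the pairwise contrasts. No imputation is performed.

**Regulation classes.** The pair of calls maps deterministically onto nine
classes (both up, both down, opposite in either orientation, single-sided
in either direction, none). UNTESTABLE is treated like NOT_SIGNIFICANT for
classification, so the mapping is total.

**Clustering.** Mean log₂ profiles per condition are clustered by
agglomerative average linkage with Euclidean distance
(`scipy.cluster.hierarchy`); proteins with an incomplete profile are
excluded with a warning. The dendrogram serializes to Newick with
branch lengths chosen so leaf-to-root depth equals the final merge height.

## Phosphopeptide model

Evidence rows carry a peptide string in the lowercase-residue convention
(lowercase s/t/y = phosphorylated) plus site labels `T234t` interpreted as
1-based **protein** coordinates. Parsing cross-validates mark counts and
residue identities against the labels; position-level validation against
the protein sequence is only possible when sequences are available (the
synthetic generator guarantees it, the packaged worked example does not
ship full-length sequences). Stringency is a post-search metadata filter
on |precursor| / |product| mass tolerances: high = 20/50 ppm, low =
50/100 ppm, bounds inclusive, so the high-stringency result is always a
subset of the low-stringency one.

Aggregation deduplicates sites by (residue, position) and unions detection
conditions across peptides covering a site. **Unique phosphopeptides are
counted by distinct unmodified (case-insensitive) sequence** — this is the
identity under which the packaged worked example's per-protein counts sum
to its printed totals row (70 peptides, 44 unique); counting distinct
modified strings would give 70. Site-type ratios are percentages over
distinct sites, rounded to one decimal.

## Bi-level identification

A protein is a bi-level *candidate* when it appears in both the
differential-expression results (a computed fold change in at least one
contrast) and the phosphosite inventories. It is *reported* when
additionally one contrast shows |log₂ FC| ≥ log₂ 1.5 with p ≤ 0.05. This
two-tier definition reproduces the study's narrowing of 40 quantified
phosphoproteins to 31 reported ones; both sub-threshold and non-significant
candidates are excluded from the reported tier. Report rows are ordered by
accession and totals are column sums, so the report is invariant under
input permutation.

## Orthology

**Alignment.** Homology scores come from exact Smith–Waterman local
alignment with affine gaps via `Bio.Align.PairwiseAligner` (BLOSUM62, gap
open 11, extend 1, i.e. a gap of length L costs 11 + L). At the proteome
sizes this package targets (10²–10³ sequences) the exact dynamic program is
affordable and removes the nondeterminism of seeded heuristics. An
independent O(nm) Gotoh implementation in the test suite checks the scores.

**Significance.** E-values use the ungapped Karlin–Altschul form
E = K·m·n·e^(−λS) with the published BLOSUM62 constants λ = 0.3176,
K = 0.134 and search space m × n per pair. Gapped λ estimation and
composition-based adjustment are out of scope; for the ortholog-detection
regime (near-identical sequences, E ≪ 10⁻¹⁰) the ungapped statistic is
amply conservative, and the empirical shuffled-sequence null in the tests
confirms random 50-mers essentially never cross the threshold.

**RBH.** (a, b) is an ortholog pair iff each is the other's highest-scoring
hit and both e-values are **strictly** below 10⁻¹⁰. Ties on raw score break
to the lexicographically smallest subject accession, making the result
deterministic and symmetric in the proteome order.

**MCL.** Orthologous groups come from Markov clustering of the undirected
similarity graph weighted by −log₁₀ E (edges below the e-value cutoff
only). Defaults: inflation 1.5, tolerance 10⁻⁶, ≤ 100 iterations,
self-loop weight = each node's maximum incident weight (1 for isolated
nodes). Columns are renormalized after inflation and pruning. Attractor
rows (positive diagonal mass) define clusters; overlapping attractor
supports merge, and any unassigned node joins its strongest attractor's
cluster, so the output is always a partition. Non-convergence returns the
current partition with a flag. With aggressive inflation the partition
collapses to the strongly connected cores, which the tests exercise on
bridged-clique toys.

**Domain confirmation.** "Similar domain architecture" is operationalized
as multiset Jaccard ≥ 0.5 between domain-token lists for *all* member
pairs; fewer than two annotated members yields *unknown* (None), distinct
from False.

## Interolog transfer and overlay

Each template bait→prey edge is expanded to the full Cartesian product of
the query-species members of the bait's and prey's ortholog groups — the
information-preserving choice for many-to-many groups — and every inferred
edge carries (template edge, bait group, prey group) provenance.
Unmappable endpoints produce skip-log entries, not errors. Direction is
preserved in the data model but ignored for neighborhood extraction and
edge classification.

Node overlay: six-sector circles for bi-level proteins (upper sector
triple = quantitative detection, lower = phospho detection, ordered
HIGH/OPT/LOW left→right), strip-shaded rectangles for differentially
expressed proteins (grey border), diamonds otherwise (black border).
Circle borders are cyan when the ≥ 1.5-fold significant filter was met,
pink otherwise. Edges: green between two circles, purple between a circle
and a rectangle, neutral otherwise. Proteins with no ortholog in the
template species appear as isolated nodes (rendering them is the default,
as in the original figure). SVG layout is a spring embedding with fixed
seed and iteration count and fixed-precision coordinates, so identical
inputs give byte-identical files; GraphML and SIF carry all attributes.

## Synthetic data generator

The generator emulates the study design, not the instrument: three
conditions × three biological replicates, log-normal intensities (protein
baselines N(17, 1.5²) on log₂ scale; replicate sd 0.2 log₂ units),
planted signed log₂ fold changes drawn uniformly from [log₂ 1.5, 2.0] for
10% of proteins per contrast, a planted sub-threshold stratum (2% of
measurements, placed on effect-free proteins) for the 3×-noise filter,
condition-dependent phosphopeptide detections (per-condition detection
probabilities 0.8/0.6/0.8) emitted as tryptic fragments (cleavage after
K/R not before P, ≤ 2 missed cleavages) with lowercase marks, orthologous
proteome pairs mutated at a configurable per-site divergence (default 5%)
over a fixed background amino-acid composition, and a random bait→prey
template network. One global seed drives all sub-generators through numpy
`SeedSequence` spawning, so a dataset is a pure function of its config.

What it does **not** emulate: spectra, retention times, peptide-level
quantification noise structure, intensity-dependent missingness, paralog
families, or domain content of sequences. Recovery results on this
generator therefore demonstrate correctness of the pipeline's logic and
statistics under the stated noise model, not performance on real LC-MS/MS
data.

**Recovery scoring.** `evaluate_recovery` reports per-stage
sensitivity/precision against the planted truth. Differential-expression
recovery is scored at the *significance step* (p ≤ 0.05 with the planted
direction), mirroring the workflow's ordering in which the 1.5-fold filter
is a downstream reporting cut: for an effect at exactly the fold cutoff,
an unbiased estimate clears the inclusive cutoff only about half the time,
so a definition entangling both filters would bound sensitivity near 0.5
by construction (the closed-form power of the n=3, sd 0.2 pooled t at a
log₂ 1.5 effect is 0.763). The fold filter is still exercised where it
belongs: in the reported/bi-level tiers and their completeness checks.

## Numerical and degenerate-input choices

* Inclusive p/FC thresholds, strict noise filter and strict RBH e-value
  threshold, as stated above.
* Lexicographic tie-breaks everywhere (RBH subjects, report ordering,
  group numbering, export element order) for determinism.
* Zero-variance t-test inputs: p = 1 for equal means, p = 0 otherwise.
* Empty site sets are an error for ratios but a valid all-zero inventory
  for aggregation with an explicit accession.
* MCL pruning threshold doubles as the convergence tolerance (10⁻⁶).
* JSON artifacts are written with sorted keys; SVG/Newick use fixed
  formatting precision (6 significant digits).

## Problem sizes

The shipped checks run at desk scale: the 31-protein / 70-peptide worked
example; 500-protein abundance matrices for differential-expression
recovery; 100 + 100 sequences (80–200 residues) for the
reciprocal-best-hit suite; ≤ 10-node graphs for the MCL oracle
comparisons; 150 template edges for transfer completeness. These sizes
give stable Monte-Carlo estimates (binomial se ≤ 0.03 on the recovery
rates) while keeping the whole suite fast enough to run routinely.

## Known limitations

* The packaged worked example transcribes a published report whose
  condition check-marks are positionally ambiguous in the available text;
  ambiguous marks were assigned leftmost-first (22 → 35 → 40 °C) with one
  narratively determined exception. Counts and totals are unaffected.
* The expression side of the worked example carries nominal synthetic
  fold-change magnitudes (2.0 / 0.5) standing in for the unpublished
  values; only the printed regulation directions are authentic.
* Phosphosite localization probabilities (Ascore-style) are not modeled;
  sites are taken as given by the upstream search.
* The e-value statistic is a calibrated stand-in for full gapped BLAST
  statistics; absolute e-values near the threshold should not be
  over-interpreted.
* Dataset-level inventories of the original study (hundreds of identified
  and differentially expressed proteins) require the raw MS data and are
  deliberately out of scope; the synthetic recovery suite covers those
  pipeline stages instead.
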