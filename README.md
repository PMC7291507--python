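# thermophos

Temperature-stress proteome/phosphoproteome integration and interolog PPI
networking for cyanobacteria.

When a cyanobacterial culture (here *Arthrospira platensis* C1) is shifted
from its optimal growth temperature (35 °C) to a cold (22 °C) or heat
(40 °C) stress, the response shows up at two regulatory levels at once:
protein abundance changes, and Ser/Thr/Tyr phosphorylation patterns change.
Proteins regulated at **both** levels — significantly up- or down-regulated
≥ 1.5-fold *and* detected as phosphorylated — are called **bi-level
regulated proteins**, and they are the natural seeds for tracing
signal-transduction cascades (two-component-system histidine kinases,
Ser/Thr kinases) down into metabolism. `thermophos` implements that
analysis as a tested, reusable pipeline for proteomics and systems-biology
researchers:

1. **Quantitative proteome** (`thermophos.quant`) — signal-threshold
   filtering (intensities < 3 × noise removed), per-protein differential
   testing of each stress against the optimum (two-sided pooled t-test on
   log₂ intensities, p ≤ 0.05; fold change FC = mean(stress)/mean(optimal)
   on linear intensities, |log₂ FC| ≥ log₂ 1.5), regulation classes across
   the two contrasts, and average-linkage hierarchical clustering of
   expression profiles.
2. **Phosphoproteome** (`thermophos.phospho`) — parsing of phosphopeptide
   evidence in the lowercase-residue convention (`TIVyKGMVRSAVLGEFYR` +
   label `Y237y`), stringency-tier filtering by mass tolerance
   (high: ±20/±50 ppm; low: ±50/±100 ppm), and per-protein site
   inventories with pS/pT/pY counts and type ratios.
3. **Bi-level integration** (`thermophos.bilevel`) — intersection of the
   two evidence layers and the published report format with column totals.
4. **Orthology** (`thermophos.orthology`) — exact Smith–Waterman local
   alignment (BLOSUM62, affine gaps 11/1) with Karlin–Altschul e-values
   (E = K·m·n·e^(−λS)), reciprocal best hits at E < 10⁻¹⁰, Markov
   clustering (MCL) of the −log₁₀ E similarity graph into orthologous
   groups, and domain-architecture confirmation (multiset Jaccard ≥ 0.5).
5. **Interolog network** (`thermophos.network`) — transfer of a curated
   bait→prey interaction template (e.g. *Synechocystis* yeast-two-hybrid
   pairs) onto the study species through the ortholog groups, with full
   provenance per inferred edge, condition-overlay node decoration
   (six-sector circles / striped rectangles / diamonds), edge classes, and
   GraphML / SIF / deterministic SVG export.
6. **Synthetic data** (`thermophos.simulate`) — a generator that emulates
   the full study design with planted ground truth, plus per-stage
   recovery scoring.

## Worked example

The package ships the published bi-level report of the C1 temperature-shift
study as a worked example: 70 phosphopeptide evidence rows for 31 proteins.

```python
from thermophos import datasets
from thermophos.bilevel import build_bilevel_report

report = build_bilevel_report(datasets.bilevel_example_records())
print(len(report.rows), report.totals)
```

prints

```
31 (70, 44, 30, 36, 15, 81)
```

i.e. 31 bi-level regulated proteins whose evidence comprises 70
phosphopeptides (44 unique unmodified sequences) carrying 30 pS + 36 pT +
15 pY = 81 distinct phosphosites — the totals row of the published table.
The curated site list of the multi-sensor histidine kinase Hik28
(SPLC1_S041070) is also packaged:

```python
print(datasets.hik28_inventory().counts)   # (5, 3, 0, 8)
```

8 sites, 5 pS and 3 pT, all detected only after the cold shift.

On synthetic data the same pipeline runs end to end from the shell:

```sh
$ thermophos simulate --seed 9 --out demo
synthetic bundle (500 proteins, 153 phosphopeptides) -> demo
$ thermophos quantify --abundance demo/abundance.tsv --out quant
signal filter removed 90 value(s)
LOW vs OPT: 22 up, 26 down -> quant/expression_LOW_vs_OPT.tsv
HIGH vs OPT: 26 up, 21 down -> quant/expression_HIGH_vs_OPT.tsv
$ thermophos phospho --peptides demo/phosphopeptides.tsv --out sites.tsv
119/153 peptides pass HIGH stringency; 67 phosphoproteins -> sites.tsv
$ thermophos bilevel --expression quant/expression_LOW_vs_OPT.tsv \
    --expression quant/expression_HIGH_vs_OPT.tsv \
    --peptides demo/phosphopeptides.tsv --out bilevel.tsv
75 candidates, 19 reported; sites pS=14 pT=10 pY=8 total=32 -> bilevel.tsv
```

The 90 removed values are the planted sub-threshold stratum; the 75
candidates are quantified phosphoproteins, of which 19 pass the significant
≥ 1.5-fold filter. `thermophos run-all --config run.yaml` chains every
stage (including orthology and network export) and writes a manifest with
input checksums and per-stage counts; identical configs give byte-identical
outputs. See `docs/methods.md` for models, parameters and limitations.

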