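# Methods

## Expansion model

The pipeline treats marker discovery as module recovery by guilt by
association. The underlying assumption is that disease genes are
co-regulated: they share upstream transcription factors and co-occur in
functional pathways. Both expansion tracks are *pure membership*
operations — a gene enters the TF track as soon as one TF regulates both
it and a seed, and enters the pathway track as soon as it shares one
kept pathway with a seed. No enrichment statistic is computed; the
knowledge bases are taken as curated fact, and their individually high
false-positive rates are controlled downstream by (1) intersecting the
two tracks, and (2) requiring the same prediction from a second,
disjoint seed set.

Consequences of this design worth knowing:

* Expansion is monotone: adding a seed, or raising the pathway size cap,
  can only grow a track. Tests assert this as a property.
* Regulation mode (activation/repression) never affects membership; it
  is carried as provenance only. The method predicts *differential*
  expression, not its direction.
* Seeds themselves usually reappear in both tracks (they are regulated
  and pathway-annotated like any gene). `PredictionResult` therefore
  exposes both the raw intersection (`predicted`) and the seed-free view
  (`novel`); reported counts include both.

## Pathway filtering

`PathwayFilterConfig` keeps a pathway when its size is ≤ `max_size`
(default 80; "more than 80 genes" is excluded, so a size-80 pathway is
kept and size-81 is dropped), its id is not explicitly excluded, and its
name matches none of the configured case-insensitive substrings. The
name-pattern list reproduces what is in practice a manual curation of
disease-unrelated pathways; the shipped default is empty because that
curation is the user's scientific judgement, not the package's.

## Cross-validation and ranking

Two predictions from disjoint seed sets are compared by plain set
algebra (overlap, one-sided remainders, Jaccard index). Co-expression
is used strictly for prioritization: each predicted gene is scored by
its number of distinct seed neighbors in the co-expression graph and the
summed weight of those edges, ordered (count desc, weight desc, symbol
asc) — the total order exists only so reports are reproducible.
`retained` (≥ 1 seed neighbor) marks the candidates one would carry into
bench validation; the others remain in the ranking tail because absence
of co-expression evidence is not evidence of absence.

## qPCR quantification

Relative expression is the Livak estimator `2^(−ddCt)` with
`ddCt = mean dCt(cancer) − mean dCt(mucosa)` over replicates, and
`dCt = Ct(gene) − Ct(reference)` within each replicate. Choices:

* **Multi-reference normalization.** The per-replicate reference Ct is
  the arithmetic mean of the reference genes' Ct values (GAPDH, 18S and
  28S rRNA by default). Averaging in Ct space equals the geometric mean
  of the reference quantities, the standard multi-reference normalizer.
* **Significance.** Two-tailed two-sample t-test on the replicate dCt
  values; Welch (unequal variance) by default, with pooled-variance and
  paired variants available since spreadsheet T.TEST conventions vary.
  Degenerate zero-variance groups: equal means give p = 1, unequal give
  p = 0. No multiple-testing correction is applied by default, matching
  the single-gene decision convention the classifier encodes; with 42
  genes at α = 0.05 roughly two false positives are expected, which
  users should weigh when interpreting any single call.
* **Efficiency.** Amplification efficiency is fixed at 100% (base 2).
  An efficiency-corrected mode (base 1 + E) is available but off by
  default.
* **Classification.** A record is called up/down only at p < α
  (α = 0.05); the arrow grade bins the symmetric fold
  `max(ratio, 1/ratio)` with half-open boundaries [2, 4), [4, 8), and
  ≥ 8 for four arrows. A ratio of exactly 1 is "none" regardless of p.

The packaged `table3.tsv` transcribes the published 42-gene × 3-patient
outcome table (ratio, p, and the printed annotation); the classifier
reproduces all 126 printed calls, and the per-patient (17/6, 25/2, 32/6)
and cross-patient (7 up in all, 40 up in ≥ 1, 41 altered in ≥ 1, CDKN1A
never significant) tallies. Raw per-replicate Ct values for that cohort
are not public, so the printed p-values themselves cannot be recomputed
— only the (ratio, p) → class mapping is checkable, and is.

## Synthetic data

`simulate_knowledge_bases` builds a universe with a planted disease
module (default 25 genes), two disjoint 10-gene seed sets, and the
wiring the method assumes: every module gene is a target of ≥ 1 TF that
also targets a seed (for each seed set separately) and co-occurs with
seeds in kept-size pathways. It also emits the failure modes the
pipeline must survive: single-track decoys at `decoy_rate` (default 0.2
of the module size per track) that the intersection must remove,
optional shared decoys wired into both tracks that quantify the
method's irreducible false positives, an oversized (> 80 genes) pathway
and a disease-unrelated "Olfactory transduction" pathway per seed set to
exercise the filters, and background TFs/pathways/edges that must stay
unreachable. A `truth.json` record carries the module, all decoy
classes and the expected intermediate counts, so end-to-end runs are
checked against construction, not against re-derivation.

`simulate_ct_data` draws, per gene, a baseline Ct uniform in [18, 30]
cycles (the plausible qPCR working range; the value cancels out of
ddCt), sets the cancer-tissue mean to `baseline − log2(true fold)`, and
adds i.i.d. Gaussian replicate noise (default sd 0.1 cycles, triplicate,
three patients). Reference genes share one baseline per patient across
both tissues. Defaults mirror the target study design: 10 seeds per
set, triplicate measurements, three reference RNAs, and roughly a third
of the module co-expressed with seeds.

What the simulation does **not** emulate: incomplete and biased
knowledge bases (real TF/pathway databases miss true edges and contain
stale ones), transcriptome-scale gene counts, correlated replicate
noise, inter-patient biological variability in the true fold change,
and amplification-efficiency differences between genes. Passing the
recovery tests therefore shows the *procedure* is implemented correctly
and is exact under its own assumptions — not that real knowledge bases
satisfy those assumptions.

All randomness derives from one master seed through named substreams
(network / pathways / coexpr / ct / folds), so regenerating one artifact
never perturbs another, and identical configs produce byte-identical
bundles.

## Numerical and engineering choices

* Gene symbols are uppercased and whitespace-stripped everywhere; an
  optional alias table resolves non-standard spellings (the packaged one
  maps BCL-2→BCL2, MK167→MKI67, TFGBRII→TGFBR2, VEGF→VEGFA).
* Duplicate TF interactions keep the first occurrence; duplicate
  pathway ids keep the last (with a warning); duplicate co-expression
  pairs keep the first.
* Problem sizes in tests and simulations (≈ 400-gene universe, 40 TFs,
  24 pathways, 500 Monte-Carlo repeats for fold-recovery checks) are
  chosen so the full suite runs in well under a minute while keeping
  Monte-Carlo standard errors far below the asserted tolerances.
* `run-all` writes a manifest with SHA-256 input hashes and the echoed
  configuration, and avoids timestamps, so identical inputs yield
  byte-identical output trees.

## Known limitations

* Predictions are only as good as the knowledge-base snapshots supplied;
  counts obtained from different database versions are not comparable.
* The intersection rule cannot remove a decoy present in both knowledge
  bases for spurious reasons (the shared-decoy simulation quantifies
  exactly this).
* The qPCR stage assumes equal amplification efficiency across genes
  unless the efficiency-corrected mode is used, and triplicates give the
  t-test little power for fold changes below ~1.5 at realistic noise.
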