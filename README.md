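# markermine

Bottom-up discovery of candidate disease biomarker genes from a small
seed set of validated markers, with qPCR-based quantification of the
candidates.

Most marker-discovery studies work top-down: measure everything, then
filter. `markermine` implements the reverse, knowledge-driven strategy.
Starting from ~10 genes with a proven disease association (the *seeds*),
it expands the candidate set by guilt by association through two
independent knowledge bases:

* **TF track** — find every transcription factor known to regulate a
  seed, then collect *all* known targets of those TFs (genes sharing an
  upstream regulator with a disease gene are plausibly co-dysregulated);
* **pathway track** — find every curated pathway containing a seed,
  drop pathways with more than 80 member genes (top-level catch-alls)
  and pathways curated as disease-unrelated, then collect all members of
  the kept pathways.

Each track alone is noisy, so only genes found in **both** tracks are
predicted. The procedure is validated by running it again from a second,
disjoint seed set and intersecting the two predictions; candidates are
then prioritized (never selected or de-selected) by co-expression with
the seeds. Finally, prioritized candidates are tested in matched
tumor/normal tissue by qPCR and quantified with the Livak method:

    dCt(tissue) = Ct(gene, tissue) − Ct(reference, tissue)
    ddCt        = mean dCt(cancer) − mean dCt(mucosa)
    ratio       = 2^(−ddCt)

Significance is a two-tailed t-test on replicate dCt values (Welch by
default). Significant calls (p < 0.05) are graded by the symmetric fold
change `max(ratio, 1/ratio)`: one arrow < 2-fold, two arrows 2–4, three
arrows 4–8, four arrows ≥ 8.

The package ships the colorectal-cancer reference data it was built
around: the two seed sets of 10 validated CRC markers each, and the
published qPCR outcome table for 42 tested candidates across 3 patients.
A synthetic-data generator produces complete input bundles (regulatory
network, pathway database, co-expression edges, Ct measurements) with a
planted disease module and a ground-truth record, so the whole pipeline
is testable offline.

## Worked example

```python
from markermine import (SimulationConfig, simulate_knowledge_bases,
                        predict_markers, cross_validate, rank_by_coexpression)

cfg = SimulationConfig(rng_seed=7)            # 25-gene planted module
sim = simulate_knowledge_bases(cfg)
pa = predict_markers(sim.seeds_training, sim.network, sim.pathways)
pb = predict_markers(sim.seeds_validation, sim.network, sim.pathways)
print(pa.counts)
cv = cross_validate(pa.novel, pb.novel)
print(len(cv.overlap), sorted(cv.overlap) == sim.truth["module"])
ranked = rank_by_coexpression(cv.overlap,
                              pa.seeds | pb.seeds, sim.coexpression)
print(len(ranked.retained))
```

prints

```
{'n_seeds': 10, 'n_tfs': 10, 'n_tf_targets': 40, 'n_pathways_kept': 5,
 'n_pathway_genes': 84, 'n_predicted': 35, 'n_predicted_novel': 25}
25 True
8
```

— the 10 training seeds reach 10 upstream TFs and 40 TF targets, the
pathway track keeps 5 pathways (the oversized decoy pathway is dropped),
and the track intersection contains 35 genes: the 10 seeds plus exactly
the 25 planted module genes (`n_predicted_novel`). The cross-validated
overlap of the two independent predictions recovers the module exactly,
and 8 of the 25 module genes are co-expressed with a seed, so ranking
retains 8.

Quantifying the packaged qPCR table:

```python
from markermine.datasets import table3
from markermine.qpcr import classify_table, summarize_patient

df = classify_table(table3())                  # 126 (gene, patient) records
print(summarize_patient(df[df.patient == "1"]))
```

```
PatientSummary(patient='1', n_tested=42, n_up=17, n_down=6, n_ns=19)
```

— in patient 1, 17 of the 42 tested candidates are significantly
upregulated and 6 downregulated at p < 0.05.

The same stages are available from the shell:

```bash
markermine simulate --seed 7 --out bundle/
markermine run-all --seeds-a bundle/seeds_training.txt \
    --seeds-b bundle/seeds_validation.txt --tf bundle/trrust.tsv \
    --pathways bundle/pathways.gmt --coexpr bundle/coexpression.tsv \
    --ct bundle/ct.csv --out run/
```

`run/` receives per-seed-set predictions with provenance, the
cross-validation overlap, the co-expression ranking, the qPCR results
and summary, and a manifest with input hashes; reruns on identical
inputs are byte-identical.

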