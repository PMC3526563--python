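# goqa — function-enrichment quality assessment of protein structure models

`goqa` is a single-model Model Quality Assessment Program (MQAP): it
estimates how good a predicted protein 3D structure is *without* the
native structure and *without* other models to compare against. The idea
is that a correct model, like a real protein, sits in a structural
neighborhood of proteins that share its function. A wrong model either
resembles nothing (no significant structural neighbors) or resembles
proteins whose function has nothing to do with the prediction target.

No coordinates are processed here: structure comparison is delegated to
an upstream DALI search, which enters only as a ranked list of structural
neighbors (SNs) with Z-scores. Function comparison uses Gene Ontology
molecular-function annotations and Wang semantic similarity.

## The scores

For an evaluated model, every structural neighbor gets a record
`(neighbor, Z-score, FS)`, where FS ∈ [0, 1] is the best-match-average
Wang similarity between the neighbor's GO molecular-function terms and
the target's. Sorted by descending Z, these records form the
*similarity list* (Slist). Fixing an FS-threshold *t* labels each record
positive (FS > *t*) or negative, and scanning the Slist top to bottom
draws a ROC-style curve whose area is the score:

- **GA(t)** = Σᵢ₌₁ᵀᴺ Δx Σⱼ₌₁ⁿ⁽ⁱ⁾ Δy, with Δy = 1/TP, Δx = 1/TN and
  n(i) the number of positives above the i-th negative — the fraction of
  (positive, negative) pairs ranked positive-first. Absolute, in [0, 1];
  good models approach 1, bad models fall below 0.5.
- **yGA(t)** multiplies each positive step by that neighbor's Z-score
  (Δy·Zⱼ). Because raw Z-scores are not comparable across targets, yGA
  only ranks models of one target.
- **GA_F / yGA_F** average a few thresholds, e.g.
  GA_579 = (GA(0.5) + GA(0.7) + GA(0.9)) / 3.
- **metaGA** = mean of GA over all thresholds 0.01 … 1.00.

A model whose neighbor search returns fewer than five significant
neighbors (Z ≥ 2) scores 0 outright. An optional post-processing step
applies Chauvenet's criterion iteratively over four yGA variants
(yGA_468, yGA_567, yGA_579, yGA_678) to flag models whose structural
neighborhood is inconsistent with the rest of the ensemble.

Validation follows the CASP QA protocol: Pearson correlation of scores
against GDT-TS (pooled and per target) and ΔGDT — the GDT gap between
the objectively best model and the model the score ranks first — binned
into <1, [1,2), [2,10), ≥10.

## Worked example

The package ships seeded generators, so the whole pipeline runs without
downloads. Simulate a fixture (toy ontology, GAF annotations, per-model
neighbor tables, GDT-TS table), then score, flag outliers, and evaluate:

```sh
goqa simulate --out demo --seed 7 --n-targets 2 --models-per-target 10
goqa score --obo demo/ontology.obo --gaf demo/annotations.gaf \
     --mapping demo/mapping.tsv --neighbors demo/neighbors \
     --targets demo/targets.tsv --model-targets demo/model_targets.tsv \
     --out demo/scores.tsv
goqa exclude --scores demo/scores.tsv --out demo/flagged.tsv
goqa evaluate --scores demo/flagged.tsv --gdt demo/gdt.tsv \
     --model-targets demo/model_targets.tsv --post-exclusion \
     --out demo/report.tsv
```

The evaluate step prints, per metric (excerpt):

```
metric: metaGA (18 models)
overall r: 0.691
per-target r: 0.739 +/- 0.073 over 2 targets
deltaGDT bins: <1: 0.0%, [1,2): 0.0%, [2,10): 50.0%, >=10: 50.0%

metric: yGA_579 (18 models)
overall r: n/a (relative metric)
per-target r: 0.909 +/- 0.077 over 2 targets
deltaGDT bins: <1: 50.0%, [1,2): 0.0%, [2,10): 50.0%, >=10: 0.0%
```

Read: metaGA (absolute) correlates 0.69 with observed quality over the
pooled 18 retained models; yGA_579 reaches a 0.91 mean per-target
correlation but, being Z-weighted, refuses a pooled correlation; for one
of the two targets yGA_579's top pick is within 1 GDT unit of the
objectively best model. Two of the twenty models were flagged by the
exclusion step (`demo/flagged.tsv` lists the triggering metrics and the
iteration).

The same machinery is available as a library:

```python
from goqa import EnsembleParams, generate_ensemble, MetricSpec, combined_score, pearson

ens = generate_ensemble(EnsembleParams(n_models=200, seed=1))
spec = MetricSpec.parse("yGA_579")
scores = [combined_score(s, spec) for s in ens.slists]
print(round(pearson(scores, [ens.gdt[s.model_id] for s in ens.slists]), 3))
# 0.866
```

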