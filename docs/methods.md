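# Methods

## Model and assumptions

The package scores a predicted protein structure by the functional
coherence of its structural neighborhood. The underlying assumption is
that structural and functional similarity are coupled for real proteins:
a model that is essentially correct should, like the native protein,
find structural neighbors (via DALI) that are functionally similar to
the prediction target, and those neighbors should be the *closest* ones
(highest Z-scores). Three failure regimes break this pattern: a
non-natural model resembles nothing (low Z, low FS); a model may share
functional sub-features without global similarity (low Z, high FS, as in
convergent evolution); or it may strongly resemble a protein of a
different function (high Z, low FS — wrong template, or divergent
evolution). The ROC-area construction rewards exactly the configuration
where high-FS neighbors concentrate at the top of the Z-ranking.

The method needs a target annotated with Gene Ontology
molecular-function terms; biological-process and cellular-component
annotations are excluded because their link to structure is indirect.
Everything downstream consumes only the Slist — (neighbor, Z, FS)
records sorted by descending Z — so the package never touches
coordinates.

## Functional similarity (Wang)

Term similarity uses Wang's graph-based measure over the is_a/part_of
DAG. Each ancestor *t* of a term *A* receives
S_A(t) = max over children t′ of t within A's ancestor subgraph of
w(t′→t)·S_A(t′), with S_A(A) = 1; similarity of two terms is the
overlap of their ancestor contributions normalised by the total
contributions. Term *sets* are pooled by best-match average. Semantic
contribution factors default to w_is_a = 0.8 and w_part_of = 0.6 — the
published defaults of the measure — and are configurable; both must lie
strictly inside (0, 1) so contributions decay and the recursion
converges. Relations other than is_a/part_of (regulates, occurs_in, …)
carry no defined weight and are dropped on load, with a count retained.
Obsolete terms are kept but flagged and are invalid similarity
arguments; alt_ids resolve to primary ids; comparing terms across
namespaces raises instead of returning 0, since the pipeline restricts
itself to one namespace and such a call indicates a join error.

## Slist construction

Neighbor chains are normalised to `<pdb lower>-<CHAIN upper>` (DALI
output dialects vary), duplicate hits to one chain keep the highest Z
(the de-redundant "pdb90" listing intent), and the query's self-hit is
removed when the query id is known. Neighbors without any annotation are
dropped by default — FS is undefined without terms — with the count
recorded; a `zero_fs` policy keeps them as certain negatives instead,
since dropping changes the positive/negative set sizes. Ties on Z break
by neighbor id ascending, giving the scores a deterministic total order.

## Scores and numerical choices

Positives are records with FS strictly greater than the threshold, even
at t = 1.0 (where every record is negative). GA's degenerate labelings,
which the 100-threshold metaGA sweep inevitably hits, are defined as:
no positives → 0 (empty inner sums); no negatives → 1 (the curve
completes before a single terminal step). The corresponding yGA limit
with no negatives is the full inner sum Σ Δy·Z. Negatives' Z-scores
never enter yGA.

Thresholds are materialised as exact rationals (`Fraction(i, 100)`) and
compared through their nearest float, so an FS parsed from text as
`0.07` is not "greater than" threshold 0.07 by a floating-point artifact
of computing `7 * 0.01`. Term self-similarity is clamped to 1 against
summation-order rounding. GA is computed by pair counting in a single
scan (cumulative positives before each negative), algebraically
identical to the stepwise area.

The zero rule — fewer than five neighbors with Z ≥ 2 scores the model 0
on every metric — is applied to the post-filter Slist, i.e. the records
actually scored; the significance threshold is inclusive. The bound Z
value 2.0 counts as significant.

## Outlier exclusion

Chauvenet's criterion flags a value whose upper-tail probability under a
normal fit of the sample falls below p = 1/(2n): cutoff =
mean + sd·Φ⁻¹(1−p). Only the upper tail is tested, because the lower
quality bound is zero and yGA outliers arise specifically from models
whose DALI search landed in an unrelated, higher-Z neighborhood. The
standard deviation uses the n−1 sample estimator (the criterion does not
prescribe one). Cutoffs are computed per metric over the retained set
for yGA_468, yGA_567, yGA_579 and yGA_678; a model strictly above *any*
cutoff is removed; removal within an iteration is simultaneous across
metrics (order-independent), and the procedure iterates to a fixed point
so a gross outlier cannot shield a smaller one. Samples of fewer than
three values, or with zero spread, are left untouched. Excluded models
keep their scores and are only flagged — exclusion can also remove a
lone good model above a poor ensemble, so each flagged model deserves
manual review.

## Evaluation

Validation mirrors CASP QA practice: Pearson r of score vs GDT-TS pooled
over all models and separately per target, the per-target values
summarised as an unweighted mean ± SD (each target counts once,
regardless of model count). yGA metrics are relative, so the pooled
correlation is refused for them. ΔGDT = GDT(objectively best) −
GDT(top-scored), with score ties broken by model id; bins are half-open
with 10 assigned to the top bin (the published bin list leaves exactly
10 unassigned between "[2,10)" and ">10"). Targets with fewer than three
models or degenerate variance are skipped from the correlation average
with a log entry; ΔGDT is still reported for them.

## Synthetic data

The generators exist because the real inputs — a dated GO release, a
GOA snapshot, and a DALI search of the PDB for thousands of CASP
models — are internet-scale downloads. The ensemble generator draws a
latent quality q ~ U(0,1) per model and makes q drive the two things the
scores measure: each neighbor is "functional" with probability
p(q) = functional_base_prob + functional_gain·q (defaults 0.15 + 0.5q),
and functional neighbors draw Z = 2 + z_scale·p(q)·U(0,1) (z_scale 30)
versus the background's Z = 2 + 6·U(0,1). Routing the Z reach through
the same functional-coherence term p(q) is deliberate: with
functional_gain = 0 the Slist distribution becomes fully independent of
q, giving a clean null in which score–GDT correlation vanishes, while at
the default gain quality drives both enrichment and closeness. FS values
come from Beta(8,2) for functional and Beta(2,8) for background
neighbors — separated around ≈0.6, where structural and functional
similarity empirically begin to couple. Observed quality is
GDT = clip(100·(0.15 + 0.7q) + N(0, 5), 0, 100). Sixty neighbors per
model keep every Z above the significance floor, so the zero rule never
fires on synthetic ensembles unless constructed to.

What the generator does *not* emulate: DALI's actual Z distribution
against the PDB, annotation sparsity and IEA bias, correlated errors
among models from one prediction group, and targets whose native
structure itself violates the structure–function coupling. Passing tests
therefore demonstrate the correctness of the scoring machinery and the
qualitative signal-recovery behaviour, not the quantitative performance
figures attainable on real CASP ensembles.

Problem sizes used in tests and the acceptance script — 200-model
ensembles, 4 synthetic targets of 50 models, 1000 random Slists of up to
50 records, 200 random DAGs of up to 30 terms — were chosen so the
whole suite completes in seconds while keeping the statistical checks
(correlation recovery, false-exclusion rate) well-powered.

## Known limitations

- Usable only for targets with molecular-function GO annotations; a
  wrong target annotation silently degrades all scores.
- yGA values are unbounded and target-relative; they must never be
  pooled across targets (the evaluation module enforces this).
- The zero rule penalises genuinely new folds, which legitimately lack
  structural neighbors.
- Exclusion assumes the ensemble majority shares a common structural
  neighborhood; on ensembles dominated by bad models it can flag the
  good ones.
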