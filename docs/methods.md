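# Methods

This note records the modelling choices behind `ddsn`, the parameters that
matter, and what the synthetic benchmark does and does not establish.

## Ontology and information content

The ontology is reduced to `is_a` edges and restricted to the subtree of a
configurable root (HP:0000118, *Phenotypic abnormality*, in production);
other relation types, obsolete terms and branches such as mode of
inheritance are dropped at parse time because they describe something other
than a clinical feature. The structure is validated as a rooted DAG: a
cycle aborts the parse with one offending cycle listed, and every retained
term must reach the root.

Term specificity is the normalized Resnik information content
`IC(t) = log(N/n_t)/log N` computed from **propagated** counts: a disease
counts toward a term if the term is an ancestor-or-self of any of its
annotations. Propagation is what makes IC monotone non-increasing towards
the root, and monotonicity is what makes "most informative common
ancestor" well-posed. Two boundary behaviours are intentional: a term
annotating a single disease has IC exactly 1, a term annotating all
diseases (the root, typically) has IC 0. Terms never reached by any
annotation get *no* IC entry rather than IC 1 — they carry no frequency
information, and scoring never needs them. Normalization is undefined for
fewer than two annotated diseases and is rejected.

Disease annotation sets themselves are **not** propagated before scoring:
the similarity machinery sees only direct annotations, and generality is
handled by where the MICA lands.

## The similarity score

The score of a disease pair is the mean MICA IC over **all** M×N ordered
annotation pairs, not a best-match average. The all-pairs reading penalizes
pairs with many mutually unrelated annotations (each near-zero MICA drags
the mean down), which is the intended behaviour for ranking clinically
coherent pairs; a best-match variant is deliberately out of scope. Two
consequences worth knowing: the self-score of a disease with more than one
annotation is generally below 1, and identical annotation sets score the
mean pairwise MICA of the set, not 1.

MICA ties on IC are broken by the lexicographically smallest term id so
results are reproducible; for identical terms the term itself is returned.
Scores are summed in a canonical order (the lexicographically smaller
annotation tuple outermost) so `score(i,j)` and `score(j,i)` are
bit-identical.

The random baseline of a disease draws, by default, as many partners as
the disease has series co-members (k = series size − 1), uniformly without
replacement from all annotated corpus diseases, from a caller-supplied
seeded generator; one draw per disease, matching the per-disease design of
the intra-series mean. The best-partner analysis excludes diseases in more
than one series and members of singleton series, flags ties, and resolves
them to the smallest partner id.

## Corpus filters

The catalogue reader operationalizes "confirmed molecular disease" with
the documented morbid-map notations: mapping key `(3)`, and exclusion of
bracketed non-disease entries, braced susceptibility entries and
`?`-prefixed unconfirmed entries, each exclusion logged with its reason so
that retained + excluded always reconciles with parsed. Rows listing
several gene symbols are retained by default (`multi_gene="exclude"`
drops them) because locus attribution does not change the phenotype
annotations the analysis uses. Annotations with qualifier `NOT`, from a
different catalogue, or outside the retained subtree are logged and
dropped. 4-tuples (disease, series, term, IC) are emitted only for
diseases with at least one annotation and one series membership, sorted
(disease, series, term) for byte-stable output.

Classification labels come either from a disease-ontology OBO whose terms
cross-reference catalogue ids (labels are the top-class names reachable by
`is_a` from any cross-referencing term; a term under two top classes
yields both labels) or from a plain two-column table. Multi-class diseases
are kept in the corpus and only excluded where the analysis demands a
unique class (the partner cross-tabulation).

## Sharing rules and the network

"First-degree ancestor" in the sharing rules means exactly one `is_a` hop.
This is the only reading under which rules 2/3 differ from generic MICA
sharing and under which two diseases meeting only at the root stay
unlinked. The network is derived from the per-pair sharing tuples, not by
one-mode projection of the bipartite graph: projection would attribute a
common parent to a pair whose annotations are identical, which rule 2
("two *different* terms") forbids. A shared term reachable by several
routes is counted once per pair (reported with the lowest rule number),
and the edge weight is the mean IC of the distinct shared terms — summed
in sorted order so weights are bit-identical across processes.
Thresholding keeps edges with `w` strictly greater than `w*` and then
drops isolated nodes; retention fractions are relative to the
unthresholded network.

Same-series stratification treats a pair as same-series when the two
membership sets intersect. Degree statistics report per-class mean ± SD,
top-degree hubs and the empirical P(k); the log-log least-squares slope is
exported as a descriptive statistic only, not a fitted power-law model.

## Dyadicity and heterophilicity

Expected dyad counts use the closed-form uniform-placement model
(`e11 = C(n,2)p`, `e10 = n(N−n)p`, `p = 2M/(N(N−1))`), which equals the
mean of the permutation distribution; a Monte-Carlo estimator is provided
for verification. Ratios with zero expectation are reported as undefined
with the reason, never clamped or returned as infinity. Classification
against 1 uses an equality tolerance of 1e-9. Diseases in several series
carry each series property independently. By default the analysis runs on
the unthresholded compact network, with the threshold exposed as a
parameter, since specificity pruning is a display concern rather than part
of the dyad model; series need at least two member nodes present in the
network to be analyzed.

## The synthetic generator

The generator emulates the joint structure the pipeline consumes — a
rooted term DAG, series-grouped diseases, annotation sets with tunable
intra-series coherence, class labels — and writes the same flat-file
dialects the parsers read, so synthetic runs exercise the production code
path end to end.

Ontology: terms are created in id order, each aiming for a normally
distributed depth around `depth_target` (default 6, SD 1.2) and attaching
to a parent at that depth rank; extra parents (up to `max_parents`,
default 2) attach at the same rank so the term's depth stays well defined.
Acyclicity holds by construction.

Cohorts: each series owns a profile of `profile_size` (default 6) terms
sampled from the descendant closure of an anchor term, so that sibling and
parent/child sharing is exercised, not just identical terms. Anchors of
non-overlapping series are chosen with disjoint closures whenever the
ontology allows (falling back with a logged note otherwise). Each disease
fills `annotations_per_disease` (default 6) slots from its profile with
probability `cohesion` (default 0.8), otherwise uniformly from the
ontology, plus `Binomial(annotations_per_disease, background_rate)`
(default rate 0.05) extra uniform noise terms. When `overlap > 0` the
first `overlap_group_size` (default 4) series form a mutually overlapping
group sharing a pool of `round(overlap·profile_size)` profile terms; the
group design (rather than isolated pairs) is what makes heterophilicity
recoverable at all — with near-complete intra-series linkage, a series
overlapping a single partner cannot push its heterogeneous dyad count
above the global-connectance expectation `e10`. All randomness flows from
one seed, echoed in every output file header where the format allows.

Deliberate simplifications: background annotations are uniform over terms
(no attempt to mimic an empirical term-frequency distribution), series are
equally sized and disjoint, annotation counts are homogeneous, and the DAG
does not reproduce the breadth or depth profile of a real phenotype
ontology. Passing the planted-structure suite therefore shows that the
pipeline recovers the kind of structure it models — cohesion shows up as
dyadicity and high intra-series scores, planted overlap as
heterophilicity — not that production-scale snapshots would yield any
particular published value.

## Problem sizes and numerical tolerances

The default study conditions are 10 series × 8 diseases over a 200-term
ontology, 50 seeds — small enough that the whole validation suite runs in
well under a minute while leaving every statistic far from its decision
threshold. Oracle-equivalence suites compare against brute-force
evaluators at 1e-12 absolute tolerance (the implementations are expected
to agree to the last bit in practice); the permutation calibration uses
1000 placements on a fixed 50-node graph and a 3-standard-error band. The
all-pairs scorer caches per-term-pair MICA ICs; production-scale all-pairs
runs are quadratic in diseases and are guarded in the CLI, but are not
part of the test suite.

The `corpus`/`score`/`network`/`assort` subcommands are thin aliases that
recompute from the (cheap, deterministic) upstream stages before writing
their stage's artifacts; with identical inputs and seeds, re-running any
stage rewrites byte-identical files.

## Known limitations

Only `is_a` semantics; no Lin/Jiang–Conrath IC variants or best-match
group similarity; no statistical testing of D/H beyond the permutation
check; no power-law fitting; cross-catalogue network comparisons (which
require third-party disease networks and vocabulary mappings) are out of
scope.
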