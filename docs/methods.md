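# Methods

This note documents the models and procedures implemented in `transdx`,
the defaults they use, and the choices made where the design was open.

## Encoding and standardization

Questionnaire items carry a category (A–H), a value kind and an ordered
code list. Categorical items are one-hot encoded, one indicator per
allowed code; indicator columns for "prefer not to answer"-style missing
codes are dropped by default, which also makes a missing categorical
response representable as an all-zero indicator block rather than a
missing value. Binary, ordinal and continuous items map to a single
numeric column: ordinal codes keep their ordering (one-hot would discard
it and roughly double the feature count). Age enters as a numeric column
and sex as a binary indicator. Subjects left with any absent numeric
value after encoding are excluded (complete-case analysis; the count is
logged). Standardization is the per-column z-score with the population
(n) standard deviation; constant columns map to 0 with a warning instead
of NaN, and standardizing twice is an error so pipelines cannot silently
double-scale.

## Clustering

**k-means** uses Lloyd iteration (scikit-learn) with Euclidean distance,
10 seeded restarts per k and relative inertia tolerance 1e-4. The number
of clusters is chosen by the mean silhouette over a k grid; ties within
1e-12 resolve toward the smaller k. Silhouette is O(n²), so above 10,000
subjects it is computed on a seeded uniform subsample (logged). For
degenerate partitions (fewer than two distinct labels, or all points
coincident) the silhouette is defined as 0; singleton-cluster members
contribute 0.

**Similarity graph.** Each subject is linked to its k_nn nearest
neighbors under the Minkowski-p distance (defaults k_nn = 100, p = 2,
i.e. Euclidean, matching the k-means metric). Directed neighbor lists
are symmetrized by union — not mutual-kNN — so every node keeps degree
at least k_nn's outgoing list and community detection never sees isolated
nodes; this is the standard substrate choice and is switchable in
principle by post-filtering the edge list. Distance ties at the k_nn-th
rank break by subject-id order, which makes the graph a pure function of
the input table. Edges are unweighted by default (binary adjacency); a
weighted mode with weight 1/(1+d) is available behind a flag.

**Louvain.** Community detection uses greedy modularity optimization
with node-aggregation passes (networkx's Louvain implementation),
seeded. Reported Q is the standard (resolution-1) Newman modularity
recomputed from the final labels by this package's own implementation of
Q = Σ_c [L_c/m − (d_c/2m)²]. Communities are relabeled contiguously by
descending size. Disconnected graphs are handled as-is (communities
never span components; the component count is logged). The resolution γ
is swept over a grid and the partition with the best feature-space
silhouette wins (ties toward fewer communities, then smaller γ);
modularity-maximum selection can be read off the returned audit table.
Feature-space silhouette was chosen as the selection metric so that both
clustering methods are judged by the same criterion.

**UMAP** provides a 2-D embedding for plotting only; it is seeded,
requires at least 10 subjects, and is never consumed by any downstream
computation.

## Cluster characterization

Diagnosis composition is a cross-tabulation emitted as (source, target,
count) flows for Sankey rendering, with a `none` pseudo-label for
subjects carrying no diagnosis; passing a second clustering instead of
diagnosis labels yields the method-vs-method overlap table.

Feature importance fits, per cluster, an L1-penalized one-vs-rest
logistic regression of membership on all standardized features
(liblinear). Logistic rather than linear regression was chosen because
membership is binary. Features with signed coefficient above the
threshold (default β > 0.2; an absolute-value mode exists) are reported
in descending order. Because features are standardized, coefficients are
on a comparable scale. The penalty C defaults to 3-fold cross-validated
log-likelihood over a small log-spaced grid; the pipeline fixes C = 1
for reproducibility and speed. Class imbalance is left unweighted.
Clusters with fewer than 10 members are skipped with a warning.

Category index scores min–max scale every item to [0, 1] over the full
cohort — not per cluster, so scores are comparable across clusters — and
average within category per subject; per-cluster summaries report mean
and quartiles. Items with max = min scale to 0 with a warning. Scores
are invariant to positive affine transforms of the raw codes.

## Diagnosis rules and comparison

A diagnosis fires when any of its OR-combined threshold clauses on scale
scores holds. Shipped defaults: depression ⇐ HAMD ≥ 7; anxiety ⇐
HAMA ≥ 10 or PDSS ≥ 8; bipolar ⇐ MDQ ≥ 7 or HCL-32 ≥ 12. A missing
scale value makes its clause false (logged). All shipped comparators are
≥, so raising a score never removes a diagnosis. Comparison of two label
sources restricts both to their shared vocabulary and flags any set
inequality as inconsistent (a symmetric-difference mode is available;
over a shared vocabulary the two coincide). Disjoint vocabularies are an
error — there is nothing comparable.

## Recommendation engines

The class vocabulary defaults to {AD, AP, MS, SH} and is extensible (an
OTHER class can simply be added to the vocabulary and the drug map). A
subject is *labeled* iff it appears in the prescription table; drug
names are lower-cased and trimmed before class lookup, and unmapped
names go to a rejection report rather than being silently dropped.

*Cluster engine:* P(class | cluster) is the fraction of the cluster's
labeled members holding the class (a member holding several classes
counts toward each); every member of a cluster gets the same
recommendation. Clusters without labeled members have undefined
probabilities and defer to the network engine.

*Network engine:* the neighborhood grows breadth-first from the target
subject in whole rings (ring r = nodes at graph distance r); expansion
stops after the first complete ring at which the cumulative labeled
count reaches the quota (default 20). Whole-ring inclusion keeps the
procedure deterministic and avoids arbitrary ordering inside a ring; a
similarity-ordered one-by-one expansion was considered and rejected as
tie-sensitive. If the subject's component is exhausted below quota the
recommendation is computed on whatever labeled members exist and flagged
`quota_unmet`; a component with no labeled member is an error. Class
counts exclude the target's own prescriptions (no leakage during
evaluation). Ranking is competition-style (tied counts share a rank) and
classes at rank ≤ 3 (configurable) are recommended — so ties can produce
more than three recommended classes, and zero-count classes are never
recommended even when fewer than three classes have nonzero counts.

Evaluation reports the distribution of recommendation-set sizes,
per-class recommendation frequency (overall and per cluster), and hit /
exact-match rates against observed prescriptions.

## Synthetic cohorts

The generator draws subjects into latent groups and emits conditionally
independent items given the group: binary items are Bernoulli with a
per-group per-category probability shift on a base rate of 0.15; ordinal
(5 levels) and categorical (4 codes) items discretize a unit-variance
latent normal shifted by the group's elevation (in σ units) with
equal-width cut points over [−2, 2]; continuous items are the shifted
normal itself. Age is uniform over 40–69 and sex Bernoulli(0.5). Scale
scores track a per-group severity so the diagnosis rules produce
structured labels, and a self-reported source is derived from the
scale-based one by toggling one random diagnosis per subject with a
configurable discordance probability. Prescriptions label a Bernoulli
fraction of subjects (default 9%, the accessibility rate typical of
population questionnaire cohorts) and draw each class independently with
the group's probability; a subject ending empty is re-drawn once and
then falls back to its group's modal class. This guarantee conditions
the draws, so the realized rate of class c is
p_c + P₀·p_c + P₀²·[c modal] with P₀ the all-empty probability — the
tests check against this closed form. No nonempty-supported joint
distribution can keep the marginals exactly p when Σp < 1.

Presets: `separable-4` (four equal groups, each elevating a disjoint
category pair by 8σ / +0.7 binary shift, group-distinct prescription
profiles) for recovery tests; `ukbb-like` (eight categories × 17 items
≈ 138 raw items expanding to ≈ 240 features, five unequal groups at
2.5σ, 9% labeled, AD-dominant class skew, 0.33 self-report discordance)
as the realistic workload; `flat-null` (one group, no structure) for
false-positive checks.

What the generator does *not* model: inter-item correlation beyond group
membership (no copulas, no item-response-theory structure), item-level
missingness patterns, or realistic marginal distributions per item.
Passing recovery tests therefore shows the machinery is correct under
conditional independence, not that real cohorts separate this cleanly.

## Pipeline and determinism

A single global seed fans out to per-stage seeds by fixed offsets, so
stages are individually reproducible. All tables are written with a
fixed float format and schema-versioned header comments; reports are
JSON with sorted keys; re-running an identical configuration reproduces
every output byte for byte. Problem sizes used by the test suite and the
acceptance script: oracle equivalence on graphs up to 300–500 nodes,
recovery and null-control experiments at n = 2,000 over 20 seeds,
probability recovery at 2,000 labeled subjects per group, determinism at
n = 5,000, and the realistic-preset run at n = 4,000.

## Known limitations

- Silhouette subsampling above 10,000 subjects makes model selection
  stochastic at population scale (seeded, logged).
- The Louvain resolution grid is coarse by default; very fine cluster
  structure may need a finer sweep.
- The network engine's quota semantics (whole rings) can overshoot the
  quota substantially on high-degree graphs (k_nn = 100 rings are
  large); the quota bounds the labeled count from below, not above.
- Exact-match evaluation is strict for multi-class prescriptions; hit
  rate is the primary headline metric.
- No drug-level (as opposed to class-level) recommendation, no dosing,
  no hybrid cluster+network engine, and no "no prescription" option.
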