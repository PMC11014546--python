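# Methods

## Model and procedure

`pertmap` evaluates groups of high-dimensional profiles by non-interpolated
mean average precision over binary rank lists. For each query profile the
remaining members of its group are the positives (`n_pos = M−1`) and the
admitted reference profiles are the negatives (`N`); candidates are ordered
by increasing dissimilarity to the query and AP is the mean of precision@k
over the ranks holding positives, equivalently the recall-increment-weighted
sum of precision. The group score is the arithmetic mean of its per-query
APs. AP is normalized by the number of positives, so a perfect ranking
scores 1 for any list length; an alternative normalization by the full list
length appears in some write-ups but breaks that property and is not used.

Three assessments instantiate the engine through different block designs:

* **activity** — queries are a perturbation's replicates, references are
  controls;
* **consistency** — queries are consensus profiles (feature-wise medians over
  replicates) sharing an annotation, references are all differently
  annotated perturbations;
* **distinctiveness** — queries are a perturbation's replicates, references
  are all other perturbations' replicates (controls excluded by default).

Block designs are declared as metadata constraints: `pos_same`/`pos_diff`
columns that must match/differ between query and positive, and
`ref_same`/`ref_diff` analogues for references. This expresses designs such
as "same well position, different plate" used to probe positional and
plate-to-plate technical variation. Within `build_instances`, `group_by`
partitions queries; a profile belongs to several query groups only in the
multi-label task. Groups with fewer than two members, and queries left
without positives or references, are skipped with machine-readable reason
codes rather than aborting a screen-scale run. In the "same plate, different
well" design, references are by default restricted with the same
`ref_same`/`ref_diff` constraints as the positives (overridable): comparing
within-plate positives against cross-plate references would otherwise
confound the contrast.

### Significance

Under the null hypothesis that query and reference profiles are
exchangeable, a query's binary rank list is a uniformly random arrangement
of `n_pos` ones among `n_total` slots: the AP null depends only on
`(n_pos, n_total)` and has exactly `C(n_total, n_pos)` equally likely
outcomes. The distribution is enumerated exactly when `C ≤ 10,000`
(configurable cap) and otherwise sampled by Monte Carlo; distributions are
cached by shape because a screen reuses few shapes many times. The group
mAP null is built by drawing, per permutation, one independent null AP per
query and averaging (default 10,000 permutations). Monte-Carlo p-values use
the add-one smoothed estimator `(b+1)/(n_perm+1)`, so the smallest
attainable p is `1/(n_perm+1)` and p is never 0; for a single-query group
with an exact null the p-value is the exact tail probability. P-values are
corrected across groups by Benjamini–Hochberg (via statsmodels), and
*percent retrieved* is the share of groups with corrected p below α = 0.05.

**Known limitation — group-level anti-conservativeness.** The independent
per-query construction matches the "reshuffle the rank list" description of
the null, and the per-query marginals are exact (verified against full
enumeration). But queries of one group share the same profile cloud, so
their APs are positively correlated under the true sampling process
(empirically r ≈ 0.35 at M = 3, N = 12 on i.i.d. normal profiles). The
independent null therefore under-disperses mAP (sd ≈ 0.11 vs ≈ 0.14 true at
that design), and the realized type-I rate at nominal 0.05 is ≈ 0.10–0.12
for typical small designs (2–4 replicates, 12–36 controls, 100–1000
features). Single-query tasks (e.g. consistency with pairs of guides, where
M−1 = 1 per query group member) are unaffected at the per-query level.
Interpret raw group p-values near the threshold accordingly; a full
profile-label permutation (re-ranking all queries per permutation from the
actual distance matrix) would restore exactness at substantially higher
cost and is a possible extension.

### Distances

Cosine distance `1 − cos(x, y)` is the default: it compares the *pattern*
of feature changes, not their magnitude, which suits perturbational
readouts. Pearson correlation distance `1 − r` and Euclidean distance are
also provided. Zero vectors (cosine) and constant vectors (correlation) are
rejected with an error naming the query's group. Ties in the rank list are
broken by original row index (deterministic); a seeded random tie-break is
available for tie-heavy (e.g. heavily discretized) data. Ties are
measure-zero for continuous features, so the default never matters there.

## Normalization and consensus

Two feature scalings are provided, optionally per group of a metadata
column (typically the plate): `standardize` (z-score with population SD) and
`mad_robustize` (subtract the median, divide by `1.4826·MAD + ε`). The
1.4826 consistency constant makes the MAD estimate the SD under normality;
ε (default 1e-12) guards the denominator, and features whose scale is
exactly zero within a group are mapped to 0 — a constant feature carries no
ranking information either way. Standardization divides by the standard
deviation (not the variance): the z-score is the statistically standard
choice and is idempotent. Consensus aggregation takes feature-wise medians
per perturbation; metadata columns that are not constant within every group
are dropped from the consensus table.

NaN policy on ingest is configurable: reject (default) or drop offending
feature columns with a logged count. Metadata columns are recognized by the
`Metadata_` prefix (the community convention for profiling tables) unless an
explicit list is given.

## Multi-label extension

A perturbation with several annotations contributes one AP per
(perturbation, label) pair: for each label, the other members are positives
and *all* non-members are references — including perturbations sharing a
different label with the query. The result is a sparse perturbation × label
matrix; absent entries are treated as missing (not zeros) in per-label and
per-perturbation means, since zeros would drag per-perturbation means toward
unannotated labels. Each AP divides by the number of positives (members
minus one), keeping entries in (0, 1] and making per-label column means
coincide with the consistency mAPs when annotations are single-label.

## Comparator methods

* **mp-value**: PCA is fit on the pooled two-group sample; scores are
  weighted by each component's explained-variance fraction; the statistic is
  the Mahalanobis distance between group centroids under the pooled
  within-group covariance of the weighted scores, ridge-regularized with
  λ = 1e-6 · trace/k for rank deficiency at n ≪ d. Significance comes from
  label permutations. Because the pooled sample is invariant under label
  permutation, refitting the PCA per permutation would reproduce the same
  projection; the implementation computes it once.
* **MMD**: the unbiased MMD² estimator with RBF kernel
  `exp(−‖x−y‖²/(2σ²))`, σ set by the median heuristic (median pairwise
  Euclidean distance of the pooled sample); label-permutation p-value. On
  literally duplicated point sets the unbiased estimator is slightly
  negative (it keeps cross-group self-pairs while dropping within-group
  diagonals); this is expected behavior, not an error.
* **k-means**: k = 2, ten restarts, lowest inertia; "detected" means the
  best partition reproduces the group labels exactly up to label swap.

Permutation p-values for the baselines use the same add-one smoothing;
under perfect separation the only permutations that tie the observed
statistic are recurrences of the observed split (probability
`1/C(n_a+n_b, n_a)` per draw), so p sits at the resolution bound up to those
ties.

## Simulation benchmark

The generator emulates a location-shift screen: control features are i.i.d.
draws from the null family (standard normal by default; a Cauchy variant
provides a heavy-tailed stress case), and each simulated perturbation draws
`round(f·d)` of its `d` features from the shifted family (default shift 1.0,
scale 1.0) and the rest from the null. Defaults per condition: 100
perturbations, 2 replicates, 12 controls, 100 features — the smallest cell
of the benchmark grid (features ∈ {100, 200, 500, 1000, 2500, 5000},
perturbed fraction ∈ {1, 2, 4, 8, 16, 32, 64}%, replicates ∈ {2, 3, 4},
controls ∈ {12, 24, 36}; one description of the control grid as 8/16/32
appears alongside two statements of 12/24/36, and the latter is adopted).
Fresh controls are generated per perturbation (independent-null default);
shifted features are the first `round(f·d)` indices — features are i.i.d.,
so the choice is immaterial and determinism aids debugging. Everything is
bit-reproducible from a single seed via spawned child sequences, so adding a
condition never perturbs another's draws.

Recall is the fraction of simulated perturbations with *raw* p < 0.05 (the
benchmark convention; a BH-corrected mode is available behind a flag).

**What the generator does not emulate:** plate/batch structure, feature
correlations, heteroscedastic features, outlier wells, or annotation noise.
Passing simulation checks therefore demonstrates the statistical machinery
(ranking, nulls, calibration of the comparators, monotone response to signal
strength and dimensionality), not robustness to the technical artifacts of
real screens — the block-design constraints exist precisely because real
data have structure this generator omits.

## Numerical and design choices

* Exact-enumeration cap `C ≤ 10,000`; Monte-Carlo nulls default to 10⁵
  samples for distribution checks and 10⁴ permutations for p-values
  (baselines use 10³ permutations per group for grid-cost reasons).
* Degenerate inputs: zero-scale features normalize to 0; all-identical
  pooled samples make the MMD bandwidth zero and raise; a rank list with no
  positives raises; empty groups and singleton groups are skipped with
  logged reason codes.
* Seeds: a single run seed fans out through `numpy` `SeedSequence.spawn`,
  one child per perturbation instance / grid cell; null-distribution caches
  are keyed by shape and seed so repeated groups share one null sample.
* Test problem sizes: the suite checks the hard regime and calibration on
  100–500 simulated groups per condition and the saturation regime at
  d = 5000 with 100 groups; these sizes give binomial standard errors of
  1–2 percentage points on the reported rates.
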