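# Methods

This note documents the models, conventions, and numerical choices behind
`duonet`, in the spirit of a statistical package's methods appendix. It
describes what each stage computes and why, what the synthetic-data
generator does and does not emulate, and where genuinely open design
questions were settled.

## Interview data model

Each spouse's interview comprises 25 alters (the partner plus 24), ordinal
tie ratings on the scale 0 = no contact, 1 = "Not Well", 2 = "Pretty Well",
3 = "Very Well", and per-alter items (relation flags, knowing,
relationship quality, support, marriage opinion, contact frequencies).
Codes 0 and 1 are kept distinct even though all structural measures treat
both as absent ties: the raw distinction is meaningful (a "Not Well" pair
has had contact) and a lower threshold remains available as a sensitivity
setting.

Alter–alter pairs missing from the tie table are treated as 0 (no contact)
and counted in the load report. Interviews naming fewer than `min_alters`
alters (default 25, configurable down to 20 to mirror interview protocols
that admit partially complete respondents) are rejected, or excluded with a
logged reason in pipeline mode — never silently dropped.

## Merging two egocentric networks

Cross-spouse alter identity is decided deterministically:

1. names are normalized (case-fold, punctuation stripped, whitespace
   collapsed) and exact key equality proposes a match;
2. a proposed match is confirmed if the name is unique on both sides, or
   corroborated by relation-flag reciprocity (own_family ↔ spouse_family,
   own_friend ↔ spouse_friend or mutual own_friend) or by matching alter
   demographics;
3. duplicate names are paired corroborated-first, then lowest-index-first,
   and flagged ambiguous in the match evidence.

Manual adjudication of ambiguous matches — feasible in a live study, not in
software — is thus approximated by the corroboration rules; the ambiguity
flags give an audit trail. Fuzzy string matching is deliberately out of
scope: the generator can perturb names (`name_noise`) to exercise the
failure path, and real deployments should clean names upstream.

Each ego's nomination of their spouse folds into the partner's ego node, so
a wife's rating of the (husband, alter) pair is additional evidence for the
husband–alter edge. For every node pair the merged weight combines all
available evidence — both spouses' alter–alter ratings, the ego's own
knowing rating for ego–alter edges — under `max` (default), `min`, or
`mean`. Maximum is the headline rule (a tie exists if either spouse
perceives it); the alternatives are retained for sensitivity analysis. The
spouse–spouse edge is forced to 3, since spouses do not rate each other.
Ego–alter knowing (1–3) and alter–alter ratings (0–3) are treated as one
ordinal scale, as the merged network does not distinguish them.

With complete interviews the merged size is 50 − (matched pairs), bounded
by 26 and 50. (A "theoretical minimum of 25" is sometimes quoted for this
design, but two egos plus 24 fully shared alters is 26 under any
construction we can produce; the package implements the arithmetic.)

## Structural measures

* **Density and components** are computed on the alter-only graph at tie
  threshold 2 ("Pretty Well" or better). Ego nodes are excluded because
  every alter connects through them by construction; with egos included the
  component count is identically 1. Isolated alters count as components —
  each is a group only the couple bridges.
* **Composition and overlap proportions** divide alter counts by the full
  network size *including both egos*. This follows the field convention for
  these measures; it caps any category sum at (size−2)/size, which
  surprises users comparing against proportions-of-alters. Role labels are
  either-spouse unions: an alter is husband-family if the husband called
  them own family and/or the wife called them spouse's family, and a shared
  friend if both spouses called them their own friend (or one spouse called
  them both their own and their spouse's friend).
* **Nominee-subgroup density** is the thresholded density among one ego's
  nominees. Alters nominated by both spouses belong to both subgroups
  (configurable via `include_shared`); the egos themselves are excluded for
  consistency with the global density.
* **Burt constraint** per spouse is computed on the binary graph of
  strongest ties only (threshold 3), over the *full* network including both
  egos and the forced spouse edge — the spouse is a real, maximally strong
  contact inside the shared network. Proportional tie strength is
  `p_ij = a_ij/d_i` and `C_i = Σ_j (p_ij + Σ_q p_iq p_qj)²`. Binary
  thresholding (not weights) is used because the edge set is defined by a
  rating category. Closed forms used as test anchors: a star ego has
  `C = 1/d`, a dyad 1, a closed triad 1.125.

Undefined measures (density of a sub-two-node group, constraint of an
isolated ego) raise a typed signal; the profile assembler converts them to
missing values with a logged reason, and clustering excludes incomplete
rows listwise.

## Relationship quality and the couple score

Quality proportions use the same size-including-egos denominator as the
composition measures. For alters rated by both spouses a single value per
item is formed first: ordinal items take the more favorable rating
(extending the maximum precedent from tie merging; `min`/`mean` available),
binary support items take logical OR, and marriage opinion uses the
ordering approve > no_opinion > disapprove. Contact frequencies map to days
per year (every day → 365, few times a week → 156, once a week → 52, few
times a month → 36, once a month → 12, few times a year → 3, once a year
→ 1, never → 0); the endpoints are fixed by their labels, the interior
values are stated conventions and config-overridable.

Couple satisfaction combines the spouses' scores as
`C = (h+w)/2 − k·|h−w|/2` with k ∈ [0,1], default 0.5: the mean at k = 0,
the lower score at k = 1, monotone nonincreasing in k, and always between
the two. The published account of this formula contains a typo in the
constraint on k ("1 ≤ k ≤ 0") and a summary-statistics inconsistency (a
reported couple-score mean exceeding the mean of the spouse means, which
the formula forbids); the formula is implemented as defined and no attempt
is made to reproduce the inconsistent summary.

## Typology

The 10 criterion measures are z-scored (population-SD convention for the
standardizer itself) and clustered two ways: Ward's minimum-variance
hierarchical clustering (scipy linkage; merge heights are monotone), and
k-means (scikit-learn, best of restarts, seeded). The default
`ward_then_kmeans` seeds k-means from the Ward-partition centroids; the
literature this design follows does not say whether the stages were chained
or independent, so both modes exist.

Cluster-count diagnostics compute, per k: total within-cluster sum of
squares (elbow judged by the largest second difference), mean silhouette
(max), Calinski–Harabasz (max), Davies–Bouldin (min), and the gap statistic
(uniform bounding-box reference, B = 50 draws, seeded; smallest k with
gap(k) ≥ gap(k+1) − s(k+1)). The majority vote over these five indices is
the default k, but the final k is an analyst decision surfaced through the
diagnostics table — this replaces a 30-index battery with a representative
subset, which is adequate because the ultimate choice is inductive anyway.

t-scores express cluster profiles as
`t(c,v) = 100 + 10·(mean_c(v) − mean(v))/sd(v)` with the overall sample
mean and (n−1) SD. The sign convention (cluster minus overall) is the one
that makes above-average clusters score above 100, which is how published
tables of this statistic read even when their prose says the subtraction
backwards. By construction the size-weighted mean of each t-score column
is 100. One-way ANOVAs report η² = SS_b/SS_total, F, and p per variable;
zero within-cluster variance is reported as F = ∞ with a `degenerate` flag
rather than an error, since perfectly separated criterion variables are
legitimate on planted data.

## Association models

Bivariate logistic models (statsmodels, Newton to gradient tolerance 1e−10)
regress one-vs-rest cluster membership on a single covariate; multinomial
models (statsmodels MNLogit) give pairwise cluster contrasts as RRRs, with
`RRR(A vs B) = 1/RRR(B vs A)` by refitting the reference. Wald intervals
and p-values are reported (the conventional OR-with-95%-CI form), not
profile likelihood. Covariates enter on interpretable scales — proportions
×10 (decile units), constraint ×100 (per 0.01) — and race/ethnicity expands
to dummies against a Latino reference. Quasi-complete separation (plausible
for clusters of n ≈ 14) is detected by coefficient/SE guards and flagged,
not raised. No multiplicity correction by default (the analysis is
exploratory); Benjamini–Hochberg is available.

The two family-centered clusters profile alike and one is small, so
`merge_family_clusters` joins them into a single Family group before
modeling, mirroring standard practice for sparse categories.

## Synthetic couples

The generator emulates the interview schema exactly and plants the
structure the pipeline is meant to find. Per archetype it fixes a roster
(how many of each ego's 24 alters are own family/friends/other, how many
alters both spouses name, with reciprocal flags on shared ones), and draws
ties from a core/isolate block pattern per ego: a Poisson number of isolate
alters with no ties, and a core whose pairs tie ("Pretty Well"+) with an
ego-specific probability, split between ratings 2 and 3 by a strong-tie
share. Roster counts jitter by ±1 per couple (including the overlap) so no
criterion variable is degenerate within archetype. Quality items and
satisfaction draw from per-archetype response probabilities chosen to be
qualitatively faithful (the disconnected type knows its network less well,
receives less support, gets less approval); these are illustrative
parameters, not estimates.

Calibration: the five archetypes' density/components targets are set
proportional to the corresponding published cluster means, rescaled so the
default mixture (46, 60, 27, 60, 14)/207 hits cohort means of 0.20
(density) and 6.73 (components); core tie probabilities and isolate means
were then solved by short simulated iteration against those targets and
frozen in the presets. Nominee-subgroup density targets were scaled down
about 10% from the published cluster means to keep them jointly consistent
with the density targets — in any generator where cross-spouse alter pairs
are unrated (they cannot be: neither spouse is asked about them), overall
density is a weighted combination of the two nominee densities, and the
published triple is slightly infeasible; the ordering across archetypes is
preserved. Verified over ten cohorts of 207: mean density 0.198
(SE 0.0025), mean components 6.73 (SE 0.15), archetype recovery ARI ≈ 0.99.

What the generator does *not* emulate: naming errors and nickname variance
(except via the optional `name_noise` mode), correlated item responses
within alters, household composition, degree heterogeneity beyond the
core/isolate split, and any dependence of satisfaction on network structure
(satisfaction is independent of archetype up to small mean shifts). Passing
recovery tests on this data therefore shows the pipeline is correct and
well-conditioned under clean block structure — not that five types would
emerge from any real cohort.

## Problem sizes and determinism

Tests and the acceptance script use cohorts of 207 couples (ten replicates
for recovery/calibration checks), 100-seed random-graph sweeps (≤ 15 nodes)
for the brute-force oracles, 20 simulated datasets for reference-fit
agreement, and 500 replicates for null p-value uniformity — sizes chosen so
the whole battery runs in about a minute while keeping Monte Carlo error
well inside the asserted margins. All randomness flows from explicit seeds;
the pipeline fans one root seed out to fixed per-stage offsets, and
identical configs produce byte-identical outputs.

## Known limitations

* Name matching is exact-after-normalization; heavy nickname use in real
  data would need upstream resolution or a linkage model.
* Constraint is undefined for an ego with no strongest ties; in sparse
  cohorts this yields missing values that shrink the clustered sample.
* The multinomial fit can be slow/fragile under separation with many small
  clusters; flagged rows should be read qualitatively.
* The typology stage assumes the criterion variables are complete; no
  imputation is provided.
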