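# Methods

This note documents the statistical procedures, the synthetic-data
generator's assumptions, and the numerical choices the package makes where
the underlying field conventions leave room.

## Data model

The observation unit is an instantaneous *scan* of the group; each scan
yields one record per visible individual: location context (`road` /
`forest`), one of eleven behavioural states, and the set of conspecifics
within 1 m ("nearest neighbours"). Directed affiliative interactions
(actor → recipient) are recorded separately. A roster carries each
individual's age class (adult / subadult / juvenile / infant) and sex.

Infants and individuals not present for the whole study are excluded
before analysis. Exclusion prunes them from neighbour sets rather than
dropping whole records, because the association-index denominator is an
individual's *total* sighting count: removing another subject's record
would silently shrink it. A record with no neighbours still counts as a
sighting for the same reason.

## Association indices

`HWI(A, B) = 2N/(n_A + n_B)`, computed separately per context and data
type. Counting rules:

* **Proximity** — `N(A, B)` increments once per scan in which either
  member lists the other within 1 m; reciprocal listings inside one scan
  are not double-counted. The matrix is symmetric.
* **Affiliative** — `N(A→B)` counts scans containing at least one A→B
  interaction; repeats within a scan collapse. The numerator is directed
  over the undirected denominator `n_A + n_B`, so affiliative HWI is
  asymmetric (the asymmetry carries real information: A may direct
  affiliation at B far more than the reverse). Interactions can optionally
  be filtered by the actor's recorded scan state (default affiliative set:
  `affiliative`, `grooming`, `play`).

Dyads never co-observed get HWI 0, not missing, so matrices stay complete
for metric computation. An individual's *top associate* is its arg-max row
entry of the symmetrised matrix; ties break to the smallest id for
determinism, and an all-zero row is an error rather than a silent guess.

## Networks and metrics

Edges are the nonzero HWI values; proximity networks are undirected,
affiliative networks directed. Density is structural (weights ignored).
Geodesic metrics run on distances `d = 1/HWI`, the standard conversion for
similarity-weighted association networks; a `weighted=False` mode
binarises instead. Betweenness is standard shortest-path-count betweenness
(unnormalised) — descriptions of it as a "sum of edge weights along
geodesics" in parts of the applied literature do not match what the common
network software actually computes, and we implement the standard
quantity. Closeness is `1/Σd` over *reachable* nodes (isolates score 0),
defined so disconnected road networks are still summarisable. Eigenvector
centrality is the dominant eigenvector of the weight matrix by power
iteration (tolerance 1e-10, cap 10,000 iterations, deterministic uniform
start, diagonal shift by the largest weight so bipartite ±λ pairs cannot
stall the iteration), max-normalised; directed graphs use the right
eigenvector with a symmetrised fallback if the iteration degenerates.

Communities come from walktrap (4-step random walks) with the dendrogram
cut at maximum weighted modularity `Q`; directed networks are collapsed to
undirected by summing reciprocal weights first. Cluster labels are
renumbered by each cluster's smallest member id so output is deterministic.

## Effort-matched comparison of contexts

Because the group spends far more scans in the forest than on the road,
road and comprehensive forest networks are not directly comparable. The
*estimated* forest network draws 100 random subsamples of forest scans —
without replacement within month, each subsample matching the road scan
count of that month — recomputes HWI per subsample, and averages
entry-wise. Agreement between estimated and comprehensive networks is
screened with Spearman rank correlations per metric (exact permutation p
for n ≤ 9, t-approximation otherwise). When every subsample equals the
full forest pool (degenerate quota), the averaging short-circuits so the
estimated matrix reproduces the comprehensive one bit-exactly.

Context effects are tested on per-individual differences
`d_i = road_i − estimated-forest_i` (positive = greater along the road;
each result carries an explicit direction label so either sign convention
can be read off). The default null is **sign-flipping**: each of 10,000
resamples flips every `d_i` independently and compares `|mean*|` with the
observed `|mean|`. A literal centered-bootstrap resampling of the observed
differences is retained as `mode="centered_bootstrap"` for audit — its
null is centred on the observed mean and is conservative by construction,
which is why sign-flipping is the default for a paired symmetry test.
Monte-Carlo p-values use the add-one correction `p = (1+k)/(1+B)` so p is
never exactly 0; exhaustive enumeration (n ≤ 20) reports the exact
`k/2^n` with the identity assignment included.

## Permutation regression

`PermutationOLS` fits ordinary least squares of each individual's road
percentage on age (adult/nonadult, subadults coded adult — they are
near-adult-sized and reproductively active), sex, own eigenvector and
betweenness centrality, and top-associate eigenvector and betweenness
centrality, all from the comprehensive forest proximity network. The
intercept represents nonadult females. Interaction terms are off by
default but accepted by the design builder for sensitivity analyses.
Dominance rank is deliberately absent from the design.

Inference permutes the raw response (Freedman–Lane-style residual schemes
are a possible extension; raw-response permutation is what the sequential
permutation-regression convention prescribes) and compares `|b*_j|` with
`|b_j|`. Each term runs until its p estimate converges — at least 50
iterations and binomial `SE(p̂) < 0.1·p̂` — or to the 5,000-iteration cap.
This reproduces the characteristic iteration pattern: tens of iterations
for clearly null terms, the full cap for significant ones. Reported
coefficients are always the plain OLS estimates on the unpermuted data;
adjusted R² is `1 − (1−R²)(n−1)/(n−p−1)`; an omnibus permutation p on R²
is tracked over the same permutation stream. `fit_exhaustive()` (n ≤ 8)
enumerates all n! permutations; `exact_perm_lm` re-implements that
enumeration as an independent per-permutation least-squares loop and
serves as the oracle in tests.

## Class-level summaries

Risk perception is probed by Mann-Whitney U tests on per-record
nearest-neighbour counts, road vs forest, within each age-sex class
(exact enumeration when the pooled sample is ≤ 12 and tie-free, otherwise
the tie- and continuity-corrected normal approximation). Records are
treated as independent observations, replicating the field procedure; the
pseudo-replication this entails is a known caveat of the method, not
corrected here. Per-class mean ± sd of metric differences are reported
with single-member classes flagged (`sd` printed as 0).

## Synthetic-data generator

`SimConfig` defaults encode the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| class counts | 9 AM, 11 AF, 2 SM, 6 JM, 5 JF, 2 infants | one adult male marked not-present-full-study |
| scans | 1,219 over 6 months (~203/month) | ~12 scans per observation day |
| p(road scan) by month | 0.15–0.24, mean ≈ 0.198 | group-level road-context probability |
| detectability | 0.85 | chance an individual is recorded per scan |
| affinity within / between block | 0.04 / 0.012 | per-scan 1 m co-occurrence probability; blocks = juveniles vs adults+subadults |
| affinity jitter | lognormal, σ = 0.25 | mean-corrected dyadic heterogeneity |
| road affinity scale | 0.7 | fewer neighbours on the road |
| road base / sex effect / betweenness effect | 12.1 / +6.0 / 2.0 per SD | percentage points of records along the road |
| interaction rate | 0.1 | affiliative thinning of affinity |

The road model is additive on the *percentage-point* scale: an
individual's marginal share of records along the road is
`base + sex_effect·male + betweenness_effect·z(betweenness)`, converted
internally to an on-road probability conditional on the group being at the
road. Keeping planted effects in the same units as the regression
coefficients makes recovery checks direct; a logistic parameterisation
would obscure what "+6 points" means. The betweenness covariate of the
road model is the z-scored weighted betweenness of the *planted* affinity
graph, so it is deterministic given the configuration.

Affinity levels were chosen so mean neighbours-per-record falls in the
0.4–0.9 range typical of tolerant macaques while leaving the two-block
structure recoverable; the within/between contrast (≈3.3:1) is what drives
walktrap recovery. What the generator does **not** emulate: spatial
movement and home-range structure, temporal autocorrelation between
consecutive scans, state-dependent association (neighbours are drawn
independently of behavioural state), kinship, and dominance. Passing tests
therefore demonstrate the *statistical machinery* is correct and
calibrated under the designed conditions — not that real field data meet
those conditions. One visible divergence: generated affiliative road
networks are sparser relative to forest networks than field data tend to
be, because event rates are homogeneous within blocks.

Generation uses a single seeded generator stream; identical seeds give
byte-identical output files.

## Problem sizes in the test suite

Calibration and recovery checks run at sizes chosen to give tight binomial
error while staying quick: 500 replicates for type-I-error calibration of
the permutation regression (199 permutations each, at which the nominal
0.05 level is exactly attainable) and of the sign-flip test; 200 generated
datasets (999 permutations per term) for the sex-effect power check;
walktrap block recovery assessed on 25 of those replicates. Exhaustive
oracles cover n ≤ 8 (regression), n ≤ 12 (sign-flip and Mann-Whitney),
and n ≤ 9 (Spearman).

## Known limitations

* The affiliative HWI's directed numerator over an undirected denominator
  is a pragmatic convention; it is not a proper association *rate* for
  rare interactions.
* Closeness on disconnected graphs sums over reachable nodes only; values
  are not comparable across nodes in different component sizes (component
  size is available from the graph when this matters).
* The sequential stopping rule makes per-term iteration counts themselves
  random; p-values near the stopping threshold carry slightly more
  Monte-Carlo noise than a fixed-iteration run of the same length.
* The pipeline assumes one context per (scan, individual) record; an
  individual seen in both contexts within a scan is not representable.
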