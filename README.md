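# socioscan

Social network analysis of behavioural scan data for wild animal groups
that split their time between human-influenced and natural contexts — the
motivating case is a group of moor macaques (*Macaca maura*) that forages
along a provisioning road bisecting its forest home range.

The package answers two questions a behavioural ecologist asks of such
data:

1. **Who spends time near humans, and why?** Each individual's percentage
   of behavioural records in the road context is regressed on life-history
   (age, sex) and social-network predictors (own and top-associate
   centrality) with permutation-based inference.
2. **What does proximity to humans do to the group's social structure?**
   Road-context networks are compared with effort-matched forest networks
   via per-individual metric differences and randomization tests, plus
   walktrap community detection.

## Model and statistics

Association strength for a dyad (A, B) is the **half-weight association
index**

```
HWI(A, B) = 2N / (n_A + n_B)
```

where `2N` counts joint sightings (proximity within 1 m, or directed
affiliative interactions) and `n_A`, `n_B` total sightings, all within one
context (road/forest). Six weighted networks are built: road, comprehensive
forest, and *estimated* forest, for each of the proximity (undirected) and
affiliative (directed) data types. The estimated forest network averages
HWI over 100 random forest-scan subsamples matched month-by-month to the
road sampling effort, correcting for unequal observation time across
contexts.

Per network, the package computes density, weighted degree, weighted
betweenness and closeness (geodesics on distances `1/HWI`), max-normalised
eigenvector centrality, and walktrap communities with weighted modularity
`Q`.

Inference is permutation-based throughout:

* `PermutationOLS.fit()` permutes the response up to 5,000 times per term
  with a sequential stopping rule, reporting each coefficient with its
  iteration count and two-tailed p-value (exact enumeration available for
  n ≤ 8);
* road-vs-forest metric differences are tested by sign-flip randomization
  (10,000 resamples; exact enumeration for small n; a centered-bootstrap
  variant is provided for comparison);
* nearest-neighbour counts per age-sex class are compared across contexts
  with Mann-Whitney U tests (exact for small tie-free samples).

A synthetic scan-data generator (`socioscan.simulate`) emulates the study
conditions — 35 individuals in fixed age-sex classes, ~1,200 scans over six
months, ~20% road-context scans, block-structured dyadic affinities and a
planted +6 percentage-point male effect on road presence — so every
statistical routine can be checked for calibration and parameter recovery
without field data.

## Worked example

```
socioscan simulate --seed 5 --out demo/
socioscan run --scans demo/scans.csv --interactions demo/interactions.csv \
              --roster demo/roster.csv --out results/
```

prints (output from the command above):

```
Permutation-based linear regression
n = 32, response = road_pct

Variable                     Coefficient  Iterations   p-value
--------------------------------------------------------------
Intercept                          5.517          50     0.882
age                               -5.997         200     0.393
sex                                5.018        5000     0.000 *
eigenvector                       17.993         600     0.146
betweenness                        0.044          50     0.824
assoc_eigenvector                 -3.488          50     0.765
assoc_betweenness                  -0.080        150     0.477
--------------------------------------------------------------
Adjusted R^2 = 0.715, omnibus p = 0.0002

6 networks written to results/
```

The sex coefficient (5.0 percentage points, p < 0.001) recovers the
generator's planted +6-point male effect on road presence; clearly null
terms stop after few permutation iterations while the significant term runs
to the 5,000-iteration cap. The output directory holds the six network
edge lists/GraphML files, per-network metric tables, the Spearman
validation of estimated vs comprehensive forest networks, the eight
randomization comparisons (4 metrics × 2 data types), age-sex-class
summaries and a manifest sufficient to reproduce the run bit-for-bit.

The same analysis is available as a library:

```python
from socioscan import SimConfig, generate, RunConfig, run_pipeline

data = generate(SimConfig(seed=5))
bundle = run_pipeline(data.scans, data.interactions, data.roster, RunConfig(seed=5))
print(bundle.regression.summary())
```

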