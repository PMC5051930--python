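# Methods

## Model and procedure

The package measures pairwise provider collaboration through shared
patient encounters and their outcomes, in five stages.

**1. Risk adjustment.** Each encounter has a binary outcome `y` and
baseline covariates. A logistic regression (maximum likelihood, via
statsmodels) yields fitted probabilities `p`, and the risk-adjusted
outcome is `r = (1 + y − p)/2`. The transform's limits are the point of
the construction: `y=1` with `p → 0` gives `r → 1` (generous reward for
an unexpected win), `y=0` with `p → 1` gives `r → 0` (heavy penalty for
an unexpected loss), while expected outcomes sit near ½; for any fixed
`p` the gap `r(1,p) − r(0,p)` is exactly ½. An alternative algebraic
reading of the transform, `1 + (y − p)²`, is rejected because it violates
these limits (it would give r = 1 to an expected win). Covariates are
user-specified; ordinal acuity (ESI 1–5) defaults to categorical coding
with the most frequent level as reference, overridable to numeric.
Complete-case analysis: encounters with a missing outcome or missing
covariates are excluded from fitting, prediction and everything
downstream, but remain visible in the bipartite structure and the
validation report. Fitted probabilities are clipped to
`[1e−9, 1 − 1e−9]` before the transform so a degenerate fit cannot zero
out the SPOI denominator.

**2. Bipartite network.** Provider events aggregate to one involvement
edge per (provider, encounter) with an `action_count`; all activities
count equally. `A_j` is provider `j`'s encounter set restricted to
encounters with a computable `r`. Both SEI and SPOI are computed over
this same restricted universe — mixing universes would break the
centring of SPOR at 1.

**3. Projection and edge weights.** Pairs are enumerated through an
inverted encounter → providers index, so only pairs that actually
co-occur are visited. A pair enters the collaboration network when its
shared count reaches the threshold (default 6); isolated providers are
dropped from the node set. Edge weights: SEI (Jaccard), SPOI (ratio of
`r`-sums over intersection and union; sums run in sorted encounter order
so identical sets give bit-identical sums and exclusive pairs score
exactly 1.0), SPOR = SPOI/SEI. An edge whose union `r`-sum is zero
(possible only under clipping-extreme fits) is dropped with a logged
warning. The threshold sweep (default 2, 4, 6, 8, 10) reports
mean/SD/5th/10th/90th/95th percentiles of SPOR per threshold; percentiles
use linear interpolation between order statistics (numpy's default,
"type 7"). Network summaries (density, mean degree, clustering) use
networkx; diameter and mean path length are computed on the largest
connected component because thresholded projections need not be
connected.

**4. Permutation null.** The `r` values are shuffled uniformly across
encounters; topology is untouched, so the edge set is identical in every
permuted network (SEI is outcome-free) and only SPOI moves. The observed
network is projected once and its intersection/union structure is encoded
as two sparse edge × encounter indicator matrices, so each of the
B = 1,000 permutations is two sparse matrix–vector products. The per-edge
p-value is the fraction of permuted SPORs *strictly* exceeding the
observed SPOR (ties do not exceed; p = 0 is possible). A
`(k+1)/(B+1)` smoothed estimator is available behind a flag for users who
need positive p-values. Seeding: one master seed spawns B substreams via
`numpy.random.SeedSequence.spawn`, so results are independent of
execution order and bit-reproducible. No multiplicity correction is
applied across edges; the 5% flag rates are nominal per-edge rates, and
under the null the expected share of edges at p ≤ 0.05 with strict
exceedance and B = 1,000 is 51/1001 ≈ 0.051.

**5. Classification and scoring groups.** Edges with p ≤ 0.05 are
high-scoring, p ≥ 0.95 low-scoring (both cuts inclusive). A provider
joins a scoring group when at least 5% of its collaborations (its degree
in the thresholded network) carry the group's label *and* it has at least
two such edges; the multiplicity floor avoids crowning providers on a
single lucky edge and is configurable. Providers may belong to both
groups. The group summary is the degree-weighted average flagged
fraction, Σ flagged / Σ degree over members.

## Synthetic data generator

The generator stands in for a protected ED-scale EHR extract and is
first-class, tested code. Defaults (the study conditions for all
calibration and power checks): 150 providers, 3,000 encounters, 8
provider pools with round-robin assignment, mixing rate 0.20 (expected
fraction of each team drawn from the whole roster rather than the home
pool), team size negative-binomial with mean 9.2 and SD 4.3 truncated at
1 (matching the observed provider-count profile of a large academic ED;
`sd=0` gives constant teams for exact-count tests), acuity levels 1–5
with probabilities 0.01/0.20/0.50/0.25/0.04 (median 3; level 1 is rare
among surveyed encounters because resuscitation patients are usually
admitted and never surveyed), and a logistic outcome model with intercept
logit(0.6) at reference acuity 3 and per-level log-odds offsets
(−0.8, −0.3, 0, +0.2, +0.4 for levels 1–5), giving a marginal positive
rate of ≈ 0.60. Each involvement emits `1 + Poisson(1.8)` action rows
with activity/action labels, matching ~2–3 actions per provider per
encounter.

Pools exist because uniformly sampled teams at this scale essentially
never reach 6 shared encounters; pooling is what makes thresholded
networks non-trivial at desk scale, at the cost of a denser projection
than a full-scale data set would show. Enriched pairs add δ (default
0.25) to the positive-outcome *probability* of any encounter whose team
contains both members, clipped to [0, 1]; enrichment on the probability
scale maps directly onto the outcome concentration SPOR measures, which
keeps power curves interpretable. `enriched_config` places disjoint
within-pool pairs deterministically so planted effects do not interact
and the pairs reliably appear in the ≥6 network. The emitted truth record
stores the full configuration, pool assignment and enriched-pair
identities for recovery tests.

The generator does **not** emulate survey non-response, resurvey
suppression, admission/discharge selection, provider turnover, or
activity-sequence realism. Passing calibration and power checks on this
generator therefore shows the machinery is correct and calibrated under
the stated structure, not that any particular real data set satisfies
that structure. The optional acuity–team-size coupling
(`acuity_team_coupling`, default 0) scales mean team size by
`1 + c·(3 − acuity)/2` for users who want sicker patients to involve
more providers; its strength is a free parameter.

## Numerical and testing choices

* Exactness where exactness is claimed: exclusive pairs give SPOR = 1.0
  bit-exactly (sorted summation), constant `r` collapses every SPOR to
  1.0, and permuted edge sets equal the observed edge set by
  construction.
* The network-mean SPOR test uses a Monte-Carlo standard error taken
  from the permutation null of the same statistic (the SD across
  permutations of the edge-mean), because edges overlap and an iid
  standard error would be too tight.
* Tail-calibration tests compare the share of edges at p ≤ α against α
  within 3 binomial standard errors at α ∈ {0.05, 0.10} and the
  symmetric upper tail. P-values are positively correlated across
  overlapping edges, so this band is approximate; at the default scale
  the realized shares have stayed inside it.
* Threshold-sweep monotonicity checks allow an absolute Monte-Carlo
  slack of 0.02 between adjacent thresholds and require strict
  improvement from threshold 2 to 10.
* Problem sizes: unit tests run at 40–100 providers and 200–1,500
  encounters; calibration, power and the acceptance script run at the
  default 150 × 3,000 scale with B = 1,000, which completes in seconds
  thanks to the sparse-matrix permutation path.
* Degenerate inputs: empty event tables, all-identical outcomes,
  single-level categorical covariates, perfect separation, disjoint
  encounter sets, zero union mass, sub-threshold networks and empty
  projections all raise or degrade explicitly (documented per function).

## Known limitations

* The desk-scale generator yields a much denser collaboration network
  (density ≈ 0.4 at threshold 6) than a full-scale multi-year extract
  would; density-dependent summaries are not comparable across scales,
  while the calibration properties (mean SPOR ≈ 1, ~5% tails) are.
* Strict-exceed p-values can be exactly 0; use the smoothed estimator if
  downstream methods cannot tolerate that.
* The 5% scoring-group rule interprets "total collaborative
  interactions" as degree in the thresholded network, not lifetime pair
  count.
* Only pairwise collaboration is scored; teams of three or more are out
  of scope, as are activity-type weighting and community detection.
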