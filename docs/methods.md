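# Methods

This note documents the models, estimators and design choices behind
`splitmaze`, and what the synthetic validation does and does not establish.

## Maze geometry

The apparatus is reconstructed from its stated dimensions: seven octagonal
enclosures (25 cm flat-to-flat, regular octagons with facets every 45°) and
seven 20 × 10 cm alleys.  A planar double-Y — central stem vertical, all
later arms at ±45° — is the unique straight-alley embedding in which every
alley spans exactly 20 cm between facing octagon facets and routes 2 and 3
converge on a single Centre Goal Box; it is adopted as the canonical layout.
Coordinates are centimetres with the origin at the start-box centre and y
increasing toward the goals.  The 14 sectors (start box, central stem, three
choice points, left/right stems, four goal alleys, three goal boxes) carry a
distance rank used by the sector-activity correlation.  Point-in-sector
assignment is boundary-inclusive with ties resolved by a fixed canonical
order, applied identically to position samples and interpolated spike
positions.

## Synthetic sessions

`simulate_session` follows the win-stay, lose-shift protocol: within a
block the rat samples unvisited goal boxes uniformly until it finds the
rewarded one (entering a wrong box is an error trial), then runs
`trials_per_block` (default 11) further trials with the same box rewarded,
extended until at least `min_correct_per_block` (default 6) of them are
correct.  Post-identification errors occur with probability `p_post`
(default 0.05) and choose a wrong route with a four-fold weight on the
partner Centre route when a Centre route is rewarded, reflecting the
observed confusion structure.  Which route reaches the Centre box is
dictated by the transparent barrier: the entrance further from the rewarded
box is blocked.

Trials consist of a hold phase in the start box (uniform 6–9 s, jittered
position), a run along the route centerline with AR(1) speed and lateral
noise, and a goal-box dwell (3–5 s when rewarded).  Tracking is sampled at
50 Hz (typical camera rate; a declared default, the source protocol does
not state one).  Run speeds default to 15 cm/s during search trials and
25 cm/s once the rewarded box is known; with the ~135 cm centerline these
reproduce the published mean travel times (9.08 s before identifying the
goal, 5.38 s after).

`simulate_place_cell` draws spikes by thinning an inhomogeneous Poisson
process with intensity

    λ(t) = baseline + peak · exp(−d(t)²/2w²) · route_gain[route(t)] · goal_gain[goal(route(t))]

where d is the distance to the nearest field centre and w the field width
(default 6 cm; defaults: peak 5 Hz, baseline 0.1 Hz).  The gains are
multiplicative and the Centre goal gain applies identically to routes 2 and
3 — the generator can therefore realise the route hypothesis, the goal
hypothesis, or neither.  The thinning bound is exact
(baseline + peak · max effective gain), and during the hold phase the
upcoming trial's route applies (prospective coding by construction).
`simulate_feature_cloud` produces a Gaussian cluster with a random SPD
covariance plus a noise cloud displaced by a stated number of Mahalanobis
units, for quality-metric validation.

## Rate maps and spatial information

The rate estimator is the ratio of kernel-weighted spike counts to the
kernel-weighted occupancy integral, with g(u) = exp(−u²/2) and smoothing
factor h = 2.5 cm.  The occupancy integral uses the rectangle rule over
tracking samples (forward time differences, last interval repeated);
sub-sample interpolation is not attempted.  Bin size defaults to 2.5 cm
(unstated in the source protocol; set equal to h, configurable) and bins
with no tracking sample within 5 cm are masked unvisited.  Spatial
information Σ Pᵢ(Rᵢ/R)log₂(Rᵢ/R) uses raw (not kernel-smoothed) occupancy
for Pᵢ over visited bins, the convention 0·log 0 = 0, and is read as bits
per spike (the per-spike form of the statistic).  An all-zero map returns 0.
Field counting thresholds at 20 % of the map peak with a 4-bin minimum and
4-connectivity — declared defaults, since no published criteria exist.

## Unit quality

Squared Mahalanobis distances use the cluster's sample feature covariance
(no shrinkage; a singular covariance flags the metrics undefined).
Isolation distance is the n_c-th smallest non-cluster distance and is
reported as undefined when fewer than n_c non-cluster spikes exist.  L sums
χ² survival probabilities of non-cluster distances with df equal to the
feature dimension (8 for four tetrode channels × two features), and
L-ratio = L/n_c.  The printed signal-to-noise expression reduces
algebraically to (μ_signal/μ_noise)², with μ taken as mean peak amplitude.
The place-cell screen uses strict inequalities.  Quality/effect association
runs two-sample Kolmogorov–Smirnov tests between differential and
non-differential cells per metric, and Spearman correlations between metric
and F-statistic after iterative two-sided Grubbs pruning (α = 0.05, one
point per iteration, applied to both variables).

## Differential firing

Per trial and sector the dependent variable is spikes-in-sector over
seconds-in-sector; covariates are the trial's mean x, mean y and mean speed
(path length over time) in the sector.  A cell is scored only when active
(pooled rate > 1 Hz on at least one route) and when every traversed route
has ≥ 5 trials (the protocol guarantees ≥ 6 correct).  Error trials are
excluded by default.

* **Rank ANCOVA:** mid-ranks of DV and covariates; OLS of ranked DV on
  ranked covariates (collinear covariates dropped with a warning); one-way
  ANOVA of the residuals against route.  A constant DV yields F = 0, p = 1.
  Post-hoc: six pairwise Tukey–Kramer comparisons of residual group means
  (the Matlab `multcompare` default the original analysis used); Šidák
  available.
* **Permutation ANCOVA:** parametric partial F for the route term on the
  raw DV, compared with k = 5000 shuffles of the DV rows against fixed
  route/covariates; p = #(F_shuff ≥ F_obs)/k, so the resolution is 1/k and
  an observed F above every shuffle reports p = 0.
* **Poisson GLM:** log-link regression of per-trial spike counts on route
  (categorical) and covariates with a log-exposure offset — the
  Poisson-faithful reading of modelling trial rates; a raw-rate fit is
  available for literal replication.  The omnibus route test is the
  likelihood-ratio χ²(3); post-hoc, six uncorrected Mann–Whitney
  comparisons of raw rates.

Classification: route-specific-k when route k differs (p < α) from each
other route; goal-dependent when routes 2 and 3 each differ from 1 and 4
while 2 vs 3 is not significant.  If several routes qualify (possible when
five or six pairs are significant) the route with the largest mean absolute
marginal-mean separation is taken — a deterministic tie-break.  Population
tests are Pearson goodness-of-fit χ²: the five pattern categories against
uniform, and centre-preferring (2, 3, goal-dependent) versus outer (1, 4)
against 50/50.

Type-I calibration of all three methods on 1000 unmodulated synthetic cells
falls within [0.03, 0.07] at α = 0.05, and gain-4 cells are recovered with
≥ 90 % label accuracy (the validation suite recomputes both).

## Ensemble decoding

Trial population vectors (per-cell sector rates) are compared by cosine
similarity to four route-average goal vectors computed with the trial held
out of its own route's average; routes with fewer than two remaining trials
are excluded, ensembles need ≥ 6 cells, and error trials are omitted.  Ties
at the arg-max are broken uniformly at random under the session seed.  The
null permutes each neuron's four goal-vector entries independently across
routes (route identity shuffled, neuron identity kept), re-decodes, and
records the match-percentage matrix; p-values are upper-tail probabilities
under an Epanechnikov-kernel smoothed CDF of the shuffle sample with a
Silverman-style bandwidth 2.345·σ̂·n^(−1/5) (configurable).  Within one
session the shuffle distribution of a tile is nearly atomic (similar trials
co-match one shuffled vector), so chance-level assessment pools sessions:
`pooled_decode` aggregates match percentages over ensembles and draws fresh
per-neuron permutations in every session per shuffle, matching the
published multi-ensemble procedure (25 ensembles, mean ~11 cells).  The
within-block trend check rank-correlates within-block trial position
(truncated at 12, the mean block length) with the correct-match indicator
and with the matched similarity.

## Goal-box similarity

Destination-box population vectors pool every cell of every session (one
entry per cell-session), with box firing read from box entry to trial end.
The six pairwise Spearman correlations are tested against a null that, for
an anchor vector A, correlates A with a vector whose entry per cell is one
of that cell's rates under the three non-A labels (cell order kept; a
random single label, i.e. without replacement).  Because the pair is
unordered and anchoring is not specified, the reported p is the maximum
over the two anchored tail probabilities — a pair counts as above chance
only from both boxes' perspectives.  This choice matters: label-mixing
attenuates rank correlation, so a single-anchor test is anti-conservative
for whichever label happens to correlate best with the anchor.

The validating generator gives each unit a broad goal-row field (35–55 cm,
spanning the three boxes) plus a route-gain start field: Centre-box firing
is then route-invariant by construction, box-to-box similarity decreases
with distance (the Centre box sits between the outer boxes), and all-box
correlations stay high through per-cell excitability — under which only the
Centre R2/R3 pair beats its null, stably across seeds.

## Behavior scoring

Blocks are split at the first correct trial; errors and mean travel times
(start-box exit to goal entry) are reported per phase, and each
post-identification error joins the unordered pair {chosen route, rewarded
route}, whose six counts sum to the total post-identification errors.

## Numerical and validation notes

* All randomness flows through `numpy.random.Generator` seeds;
  session-level seeds fan out to per-stage child seeds via `SeedSequence`
  so stages re-run reproducibly in isolation.
* The rate-map estimator matches an explicit double-loop implementation to
  1e-10; the rank-ANCOVA F matches a normal-equations/textbook-ANOVA
  oracle to 1e-8; pattern χ² statistics match exact rational arithmetic.
* Validation problem sizes (1000 null cells at k = 1000 permutation
  shuffles, 200 recovery cells, 25 pooled ensembles at 2000 shuffles, four
  60-cell goal-box sessions at 5000 shuffles) are the package's chosen
  balance of statistical resolution and runtime; the shuffle counts for the
  published analyses default to their stated values (5000 and 10,000).
* Known limitations of the generator: no theta rhythm, phase precession,
  overdispersion or rate remapping; trajectories follow centerlines with
  stationary noise rather than learned paths; spike waveforms are not
  simulated (waveform width enters only as metadata).  Passing synthetic
  validation therefore demonstrates correctness and calibration of the
  estimators under Poisson spiking and the stated task structure, not
  robustness to every property of real recordings — in particular the
  Poisson GLM's calibration would degrade under strong overdispersion,
  which is why the rank and permutation methods are the defaults.
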