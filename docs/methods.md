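# Methods

## Study system and data model

The package targets closed-population assessment of adult *Tachypleus
tridentatus* monitored by tag-and-release across three Taiwan Strait
subregions (Kinmen, Penghu, Taiwan main island). The primary record is the
capture event: one row per animal handled, carrying tag id, ISO date,
subregion, WGS84 coordinates, event kind (`first_capture_tagged`,
`first_capture_untagged`, `recapture`), a release flag, and optional sex,
prosomal width (cm) and gear. Effort logs hold one row per subregion-month
in the unit conventional for the subregion: person-times for Kinmen and
Taiwan, net sets for Penghu.

Occasions are calendar months containing at least one event; a calendar
year is one closed period. This matches a program whose abundance is
reported both monthly and annually, and keeps the closure assumption at
the scale where it is most defensible. Per occasion t the aggregation
yields C_t (all events), R_t (recaptures of tags marked in an *earlier*
occasion), U_t (newly tagged releases), and M_t via M_{t+1} = M_t + U_t.
Two policy choices matter:

* **Untagged first captures are removals.** Animals recorded but not
  tagged never enter the marked pool and leave the at-risk population.
  This mirrors monitoring data where the marked total is below the
  captured total every year.
* **Cross-year carryover (default on).** Tags marked in earlier years seed
  M_1 of later years and their recaptures count in R_t, consistent with
  multi-year tag persistence and an assumed zero natural mortality of
  tagged adults. Analyses of independently simulated years disable it.
* A tag recaptured twice in one year contributes to R_t once per
  recapture event (each row counts); recaptures in the same month a tag
  was applied fall outside R_t's "marked in an earlier occasion"
  definition and count only in C_t.

## Schnabel estimation

N̂ = Σ_t C_t M_t / (Σ_t R_t + 1), with Var(1/N̂) = Σ_t R_t / (Σ_t C_t M_t)²
and SE(1/N̂) its square root. Uncertainty is handled on the reciprocal
scale throughout, treating Σ R_t as approximately Poisson.

Confidence intervals: for Σ R_t < 50 the default is exact (Garwood)
Poisson limits on Σ R_t via the chi-square relation, inverted through
N = ΣCM / limit (the small-count rule of standard mark-recapture
practice); for larger counts, a normal interval on 1/N̂ clipped below at
10⁻¹² and inverted. With zero recaptures the upper abundance bound is
reported as unbounded and flagged rather than fabricated. Both methods
produce the strongly right-skewed intervals characteristic of reciprocal-
scale inference.

The cross-subregion comparison draws 1/N per region from a normal centred
on (1/N̂, SE(1/N̂)) truncated to positive (rejection at ≤ 10⁻¹²), inverts
to N, and reports equal-tailed 95% intervals and pairwise exceedance
probabilities P(N_A > N_B). It is fully seeded; the per-region streams
come from independent `SeedSequence` spawns so adding a region never
perturbs another's draws.

## Bayesian N-mixture model

Each stratum has latent abundance N and constant per-occasion detection
probability p (model M0). The multinomial structure over capture histories
reduces to two sufficient statistics — n distinct individuals detected and
y total capture events — giving the kernel

log L(N, p) = log[N!/(N−n)!] + y log p + (A(N) − y) log(1−p),

where A(N) is the count of at-risk animal-occasions: N·T, reduced by the
cumulative removals before each occasion when the removal toggle is on
(default on, matching the tag-or-remove protocol).

Priors: N ~ log-normal with location log(5n) and scale 1.5 (weakly
informative — roughly "abundance is within a couple of orders of magnitude
of 5× the count", appropriate when detection may be low), p ~ Beta(1,1).
These hyperparameters are package defaults, stated rather than inherited
from any external analysis.

**Sampling.** N is discrete, so the sampler marginalizes it against the
discretized log-normal prior over [n, N_max], N_max = max(10n, 1000)
(enforced ≥ 10n). The remaining 1-D posterior over logit(p) is sampled by
stepping-out slice sampling (Neal 2003): 4 chains × 2000 draws after 1000
warm-up steps by default, chains initialized from a 400-point scan of the
marginal (mode plus one posterior-SD jitter), slice width retuned every 50
warm-up steps to the typical slice extent. Slice sampling was chosen over
random-walk Metropolis because a 1-D target with steep tails collapses an
acceptance-targeted random-walk step size and leaves chains stranded;
slice steps adapt to the local scale automatically and deliver near-iid
draws (bulk ESS ≈ the draw count in practice). N is then drawn exactly per
retained p draw by inverse-CDF sampling of its discrete conditional, so
the N margin inherits the p chain's convergence. The config retains the
standard sampler fields (chains, draws, tune, target acceptance); the
slice kernel has no acceptance knob and ignores the target.

**Diagnostics.** Rank-normalized split R̂ and bulk ESS per parameter
(arviz implementations of the standard estimators). R̂ > 1.01 flags the
result as non-converged (returned, not discarded). Posterior mass above
0.9·N_max beyond 10⁻³ raises a truncation warning; the analysis drivers
respond by refitting with N_max quadrupled until the mass fits.

**Oracle.** `grid_posterior` normalizes the same joint by direct summation
over an (N, p) grid (512 p midpoints by default), giving exhaustive
marginals, means and equal-tailed intervals. The MCMC path is validated
against it (agreement within 3 Monte Carlo SEs), and prior-only and
symmetric-data identities hold on the grid exactly.

## Descriptive summaries

Recapture rate = 100·recaptured/captured and CPUE = captured/effort, both
rounded half-up at two decimals via exact `Decimal` rationals — half-up
(not banker's) is the convention that reproduces the program's printed
annual tables cell-for-cell. CPUE keeps its unit annotation because the
Penghu net-set denominator is not comparable with person-times; no
cross-gear standardization is attempted. Size summaries are plain
five-number summaries of prosomal width per subregion and sex.

## Movement

Straight-line displacement is the haversine great-circle distance on a
sphere of radius 6371.0088 km (IUGG mean). At Taiwan Strait latitudes and
scales (< 400 km) this sits within 0.5% of the WGS84 geodesic, verified
in tests against an independent Vincenty iteration. Days at liberty is
the exact calendar difference, exclusive of the release day. Each
recapture is paired with the most recent prior release of the same tag, so
serial recaptures chain through intermediate re-releases.

## Connectivity

Core areas are the fourth quartile (Q4) of the habitat-quality index:
threshold at the 75th percentile (linear-interpolation quantile) of
non-nodata cells, cells at or above it grouped into 8-connected patches
labeled in row-major discovery order. Resistance is the linear inversion
r = 1 + 99(1 − HQI) onto the conventional [1, 100] range — the mapping is
a package design choice, recorded in output metadata, since suitability-
to-resistance transforms are not standardized. Nodata cells are
impassable.

Corridors are least-cost routes over 8-connected moves costing
step·(r_i + r_j)/2 with step = cell size (orthogonal) or cell size·√2
(diagonal) — the average-node-cost convention of corridor-mapping tools.
Patch-to-patch cost minimizes over all source and target cells
(multi-source Dijkstra; heap keyed (cost, row, col) for deterministic
tie-breaking). Unreachable pairs are flagged with infinite cost, not
dropped. Pair policy: all reachable pairs by default; a neighbor-limited
mode keeps only corridors crossing no third core patch. Rasters
interchange as ESRI ASCII grids.

## Synthetic data

The generator emulates the assumed sampling process exactly: each of
true_N animals is detected independently with probability p at each of T
monthly occasions (April-September by default); first detections are
tagged-and-released with probability `tagging_prob`, otherwise removed;
later detections of tagged animals are recaptures. Coordinates are uniform
in per-subregion bounding boxes, sexes are balanced, prosomal widths are
normal by sex (F: 28 ± 4.5 cm, M: 24 ± 4 cm, clipped to 9-40 cm) —
descriptive dressing matched to the observed size range, not used by any
estimator. One master seed splits into independent streams (detection,
coordinates, dates, biology). The generator records its own per-occasion
tallies, which the aggregation module must reproduce exactly — a
generator-vs-aggregator cross-validation that pins both sides to one world
model.

Habitat rasters are sums of equal Gaussian bumps rescaled to [0, 1]. Bump
centers are rejection-placed with a minimum separation that guarantees one
Q4 core patch per bump: because 25% of all cells must exceed the Q4
threshold, the quartile set spills well beyond the bumps, and distinct
patches require the inter-bump saddle (height 2e^{−d²/8w²}) to dip below
the threshold near the quartile-disk radius r* = √(0.25·area/(π·bumps)).
The default separation solves d² > 8w²ln2 + 4r*² with a 25% margin on r*
for edge clipping.

Displacement pairs use exponential jump lengths with uniform bearings
(spherical direct problem) and 30-500 days at liberty.

What the generator does **not** emulate: spatial clustering of effort or
animals, detection heterogeneity among individuals, tag loss, mortality of
tagged animals, births/immigration within a year, or current-driven
movement. Passing tests therefore demonstrate correctness of the
estimators *under their own assumptions*, not robustness to the
heterogeneity and non-closure real surveys face.

## Problem sizes and validation experiments

* Schnabel recovery: 500 simulated surveys at (N=1000, p=0.1, T=6,
  everyone tagged); median estimate within 5% of truth.
* N-mixture calibration: 200 simulated surveys at (N=300, p=0.15, T=6);
  95% credible-interval coverage required in [90%, 99%] and median
  relative error of the posterior median below 10%. The calibration fits
  use 2 chains × 500 draws (300 warm-up): slice draws are nearly
  independent, so a thousand retained draws resolve a 95% interval
  adequately once sampler-vs-oracle agreement has been established at
  full settings.
* Sampler-vs-grid agreement: 5 seeded datasets, posterior means of N and
  p within 3 Monte Carlo SEs of the exhaustive grid posterior.
* Least-cost paths: equality (rel. 10⁻¹²) with an exhaustive
  simple-path DFS (exact cost-bound pruning) on 100 seeded 5×5 grids,
  plus exact linearity under resistance scaling and endpoint symmetry.
* Poisson CI limits: match a brute-force bisection on the Poisson tail
  sums to 4 significant digits for counts ≤ 50.

The acceptance script (`scripts/acceptance.py`) re-runs scaled versions of
the stochastic experiments (300 Schnabel replicates, 120 calibration
replicates, 3 oracle datasets, 30 brute-force grids) so the whole
recomputation stays in a few minutes while keeping Monte Carlo error on
the reported summaries small.

## Known limitations

* The constant-p M0 likelihood ignores individual heterogeneity and
  behavioral (trap-shy/trap-happy) responses; with heterogeneous real
  data both estimators are known to be biased low.
* Within-year closure is an approximation for a mobile marine species.
  Strata are subregion-years with monthly occasions; a finer (e.g.
  monthly) stratification would improve closure realism but starve each
  stratum of recaptures, and the within-month occasion granularity such a
  fit would need is not defined by the record model.
* The N marginalization bounds the posterior at N_max; extremely low
  detection (n ≪ N) can hit the bound, which is why the truncation flag
  exists and should be honored.
* Q4 core extraction on a near-constant raster degenerates to "everything
  is core" — the quantile definition, connectivity rule and resistance
  mapping are all configurable precisely because none is canonical.
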