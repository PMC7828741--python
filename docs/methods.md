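# Methods

## Segregation indices

Evenness is the only segregation dimension implemented.  For unit *i* with
group proportions *π_ri* the entropy score is *E_i = Σ_r π_ri log(1/π_ri)*
in natural log, with the limit convention 0·log(1/0) = 0 enforced by an
explicit guard.  The Theil index *H = Σ_i t_i (E − E_i)/(E·T)* is the
population-weighted average shortfall of unit entropy below the metro
entropy *E*; it is 0 when every unit mirrors the metro composition and 1
when no two groups share a unit.  *H* is undefined when the metro hosts a
single group (*E* = 0); this raises a dedicated error rather than
returning a sentinel.

Two city-level summaries are deliberately computed and labelled apart: the
Theil index *H*, and the mean ± SD across units of the normalized local
entropy *e_i = E_i / log r* (a 0–1 diversity score).  Field reports often
quote a per-city "entropy index (mean ± SD)" that can only be a summary of
the local normalized scores, while the index formula defines a single
city-level *H*; emitting both, clearly named, avoids conflating them.
Because it is unstated whether such per-city means are population
weighted, both the unweighted (default) and population-weighted mean/SD of
*e_i* are emitted.

Quartile classification of *e_i* uses linear-interpolation empirical
quartiles; classes ascending are highly_segregated (< Q1), segregated
([Q1, Q2)), integrated ([Q2, Q3)), highly_integrated (≥ Q3).  No
theoretical basis exists for these cut-points; quantiles simply
characterize the distribution.  Identical values collapse to one class
with a warning.

## SES percentiles

Unit SES scores are only ordinal (the population-weighted mean of group
ranks 1–3 in the synthetic cities), so exposure is measured on a
percentile scale that is invariant to monotone rescaling: units are sorted
by score and each gets the population-weighted midpoint percentile
100·(cum_pop_below + pop/2)/T, with score ties sharing their block's
midpoint.  The population-weighted mean percentile is 50 by construction.

## Trajectories and exposure profiles

Journeys are routed by shortest path through the undirected metric street
graph.  Ties between equal-length paths are broken by the
lexicographically smallest node sequence, realized as a Dijkstra pass from
the destination plus a greedy forward walk to the smallest-id neighbor on
a shortest path; this makes routing fully deterministic.

Trajectories are divided into half-open distance bands [k·500, (k+1)·500)
m measured from the origin (band length configurable).  Each band's value
is the length-weighted mean percentile of the units the sub-polyline
crosses; a plain "nearest unit at the midpoint" join is the degenerate
case of the same machinery when an edge lies inside one unit.  Polyline
pieces are assigned by their midpoint; a midpoint on a shared boundary
goes to the smallest unit id (deterministic).  A final partial band
shorter than 50 m is dropped as noise; participants whose journeys end
before band *k* simply drop out of that band (no imputation), so band
sample sizes are non-increasing in distance.

Per SES-of-origin group the profile holds, for each band, the mean and
sample variance (ddof = 1; zero when one participant) across participants
present.  The headline statistic is the signed maximum deviation of the
band means from the group's origin baseline (the mean percentile of the
group's journey-origin units), restricted to bands with at least `min_n`
participants (default 10, a variance guard for sparse tails; ties go to
the smallest band).  The distance reported is the band midpoint
(k + 0.5)·0.5 km, hence odd multiples of 0.25 km.  Two distance notions
circulate for this statistic — the distance at which the maximum is
achieved versus the group's average traveled distance — and the package
reports the former explicitly while average lengths are available from the
trajectory table; neither is asserted to be the other.

No description of the significance test behind published
maximum-difference p-values exists, so the package uses an explicit
permutation test: SES-of-origin labels are permuted across participants B
times, |max diff| recomputed each time (baseline included, since it
depends on the labels), and p = (1 + #{perm ≥ observed})/(B + 1).  With a
continuous statistic this is exact: under label independence
P(p ≤ α) = α on the attainable lattice.

## Origin designs and the crossing/confined contrast

Intercept surveys anchor journeys differently across programs: home-origin
designs route from the participant's home intersection to the interview
point, while on-route designs use the journey's start near the route.
The participant record therefore carries both a journey origin
(`origin_node`/`origin_unit`) and a `home_unit`; SES-of-origin always
comes from the home unit.  The synthetic `crossing` scenario uses the
home-origin design (the two units coincide), while the `confined` scenario
uses the on-route design.  This is what produces the documented contrast:
a gradient-crossing route lets low-SES-origin participants accumulate a
large positive percentile excursion, whereas an insular high-SES route
sampled on-route yields journeys that stay near the route's own percentile
and a strongly attenuated excursion.  Under a city-wide home-origin design
a high-SES-confined route would mechanically *maximize* the excursion of
the few low-SES participants traveling to it, which contradicts how such
programs are actually measured.

## Synthetic cities

Units are 500-m squares on a rows × cols grid.  The SES composition of a
column at relative position *x* ∈ [0, 1] has Dirichlet mean
softmax(g·(1−2x), g·(1−2|x−0.5|), g·(2x−1)) — uniform at gradient strength
g = 0, hard west-low/east-high sorting as g grows — with concentration
`mixing_noise` (default 8, a visibly mixed but sorted city).  Dirichlet
draws use inverse-CDF gamma coupling on common uniforms so compositions
respond monotonically to g under a fixed seed.  Unit populations are
Poisson (default mean 1000, a neighborhood-scale count); integer group
counts come from a deterministic largest-remainder split of the drawn
composition, so counts sum exactly to the unit total.  All randomness runs
through named substreams per (seed, operation), so adding participants
never perturbs unit generation.

The street network is the corner lattice of the grid with Euclidean edge
weights; routes are west–east paths along a central grid line (crossing)
or the longest stretch flanked by dominantly high-SES units (confined,
which errors when no such stretch of two or more columns exists).  Homes
are sampled proportional to unit population; destinations uniformly over
route nodes — true interview-point weights are unknown, so uniformity is a
stand-in, not an inference about any study design.

Raw surveys are emitted in four city dialects whose every value is legal
under the harmonization codebook (different SES codings, category tokens,
birthdate vs. age, cm vs. m heights, per-city variable availability).  The
binary meets-PA-during-program outcome is drawn from a logistic model with
configurable fixed effects and a city random intercept, then encoded as
program minutes (≥ 150 iff positive) so harmonization genuinely recovers
it.  Default effects follow the published multivariable odds ratios (sex
0.90; SES middle 0.94, high 1.21; education 0.92/1.43/1.88) with city SD
1.0, matching the wide between-city prevalence range; descriptive-variable
marginals follow the published per-city frequencies.

What the generator does **not** emulate: real road topology, geocoding or
the four cities' shapes; spatial autocorrelation beyond the single
west–east gradient; route choice behavior (shortest path only); item
nonresponse and misreporting; survey weighting.  Passing tests therefore
demonstrate correctness of the computations and estimator behavior under
a controlled data-generating process, not agreement with any real city's
numbers.

## Harmonization choices

Age uses completed years (floor) at the observation date — the standard
survey convention.  The program-PA classification treats program minutes
as moderate intensity and applies the 150-min threshold to the single
event; frequency-adjusted weekly variants are out of scope.  The safety
Likert splits 1–2 / 3 / 4–5 into unsafe / neither / safe (three output
classes are named in the field, cut-points are not).  Self-rated health
maps 1 → excellent, 2 → good, 3–5 → fair, reconciling the "very good"
questionnaire wording with the excellent/good/fair reporting convention.
Denominators are per-variable complete cases; unavailable variables stay
missing, never imputed.  No multiple-testing correction is applied (raw
p-values are the field's reporting convention).  χ² tests compare
variable × city tables; which pairwise comparisons produced any particular
published p-value column is ambiguous, so that choice is documented rather
than asserted.

## Two-level logistic model

The PA model is outcome ~ sex + SES + education with a city random
intercept u_g ~ N(0, σ²); reference levels are male, low SES and primary
education.  No installed Python package fits this by maximum likelihood,
so the package implements adaptive Gauss–Hermite quadrature (default 21
nodes): each group's nodes are re-centered and re-scaled at the posterior
mode of u_g (found by Newton), which stays accurate when large groups make
the integrand far narrower than fixed nodes — the regime where
non-adaptive quadrature silently plateaus.  Gradients use Fisher's
identity (posterior expectation of the complete-data score); standard
errors come from a central-difference Hessian of that gradient, ORs and
95% CIs are Wald.  σ is optimized with a floor of 1e-4 (a fit at the floor
means "effectively zero"); constant covariate columns are dropped with a
warning; separation or non-convergence raises with diagnostics.  The
σ = 0 limiting case is cross-checked against a plain logistic fit in the
tests.

## Numerical conventions

Planar coordinates in meters throughout (no geodesy; the 500-m bands and
route lengths need only metric geometry).  Proportion sums validated to
1e-9; geometric midpoint-containment tolerance 1e-6 m; oracle agreement
asserted to 1e-12.  Tie-breaks are everywhere lexicographic /
smallest-index.  Seeds derive named substreams via CRC-32 labels and stay
below 2^31.

## Evaluation problem sizes

The self-evaluation harness (`ciclovia.evaluation`, driven by the test
suite and `scripts/acceptance.py`) uses sizes chosen to keep every study
well-powered at desk scale: 100 random 10-unit tables for the Theil
oracle; 100 random graphs of ≤ 12 nodes against exhaustive enumeration;
20 seeds × 500 participants for the planted-span (Δ = 40) recovery and the
crossing/confined attenuation contrast; 500 label-shuffle replicates ×
B = 199 for permutation calibration, pooling the three group tests per
replicate (1500 indicators) so the rejection-rate estimate has SD ≈ 0.006
rather than 0.010; and 200 replicates of 4 cities × 800 participants for
CI coverage of a planted log-OR of 0.7 with city SD 0.3.

## Known limitations

The planted-span construction only reaches spans strictly below 50
percentile points (block-midpoint geometry caps two-block designs at 50).
The confined-route generator requires a contiguous high-SES stretch and
refuses otherwise rather than relaxing the 75% containment contract.  The
permutation test assumes exchangeability of labels given trajectories,
which the label-shuffle null satisfies by construction but real
self-selected participation would not.  With only four groups the random
-intercept SD is weakly identified; fixed-effect coverage is the quantity
validated.
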