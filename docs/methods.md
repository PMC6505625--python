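# Methods

This note records the models and procedures implemented in `mobsent`, the
choices made where a definition left the construction open, and what the
synthetic populations do and do not establish about real data.

## Geometry

All planar work happens in meters in a local spherical azimuthal-equidistant
(AEQD) frame (Earth radius 6,371 km). AEQD preserves distance and bearing
from its origin exactly, and every distance the analyses consume is a
distance *from* a per-user origin (the expected location), so those distances
are exact great-circle values by construction. Ellipsoidal corrections are
orders of magnitude below the ~10 m GPS noise floor of geotagged messages and
are not applied. The projection is singular at the antipode; points within
~6 km of it are rejected. Internal geometry of clusters thousands of km from
the origin is tangentially compressed by the factor sin(c)/c (≈ 14% at
6,000 km); this affects only the shape of remote locales, never their
distance from the origin, and is far below the 100 m locale radius at the
scales involved.

The expected location is the planar mean computed about the coordinate
bounding-box midpoint and mapped back to the sphere; the per-user frame is
then re-centered on it. Whether the gyradius uses planar or great-circle
distances is immaterial at these scales — the test suite holds the
implementation to an independent haversine-RMS oracle within 0.1% on 10 km
trajectories.

## Filtering

Bot accounts are users for whom at least half (inclusive, ≥ 0.5) of messages
contain any of the keywords {pressure, humid, humidity, earthquake, traffic,
coupon}. Matching is on lowercased *tokens*: substring matching would make
'humidity' redundant with 'humid', contradicting the keyword list itself.
Check-ins are recognized by the stable `4sq.com` share-URL marker
(case-insensitive) rather than the variable "I'm at …" phrasing. Check-in
messages keep their positions for all mobility analyses and are excluded only
from happiness scoring. The default activity threshold is 30 messages
(inclusive); the trajectory-shape analyses use "more than 50" (strict) and
the locale analyses "at least 800".

## Trajectory normalization

The inertia tensor is the second-moment matrix of mean-centered coordinates
with equal unit masses (n denominator). "Principal axis points due west"
fixes a line, not a direction; the 180° ambiguity is resolved so that the
user's mode-locale center (fallback: the coordinate median along the axis)
lands at x ≥ 0, which reproduces the home-east / work-west population layout
deterministically. σ_x and σ_y are computed after rotation, before division,
with the population (n) convention, matching the tensor. When the two
eigenvalues tie numerically, any direction is an eigenvector and the solver's
choice is unstable, so the east–west axis is used directly (this also makes
normalization idempotent: a normalized trajectory has an exactly isotropic
tensor). Collinear trajectories (σ_y = 0) have no frame and are excluded
with a logged reason.

Density grid default: x ∈ [−6, 6], y ∈ [−4, 4], 0.1-unit cells;
out-of-extent points are dropped and counted, and the grid renormalizes over
in-extent mass. The corridor half-width defaults to 1 normalized unit — the
published figure it mirrors does not state its width, so this is a package
convention. The isotropy ratio is defined as √(λ_minor/λ_major), equal to
σ_minor/σ_major, which is 1 for circular motion and 0 for collinear; the
source analyses never write it algebraically, so this definition is likewise
a recorded convention.

## Locales

The locale *definition* (≤ 100 m radius, ≥ 10 members, center = member mean,
non-overlapping circles) does not determine an algorithm. The construction
used is deterministic and O(n·k): a chronological leader pass (join the
nearest candidate whose running-mean center is within 100 m, else open one),
at most 20 nearest-center refinement sweeps with mean updates, then greedy
acceptance in descending count (ties: earliest first message) with radius =
maximum member distance, rejecting any candidate whose circle overlaps an
accepted one. Overlap resolution therefore keeps the higher-count locale,
preserving the head of the rank distribution that the Zipf analysis uses.
Every extraction post-asserts the three invariants. Ranks break count ties
by earliest first visit; the Zipf fit is OLS of log₁₀ p on log₁₀ rank over
all pooled (rank, p) points with no rank truncation.

Note a structural bias of event-based locale detection: with the 10-message
acceptance floor, users with few messages have their low-probability locales
censored, which flattens the pooled rank–probability slope. At ~60 messages
per user the fitted slope is ≈ −1.1 against a generating exponent of 1.3; at
~900 messages per user the fit recovers −1.33 ± 0.01. This is why the locale
analyses are run on the heavy-user condition.

## Hedonometer

h_avg(T) = Σ h(wᵢ)fᵢ / Σ fᵢ over lexicon words outside the *open* neutral
band (5−Δh, 5+Δh); Δh = 1, so scores of exactly 4.0 or 6.0 are retained. A
text with no scorable word yields an explicit no-score, never 0. Scoring is
always on pooled bags of words — per-bin, not per-message — and the binned
trends use equal-population bins (stable sort, remainder to the low bins).
The bin representative distance for log fits is the median, robust to the
heavy right tail; bins below the trend's minimum can be excluded from the
fit, since the model is log-linear only beyond the commute-scale dip. The
tokenizer lowercases, extracts lexicon tokens that plain splitting would
destroy (emoticons) longest-match-first, then splits on whitespace and strips
edge punctuation, keeping internal apostrophes.

## Word shifts

Normalized frequencies are taken over the *scorable* words of each text (not
all lexicon words): with that convention the decomposition
Σ_w (h(w) − h_ref)(p_comp − p_ref) = h_comp − h_ref
is an exact algebraic identity under the same neutral-band filter as the
scores themselves, which is the only convention under which per-word
percentages can sum to the printed total difference. A word scoring exactly
h_ref contributes identically zero and is classified "−". Ranking is by
absolute percent contribution, ties alphabetical.

## Synthetic populations

The generator emulates the statistical structure the analyses assume, with
ground truth exposed so every stage has a recovery test.

Per individual: 3–15 locales (home, work at lognormal separation, median
3 km, ln-σ 0.6; satellites Gaussian around home, spread 800 m, minimum
separation 250 m), visitation exactly Zipf with exponent 1.3 carrying 80% of
messages; the remainder scatters uniformly within 3 *structure* gyradii —
the RMS spread of the true locale mixture, used instead of the realized
gyradius to avoid a circular definition. GPS noise is isotropic Gaussian
with σ = 5 m (86.5% of positions inside a 10 m circle — the 2-σ Rayleigh
containment). Message volume is lognormal, median 60 (900 with ln-σ 0.3 in
the heavy-user condition). Local time is UTC plus a per-user offset from
{−8…−5} h; mode-locale messages follow a week-hour cycle peaked at 8–10 am
and 10 pm–midnight with 2–4 am/pm minima, other messages a flatter
evening-weighted cycle.

Travel has two tiers. Ordinary excursions have marginal per-message
probability 0.01 (lognormal distance, median 500 km) but are concentrated in
a 30% traveller subset — i.i.d. per-message trips would give nearly half of
light users an in-sample trip, dragging their estimated centers kilometers
from home and destroying the sub-km near-distance structure that real
populations show. A 10% long-haul subpopulation additionally splits life
between two residences (lognormal separation, median 6,000 km, ln-σ 0.35,
30% of messages at the remote site). This subpopulation is what fills the
far tail: the farthest equal-population distance decile then sits at a
geometric mean of ≈ 2,500 km, matching the corpus the pipeline targets; a
1%-per-message trip model alone cannot populate a 10% decile at that
distance.

Happiness model: each message's words are drawn from a negative-enriched and
a positive-enriched pool of the packaged lexicon so that the expected
filtered score at true distance d equals μ(d), piecewise log-linear with a
shallow plateau below 30 m, a dip h = 5.92 at 10 km, and growth through
μ(2,500 km) = 6.13. The near-side slope is anchored at μ(262 m) = 5.96,
where 262 m is the measured geometric-mean distance of the nearest decile of
the default population — the two anchors (5.96 near, 6.13 far) are the
calibration the generator is specified to satisfy, fixed once at design time.
Word counts per message are 1 + Poisson(6) with 15% neutral filler.

Contamination: 2% of accounts are bots posting keyword feeds from a fixed
point; 5% of non-bot messages are rewritten as `4sq.com` check-ins.
`generate_correlated_pairs` provides the separate city-level model: bivariate
Gaussian pairs with population correlation 0.24 (mean gyradius vs city land
area).

What the generator does *not* emulate: road networks or gravity-model trip
structure, demographic or linguistic heterogeneity, bursty temporal
correlation within trips, message-length or vocabulary realism beyond the
15-word fixture, and spatially autocorrelated neighborhoods (so pipeline
spatial-autocorrelation values on synthetic data sit near the null). Passing
recovery tests therefore establishes correctness of the estimators under the
stated generative assumptions, not fidelity of those assumptions to any real
corpus.

## Problem sizes and determinism

Default study conditions: 3,000 individuals (≈ 160k messages, ≥ 10⁵ scorable
words per distance decile) for the happiness trend; 300 heavy users
(≈ 270k messages) for the locale analyses; 100 replicates × 472 pairs for
correlation recovery; 500 individuals for the normalization contract. A full
test run takes well under a minute on one core. All randomness flows through
a single integer seed per run; identical (config, seed) reproduce corpora
bit-for-bit, and pipeline stage manifests record input/output hashes so
reruns are byte-identical.

## Known limitations

* Locale extraction is greedy; pathological geometries (chains of clusters
  ~150 m apart) can merge or discard borderline candidates that a global
  optimizer would keep. Determinism was preferred over optimality.
* The leader pass is chronological, so the candidate seeding depends on
  message order; the refinement sweeps remove most but not all of that
  dependence.
* Moran's I / Geary's C use dense k-nearest-neighbour weights (k = 8,
  row-standardized) and are intended for the ~10³–10⁴ unit scale of
  per-city mode-location sets, not for millions of units.
* The spatial-weights scheme, corridor half-width, and isotropy-ratio
  definition are package conventions where the mirrored analyses leave the
  choice unstated; all are configurable.
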