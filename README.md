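# mobsent

Mobility and happiness analysis of geolocated message streams.

`mobsent` characterizes the *pattern of life* of people who geotag their
social-media messages, and couples that movement structure to a lexicon-based
measurement of expressed happiness. It is aimed at computational social
scientists and digital epidemiologists who work with event-based location
data (a position is observed only when a person posts) rather than continuous
mobile-phone traces.

## What it computes

For each individual *a* with message positions r₁ … r_N:

* **Expected location** — the center of mass of the trajectory,
  r̄ = (1/N) Σᵢ rᵢ, computed in a local azimuthal-equidistant planar frame.
* **Gyradius** (radius of gyration) — r_g = √[(1/N) Σᵢ ‖rᵢ − r̄‖²], the RMSE
  of predicting every position by the mean position; population CCDF, plus
  Moran's I and Geary's C spatial autocorrelation of per-unit scalars.
* **Normalized trajectory** — translate by r̄, rotate so the principal axis of
  the equal-mass inertia tensor lies east–west with the mode side east,
  rescale by the per-axis standard deviations. Pooled over users this yields
  the population density map, the principal-axis corridor profile, and the
  isotropy ratio √(λ₂/λ₁) by gyradius decile.
* **Locales** — circles of radius ≤ 100 m holding ≥ 10 of a user's messages,
  pairwise non-overlapping, centered on their member mean; visitation
  probabilities pᵢ = countᵢ/N follow an approximate Zipf law p(r) ∝ r^(−s)
  with s ≈ 1.3 for heavy users, fit by OLS on log–log axes. The rank-1 locale
  is the user's *mode location*; week-hour distributions contrast mode-locale
  and other messages.
* **Hedonometer** — a text T scores h_avg(T) = Σᵢ h(wᵢ) fᵢ / Σᵢ fᵢ over
  lexicon words outside the open neutral band (5−Δh, 5+Δh), Δh = 1. Messages
  are pooled into ten equal-population bins by distance from expected location
  (or users by gyradius) and each bin's bag of words is scored once.
* **Word shifts** — the difference h(T_comp) − h(T_ref) decomposes exactly
  into per-word contributions δ(w) = (h(w) − h_ref)(p_comp(w) − p_ref(w)),
  classified ± by score relative to the reference text and ↑/↓ by frequency
  change.

Because no suitable public corpus ships with position *and* text, the package
includes a first-class synthetic-population generator
(`mobsent.synthetic`) with exposed ground truth: home/work locale structure,
Zipf visitation, GPS noise, diurnal cycles, traveller and long-haul
subpopulations, bot and check-in contamination, and a distance-conditional
vocabulary whose expected filtered score μ(d) dips at commute scale and then
grows logarithmically with distance.

## Worked example

```python
import numpy as np
from mobsent import filtering, locales, mobility
from mobsent import hedonometer as hd
from mobsent.lexicon import load_packaged_lexicon
from mobsent.synthetic import PopulationConfig, generate_population

lexicon = load_packaged_lexicon()
corpus, truth = generate_population(PopulationConfig(n_individuals=600), seed=42)
report = filtering.apply_filters(corpus, min_messages=30)

summaries = mobility.summarize_corpus(report.corpus)
profiles = locales.extract_profiles(report.corpus)
fit = locales.fit_zipf(locales.pooled_rank_probabilities(profiles))

dist = mobility.per_message_distances(report.corpus, summaries)
eligible = filtering.sentiment_eligible(report.corpus.frame, set())
trend = hd.happiness_by_distance(
    report.corpus.frame.loc[eligible, "text"].tolist(),
    dist[eligible.to_numpy()].to_numpy(), lexicon)
```

prints (via the obvious `print` statements):

```
600 users generated, 534 survive filtering (12 bots, 1930 check-ins flagged)
median gyradius: 2.42 km
Zipf rank-probability slope: -1.11 (se 0.017)
nearest bin:  d_med =     319 m  h_avg = 5.937
farthest bin: d_med = 2013726 m  h_avg = 6.110
```

Reading the output: two bot accounts per hundred users are removed by the
keyword rule and check-ins are flagged (they stay in the mobility corpus but
are excluded from scoring). The pooled rank–probability slope at ~60 messages
per user is shallower than the generating exponent because locales need 10
messages to be detected — the tail of the rank distribution is censored. The
heavy-user condition (`PopulationConfig.heavy_users(300)`, ~900 messages
each) recovers the −1.3 slope; that is why locale analyses threshold on
highly active users. The nearest distance decile scores ≈ 5.95 and the
farthest (≈ 2000 km) ≈ 6.11: expressed happiness rises logarithmically with
distance from the expected location.

The same analyses are available as a CLI over files on disk:

```sh
mobsent report --corpus corpus.jsonl --out out/ --seed 42 --n-individuals 200
mobsent wordshift --ref out/bin_nearest.counts --comp out/bin_farthest.counts --out out/
```

## Layout

```
src/mobsent/
  corpus.py      message data model + line-delimited JSON / CSV IO
  lexicon.py     happiness lexicon + packaged 15-word fixture
  filtering.py   bot removal, check-in tagging, activity thresholds
  geo.py         spherical azimuthal-equidistant projection
  mobility.py    expected location, gyradius, CCDF, Moran's I / Geary's C
  trajnorm.py    inertia-tensor normalization, density map, corridor, isotropy
  locales.py     locale extraction, Zipf fit, diurnal profiles
  hedonometer.py tokenization, filtered scoring, equal-population binning
  wordshift.py   exact per-word decomposition of happiness differences
  synthetic.py   population generator with ground truth
  pipeline.py    stage orchestration with manifests
  cli.py         click-based command line
```

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
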