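"""Synthetic geolocated-message populations with exposed ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes, so that every stage is testable without any corpus download:

* per-user **home/work locale structure**: a home locale, a work locale at a
  lognormal separation (median 3 km), and satellite locales scattered around
  home; visitation over a user's locales is exactly Zipf (default exponent
  1.3), carrying 80% of messages, the remainder scattered uniformly within
  3 structure-gyradii;
* **GPS noise**: isotropic Gaussian, sigma 5 m, so ~95% of positions fall
  inside a 10 m circle around the sampled point;
* **diurnal cycles**: mode-locale messages concentrate in the morning
  (8-10 am) and late evening (10 pm-midnight) with afternoon/overnight
  minima; other messages follow a flatter evening-weighted cycle; local time
  is UTC plus a per-user fixed offset from {-8,...,-5} hours;
* **travel**: ordinary users take rare long-range excursions; trips are
  concentrated in a 30% "traveller" subset (marginal per-message probability
  0.01, distance lognormal, median 500 km).  A separate long-haul
  subpopulation (default 10%) splits its life between two residences
  thousands of km apart, which is what populates the far tail of the pooled
  distance distribution (the farthest equal-population decile sits near
  2500 km, as in the corpus the pipeline targets);
* **distance-conditional vocabulary**: each message's words are drawn from a
  negative-enriched and a positive-enriched pool of the packaged lexicon,
  mixed so that the expected filtered score of words written at distance d
  from the user's expected location equals mu(d) (see
  :func:`truth_happiness_at`): a shallow maximum close to home, a dip at
  commute scale (10 km), then logarithmic growth calibrated through
  mu = 6.13 at 2500 km;
* **contamination**: bot accounts emitting keyword feeds (2% of users) and
  Foursquare-style check-in messages carrying a ``4sq.com`` marker (5% of
  messages).

All randomness flows through a single integer seed; the same (config, seed)
pair reproduces the corpus exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .geo import unproject_local
from .lexicon import Lexicon, load_packaged_lexicon

__all__ = [
    "PopulationConfig",
    "UserTruth",
    "GroundTruth",
    "generate_population",
    "generate_correlated_pairs",
    "truth_happiness_at",
    "DEFAULT_CITY_CORRELATION",
]

#: correlation between a city's mean gyradius and its land area in the
#: generator's city-level model
DEFAULT_CITY_CORRELATION = 0.24

# hour-of-day sampling weights (relative), index = local hour 0..23
_MODE_HOUR_WEIGHTS = np.array(
    [0.9, 0.7, 0.5, 0.5, 0.6, 0.8, 1.2, 2.0, 3.0, 3.0, 1.6, 1.2,
     1.0, 0.7, 0.4, 0.4, 0.7, 1.0, 1.2, 1.4, 1.6, 1.8, 2.2, 2.2]
)
_OTHER_HOUR_WEIGHTS = np.array(
    [1.0, 0.8, 0.6, 0.5, 0.5, 0.6, 0.8, 1.0, 1.2, 1.2, 1.3, 1.5,
     1.6, 1.5, 1.4, 1.4, 1.5, 1.6, 1.7, 1.7, 1.6, 1.4, 1.2, 1.1]
)


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for a synthetic population.

    Distances are meters; medians of lognormal distributions are true medians
    (sigma parameters are on the natural-log scale).
    """

    n_individuals: int = 3000
    # message volume
    msgs_median: float = 60.0
    msgs_sigma: float = 0.5
    # locale structure
    n_locales_min: int = 3
    n_locales_max: int = 15
    zipf_exponent: float = 1.3
    locale_fraction: float = 0.8
    homework_sep_median_m: float = 3000.0
    homework_sep_sigma: float = 0.6
    satellite_spread_m: float = 800.0
    min_locale_sep_m: float = 250.0
    gps_noise_sigma_m: float = 5.0
    scatter_gyradius_multiple: float = 3.0
    # ordinary travel: marginal per-message excursion probability 0.01,
    # concentrated in a traveller subset so most users keep clean centers
    trip_prob: float = 0.01
    traveller_fraction: float = 0.3
    trip_median_m: float = 500e3
    trip_sigma: float = 0.9
    # long-haul (bi-local) subpopulation
    longhaul_fraction: float = 0.10
    longhaul_sep_median_m: float = 6.0e6
    longhaul_sep_sigma: float = 0.35
    longhaul_visit_frac: float = 0.3
    n_remote_locales: int = 3
    # happiness model mu(d)
    h_dip: float = 5.92
    d_dip_m: float = 10_000.0
    h_near: float = 5.96
    d_near_ref_m: float = 262.0  # calibrated: nearest-decile reference distance
    h_far: float = 6.13
    d_far_ref_m: float = 2.5e6
    d_floor_m: float = 30.0
    # vocabulary
    words_per_msg_mean: float = 7.0
    neutral_word_prob: float = 0.15
    # contamination
    bot_fraction: float = 0.02
    checkin_fraction: float = 0.05
    # local-time offsets, hours
    utc_offsets_h: tuple = (-8, -7, -6, -5)

    def __post_init__(self):
        for name in (
            "locale_fraction",
            "trip_prob",
            "traveller_fraction",
            "longhaul_fraction",
            "longhaul_visit_frac",
            "bot_fraction",
            "checkin_fraction",
            "neutral_word_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if self.n_locales_min < 2 or self.n_locales_max < self.n_locales_min:
            raise ValueError("invalid n_locales range")

    @classmethod
    def heavy_users(cls, n_individuals: int = 300, **overrides) -> "PopulationConfig":
        """The heavy-user study condition: ~900 messages per individual."""
        base = dict(n_individuals=n_individuals, msgs_median=900.0, msgs_sigma=0.3)
        base.update(overrides)
        return cls(**base)


def truth_happiness_at(config: PopulationConfig, d: float) -> float:
    """Expected filtered happiness score mu(d) at distance d (m) from the
    expected location.

    Piecewise log-linear: a shallow plateau below ``d_floor_m``, decline to
    ``h_dip`` at the commute-scale dip ``d_dip_m``, then logarithmic growth
    through (``d_far_ref_m``, ``h_far``).
    """
    d = float(max(d, config.d_floor_m))
    if d <= config.d_dip_m:
        slope = (config.h_near - config.h_dip) / np.log10(
            config.d_dip_m / config.d_near_ref_m
        )
        return config.h_dip + slope * np.log10(config.d_dip_m / d)
    slope = (config.h_far - config.h_dip) / np.log10(config.d_far_ref_m / config.d_dip_m)
    return config.h_dip + slope * np.log10(d / config.d_dip_m)


def _mu_array(config: PopulationConfig, d: np.ndarray) -> np.ndarray:
    return np.array([truth_happiness_at(config, v) for v in d])


@dataclass
class UserTruth:
    user_id: str
    home_latlon: tuple[float, float]
    work_latlon: tuple[float, float] | None
    locale_centers_latlon: list  # ordered by descending true probability
    locale_probs: np.ndarray  # aligned, descending
    structure_gyradius_m: float
    utc_offset_min: int
    is_bot: bool
    is_longhaul: bool
    is_traveller: bool


@dataclass
class GroundTruth:
    users: dict
    zipf_exponent: float
    bot_ids: set
    checkin_ids: set
    config: PopulationConfig

    def mu(self, d: float) -> float:
        return truth_happiness_at(self.config, d)


def _word_pools(lexicon: Lexicon):
    pos_w, pos_h, neg_w, neg_h, neu_w = [], [], [], [], []
    for w, h in lexicon.entries.items():
        if lexicon.is_neutral(w):
            neu_w.append(w)
        elif h >= 5.0:
            pos_w.append(w)
            pos_h.append(h)
        else:
            neg_w.append(w)
            neg_h.append(h)
    return (
        np.array(pos_w),
        float(np.mean(pos_h)),
        np.array(neg_w),
        float(np.mean(neg_h)),
        np.array(neu_w) if neu_w else np.array(["and"]),
    )


def _sample_separated(rng, n, spread, min_sep, anchors):
    """n Gaussian points around the origin, each >= min_sep from all previous
    points and anchors (best effort, 25 tries each)."""
    pts = []
    for _ in range(n):
        for _ in range(25):
            p = rng.normal(0.0, spread, 2)
            others = anchors + pts
            if all(np.hypot(*(p - q)) >= min_sep for q in others):
                break
        pts.append(p)
    return pts


def _week_hours(rng, n, hour_weights):
    """Sample n week-hours (0..167, Monday 00:00 first): uniform day, weighted hour."""
    w = np.tile(hour_weights, 7).astype(float)
    w /= w.sum()
    return rng.choice(168, size=n, p=w)


def _times_utc(rng, week_hour, offset_min):
    base = pd.Timestamp("2011-01-03 00:00:00")  # a Monday, local time
    week = rng.integers(0, 52, size=len(week_hour))
    minute = rng.integers(0, 60, size=len(week_hour))
    second = rng.integers(0, 60, size=len(week_hour))
    local = (
        base.value
        + (week * 7 * 24 * 3600 + week_hour * 3600 + minute * 60 + second) * 10**9
    )
    utc = pd.to_datetime(local - int(offset_min) * 60 * 10**9, utc=True)
    return utc


def _generate_user(rng, config: PopulationConfig, uid: str, lexicon_pools):
    pos_w, pos_mean, neg_w, neg_mean, neu_w = lexicon_pools
    n_msgs = max(5, int(np.round(np.exp(rng.normal(np.log(config.msgs_median), config.msgs_sigma)))))
    offset_min = int(rng.choice(config.utc_offsets_h)) * 60
    is_bot = False  # bots handled separately
    is_longhaul = rng.random() < config.longhaul_fraction
    is_traveller = (not is_longhaul) and rng.random() < config.traveller_fraction

    # home-site locale layout (planar meters about the home locale)
    K = int(rng.integers(config.n_locales_min, config.n_locales_max + 1))
    sep = np.exp(rng.normal(np.log(config.homework_sep_median_m), config.homework_sep_sigma))
    ang = rng.uniform(0, 2 * np.pi)
    home = np.zeros(2)
    work = sep * np.array([np.cos(ang), np.sin(ang)])
    sats = _sample_separated(
        rng, K - 2, config.satellite_spread_m, config.min_locale_sep_m, [home, work]
    )
    centers = [home, work] + sats
    ranks = np.arange(1, K + 1, dtype=float)
    zipf = ranks ** -config.zipf_exponent
    zipf /= zipf.sum()

    # remote site for long-haul users
    remote_centers: list = []
    remote_zipf = np.array([])
    remote_origin = None
    if is_longhaul:
        d_lh = np.exp(
            rng.normal(np.log(config.longhaul_sep_median_m), config.longhaul_sep_sigma)
        )
        ang2 = rng.uniform(0, 2 * np.pi)
        remote_origin = d_lh * np.array([np.cos(ang2), np.sin(ang2)])
        rsats = _sample_separated(
            rng,
            config.n_remote_locales - 1,
            config.satellite_spread_m,
            config.min_locale_sep_m,
            [np.zeros(2)],
        )
        remote_centers = [remote_origin] + [remote_origin + p for p in rsats]
        rranks = np.arange(1, config.n_remote_locales + 1, dtype=float)
        remote_zipf = rranks ** -config.zipf_exponent
        remote_zipf /= remote_zipf.sum()

    # component mixture: trips, then home/remote site, locale vs scatter
    p_trip = (config.trip_prob / max(config.traveller_fraction, 1e-12)) if is_traveller else 0.0
    p_home_site = (1.0 - p_trip) * (1.0 - (config.longhaul_visit_frac if is_longhaul else 0.0))
    p_remote_site = (1.0 - p_trip) * (config.longhaul_visit_frac if is_longhaul else 0.0)

    comp_centers = []
    comp_probs = []
    comp_kind = []  # "locale", "scatter", "trip"
    comp_site = []  # 0 home, 1 remote

    hcent = np.asarray(centers)
    hmean = (zipf[:, None] * hcent).sum(axis=0)
    rg_home = float(np.sqrt((zipf * ((hcent - hmean) ** 2).sum(axis=1)).sum()))
    for c, p in zip(centers, zipf):
        comp_centers.append(c)
        comp_probs.append(p_home_site * config.locale_fraction * p)
        comp_kind.append("locale")
        comp_site.append(0)
    comp_centers.append(hmean)
    comp_probs.append(p_home_site * (1.0 - config.locale_fraction))
    comp_kind.append("scatter")
    comp_site.append(0)

    rg_remote = 0.0
    if is_longhaul:
        rcent = np.asarray(remote_centers)
        rmean = (remote_zipf[:, None] * rcent).sum(axis=0)
        rg_remote = float(
            np.sqrt((remote_zipf * ((rcent - rmean) ** 2).sum(axis=1)).sum())
        )
        rg_remote = max(rg_remote, config.satellite_spread_m)
        for c, p in zip(remote_centers, remote_zipf):
            comp_centers.append(c)
            comp_probs.append(p_remote_site * config.locale_fraction * p)
            comp_kind.append("locale")
            comp_site.append(1)
        comp_centers.append(rmean)
        comp_probs.append(p_remote_site * (1.0 - config.locale_fraction))
        comp_kind.append("scatter")
        comp_site.append(1)

    if p_trip > 0:
        comp_centers.append(home)
        comp_probs.append(p_trip)
        comp_kind.append("trip")
        comp_site.append(0)

    comp_probs = np.asarray(comp_probs)
    comp_probs /= comp_probs.sum()

    # expected position (planar, home frame)
    exp_pos = sum(p * c for p, c in zip(comp_probs, comp_centers))

    idx = rng.choice(len(comp_probs), size=n_msgs, p=comp_probs)
    pos = np.empty((n_msgs, 2))
    rg_struct = max(rg_home, config.satellite_spread_m)
    for j, (c, kind, site) in enumerate(zip(comp_centers, comp_kind, comp_site)):
        sel = idx == j
        m = int(sel.sum())
        if m == 0:
            continue
        if kind == "locale":
            pos[sel] = c + rng.normal(0.0, config.gps_noise_sigma_m, (m, 2))
        elif kind == "scatter":
            rmax = config.scatter_gyradius_multiple * (rg_struct if site == 0 else rg_remote)
            r = rmax * np.sqrt(rng.random(m))
            th = rng.uniform(0, 2 * np.pi, m)
            pos[sel] = c + np.column_stack([r * np.cos(th), r * np.sin(th)])
        else:  # trip
            td = np.exp(rng.normal(np.log(config.trip_median_m), config.trip_sigma, m))
            th = rng.uniform(0, 2 * np.pi, m)
            pos[sel] = c + np.column_stack([td * np.cos(th), td * np.sin(th)])

    d_true = np.hypot(pos[:, 0] - exp_pos[0], pos[:, 1] - exp_pos[1])

    # vocabulary: per-word pool choice so expected filtered score is mu(d)
    n_words = 1 + rng.poisson(max(config.words_per_msg_mean - 1.0, 0.0), n_msgs)
    mu = _mu_array(config, d_true)
    q = np.clip((mu - neg_mean) / (pos_mean - neg_mean), 0.0, 1.0)
    q_word = np.repeat(q, n_words)
    total = int(n_words.sum())
    is_neutral = rng.random(total) < config.neutral_word_prob
    is_pos = rng.random(total) < q_word
    words = np.where(
        is_neutral,
        neu_w[rng.integers(0, len(neu_w), total)],
        np.where(
            is_pos,
            pos_w[rng.integers(0, len(pos_w), total)],
            neg_w[rng.integers(0, len(neg_w), total)],
        ),
    )
    bounds = np.concatenate([[0], np.cumsum(n_words)])
    texts = [" ".join(words[bounds[i] : bounds[i + 1]]) for i in range(n_msgs)]

    # timestamps: mode-locale messages follow the mode diurnal cycle
    is_mode_msg = idx == 0  # component 0 is the home (rank-1) locale
    wh = np.empty(n_msgs, dtype=int)
    wh[is_mode_msg] = _week_hours(rng, int(is_mode_msg.sum()), _MODE_HOUR_WEIGHTS)
    wh[~is_mode_msg] = _week_hours(rng, int((~is_mode_msg).sum()), _OTHER_HOUR_WEIGHTS)
    times = _times_utc(rng, wh, offset_min)

    # place the user's home frame on the globe (continental-US-like band)
    base_lat = rng.uniform(27.0, 47.0)
    base_lon = rng.uniform(-120.0, -75.0)
    lat, lon = unproject_local(pos[:, 0], pos[:, 1], base_lat, base_lon)

    # ground-truth locale list (both sites), descending probability
    truth_centers = []
    truth_probs = []
    for c, p, kind in zip(comp_centers, comp_probs, comp_kind):
        if kind == "locale":
            clat, clon = unproject_local(c[0], c[1], base_lat, base_lon)
            truth_centers.append((float(clat), float(clon)))
            truth_probs.append(float(p))
    order = np.argsort(truth_probs, kind="mergesort")[::-1]
    truth_centers = [truth_centers[i] for i in order]
    truth_probs = np.asarray(truth_probs)[order]

    hlat, hlon = unproject_local(home[0], home[1], base_lat, base_lon)
    wlat, wlon = unproject_local(work[0], work[1], base_lat, base_lon)
    truth = UserTruth(
        user_id=uid,
        home_latlon=(float(hlat), float(hlon)),
        work_latlon=(float(wlat), float(wlon)),
        locale_centers_latlon=truth_centers,
        locale_probs=truth_probs,
        structure_gyradius_m=rg_struct,
        utc_offset_min=offset_min,
        is_bot=False,
        is_longhaul=is_longhaul,
        is_traveller=is_traveller,
    )
    frame = pd.DataFrame(
        {
            "user_id": uid,
            "message_id": [f"{uid}-{i}" for i in range(n_msgs)],
            "time_utc": times,
            "utc_offset_min": offset_min,
            "lat": lat,
            "lon": lon,
            "text": texts,
        }
    )
    return frame, truth


_BOT_TEXTS = (
    "pressure 1013 hPa humidity 78% wind NW",
    "traffic alert: congestion on I-95 northbound",
    "earthquake magnitude 2.1 reported",
    "coupon of the day: 20% off everything",
    "humid conditions expected, humidity rising",
)


def _generate_bot(rng, config: PopulationConfig, uid: str):
    n_msgs = max(5, int(np.round(np.exp(rng.normal(np.log(config.msgs_median), config.msgs_sigma)))))
    offset_min = int(rng.choice(config.utc_offsets_h)) * 60
    base_lat = rng.uniform(27.0, 47.0)
    base_lon = rng.uniform(-120.0, -75.0)
    pos = rng.normal(0.0, config.gps_noise_sigma_m, (n_msgs, 2))
    lat, lon = unproject_local(pos[:, 0], pos[:, 1], base_lat, base_lon)
    texts = [_BOT_TEXTS[int(i)] for i in rng.integers(0, len(_BOT_TEXTS), n_msgs)]
    wh = _week_hours(rng, n_msgs, np.ones(24))
    times = _times_utc(rng, wh, offset_min)
    frame = pd.DataFrame(
        {
            "user_id": uid,
            "message_id": [f"{uid}-{i}" for i in range(n_msgs)],
            "time_utc": times,
            "utc_offset_min": offset_min,
            "lat": lat,
            "lon": lon,
            "text": texts,
        }
    )
    truth = UserTruth(
        user_id=uid,
        home_latlon=(float(base_lat), float(base_lon)),
        work_latlon=None,
        locale_centers_latlon=[(float(base_lat), float(base_lon))],
        locale_probs=np.array([1.0]),
        structure_gyradius_m=0.0,
        utc_offset_min=offset_min,
        is_bot=True,
        is_longhaul=False,
        is_traveller=False,
    )
    return frame, truth


def generate_population(
    config: PopulationConfig, seed: int, lexicon: Lexicon | None = None
) -> tuple[Corpus, GroundTruth]:
    """Generate a synthetic corpus and its ground truth.

    Reproducible: the same (config, seed) yields an identical corpus.
    """
    rng = np.random.default_rng(seed)
    lexicon = lexicon or load_packaged_lexicon()
    pools = _word_pools(lexicon)

    n_bots = int(np.round(config.bot_fraction * config.n_individuals))
    frames = []
    users: dict = {}
    for i in range(config.n_individuals):
        uid = f"u{i:05d}"
        if i < n_bots:
            frame, truth = _generate_bot(rng, config, uid)
        else:
            frame, truth = _generate_user(rng, config, uid, pools)
        frames.append(frame)
        users[uid] = truth

    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["user_id", "message_id", "time_utc", "utc_offset_min", "lat", "lon", "text"]
        )

    checkin_ids: set = set()
    if len(df):
        bot_mask = df["user_id"].map(lambda u: users[u].is_bot)
        chk = (~bot_mask) & (rng.random(len(df)) < config.checkin_fraction)
        suffix = rng.integers(0, 36**6, size=len(df))
        place = rng.choice(["starbucks", "the gym", "the airport", "the office"], size=len(df))
        texts = df["text"].to_numpy(dtype=object)
        for i in np.flatnonzero(chk.to_numpy()):
            texts[i] = f"i'm at {place[i]} http://4sq.com/{suffix[i]:06x}"
        df["text"] = texts
        checkin_ids = set(df.loc[chk.to_numpy(), "message_id"])

    corpus = Corpus(df)
    truth = GroundTruth(
        users=users,
        zipf_exponent=config.zipf_exponent,
        bot_ids={u for u, t in users.items() if t.is_bot},
        checkin_ids=checkin_ids,
        config=config,
    )
    return corpus, truth


def generate_correlated_pairs(
    n: int, rho: float = DEFAULT_CITY_CORRELATION, seed: int = 0
) -> np.ndarray:
    """n bivariate-Gaussian pairs with population correlation rho.

    Emulates city-level (mean gyradius, land area) tables for
    correlation-recovery experiments.  Returns an (n, 2) array.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = rho * x + np.sqrt(1.0 - rho**2) * z
    return np.column_stack([x, y])
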