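"""Tweet locales: recurrent sub-100 m message clusters, their rank structure,
the Zipf rank-probability fit, and the diurnal mode-location cycle.

A *locale* is a circle of radius <= 100 m containing at least 10 of one
user's messages, centered on the mean position of its members, with the
circles of a user's distinct locales pairwise non-overlapping.  The rank-1
(most-visited) locale is the user's *mode location*.  Locale visitation
probabilities p_i = count_i / N need not sum to one: messages can fall
outside every locale.

The definition fixes the object but not its construction; the deterministic
procedure used here is:

1. **Leader pass** (chronological): each message joins the nearest existing
   candidate whose running-mean center is within ``radius_max``, updating
   that center, or opens a new candidate.
2. **Refinement**: repeat { reassign every message to its nearest candidate
   center if within ``radius_max``; recompute centers as member means } until
   assignments are stable or 20 iterations.
3. **Greedy acceptance** in descending count (ties: earliest first message):
   the circle radius is the maximum member distance; a candidate is accepted
   iff count >= ``min_count`` and its circle overlaps no accepted circle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import Corpus
from .geo import project_local, unproject_local
from .mobility import TrajectorySummary, trajectory_summary

logger = logging.getLogger(__name__)

__all__ = [
    "Locale",
    "LocaleProfile",
    "extract_locales",
    "locale_probabilities",
    "extract_profiles",
    "mode_location",
    "pooled_rank_probabilities",
    "fit_zipf",
    "diurnal_profiles",
]

MAX_REFINE_ITERATIONS = 20


@dataclass
class Locale:
    center_lat: float
    center_lon: float
    radius_m: float
    member_ids: np.ndarray
    count: int
    first_time: pd.Timestamp
    rank: int | None = None


@dataclass
class LocaleProfile:
    """One user's ranked locales with visitation probabilities."""

    user_id: str
    n_messages: int
    locales: list[Locale] = field(default_factory=list)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([loc.count / self.n_messages for loc in self.locales])

    @property
    def mode(self) -> Locale | None:
        return self.locales[0] if self.locales else None


def _leader_pass(xy: np.ndarray, radius_max: float):
    """Chronological single pass; returns candidate centers and assignments."""
    centers: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    counts: list[int] = []
    assign = np.empty(len(xy), dtype=int)
    for i, p in enumerate(xy):
        if centers:
            c = np.asarray(centers)
            d = np.hypot(c[:, 0] - p[0], c[:, 1] - p[1])
            j = int(np.argmin(d))
            if d[j] <= radius_max:
                sums[j] += p
                counts[j] += 1
                centers[j] = sums[j] / counts[j]
                assign[i] = j
                continue
        centers.append(p.astype(float).copy())
        sums.append(p.astype(float).copy())
        counts.append(1)
        assign[i] = len(centers) - 1
    return np.asarray(centers), assign


def _refine(xy: np.ndarray, centers: np.ndarray, radius_max: float):
    """Nearest-center reassignment with mean updates until stable."""
    assign = np.full(len(xy), -1, dtype=int)
    for _ in range(MAX_REFINE_ITERATIONS):
        d = np.hypot(
            xy[:, 0][:, None] - centers[None, :, 0],
            xy[:, 1][:, None] - centers[None, :, 1],
        )
        nearest = np.argmin(d, axis=1)
        within = d[np.arange(len(xy)), nearest] <= radius_max
        new_assign = np.where(within, nearest, -1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        keep = []
        new_centers = []
        for j in range(len(centers)):
            members = xy[assign == j]
            if len(members):
                keep.append(j)
                new_centers.append(members.mean(axis=0))
        if not new_centers:
            return np.empty((0, 2)), assign
        remap = {j: k for k, j in enumerate(keep)}
        assign = np.array([remap.get(a, -1) for a in assign])
        centers = np.asarray(new_centers)
    return centers, assign


def extract_locales(
    user_frame: pd.DataFrame,
    radius_max: float = 100.0,
    min_count: int = 10,
    summary: TrajectorySummary | None = None,
) -> list[Locale]:
    """Extract the locales of one user's (time-sorted) messages.

    Deterministic: identical input order gives identical output.  Returns
    accepted locales (possibly empty), unranked.
    """
    if len(user_frame) == 0:
        return []
    if summary is None:
        summary = trajectory_summary(user_frame)
    x, y = project_local(
        user_frame["lat"].to_numpy(float),
        user_frame["lon"].to_numpy(float),
        summary.expected_lat,
        summary.expected_lon,
    )
    xy = np.column_stack([x, y])
    times = user_frame["time_utc"].to_numpy()
    ids = user_frame["message_id"].to_numpy()

    centers, _ = _leader_pass(xy, radius_max)
    centers, assign = _refine(xy, centers, radius_max)
    if centers.size == 0:
        return []

    # candidate bookkeeping
    cand = []
    for j in range(len(centers)):
        members = np.flatnonzero(assign == j)
        if len(members) == 0:
            continue
        d = np.hypot(xy[members, 0] - centers[j, 0], xy[members, 1] - centers[j, 1])
        cand.append(
            {
                "center": centers[j],
                "members": members,
                "count": len(members),
                "radius": float(d.max()),
                "first_time": times[members].min(),
            }
        )
    cand.sort(key=lambda c: (-c["count"], c["first_time"]))

    accepted: list[dict] = []
    for c in cand:
        if c["count"] < min_count:
            continue  # sorted by count: all later candidates also fail
        ok = True
        for a in accepted:
            gap = float(np.hypot(*(c["center"] - a["center"])))
            if gap < c["radius"] + a["radius"]:
                ok = False
                break
        if ok:
            accepted.append(c)

    out = []
    for c in accepted:
        clat, clon = unproject_local(
            c["center"][0], c["center"][1], summary.expected_lat, summary.expected_lon
        )
        out.append(
            Locale(
                center_lat=float(clat),
                center_lon=float(clon),
                radius_m=c["radius"],
                member_ids=ids[c["members"]],
                count=c["count"],
                first_time=pd.Timestamp(c["first_time"]),
            )
        )
    _assert_invariants(out, radius_max, min_count, summary)
    return out


def _assert_invariants(locales, radius_max, min_count, summary):
    for loc in locales:
        assert loc.radius_m <= radius_max + 1e-6
        assert loc.count >= min_count
    for i, a in enumerate(locales):
        ax, ay = project_local(a.center_lat, a.center_lon, summary.expected_lat, summary.expected_lon)
        for b in locales[i + 1 :]:
            bx, by = project_local(b.center_lat, b.center_lon, summary.expected_lat, summary.expected_lon)
            gap = float(np.hypot(ax - bx, ay - by))
            assert gap + 1e-6 >= a.radius_m + b.radius_m, "locale circles overlap"


def locale_probabilities(
    locales: list[Locale], n_messages: int, user_id: str = ""
) -> LocaleProfile:
    """Rank locales (count desc, ties by earliest first visit) and attach p_i = count/N."""
    if n_messages <= 0:
        raise ValueError("n_messages must be positive")
    total = sum(loc.count for loc in locales)
    if total > n_messages:
        raise ValueError("locale membership exceeds message count")
    ranked = sorted(locales, key=lambda loc: (-loc.count, loc.first_time))
    for r, loc in enumerate(ranked, start=1):
        loc.rank = r
    return LocaleProfile(user_id=user_id, n_messages=n_messages, locales=ranked)


def extract_profiles(
    corpus: Corpus,
    radius_max: float = 100.0,
    min_count: int = 10,
    summaries: dict[str, TrajectorySummary] | None = None,
) -> dict[str, LocaleProfile]:
    out = {}
    for uid, g in corpus.iter_users():
        s = summaries.get(uid) if summaries else None
        locs = extract_locales(g, radius_max, min_count, summary=s)
        out[uid] = locale_probabilities(locs, len(g), user_id=uid)
    return out


def mode_location(profile: LocaleProfile) -> tuple[float, float] | None:
    """Center of the rank-1 locale, or None if the user has no locales."""
    if not profile.locales:
        return None
    top = profile.locales[0]
    return (top.center_lat, top.center_lon)


def pooled_rank_probabilities(profiles: dict[str, LocaleProfile]) -> pd.DataFrame:
    """All (user, rank, probability) points pooled over users."""
    rows = []
    for uid, prof in profiles.items():
        for loc in prof.locales:
            rows.append(
                {"user_id": uid, "rank": loc.rank, "probability": loc.count / prof.n_messages}
            )
    return pd.DataFrame(rows, columns=["user_id", "rank", "probability"])


def fit_zipf(rank_prob: pd.DataFrame):
    """OLS of log10 probability on log10 rank over pooled locale points.

    Returns a statsmodels results object; the Zipf slope is ``res.params[1]``
    (about -1.3 for locale visitation).
    """
    usable = rank_prob[(rank_prob["rank"] >= 1) & (rank_prob["probability"] > 0)]
    if usable["rank"].nunique() < 2:
        raise ValueError("need >= 2 distinct ranks with positive probability")
    X = sm.add_constant(np.log10(usable["rank"].to_numpy(float)))
    return sm.OLS(np.log10(usable["probability"].to_numpy(float)), X).fit()


def diurnal_profiles(
    corpus: Corpus, profiles: dict[str, LocaleProfile]
) -> pd.DataFrame:
    """Week-hour distributions of mode-locale vs other messages.

    Messages lacking a local-time offset are excluded.  Bins are the 168
    hours of the week, Monday 00:00 first.  Each returned curve sums to 1;
    a curve with no eligible messages is all-NaN.
    """
    mode_ids: set = set()
    users_with_mode = set()
    for uid, prof in profiles.items():
        if prof.mode is not None:
            users_with_mode.add(uid)
            mode_ids.update(prof.mode.member_ids.tolist())

    df = corpus.frame
    eligible = df["utc_offset_min"].notna() & df["user_id"].isin(users_with_mode)
    sub = df[eligible]
    local = sub["time_utc"] + pd.to_timedelta(sub["utc_offset_min"], unit="m")
    week_hour = local.dt.dayofweek * 24 + local.dt.hour
    is_mode = sub["message_id"].isin(mode_ids)

    out = pd.DataFrame({"week_hour": np.arange(168)})
    for name, mask in (("mode", is_mode), ("other", ~is_mode)):
        counts = week_hour[mask].value_counts().reindex(np.arange(168), fill_value=0)
        total = counts.sum()
        out[name] = counts.to_numpy() / total if total > 0 else np.nan
    return out
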