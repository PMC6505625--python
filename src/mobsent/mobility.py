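"""Per-user mobility summaries and population-level spatial statistics.

The central quantities:

* **expected location** — the center of mass of a user's message positions
  (planar mean in a local projection, mapped back to lat/lon);
* **gyradius** (radius of gyration) — the RMS distance of the user's messages
  from their expected location,  r_g = sqrt( (1/N) sum_i d_i^2 );  equivalently
  the RMSE of predicting every position by the mean position;
* the population **CCDF** of gyradii;
* global **Moran's I** and **Geary's C** spatial autocorrelation of a scalar
  (e.g. gyradius at mode location) over planar coordinates, with
  row-standardized k-nearest-neighbour weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .corpus import Corpus
from .geo import project_local, unproject_local

__all__ = [
    "TrajectorySummary",
    "expected_location",
    "gyradius",
    "trajectory_summary",
    "summarize_corpus",
    "per_message_distances",
    "gyradius_ccdf",
    "knn_weights",
    "morans_i",
    "gearys_c",
]


@dataclass
class TrajectorySummary:
    """One user's mobility profile."""

    user_id: str
    n: int
    expected_lat: float
    expected_lon: float
    gyradius_m: float
    distances_m: np.ndarray  # per-message, in corpus row order for this user
    message_ids: np.ndarray


def _planar_about_midpoint(lat: np.ndarray, lon: np.ndarray):
    """Project about the coordinate-wise midpoint of the bounding box."""
    olat = (lat.min() + lat.max()) / 2.0
    olon = (lon.min() + lon.max()) / 2.0
    x, y = project_local(lat, lon, olat, olon)
    return x, y, olat, olon


def expected_location(lat, lon) -> tuple[float, float]:
    """Center of mass of positions: planar mean mapped back to lat/lon degrees."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lat.size == 0:
        raise ValueError("expected_location requires at least one position")
    x, y, olat, olon = _planar_about_midpoint(lat, lon)
    elat, elon = unproject_local(x.mean(), y.mean(), olat, olon)
    return float(elat), float(elon)


def gyradius(lat, lon) -> float:
    """RMS distance (m) of positions from their center of mass."""
    return trajectory_summary_from_positions("", lat, lon).gyradius_m


def trajectory_summary_from_positions(
    user_id: str, lat, lon, message_ids=None
) -> TrajectorySummary:
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lat.size == 0:
        raise ValueError("trajectory requires at least one position")
    elat, elon = expected_location(lat, lon)
    # AEQD about the expected location: planar distance from origin is exact
    x, y = project_local(lat, lon, elat, elon)
    d = np.hypot(x, y)
    rg = float(np.sqrt(np.mean(d**2)))
    if message_ids is None:
        message_ids = np.arange(lat.size)
    return TrajectorySummary(
        user_id=user_id,
        n=int(lat.size),
        expected_lat=elat,
        expected_lon=elon,
        gyradius_m=rg,
        distances_m=d,
        message_ids=np.asarray(message_ids),
    )


def trajectory_summary(user_frame: pd.DataFrame) -> TrajectorySummary:
    """Mobility summary for one user's messages (a corpus sub-frame)."""
    uid = user_frame["user_id"].iloc[0] if len(user_frame) else ""
    return trajectory_summary_from_positions(
        uid,
        user_frame["lat"].to_numpy(),
        user_frame["lon"].to_numpy(),
        user_frame["message_id"].to_numpy(),
    )


def summarize_corpus(corpus: Corpus) -> dict[str, TrajectorySummary]:
    """TrajectorySummary per user."""
    return {uid: trajectory_summary(g) for uid, g in corpus.iter_users()}


def per_message_distances(corpus: Corpus, summaries: dict[str, TrajectorySummary]) -> pd.Series:
    """Distance from expected location for every message, aligned to corpus rows."""
    dist = pd.Series(np.nan, index=corpus.frame.index)
    for uid, g in corpus.iter_users():
        s = summaries[uid]
        dist.loc[g.index] = s.distances_m
    return dist


def summaries_frame(summaries: dict[str, TrajectorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "user_id": s.user_id,
                "n": s.n,
                "expected_lat": s.expected_lat,
                "expected_lon": s.expected_lon,
                "gyradius_m": s.gyradius_m,
            }
            for s in summaries.values()
        ]
    )


def gyradius_ccdf(values) -> pd.DataFrame:
    """Complementary CDF: for each distinct value v, the fraction of values >= v.

    Monotone non-increasing; starts at 1 for the minimum, ends at (#ties at
    max)/n at the maximum.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("gyradius_ccdf requires at least one value")
    uniq = np.unique(v)
    # count of values >= u via searchsorted on the ascending sort
    frac = (v.size - np.searchsorted(v, uniq, side="left")) / v.size
    return pd.DataFrame({"value": uniq, "ccdf": frac})


# -- spatial autocorrelation ----------------------------------------------


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix (dense, n x n)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        k = n - 1
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in np.atleast_1d(idx[i]) if j != i][:k]
        w[i, neigh] = 1.0 / len(neigh)
    return w


def _check_values(values: np.ndarray):
    if values.size < 3:
        raise ValueError("need at least 3 units")
    if np.allclose(values, values[0]):
        raise ValueError("values are constant: autocorrelation undefined")


def morans_i(values, coords, k: int = 8, weights: np.ndarray | None = None) -> float:
    """Global Moran's I with row-standardized kNN weights.

    Expectation under no spatial autocorrelation is -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    _check_values(x)
    w = knn_weights(coords, k) if weights is None else np.asarray(weights, dtype=float)
    z = x - x.mean()
    s0 = w.sum()
    return float(len(x) / s0 * (z @ w @ z) / (z @ z))


def gearys_c(values, coords, k: int = 8, weights: np.ndarray | None = None) -> float:
    """Geary's C with row-standardized kNN weights; null expectation 1."""
    x = np.asarray(values, dtype=float)
    _check_values(x)
    w = knn_weights(coords, k) if weights is None else np.asarray(weights, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = w.sum()
    diff2 = (x[:, None] - x[None, :]) ** 2
    return float((n - 1) / (2.0 * s0) * (w * diff2).sum() / (z @ z))
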