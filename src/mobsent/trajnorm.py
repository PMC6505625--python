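"""Trajectory normalization into a common intrinsic reference frame.

Each user's message positions are (1) translated so their expected location is
the origin, (2) rotated so the principal axis of the trajectory's inertia
tensor (equal unit mass at every message position) lies along the x-axis with
the user's mode side pointing east (+x), and (3) rescaled by the per-axis
standard deviations sigma_x, sigma_y computed after rotation (population
convention, n denominator).  The result is dimensionless and directly
poolable across users, which is what the population density map, the
principal-axis corridor profile and the isotropy-ratio statistics consume.

The principal axis fixes a line, not a direction: the 180-degree ambiguity is
resolved so that the user's mode location (rank-1 locale center; fallback the
coordinate median along the axis) has x >= 0.  Users whose trajectory is
perfectly collinear (sigma_y = 0) have no well-defined frame and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import project_local
from .hedonometer import equal_count_bins
from .mobility import TrajectorySummary

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateTrajectoryError",
    "NormalizedTrajectory",
    "DensityGrid",
    "inertia_tensor",
    "normalize_trajectory",
    "normalize_population",
    "density_map",
    "corridor_profile",
    "isotropy_ratio",
    "isotropy_by_gyradius",
]


class DegenerateTrajectoryError(ValueError):
    """Trajectory has no well-defined normalized frame (e.g. collinear points)."""


@dataclass
class NormalizedTrajectory:
    points: np.ndarray  # (n, 2) dimensionless (x/sigma_x, y/sigma_y)
    sigma_x: float  # meters, along the principal axis
    sigma_y: float  # meters, orthogonal
    principal_axis_bearing: float  # degrees clockwise from north, in [0, 180)
    orientation_flip: bool  # True if the 180-degree flip was applied
    eigenvalues: tuple[float, float]  # descending
    mode_x: float | None = None  # mode location along x, normalized units


@dataclass
class DensityGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    prob: np.ndarray  # shape (len(x_edges)-1, len(y_edges)-1), sums to 1
    n_dropped: int  # points outside the grid extent

    def to_frame(self) -> pd.DataFrame:
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "prob": self.prob.ravel()}
        )


def inertia_tensor(xy: np.ndarray) -> np.ndarray:
    """Second-moment matrix of mean-centered coordinates with equal unit masses.

    Returns the 2x2 symmetric positive-semidefinite matrix
    (1/n) sum_i c_i c_i^T with c_i the centered coordinates.  Requires at
    least 2 distinct points (otherwise no axis is defined).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    if len(np.unique(xy, axis=0)) < 2:
        raise DegenerateTrajectoryError("need >= 2 distinct points for an inertia tensor")
    c = xy - xy.mean(axis=0)
    return (c.T @ c) / len(c)


def _principal_axis(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues descending, principal eigenvector)."""
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    if np.isclose(evals[0], evals[1]):
        # tie: every direction is (numerically) an eigenvector, and eigh's
        # choice is unstable; the east-west axis is the closest valid one
        logger.info("inertia eigenvalue tie; using the east-west axis")
        e1 = np.array([1.0, 0.0])
    else:
        e1 = evecs[:, 0]
    return evals, e1


def normalize_trajectory(
    user_frame_or_xy,
    summary: TrajectorySummary | None = None,
    mode_location: tuple[float, float] | None = None,
) -> NormalizedTrajectory:
    """Normalize one user's trajectory.

    Parameters
    ----------
    user_frame_or_xy : DataFrame with lat/lon columns, or (n, 2) planar meters
        Raw positions.  A DataFrame is projected about the user's expected
        location.
    summary : optional TrajectorySummary
        Reused for the projection origin when given.
    mode_location : optional (lat, lon)
        The user's mode (rank-1 locale) center, used to resolve the
        180-degree orientation ambiguity; falls back to the coordinate
        median along the principal axis.
    """
    mode_xy = None
    if isinstance(user_frame_or_xy, pd.DataFrame):
        lat = user_frame_or_xy["lat"].to_numpy(dtype=float)
        lon = user_frame_or_xy["lon"].to_numpy(dtype=float)
        if summary is None:
            from .mobility import trajectory_summary

            summary = trajectory_summary(user_frame_or_xy)
        x, y = project_local(lat, lon, summary.expected_lat, summary.expected_lon)
        xy = np.column_stack([x, y])
        if mode_location is not None:
            mx, my = project_local(
                mode_location[0], mode_location[1], summary.expected_lat, summary.expected_lon
            )
            mode_xy = np.array([float(mx), float(my)])
    else:
        xy = np.asarray(user_frame_or_xy, dtype=float)
        if mode_location is not None:
            mode_xy = np.asarray(mode_location, dtype=float)

    center = xy.mean(axis=0)
    xy = xy - center  # exact planar centering
    tensor = inertia_tensor(xy)
    evals, e1 = _principal_axis(tensor)

    # rotation sending the principal axis to the x-axis
    theta = np.arctan2(e1[1], e1[0])
    rot = np.array(
        [[np.cos(-theta), -np.sin(-theta)], [np.sin(-theta), np.cos(-theta)]]
    )
    pts = xy @ rot.T
    if mode_xy is not None:
        mode_r = rot @ (mode_xy - center)
        mode_x = float(mode_r[0])
    else:
        mode_x = float(np.median(pts[:, 0]))

    flip = mode_x < 0.0
    if flip:
        pts = -pts  # 180-degree rotation keeps orientation (no reflection)
        mode_x = -mode_x

    sigma_x = float(pts[:, 0].std())  # population (n) convention
    sigma_y = float(pts[:, 1].std())
    if sigma_y <= 0.0 or sigma_x <= 0.0:
        raise DegenerateTrajectoryError("collinear trajectory: sigma is zero after rotation")
    out = pts / np.array([sigma_x, sigma_y])

    bearing = float(np.degrees(np.arctan2(e1[0], e1[1])) % 180.0)
    return NormalizedTrajectory(
        points=out,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        principal_axis_bearing=bearing,
        orientation_flip=bool(flip),
        eigenvalues=(float(evals[0]), float(evals[1])),
        mode_x=(mode_x / sigma_x) if mode_xy is not None else None,
    )


def normalize_population(
    corpus,
    summaries: dict[str, TrajectorySummary],
    mode_locations: dict[str, tuple[float, float]] | None = None,
    min_locations: int = 50,
    strict: bool = True,
) -> dict[str, NormalizedTrajectory]:
    """Normalize every eligible user; degenerate users are skipped and logged.

    Eligibility follows the trajectory-shape threshold: more than
    ``min_locations`` messages (strict) by default.
    """
    out: dict[str, NormalizedTrajectory] = {}
    mode_locations = mode_locations or {}
    for uid, g in corpus.iter_users():
        n = len(g)
        too_few = n <= min_locations if strict else n < min_locations
        if too_few:
            continue
        try:
            out[uid] = normalize_trajectory(
                g, summaries.get(uid), mode_locations.get(uid)
            )
        except DegenerateTrajectoryError as exc:
            logger.info("excluding user from normalization: %s", exc)
    return out


def density_map(
    points: np.ndarray,
    x_range: tuple[float, float] = (-6.0, 6.0),
    y_range: tuple[float, float] = (-4.0, 4.0),
    cell: float = 0.1,
) -> DensityGrid:
    """Probability density grid of pooled normalized positions; mass sums to 1."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("density_map requires at least one point")
    x_edges = np.arange(x_range[0], x_range[1] + cell / 2, cell)
    y_edges = np.arange(y_range[0], y_range[1] + cell / 2, cell)
    h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    total = h.sum()
    if total == 0:
        raise ValueError("no points fall inside the grid extent")
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        prob=h / total,
        n_dropped=int(len(pts) - total),
    )


def corridor_profile(
    points: np.ndarray,
    half_width: float = 1.0,
    x_range: tuple[float, float] = (-6.0, 6.0),
    cell: float = 0.1,
) -> pd.DataFrame:
    """Histogram over x/sigma_x of points inside the principal-axis corridor
    |y/sigma_y| <= half_width, normalized to total mass 1."""
    pts = np.asarray(points, dtype=float)
    sel = pts[np.abs(pts[:, 1]) <= half_width]
    if len(sel) == 0:
        raise ValueError("no points inside the corridor")
    edges = np.arange(x_range[0], x_range[1] + cell / 2, cell)
    h, _ = np.histogram(sel[:, 0], bins=edges)
    if h.sum() == 0:
        raise ValueError("no corridor points inside the x extent")
    return pd.DataFrame(
        {
            "x_left": edges[:-1],
            "x_right": edges[1:],
            "prob": h / h.sum(),
        }
    )


def isotropy_ratio(norm: NormalizedTrajectory) -> float:
    """sqrt(minor / major inertia eigenvalue), in (0, 1]; 1 = circular, 0 = collinear."""
    major, minor = norm.eigenvalues
    if major <= 0:
        raise DegenerateTrajectoryError("degenerate inertia tensor")
    return float(np.sqrt(max(minor, 0.0) / major))


def isotropy_by_gyradius(
    norms: dict[str, NormalizedTrajectory],
    summaries: dict[str, TrajectorySummary],
    k: int = 10,
) -> pd.DataFrame:
    """Mean isotropy ratio (with standard error) per gyradius decile."""
    uids = [u for u in norms if u in summaries]
    rg = np.array([summaries[u].gyradius_m for u in uids])
    ratio = np.array([isotropy_ratio(norms[u]) for u in uids])
    bins = equal_count_bins(rg, k, ids=uids)
    rows = []
    for b in range(k):
        sel = bins == b
        vals = ratio[sel]
        rows.append(
            {
                "decile": b + 1,
                "n_users": int(sel.sum()),
                "gyradius_median_m": float(np.median(rg[sel])),
                "isotropy_mean": float(vals.mean()),
                "isotropy_se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
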