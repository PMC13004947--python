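"""Cluster detection from trajectory mean positions, with matched controls.

RNAPII clusters appear in single-molecule data as local accumulations of
trajectories. Each trajectory is reduced to its mean position; clusters are
found by density-based clustering (DBSCAN, eps = 0.2 µm, at least 15
points), and per-cluster kinetics are compared against the rest of the
nucleoplasm and against randomly placed control spots of matched size that
overlap neither clusters nor each other and stay within the nuclear mask.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .decomposition import Measurement, fold_change

__all__ = [
    "TrajCluster",
    "ControlSpot",
    "mean_positions",
    "density_cluster",
    "eps_elbow_scan",
    "filter_hlb_like",
    "place_control_spots",
    "inside_outside_kinetics",
]

DEFAULT_EPS = 0.2          # µm, DBSCAN neighborhood radius
DEFAULT_MIN_SAMPLES = 15   # minimum points to seed a cluster
CONTROLS_PER_CLUSTER = 30


@dataclasses.dataclass
class TrajCluster:
    member_ids: np.ndarray     # trajectory ids
    centroid: np.ndarray       # (x, y) µm
    radius: float              # max member distance to centroid, µm
    nucleus_id: int | str | None = None

    @property
    def n_members(self) -> int:
        return self.member_ids.size


@dataclasses.dataclass(frozen=True)
class ControlSpot:
    center: tuple
    radius: float
    nucleus_id: int | str | None = None


def mean_positions(trajectories: pd.DataFrame) -> pd.DataFrame:
    """One (x̄, ȳ) per trajectory from a long localization table."""
    if len(trajectories) == 0:
        raise ValueError("empty trajectory table")
    g = trajectories.groupby("trajectory")[["x", "y"]].mean()
    g.index.name = "trajectory"
    return g


def density_cluster(points: pd.DataFrame, eps: float = DEFAULT_EPS,
                    min_samples: int = DEFAULT_MIN_SAMPLES,
                    nucleus_id=None):
    """DBSCAN on trajectory mean positions.

    A core point has at least ``min_samples`` neighbors within ``eps``
    (itself included); clusters are connected components of core points plus
    any border points within ``eps`` of a core. Returns
    ``(clusters, labels)`` where ``labels`` is a Series indexed like
    ``points`` with -1 for noise.
    """
    xy = points[["x", "y"]].to_numpy(float)
    if xy.shape[0] == 0:
        return [], pd.Series([], dtype=int, name="cluster")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        members = points.index.to_numpy()[sel]
        centroid = xy[sel].mean(axis=0)
        radius = float(np.max(np.linalg.norm(xy[sel] - centroid, axis=1)))
        clusters.append(TrajCluster(member_ids=members, centroid=centroid,
                                    radius=radius, nucleus_id=nucleus_id))
    return clusters, pd.Series(labels, index=points.index, name="cluster")


def eps_elbow_scan(points: pd.DataFrame, eps_values,
                   min_samples: int = DEFAULT_MIN_SAMPLES) -> pd.DataFrame:
    """Cluster count as a function of the DBSCAN eps, for elbow plotting.

    No automatic knee selection is done; the table is meant for visual
    inspection.
    """
    eps_values = np.asarray(list(eps_values), float)
    if np.any(np.diff(eps_values) <= 0):
        raise ValueError("eps_values must be strictly increasing")
    counts = []
    for eps in eps_values:
        clusters, _ = density_cluster(points, eps=eps, min_samples=min_samples)
        counts.append(len(clusters))
    return pd.DataFrame({"eps": eps_values, "n_clusters": counts})


def filter_hlb_like(clusters, count_percentile: float = 95.0,
                    radius_percentile: float = 95.0):
    """Drop clusters that are unusually large AND unusually populous.

    Histone locus bodies and random dense accumulations stand out from
    ordinary clusters by both member count and spatial extent; a cluster is
    removed when it exceeds the given percentile of member count and of
    radius among the clusters of its nucleus. Returns ``(kept, dropped)``.
    """
    if len(clusters) < 2:
        return list(clusters), []
    counts = np.array([c.n_members for c in clusters], float)
    radii = np.array([c.radius for c in clusters], float)
    c_cut = np.percentile(counts, count_percentile)
    r_cut = np.percentile(radii, radius_percentile)
    kept, dropped = [], []
    for c in clusters:
        (dropped if (c.n_members > c_cut and c.radius > r_cut) else kept).append(c)
    return kept, dropped


def place_control_spots(clusters, nucleus_center, nucleus_radius,
                        n_per_cluster: int = CONTROLS_PER_CLUSTER,
                        seed=None, max_attempts: int = 10000):
    """Random size-matched control spots satisfying all placement criteria.

    For every detected cluster, ``n_per_cluster`` spots with the cluster's
    effective radius are rejection-sampled inside the circular nuclear mask
    such that each spot (i) does not overlap any cluster, (ii) does not
    overlap any other control spot, and (iii) lies entirely within the mask.
    On placement failure after ``max_attempts`` draws a partial list is
    returned with a warning.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(nucleus_center, float)
    spots: list[ControlSpot] = []
    cluster_xy = np.array([c.centroid for c in clusters], float).reshape(-1, 2)
    cluster_r = np.array([c.radius for c in clusters], float)
    for cluster in clusters:
        r = cluster.radius
        placed = 0
        attempts = 0
        while placed < n_per_cluster and attempts < max_attempts:
            attempts += 1
            # uniform point in the disc where the whole spot fits
            rho = (nucleus_radius - r) * np.sqrt(rng.random())
            theta = rng.random() * 2 * np.pi
            p = center + rho * np.array([np.cos(theta), np.sin(theta)])
            if cluster_xy.size:
                d = np.linalg.norm(cluster_xy - p, axis=1)
                if np.any(d < cluster_r + r):
                    continue
            ok = True
            for s in spots:
                if np.linalg.norm(np.asarray(s.center) - p) < s.radius + r:
                    ok = False
                    break
            if not ok:
                continue
            spots.append(ControlSpot(center=(float(p[0]), float(p[1])), radius=r,
                                     nucleus_id=cluster.nucleus_id))
            placed += 1
        if placed < n_per_cluster:
            warnings.warn(
                f"placed only {placed}/{n_per_cluster} control spots for a cluster",
                UserWarning, stacklevel=2,
            )
    return spots


def _point_in_any_disc(xy, centers, radii):
    if len(centers) == 0:
        return np.zeros(xy.shape[0], bool)
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    d = np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2)
    return np.any(d <= radii[None, :], axis=1)


def inside_outside_kinetics(points: pd.DataFrame, assigned_state, clusters,
                            control_spots, bound_state: int = 0) -> pd.DataFrame:
    """Bound fraction inside clusters, outside, and in control spots.

    ``points`` holds per-trajectory mean positions; ``assigned_state`` is an
    aligned array of kinetic-bin indices (0 = bound). A trajectory is inside
    when its mean position falls in any cluster disc. Returns a one-row-per-
    region table with bound fraction, count and sd (binomial), plus
    inside/outside and inside/control enrichment folds with propagated sd.
    """
    xy = points[["x", "y"]].to_numpy(float)
    state = np.asarray(assigned_state)
    if state.shape[0] != xy.shape[0]:
        raise ValueError("assigned_state must align with points")
    in_cluster = _point_in_any_disc(
        xy, [c.centroid for c in clusters], [c.radius for c in clusters])
    in_control = _point_in_any_disc(
        xy, [s.center for s in control_spots], [s.radius for s in control_spots])
    in_control &= ~in_cluster
    outside = ~in_cluster

    rows = {}
    for name, sel in [("inside", in_cluster), ("outside", outside),
                      ("control", in_control)]:
        n = int(sel.sum())
        if n == 0:
            rows[name] = Measurement(np.nan, np.nan), 0
            continue
        p = float(np.mean(state[sel] == bound_state))
        sd = float(np.sqrt(p * (1 - p) / n))
        rows[name] = Measurement(p, sd), n

    table = pd.DataFrame(
        {
            "bound_fraction": [rows[k][0].value for k in ("inside", "outside", "control")],
            "sd": [rows[k][0].sd for k in ("inside", "outside", "control")],
            "n_trajectories": [rows[k][1] for k in ("inside", "outside", "control")],
        },
        index=["inside", "outside", "control"],
    )
    folds = {}
    for name, denom in [("inside_vs_outside", "outside"), ("inside_vs_control", "control")]:
        m_in, m_dn = rows["inside"][0], rows[denom][0]
        if np.isfinite(m_in.value) and np.isfinite(m_dn.value) and m_dn.value > 0:
            folds[name] = fold_change(m_in, m_dn)
        else:
            folds[name] = Measurement(np.nan, np.nan)
    table.attrs["folds"] = folds
    return table
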