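"""Diffusion-state inference from single-molecule trajectories.

Trajectories are short 2D random walks recorded at ~10 ms per frame. Each
trajectory is assumed to move with a single diffusion coefficient D drawn
from an unknown mixture over a fixed log-spaced grid of 100 values between
0.001 and 100 µm²/s. The default per-trajectory likelihood is the exact
regular-Brownian-motion-with-error (RBME) form: per-axis jump vectors are
Gaussian with a tridiagonal covariance whose off-diagonal encodes the shared
localization noise of consecutive jumps (a cheaper jumps-independent
exponential approximation is also available). Mixture weights over the grid
("occupancies") are estimated by expectation-maximization; per-trajectory
diffusion coefficients are the occupancy-weighted geometric mean of the
grid; kinetic states (bound / intermediate / fast) are delimited by local
minima of the smoothed occupancy profile.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "DiffusionGrid",
    "OccupancyProfile",
    "KineticBins",
    "FractionEstimate",
    "diffusion_grid",
    "jump_statistics",
    "rbme_grid_loglik",
    "trajectory_grid_loglik",
    "estimate_occupancy",
    "find_state_boundaries",
    "assign_trajectory_D",
    "compute_fractions",
    "estimate_localization_error",
]

GRID_MIN = 1e-3
GRID_MAX = 1e2
GRID_SIZE = 100

#: default localization error, µm (estimated separately from chromatin-bound
#: histone data; see :func:`estimate_localization_error`)
DEFAULT_SIGMA_LOC = 0.030

STATE_LABELS_3 = ("bound", "intermediate", "fast")


@dataclasses.dataclass(frozen=True)
class DiffusionGrid:
    """Log-spaced grid of candidate diffusion coefficients (µm²/s)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid must be a 1D array with at least 2 values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return self.values.size


def diffusion_grid(dmin: float = GRID_MIN, dmax: float = GRID_MAX,
                   size: int = GRID_SIZE) -> DiffusionGrid:
    """100 log-spaced diffusion coefficients from 0.001 to 100 µm²/s."""
    return DiffusionGrid(np.geomspace(dmin, dmax, size))


@dataclasses.dataclass
class OccupancyProfile:
    """Posterior mass over the diffusion grid, plus per-trajectory responsibilities."""

    grid: DiffusionGrid
    occupancy: np.ndarray          # (n_grid,), sums to 1
    localization_sigma: float      # µm
    n_trajectories: int
    responsibilities: np.ndarray | None = None  # (n_traj, n_grid)
    log_likelihood: float = np.nan
    n_iter: int = 0

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (len(self.grid),):
            raise ValueError("occupancy must match grid length")
        if not np.isclose(occ.sum(), 1.0, atol=1e-9):
            raise ValueError("occupancy must sum to 1")
        self.occupancy = occ


@dataclasses.dataclass(frozen=True)
class KineticBins:
    """Diffusion-coefficient cut points delimiting ordered kinetic states."""

    boundaries: tuple      # strictly increasing cut points, µm²/s
    labels: tuple          # len(boundaries) + 1 state names

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need exactly one more label than boundaries")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "labels", tuple(self.labels))

    def assign(self, d_values):
        """Bin index for each diffusion coefficient (0 = slowest state)."""
        return np.searchsorted(np.asarray(self.boundaries), np.asarray(d_values, float),
                               side="right")


@dataclasses.dataclass
class FractionEstimate:
    """Per-field kinetic-state fractions and their across-field summary."""

    labels: tuple
    per_field: pd.DataFrame     # index = field id, columns = labels
    mean: np.ndarray
    sd: np.ndarray
    n_fields: int


# ---------------------------------------------------------------------------
# jump statistics and grid likelihood
# ---------------------------------------------------------------------------

def jump_statistics(trajectories: pd.DataFrame):
    """Sufficient statistics per trajectory: jump count and summed squared jump.

    Parameters
    ----------
    trajectories
        Long-format table with columns ``trajectory``, ``frame``, ``x``, ``y``
        (positions in µm), sorted or sortable by frame within trajectory.

    Returns
    -------
    ids : ndarray of trajectory ids (trajectories with ≥1 jump)
    n_jumps : ndarray of jump counts
    sum_sq : ndarray of summed squared 2D jump lengths (µm²)
    """
    df = trajectories.sort_values(["trajectory", "frame"], kind="stable")
    tid = df["trajectory"].to_numpy()
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    same = tid[1:] == tid[:-1]
    dx = np.diff(x)[same]
    dy = np.diff(y)[same]
    sq = dx * dx + dy * dy
    jump_tid = tid[1:][same]
    ids, inverse = np.unique(jump_tid, return_inverse=True)
    n_jumps = np.bincount(inverse, minlength=ids.size)
    sum_sq = np.bincount(inverse, weights=sq, minlength=ids.size)
    return ids, n_jumps, sum_sq


def trajectory_grid_loglik(n_jumps, sum_sq, grid: DiffusionGrid,
                           sigma_loc: float, frame_interval: float) -> np.ndarray:
    """Log-likelihood of each trajectory's jumps under each grid D.

    Jumps-independent approximation: squared 2D jump lengths are exponential
    with mean ``4 * (D * dt + sigma_loc**2)``, so the trajectory
    log-likelihood is ``-n * log(m) - S / m`` with ``m`` the exponential
    mean, ``n`` the jump count and ``S`` the summed squared jump length.
    This ignores the negative correlation between consecutive jumps induced
    by shared localization noise; :func:`rbme_grid_loglik` is exact.

    Returns an ``(n_traj, n_grid)`` array.
    """
    n = np.atleast_1d(np.asarray(n_jumps, float))
    S = np.atleast_1d(np.asarray(sum_sq, float))
    if n.size == 0 or np.any(n < 1):
        raise ValueError("every trajectory needs at least one jump")
    m = 4.0 * (grid.values * frame_interval + sigma_loc ** 2)  # (n_grid,)
    return -np.outer(n, np.log(m)) - np.outer(S, 1.0 / m)


def rbme_grid_loglik(trajectories: pd.DataFrame, grid: DiffusionGrid,
                     sigma_loc: float, frame_interval: float):
    """Exact Brownian-motion-with-error log-likelihood on the grid.

    For a trajectory of n jumps, the per-axis jump vector is Gaussian with
    tridiagonal Toeplitz covariance: variance ``2*D*dt + 2*sigma**2`` on the
    diagonal and ``-sigma**2`` on the off-diagonals (consecutive jumps share
    the middle localization's noise). That matrix diagonalizes in the
    discrete sine basis with eigenvalues
    ``2*D*dt + 2*sigma**2 * (1 - cos(k*pi/(n+1)))``, so each trajectory
    needs one orthonormal DST of its jump components and the grid evaluation
    is a weighted sum over modes. The low-frequency modes suppress the noise
    term, which makes slow diffusion far better identified than under the
    jumps-independent approximation.

    Returns ``(ids, loglik)`` with ``loglik`` of shape (n_traj, n_grid).
    """
    from scipy.fft import dst

    df = trajectories.sort_values(["trajectory", "frame"], kind="stable")
    tid = df["trajectory"].to_numpy()
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    same = tid[1:] == tid[:-1]
    dx = np.diff(x)[same]
    dy = np.diff(y)[same]
    jump_tid = tid[1:][same]
    ids, inverse = np.unique(jump_tid, return_inverse=True)
    if ids.size == 0:
        raise ValueError("no trajectory has at least one jump")
    n_jumps = np.bincount(inverse, minlength=ids.size)
    order = np.argsort(inverse, kind="stable")
    dx, dy = dx[order], dy[order]
    starts = np.concatenate([[0], np.cumsum(n_jumps)])

    G = grid.values.size
    loglik = np.empty((ids.size, G))
    a = 2.0 * grid.values * frame_interval          # (G,)
    for n in np.unique(n_jumps):
        sel = np.nonzero(n_jumps == n)[0]
        seg = np.stack([
            np.stack([dx[starts[i]:starts[i] + n],
                      dy[starts[i]:starts[i] + n]]) for i in sel
        ])                                           # (m, 2, n)
        c = dst(seg, type=1, norm="ortho", axis=-1)
        q = (c ** 2).sum(axis=1)                     # (m, n) both axes
        k = np.arange(1, n + 1)
        noise = 2.0 * sigma_loc ** 2 * (1.0 - np.cos(k * np.pi / (n + 1)))
        lam = a[:, None] + noise[None, :]            # (G, n)
        logdet = np.log(lam).sum(axis=1)             # (G,)
        loglik[sel] = -logdet[None, :] - 0.5 * q @ (1.0 / lam.T)
    return ids, loglik


# ---------------------------------------------------------------------------
# occupancy estimation (fixed-grid finite-mixture EM)
# ---------------------------------------------------------------------------

def estimate_occupancy(trajectories: pd.DataFrame, grid: DiffusionGrid | None = None,
                       sigma_loc: float = DEFAULT_SIGMA_LOC,
                       frame_interval: float = 0.010,
                       max_iter: int = 200, tol: float = 1e-8,
                       likelihood: str = "rbme") -> OccupancyProfile:
    """Estimate diffusion-coefficient occupancies over a fixed grid by EM.

    The mixture components (one per grid point) are fixed; only their weights
    are free. Weights start uniform and are updated until the mean
    log-likelihood improves by less than ``tol`` or ``max_iter`` iterations.
    The per-trajectory likelihood is the exact Brownian-motion-with-error
    form by default (``likelihood="rbme"``); ``"independent"`` selects the
    faster jumps-independent approximation. Per-trajectory posterior
    responsibilities are retained for downstream assignment of individual
    diffusion coefficients.
    """
    if grid is None:
        grid = diffusion_grid()
    if len(trajectories) == 0:
        raise ValueError("empty trajectory table")
    if likelihood == "rbme":
        ids, ll = rbme_grid_loglik(trajectories, grid, sigma_loc, frame_interval)
    elif likelihood == "independent":
        ids, n_jumps, sum_sq = jump_statistics(trajectories)
        if ids.size == 0:
            raise ValueError("no trajectory has at least one jump")
        ll = trajectory_grid_loglik(n_jumps, sum_sq, grid, sigma_loc,
                                    frame_interval)
    else:
        raise ValueError("likelihood must be 'rbme' or 'independent'")

    k = len(grid)
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logr = ll + np.log(np.maximum(weights, 1e-300))
        mx = logr.max(axis=1, keepdims=True)
        r = np.exp(logr - mx)
        norm = r.sum(axis=1, keepdims=True)
        loglik = float(np.sum(np.log(norm) + mx))
        r /= norm
        weights = r.mean(axis=0)
        weights /= weights.sum()
        if loglik - prev < tol * abs(loglik):
            break
        prev = loglik

    logr = ll + np.log(np.maximum(weights, 1e-300))
    mx = logr.max(axis=1, keepdims=True)
    r = np.exp(logr - mx)
    r /= r.sum(axis=1, keepdims=True)

    resp = pd.DataFrame(r, index=pd.Index(ids, name="trajectory"))
    profile = OccupancyProfile(
        grid=grid,
        occupancy=weights,
        localization_sigma=sigma_loc,
        n_trajectories=ids.size,
        responsibilities=resp,
        log_likelihood=loglik,
        n_iter=n_iter,
    )
    return profile


# ---------------------------------------------------------------------------
# state boundaries and per-trajectory assignment
# ---------------------------------------------------------------------------

def find_state_boundaries(profile: OccupancyProfile, smooth_sigma: float = 3.0,
                          min_prominence_frac: float = 0.01,
                          labels=None) -> KineticBins:
    """Split the occupancy profile into kinetic states at its local minima.

    The occupancy curve is smoothed with a Gaussian kernel (``smooth_sigma``
    grid points); interior minima with prominence at least
    ``min_prominence_frac`` of the peak occupancy become state boundaries. The
    first state runs from the grid minimum to the first boundary, the last
    from the final boundary to the grid maximum. With exactly two boundaries
    the states are labeled bound / intermediate / fast unless ``labels`` is
    given.
    """
    occ = gaussian_filter1d(profile.occupancy, smooth_sigma, mode="nearest")
    prominence = min_prominence_frac * occ.max()
    minima, _ = find_peaks(-occ, prominence=prominence)
    bounds = tuple(profile.grid.values[i] for i in minima)
    if labels is None:
        if len(bounds) == 2:
            labels = STATE_LABELS_3
        else:
            labels = tuple(f"state_{i}" for i in range(len(bounds) + 1))
    return KineticBins(boundaries=bounds, labels=labels)


def assign_trajectory_D(responsibilities, grid: DiffusionGrid) -> np.ndarray:
    """Occupancy-weighted geometric mean diffusion coefficient per trajectory.

    ``exp(sum_i w_i * ln D_i)`` over the grid, one value per responsibility
    row.
    """
    w = np.atleast_2d(np.asarray(responsibilities, float))
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("responsibilities must have positive total weight")
    w = w / totals[:, None]
    return np.exp(w @ np.log(grid.values))


def compute_fractions(assigned_d, field_ids, bins: KineticBins) -> FractionEstimate:
    """Kinetic-state fractions per field of view and their mean ± sd.

    Each trajectory contributes to the state whose diffusion-coefficient bin
    contains its assigned D; per-field fractions are counts over the field
    total, and the summary is the mean and standard deviation across fields.
    """
    d = np.asarray(assigned_d, float)
    fields = np.asarray(field_ids)
    if d.shape != fields.shape:
        raise ValueError("assigned_d and field_ids must align")
    if d.size == 0:
        raise ValueError("no trajectories to bin")
    state = bins.assign(d)
    uniq = np.unique(fields)
    rows = []
    for f in uniq:
        sel = state[fields == f]
        if sel.size == 0:
            raise ValueError(f"field {f!r} has zero trajectories")
        counts = np.bincount(sel, minlength=len(bins.labels))
        rows.append(counts / counts.sum())
    per_field = pd.DataFrame(rows, index=pd.Index(uniq, name="field"),
                             columns=list(bins.labels))
    return FractionEstimate(
        labels=bins.labels,
        per_field=per_field,
        mean=per_field.mean(axis=0).to_numpy(),
        sd=per_field.std(axis=0, ddof=1).to_numpy() if len(uniq) > 1
        else np.zeros(len(bins.labels)),
        n_fields=len(uniq),
    )


# ---------------------------------------------------------------------------
# localization error
# ---------------------------------------------------------------------------

def estimate_localization_error(trajectories: pd.DataFrame,
                                assigned_d: pd.Series | None = None,
                                slow_percentile: float = 5.0,
                                frame_interval: float = 0.010,
                                min_trajectories: int = 100) -> float:
    """Localization error from the slowest trajectories' residual jitter.

    For effectively immobile emitters every apparent displacement is pure
    localization noise: the distance between two localizations, each with
    per-axis error ``sigma_loc``, is Rayleigh with scale ``sqrt(2)*sigma_loc``
    and mean ``sigma_loc * sqrt(pi)``. The estimate therefore selects the
    trajectories whose assigned D lies in the lowest ``slow_percentile`` (all
    trajectories when ``assigned_d`` is None), computes the mean consecutive
    displacement m, and returns ``m / sqrt(pi)`` (µm).
    """
    ids, n_jumps, sum_sq = jump_statistics(trajectories)
    if ids.size < min_trajectories:
        raise ValueError(f"need at least {min_trajectories} trajectories")
    if assigned_d is not None:
        d = pd.Series(assigned_d).reindex(ids).to_numpy(float)
        cutoff = np.nanpercentile(d, slow_percentile)
        keep = d <= cutoff
        if keep.sum() < 10:
            raise ValueError("too few slow trajectories for the estimate")
    else:
        keep = np.ones(ids.size, bool)
    keep_ids = set(ids[keep])
    df = trajectories[trajectories["trajectory"].isin(keep_ids)]
    df = df.sort_values(["trajectory", "frame"], kind="stable")
    tid = df["trajectory"].to_numpy()
    same = tid[1:] == tid[:-1]
    dx = np.diff(df["x"].to_numpy(float))[same]
    dy = np.diff(df["y"].to_numpy(float))[same]
    mean_disp = float(np.mean(np.hypot(dx, dy)))
    return mean_disp / np.sqrt(np.pi)
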