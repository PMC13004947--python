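"""Displacement-angle anisotropy of single-molecule trajectories.

For each interior localization of a trajectory the turning angle between the
incoming and outgoing jump vectors is computed from their dot product
(0° = same direction, 180° = full reversal). Free Brownian motion yields a
uniform turning-angle distribution; confinement or rebinding inflates the
backward window. The fold-anisotropy statistic is

    f = P(angle in [150°, 180°]) / P(angle in [0°, 30°]),

with both windows closed. Jumps shorter than a minimum length (default
0.2 µm) are excluded, as are trajectories assigned to the chromatin-bound
state, since near-stationary molecules would be dominated by localization
noise. Uncertainty comes from repeatedly recomputing f on random 50%
subsamples drawn without replacement.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["AngleSet", "compute_angles", "fold_anisotropy", "bootstrap_anisotropy"]

BACKWARD_WINDOW = (150.0, 180.0)
FORWARD_WINDOW = (0.0, 30.0)


@dataclasses.dataclass
class AngleSet:
    """Turning angles in degrees with optional per-angle source labels."""

    angles: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.size and (a.min() < 0 or a.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")
        self.angles = a

    @property
    def n_angles(self) -> int:
        return self.angles.size

    def subset(self, label) -> "AngleSet":
        if self.labels is None:
            raise ValueError("angle set carries no labels")
        sel = np.asarray(self.labels) == label
        return AngleSet(self.angles[sel])


def compute_angles(trajectories: pd.DataFrame, min_jump: float = 0.2,
                   exclude_states=("bound",), state_column: str = "state",
                   label_column: str | None = None) -> AngleSet:
    """Turning angles between consecutive jumps of each trajectory.

    ``trajectories`` is a long table with columns ``trajectory``, ``frame``,
    ``x``, ``y`` (µm) and optionally a per-row kinetic-state column; rows of
    excluded states (default: bound) are dropped before angle computation.
    Angle pairs in which either jump is shorter than ``min_jump`` are
    skipped. When ``label_column`` is given (e.g. inside/outside cluster),
    each angle inherits the label of its central localization.
    """
    df = trajectories
    if state_column in df.columns and exclude_states:
        df = df[~df[state_column].isin(exclude_states)]
    df = df.sort_values(["trajectory", "frame"], kind="stable")
    tid = df["trajectory"].to_numpy()
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    same = tid[1:] == tid[:-1]
    # jump vectors and the trajectory they belong to
    vx, vy = np.diff(x), np.diff(y)
    jump_tid = tid[1:]
    # consecutive jump pairs within one trajectory
    pair = same[1:] & same[:-1] & (jump_tid[1:] == jump_tid[:-1])
    v1x, v1y = vx[:-1][pair], vy[:-1][pair]
    v2x, v2y = vx[1:][pair], vy[1:][pair]
    n1 = np.hypot(v1x, v1y)
    n2 = np.hypot(v2x, v2y)
    keep = (n1 >= min_jump) & (n2 >= min_jump) & (n1 > 0) & (n2 > 0)
    cosang = np.zeros(keep.sum())
    if keep.any():
        cosang = (v1x[keep] * v2x[keep] + v1y[keep] * v2y[keep]) / (n1[keep] * n2[keep])
        cosang = np.clip(cosang, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    labels = None
    if label_column is not None:
        lab = df[label_column].to_numpy()
        # central localization of each angle = endpoint of the first jump
        central = lab[1:][:-1][pair] if lab.size > 1 else np.array([])
        labels = central[keep]
    return AngleSet(angles, labels)


def fold_anisotropy(angles: AngleSet | np.ndarray) -> float:
    """Backward/forward probability ratio of the turning-angle distribution.

    Both windows are closed: backward = [150°, 180°], forward = [0°, 30°].
    Returns NaN when no angle falls in the forward window (undefined ratio,
    not infinity); raises on an empty angle set.
    """
    a = angles.angles if isinstance(angles, AngleSet) else np.asarray(angles, float)
    if a.size == 0:
        raise ValueError("empty angle set")
    backward = np.count_nonzero((a >= BACKWARD_WINDOW[0]) & (a <= BACKWARD_WINDOW[1]))
    forward = np.count_nonzero((a >= FORWARD_WINDOW[0]) & (a <= FORWARD_WINDOW[1]))
    if forward == 0:
        return float("nan")
    return backward / forward


def bootstrap_anisotropy(angles: AngleSet | np.ndarray, frac: float = 0.5,
                         n_boot: int = 20, seed=None):
    """Mean ± sd of fold-anisotropy over random subsamples.

    Each of the ``n_boot`` subsamples contains ``floor(frac * N)`` angles
    drawn without replacement (a half-sample jackknife rather than the
    classical with-replacement bootstrap). Returns ``(mean, sd)``; undefined
    subsample ratios (empty forward window) are dropped from the summary.
    """
    a = angles.angles if isinstance(angles, AngleSet) else np.asarray(angles, float)
    if a.size < 2:
        raise ValueError("need at least 2 angles")
    size = int(frac * a.size)
    if size < 10:
        warnings.warn("subsample smaller than 10 angles; estimate will be noisy",
                      UserWarning, stacklevel=2)
    size = max(size, 1)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        sub = rng.choice(a, size=size, replace=False)
        f = fold_anisotropy(sub)
        if np.isfinite(f):
            vals.append(f)
    vals = np.asarray(vals)
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.std(ddof=0))
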