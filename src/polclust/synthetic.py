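"""Synthetic data generators with known ground truth for every pipeline stage.

Three generators emulate the raw inputs of a live-embryo imaging experiment:

* single-molecule trajectory tables — mixtures of bound / intermediate /
  fast Brownian walks with localization noise, confined to a circular
  nucleus, with optional hotspots that concentrate bound molecules;
* volumetric nucleus movies — an ellipsoidal nucleus of uniform baseline
  with Gaussian intensity clusters (two-population lifetimes) and up to two
  bright, persistent histone locus bodies, plus additive Gaussian noise
  (appropriate for deconvolved data whose shot statistics are already
  distorted);
* coupled MCP/RNAPII burst traces driven by the polymerase-loading
  simulator.

Each trajectory keeps one diffusive state for its whole life; track lengths
are geometric (memoryless photobleaching) with a minimum of 3 localizations
so turning angles exist. All generators are deterministic under a seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .simulator import SimConfig, simulate_trace

__all__ = [
    "SmtSimConfig",
    "NucleusMovieConfig",
    "generate_smt_trajectories",
    "generate_nucleus_movie",
    "generate_coupled_traces",
]

PIXEL_SIZE = 0.108  # µm per pixel, camera sampling


@dataclasses.dataclass(frozen=True)
class SmtSimConfig:
    """Ground-truth parameters for trajectory generation."""

    n_trajectories: int = 10_000
    state_fractions: tuple = (0.5, 0.2, 0.3)
    state_diffusion_coefficients: tuple = (0.002, 0.2, 8.0)  # µm²/s
    frame_interval: float = 0.010          # s
    localization_sigma: float = 0.030      # µm, per axis per localization
    mean_track_length: float = 8.0         # frames, geometric truncation
    min_track_length: int = 3
    nucleus_radius: float = 3.0            # µm
    n_bound_hotspots: int = 0
    hotspot_radius: float = 0.15           # µm
    hotspot_bound_prob: float = 0.8        # chance a bound track starts in a hotspot
    seed: int | None = None

    def __post_init__(self):
        f = np.asarray(self.state_fractions, float)
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("state fractions must sum to 1")
        if np.any(f < 0):
            raise ValueError("state fractions must be nonnegative")
        d = np.asarray(self.state_diffusion_coefficients, float)
        if d.size != f.size:
            raise ValueError("one diffusion coefficient per state required")
        if np.any(d < 0) or np.any(d > 100):
            raise ValueError("diffusion coefficients must lie in [0, 100] µm²/s")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_trajectories <= 0:
            raise ValueError("n_trajectories must be positive")
        if self.mean_track_length < self.min_track_length:
            raise ValueError("mean track length below the minimum length")


def _reflect_into_disc(p: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back inside a disc of the given radius."""
    r = np.hypot(p[0], p[1])
    while r > radius:
        p = p * (2 * radius - r) / r
        r = abs(2 * radius - r)
    return p


def generate_smt_trajectories(config: SmtSimConfig):
    """Simulate trajectory tables with per-trajectory ground-truth states.

    Each trajectory draws a state from ``state_fractions``, a geometric track
    length (minimum ``min_track_length`` localizations), and a uniform start
    position in the nuclear disc (bound trajectories may instead start in a
    hotspot). Steps are Gaussian with per-axis variance ``2*D*dt``, reflected
    at the nuclear boundary; every localization then gains independent
    Gaussian noise of sd ``localization_sigma`` per axis (noisy positions may
    fall marginally outside the boundary; true positions never do).

    Returns ``(table, truth)``: a long table with columns ``trajectory``,
    ``frame``, ``x``, ``y`` (µm) and ``x_px``/``y_px`` (0.108 µm pixels), and
    a per-trajectory frame with the true state index and D.
    """
    rng = np.random.default_rng(config.seed)
    fractions = np.asarray(config.state_fractions, float)
    dcoefs = np.asarray(config.state_diffusion_coefficients, float)
    n = config.n_trajectories
    states = rng.choice(fractions.size, size=n, p=fractions)

    # geometric number of extra frames beyond the minimum
    extra_mean = config.mean_track_length - config.min_track_length
    if extra_mean > 0:
        lengths = config.min_track_length + rng.geometric(
            1.0 / (extra_mean + 1.0), size=n) - 1
    else:
        lengths = np.full(n, config.min_track_length)

    hotspots = None
    if config.n_bound_hotspots > 0:
        rho = (config.nucleus_radius - config.hotspot_radius) * np.sqrt(
            rng.random(config.n_bound_hotspots))
        th = rng.random(config.n_bound_hotspots) * 2 * np.pi
        hotspots = np.column_stack([rho * np.cos(th), rho * np.sin(th)])

    step_sd = np.sqrt(2.0 * dcoefs * config.frame_interval)
    rows_id, rows_frame, xs, ys = [], [], [], []
    for i in range(n):
        L = int(lengths[i])
        s = states[i]
        if (hotspots is not None and s == 0
                and rng.random() < config.hotspot_bound_prob):
            h = hotspots[rng.integers(hotspots.shape[0])]
            p = h + rng.normal(scale=config.hotspot_radius / 2.0, size=2)
            p = _reflect_into_disc(p, config.nucleus_radius)
        else:
            rho = config.nucleus_radius * np.sqrt(rng.random())
            th = rng.random() * 2 * np.pi
            p = np.array([rho * np.cos(th), rho * np.sin(th)])
        pos = np.empty((L, 2))
        pos[0] = p
        steps = rng.normal(scale=step_sd[s], size=(L - 1, 2))
        for j in range(1, L):
            p = _reflect_into_disc(p + steps[j - 1], config.nucleus_radius)
            pos[j] = p
        noisy = pos + rng.normal(scale=config.localization_sigma, size=pos.shape)
        rows_id.append(np.full(L, i))
        rows_frame.append(np.arange(L))
        xs.append(noisy[:, 0])
        ys.append(noisy[:, 1])

    table = pd.DataFrame({
        "trajectory": np.concatenate(rows_id),
        "frame": np.concatenate(rows_frame),
        "x": np.concatenate(xs),
        "y": np.concatenate(ys),
    })
    table["x_px"] = table["x"] / PIXEL_SIZE
    table["y_px"] = table["y"] / PIXEL_SIZE
    truth = pd.DataFrame({
        "trajectory": np.arange(n),
        "state": states,
        "diffusion_coefficient": dcoefs[states],
        "track_length": lengths,
    }).set_index("trajectory")
    return table, truth


# ---------------------------------------------------------------------------
# volumetric movies
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NucleusMovieConfig:
    """Ground-truth parameters for a synthetic nucleus movie."""

    shape: tuple = (30, 16, 64, 64)        # (T, Z, Y, X) voxels
    voxel_size: tuple = (0.3, 0.108, 0.108)  # µm (z, y, x)
    nucleus_center: tuple | None = None    # voxels (z, y, x); image center if None
    nucleus_radii: tuple = (2.0, 2.5, 2.5)  # µm ellipsoid semi-axes (z, y, x)
    baseline: float = 1.0
    n_clusters: int = 6
    cluster_amplitude: float = 3.0         # peak fold over baseline
    cluster_sigma: float = 0.25            # µm, isotropic
    lifetime_mixture: tuple = (0.33, 2.0, 7.0)  # (weight_short, mean_short, mean_long) min
    lifetime_sigmas: tuple = (0.8, 2.0)    # min, per component
    frame_interval: float = 10.0           # s
    n_hlbs: int = 2
    hlb_amplitude: float = 8.0
    hlb_sigma: float = 0.35                # µm
    background_noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.shape) != 4:
            raise ValueError("shape must be (T, Z, Y, X)")
        if len(self.voxel_size) != 3:
            raise ValueError("voxel_size must be (z, y, x)")
        if not 0 <= self.n_hlbs <= 2:
            raise ValueError("a nucleus carries at most two HLBs")
        if self.n_clusters > 0 and self.cluster_amplitude <= 1:
            raise ValueError("cluster amplitude must exceed 1 (fold over baseline)")
        w = self.lifetime_mixture[0]
        if not 0 <= w <= 1:
            raise ValueError("lifetime mixture weight must lie in [0, 1]")


def _ellipsoid_mask(shape_zyx, center_vox, radii_um, voxel_size):
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape_zyx], indexing="ij")
    coords = [(g - c) * v for g, c, v in zip((zz, yy, xx), center_vox, voxel_size)]
    return sum((c / r) ** 2 for c, r in zip(coords, radii_um)) <= 1.0


def _gaussian_blob(shape_zyx, center_vox, sigma_um, voxel_size, amplitude):
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape_zyx], indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip((zz, yy, xx), center_vox,
                                                   voxel_size))
    return amplitude * np.exp(-d2 / (2.0 * sigma_um ** 2))


def generate_nucleus_movie(config: NucleusMovieConfig):
    """Render a 4D nucleus movie with known cluster ground truth.

    Intensity per frame = baseline inside the nuclear ellipsoid + isotropic
    Gaussian blobs for live clusters and HLBs + additive Gaussian noise.
    Cluster lifetimes are drawn from the two-population mixture (Gaussian
    components truncated below one frame); each cluster's birth frame is
    uniform over the movie and tracks that would outlive the movie are
    truncated at the last frame. HLBs persist for the whole movie.

    Returns ``(movie, truth, mask)``: the (T,Z,Y,X) float stack, a table of
    blob ground truth (positions in voxels, birth/death frames, amplitude,
    kind), and the 3D nuclear mask.
    """
    rng = np.random.default_rng(config.seed)
    T, Z, Y, X = config.shape
    vz, vy, vx = config.voxel_size
    center = (np.array(config.nucleus_center, float)
              if config.nucleus_center is not None
              else np.array([(Z - 1) / 2, (Y - 1) / 2, (X - 1) / 2]))
    mask = _ellipsoid_mask((Z, Y, X), center, config.nucleus_radii,
                           config.voxel_size)

    def _random_center(margin_um):
        # rejection-sample a voxel center inside the shrunken ellipsoid
        radii = np.maximum(np.asarray(config.nucleus_radii) - margin_um, 0.3)
        for _ in range(1000):
            u = rng.uniform(-1, 1, 3)
            if (u ** 2).sum() <= 1.0:
                offs = u * radii / np.array(config.voxel_size)
                return center + offs
        return center

    records = []
    blobs = []  # (center_vox, sigma, amplitude, birth, death)
    w_short, mean_short, mean_long = config.lifetime_mixture
    sd_short, sd_long = config.lifetime_sigmas
    for i in range(config.n_clusters):
        c = _random_center(3.0 * config.cluster_sigma)
        if rng.random() < w_short:
            life_min, kind = rng.normal(mean_short, sd_short), "short"
        else:
            life_min, kind = rng.normal(mean_long, sd_long), "long"
        life_frames = max(1, int(round(life_min * 60.0 / config.frame_interval)))
        birth = int(rng.integers(0, max(1, T - 1)))
        death = min(T - 1, birth + life_frames - 1)
        amp = (config.cluster_amplitude - 1.0) * config.baseline
        blobs.append((c, config.cluster_sigma, amp, birth, death))
        records.append({
            "kind": "cluster", "component": kind, "z": c[0], "y": c[1],
            "x": c[2], "sigma_um": config.cluster_sigma, "amplitude": amp,
            "birth_frame": birth, "death_frame": death,
            "lifetime_min": life_min,
        })
    for i in range(config.n_hlbs):
        c = _random_center(3.0 * config.hlb_sigma)
        amp = (config.hlb_amplitude - 1.0) * config.baseline
        blobs.append((c, config.hlb_sigma, amp, 0, T - 1))
        records.append({
            "kind": "hlb", "component": "hlb", "z": c[0], "y": c[1], "x": c[2],
            "sigma_um": config.hlb_sigma, "amplitude": amp,
            "birth_frame": 0, "death_frame": T - 1,
            "lifetime_min": T * config.frame_interval / 60.0,
        })

    movie = np.zeros(config.shape, dtype=float)
    base = np.where(mask, config.baseline, 0.0)
    for t in range(T):
        frame = base.copy()
        for (c, sigma, amp, birth, death) in blobs:
            if birth <= t <= death:
                frame += _gaussian_blob((Z, Y, X), c, sigma,
                                        config.voxel_size, amp)
        if config.background_noise_sigma > 0:
            frame = frame + rng.normal(scale=config.background_noise_sigma,
                                       size=frame.shape)
        movie[t] = frame
    truth = pd.DataFrame(records)
    return movie, truth, mask


# ---------------------------------------------------------------------------
# coupled burst traces
# ---------------------------------------------------------------------------

def generate_coupled_traces(sim_config: SimConfig, duration: float,
                            noise_sigma: float = 0.0, n_nuclei: int = 1,
                            seed=None):
    """Paired MCP and RNAPII traces driven by the loading simulator.

    The MCP trace is proportional to the number of polymerases currently on
    the gene body (each elongating polymerase carries one nascent
    transcript); the RNAPII trace is the simulator's gene-region enrichment.
    Independent Gaussian noise of sd ``noise_sigma`` is added to both.
    Returns a list of ``n_nuclei`` DataFrames with columns ``time``, ``mcp``,
    ``rnapii`` and the ground-truth ``engaged_count``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_nuclei):
        trace = simulate_trace(sim_config, duration, rng=rng)
        mcp = trace["engaged_count"].to_numpy(float)
        rnapii = trace["rnapii_enrichment"].to_numpy(float)
        if noise_sigma > 0:
            mcp = mcp + rng.normal(scale=noise_sigma, size=mcp.size)
            rnapii = rnapii + rng.normal(scale=noise_sigma, size=rnapii.size)
        out.append(pd.DataFrame({
            "time": trace["time"].to_numpy(),
            "mcp": mcp,
            "rnapii": rnapii,
            "engaged_count": trace["engaged_count"].to_numpy(),
        }))
    return out
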