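"""File formats, run configuration, seeding, and pipeline orchestration.

Conventions: trajectory tables are CSV with columns ``trajectory``,
``frame``, ``x``, ``y`` (µm; pixel columns at 0.108 µm/px accepted and
converted); image stacks are multi-page TIFF in (T, Z, Y, X) order with
voxel size 0.108 × 0.108 × 0.3 µm by default; voxel indices are 0-based and
physical coordinates are point localizations in µm. All randomness flows
from a single global seed through per-stage derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("polclust")

__all__ = [
    "RunConfig",
    "DEFAULT_PARAMETERS",
    "read_trajectories",
    "write_trajectories",
    "read_stack",
    "write_stack",
    "derive_seed",
    "run_pipeline",
]

PIXEL_SIZE = 0.108          # µm per pixel
DEFAULT_VOXEL_SIZE = (0.3, 0.108, 0.108)  # µm (z, y, x)

#: Every analysis constant in one place (units in comments).
DEFAULT_PARAMETERS = {
    "pixel_size_um": 0.108,            # camera sampling
    "frame_interval_s": 0.010,         # single-molecule exposure
    "grid_min": 1e-3,                  # µm²/s, diffusion grid lower edge
    "grid_max": 1e2,                   # µm²/s, diffusion grid upper edge
    "grid_size": 100,                  # log-spaced grid points
    "sigma_loc_um": 0.030,             # localization error
    "min_jump_um": 0.2,                # anisotropy jump filter
    "angle_window_deg": 30.0,          # forward/backward half-window
    "dbscan_eps_um": 0.2,              # trajectory-clustering radius
    "dbscan_min_samples": 15,          # trajectory-clustering minimum points
    "controls_per_cluster": 30,
    "enrichment_threshold": 1.65,      # cluster mean-enrichment filter
    "z_tolerance_um": 0.6,             # lifetime linking (2 z-slices)
    "burst_sampling_s": 9.0,           # two-color volumetric cadence
    "min_burst_duration_s": 30.0,
    "psf_fwhm_nm": 400.0,              # simulator point spread function
    "elongation_rate_kb_per_min": 2.5,
    "gene_length_kb": 2.8,
    "nucleus_diameter_um": 5.0,
    "molecule_diameter_nm": 15.0,
    "n_total_molecules": 50_000,
    "sim_dt_s": 0.1,
    "promoter_on_min": 15.0,
    "gene_region_diameter_um": 1.0,
}


@dataclasses.dataclass
class RunConfig:
    """Pipeline run configuration: stage parameters, seed, and paths."""

    seed: int = 0
    output_dir: str = "polclust_out"
    stages: tuple = ("simulate", "fit-kinetics", "anisotropy")
    parameters: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PARAMETERS))
    log_level: str = "INFO"


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# trajectory tables
# ---------------------------------------------------------------------------

def read_trajectories(path, pixel_size: float = PIXEL_SIZE) -> pd.DataFrame:
    """Read and validate a trajectory CSV.

    Requires ``trajectory`` and ``frame`` plus either µm columns (``x``,
    ``y``) or pixel columns (``x_px``, ``y_px``), which are converted at
    ``pixel_size`` µm/px. Frames must be consecutive within each trajectory
    (the tracker allows no blinking gaps).
    """
    df = pd.read_csv(path)
    required = {"trajectory", "frame"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    if not {"x", "y"}.issubset(df.columns):
        if {"x_px", "y_px"}.issubset(df.columns):
            df["x"] = df["x_px"] * pixel_size
            df["y"] = df["y_px"] * pixel_size
        else:
            raise ValueError("need x/y (µm) or x_px/y_px (pixel) columns")
    df = df.sort_values(["trajectory", "frame"], kind="stable")
    frame_steps = df.groupby("trajectory")["frame"].diff().dropna()
    if (frame_steps != 1).any():
        raise ValueError("frames must be consecutive within each trajectory")
    return df.reset_index(drop=True)


def write_trajectories(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "x_px" not in out.columns:
        out["x_px"] = out["x"] / PIXEL_SIZE
        out["y_px"] = out["y"] / PIXEL_SIZE
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def read_stack(path, voxel_size=None):
    """Read a (T, Z, Y, X) TIFF stack and return (array, metadata dict).

    Voxel size comes from the file's JSON description when present, else
    from ``voxel_size``, else the 0.108/0.108/0.3 µm default. A plain 2D
    image without axis metadata is rejected as ambiguous.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            meta = {}
    if arr.ndim == 2 and "axes" not in meta:
        raise ValueError("2D image without axis metadata: stack order ambiguous")
    if arr.ndim == 3:
        arr = arr[None]  # single time point
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret stack of shape {arr.shape}")
    vs = tuple(meta.get("voxel_size_um", voxel_size or DEFAULT_VOXEL_SIZE))
    meta["voxel_size_um"] = vs
    meta["depth_um"] = arr.shape[1] * vs[0]
    return arr, meta


def write_stack(arr: np.ndarray, path, voxel_size=DEFAULT_VOXEL_SIZE) -> None:
    """Write a (T, Z, Y, X) stack as TIFF with JSON voxel metadata."""
    if arr.ndim != 4:
        raise ValueError("stack must be (T, Z, Y, X)")
    desc = json.dumps({"axes": "TZYX", "voxel_size_um": list(voxel_size)})
    tifffile.imwrite(str(path), arr, description=desc,
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested synthetic-data stages end to end.

    Stages: ``simulate`` (trajectory generation), ``fit-kinetics``
    (occupancy → boundaries → per-field fractions), ``anisotropy``. Each
    stage writes CSV outputs into ``config.output_dir`` and the manifest
    records parameters, derived seeds and output hashes.
    """
    from . import anisotropy as aniso
    from . import smt, synthetic

    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    p = config.parameters
    manifest = {"seed": config.seed, "stages": {}, "parameters": p}
    known = {"simulate", "fit-kinetics", "anisotropy"}
    unknown = set(config.stages) - known
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if ("fit-kinetics" in config.stages or "anisotropy" in config.stages) \
            and "simulate" not in config.stages:
        raise ValueError("fit-kinetics and anisotropy require the simulate stage")

    table = truth = None
    if "simulate" in config.stages:
        cfg = synthetic.SmtSimConfig(seed=derive_seed(config.seed, "simulate"))
        table, truth = synthetic.generate_smt_trajectories(cfg)
        path = outdir / "trajectories.csv"
        write_trajectories(table, path)
        truth.to_csv(outdir / "trajectories_truth.csv")
        manifest["stages"]["simulate"] = {
            "seed": derive_seed(config.seed, "simulate"),
            "outputs": {"trajectories.csv": _sha256(path)},
            "n_trajectories": int(truth.shape[0]),
        }
        logger.info("simulated %d trajectories", truth.shape[0])

    profile = bins = None
    if "fit-kinetics" in config.stages:
        grid = smt.diffusion_grid(p["grid_min"], p["grid_max"], p["grid_size"])
        profile = smt.estimate_occupancy(
            table, grid, sigma_loc=p["sigma_loc_um"],
            frame_interval=p["frame_interval_s"])
        bins = smt.find_state_boundaries(profile)
        d = smt.assign_trajectory_D(profile.responsibilities.to_numpy(), grid)
        ids = profile.responsibilities.index.to_numpy()
        fields = ids % 5  # synthetic fields of view
        fractions = smt.compute_fractions(d, fields, bins)
        occ_path = outdir / "occupancy.csv"
        pd.DataFrame({"D": grid.values, "occupancy": profile.occupancy}
                     ).to_csv(occ_path, index=False)
        frac_path = outdir / "fractions.csv"
        fractions.per_field.to_csv(frac_path)
        manifest["stages"]["fit-kinetics"] = {
            "boundaries": list(bins.boundaries),
            "mean_fractions": dict(zip(bins.labels, fractions.mean.tolist())),
            "outputs": {"occupancy.csv": _sha256(occ_path),
                        "fractions.csv": _sha256(frac_path)},
        }

    if "anisotropy" in config.stages:
        labeled = table.copy()
        if bins is not None:
            d = smt.assign_trajectory_D(profile.responsibilities.to_numpy(),
                                        profile.grid)
            state_idx = bins.assign(d)
            state_map = dict(zip(profile.responsibilities.index,
                                 [bins.labels[i] for i in state_idx]))
            labeled["state"] = labeled["trajectory"].map(state_map)
        angles = aniso.compute_angles(labeled, min_jump=p["min_jump_um"])
        if angles.n_angles >= 2:
            mean_f, sd_f = aniso.bootstrap_anisotropy(
                angles, seed=derive_seed(config.seed, "anisotropy"))
        else:
            mean_f, sd_f = float("nan"), float("nan")
        ang_path = outdir / "angles.csv"
        pd.DataFrame({"angle_deg": angles.angles}).to_csv(ang_path, index=False)
        manifest["stages"]["anisotropy"] = {
            "n_angles": int(angles.n_angles),
            "fold_anisotropy_mean": mean_f,
            "fold_anisotropy_sd": sd_f,
            "outputs": {"angles.csv": _sha256(ang_path)},
        }

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
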