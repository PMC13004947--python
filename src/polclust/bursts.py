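"""MS2 transcription-spot traces, burst segmentation, and cross-correlation.

Two-channel volumetric movies carry nascent-transcript signal (MCP bound to
MS2 stem loops) and RNAPII signal. Per frame, the MS2 spot is segmented by a
difference of Gaussians, small and extra-nuclear objects are discarded, and
the brightest surviving object per nucleus is tracked. Intensity traces are
read from a 3-slice max projection: RNAPII as the integrated intensity in an
11-pixel (1.2 µm) diameter disc around the spot, normalized to the nuclear
mean; MCP as the brightest 2×2 square. Bursts are intervals between
consecutive local minima of the smoothed MCP trace, kept when longer than
30 s; the loading rate is the slope of the RNAPII rise from burst start to
its maximum. Trace synchrony is quantified by the full normalized discrete
cross-correlation, whose lag-0 value equals the Pearson correlation
coefficient.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "SpotObservation",
    "BurstTrace",
    "Burst",
    "disc_mask",
    "segment_ms2_spot",
    "extract_traces",
    "smooth_trace",
    "segment_bursts",
    "cross_correlate",
    "control_sphere_cc",
]

SPOT_DOG_SIGMAS = (1.5, 6.0)
SPOT_MIN_VOXELS = 6
SPOT_PERCENTILE = 99.9
DISC_DIAMETER_PX = 11            # 1.2 µm at 0.108 µm/px
SMOOTH_WINDOW = 3                # samples (27 s at 9 s cadence)
MIN_BURST_DURATION = 30.0        # s
MINIMA_PROMINENCE_FRAC = 0.05


@dataclasses.dataclass
class SpotObservation:
    frame: int
    nucleus_id: int
    centroid: tuple              # (z, y, x) voxels, weighted centroid
    peak_intensity: float
    missing: bool = False


@dataclasses.dataclass
class BurstTrace:
    time: np.ndarray             # s
    mcp: np.ndarray
    rnapii: np.ndarray           # enrichment over nuclear background
    smoothed: bool = False

    def __post_init__(self):
        t = np.asarray(self.time, float)
        if not (len(t) == len(self.mcp) == len(self.rnapii)):
            raise ValueError("time, mcp and rnapii must have equal lengths")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        self.time = t
        self.mcp = np.asarray(self.mcp, float)
        self.rnapii = np.asarray(self.rnapii, float)


@dataclasses.dataclass
class Burst:
    start: float                 # s
    end: float                   # s
    loading_rate: float          # enrichment per s
    max_rnapii: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def disc_mask(diameter_px: int = DISC_DIAMETER_PX) -> np.ndarray:
    """Boolean disc of the given pixel diameter (center at the middle pixel)."""
    r = diameter_px / 2.0
    c = (diameter_px - 1) / 2.0
    yy, xx = np.mgrid[:diameter_px, :diameter_px]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2


# ---------------------------------------------------------------------------
# spot segmentation
# ---------------------------------------------------------------------------

def segment_ms2_spot(volume: np.ndarray, nuclear_labels: np.ndarray,
                     percentile: float = SPOT_PERCENTILE,
                     sigmas=SPOT_DOG_SIGMAS, min_voxels: int = SPOT_MIN_VOXELS,
                     frame: int = 0) -> list:
    """Locate the MS2 spot in each nucleus of one volume.

    Difference of Gaussians (sigmas 1.5 and 6) → percentile threshold →
    objects below ``min_voxels`` voxels removed → objects outside the
    nuclear labels removed → the brightest object per nucleus kept, located
    at its intensity-weighted centroid. Nuclei without a surviving object
    yield a missing-frame marker.
    """
    if volume.shape != nuclear_labels.shape:
        raise ValueError("volume and nuclear labels must be aligned")
    lo, hi = sigmas
    vol = volume.astype(float)
    dog = ndimage.gaussian_filter(vol, lo) - ndimage.gaussian_filter(vol, hi)
    thr = np.percentile(dog, percentile)
    binary = dog > thr
    objects = sk_label(binary)
    best: dict[int, tuple] = {}
    for rp in regionprops(objects, intensity_image=vol):
        if rp.area < min_voxels:
            continue
        cz, cy, cx = (int(round(c)) for c in rp.centroid)
        nucleus = int(nuclear_labels[cz, cy, cx])
        if nucleus == 0:
            continue
        peak = float(rp.intensity_max)
        if nucleus not in best or peak > best[nucleus][0]:
            best[nucleus] = (peak, rp)
    observations = []
    for nucleus in np.unique(nuclear_labels):
        if nucleus == 0:
            continue
        nucleus = int(nucleus)
        if nucleus in best:
            peak, rp = best[nucleus]
            observations.append(SpotObservation(
                frame=frame, nucleus_id=nucleus,
                centroid=tuple(rp.centroid_weighted), peak_intensity=peak))
        else:
            observations.append(SpotObservation(
                frame=frame, nucleus_id=nucleus, centroid=(np.nan,) * 3,
                peak_intensity=np.nan, missing=True))
    return observations


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def _interpolate_gaps(values: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly fill NaN runs up to ``max_gap`` samples; longer runs stay NaN."""
    out = values.astype(float).copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    idx = np.arange(out.size)
    runs = []
    start = None
    for i, bad in enumerate(isnan):
        if bad and start is None:
            start = i
        elif not bad and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, out.size - 1))
    for s, e in runs:
        if e - s + 1 <= max_gap and s > 0 and e < out.size - 1:
            out[s:e + 1] = np.interp(idx[s:e + 1], [s - 1, e + 1],
                                     [out[s - 1], out[e + 1]])
    return out


def extract_traces(rnapii_stack: np.ndarray, mcp_stack: np.ndarray,
                   spot_track: list, nuclear_mask: np.ndarray,
                   frame_interval: float = 9.0,
                   disc_diameter_px: int = DISC_DIAMETER_PX,
                   smooth: bool = True, max_gap: int = 2) -> BurstTrace:
    """Paired RNAPII/MCP intensity traces around a tracked MS2 spot.

    Per frame: a 3-slice max projection in z centered on the spot's z slice;
    RNAPII = integrated intensity in the 1.2 µm disc around the spot,
    divided by the per-frame nuclear mean (enrichment); MCP = sum of the
    brightest 2×2 square in the disc neighborhood. Missing spot frames are
    linearly interpolated up to ``max_gap`` consecutive samples.
    """
    if rnapii_stack.shape != mcp_stack.shape:
        raise ValueError("channel stacks must share a shape")
    n_frames = rnapii_stack.shape[0]
    if len(spot_track) != n_frames:
        raise ValueError("spot track must cover every frame (gaps as missing)")
    mask2d = nuclear_mask.astype(bool)
    if mask2d.ndim == 3:
        mask2d = mask2d.max(axis=0)
    disc = disc_mask(disc_diameter_px)
    half = disc_diameter_px // 2
    rnapii = np.full(n_frames, np.nan)
    mcp = np.full(n_frames, np.nan)
    clipped = False
    for f in range(n_frames):
        obs = spot_track[f]
        if obs is None or getattr(obs, "missing", False):
            continue
        cz, cy, cx = obs.centroid
        cz, cy, cx = int(round(cz)), int(round(cy)), int(round(cx))
        z0, z1 = max(0, cz - 1), min(rnapii_stack.shape[1], cz + 2)
        proj_r = rnapii_stack[f, z0:z1].max(axis=0).astype(float)
        proj_m = mcp_stack[f, z0:z1].max(axis=0).astype(float)
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        if y0 < 0 or x0 < 0 or y1 > proj_r.shape[0] or x1 > proj_r.shape[1]:
            clipped = True
            yy0, xx0 = max(y0, 0), max(x0, 0)
            yy1, xx1 = min(y1, proj_r.shape[0]), min(x1, proj_r.shape[1])
            sub_r = proj_r[yy0:yy1, xx0:xx1]
            sub_m = proj_m[yy0:yy1, xx0:xx1]
            sub_disc = disc[yy0 - y0:disc.shape[0] - (y1 - yy1),
                            xx0 - x0:disc.shape[1] - (x1 - xx1)]
        else:
            sub_r = proj_r[y0:y1, x0:x1]
            sub_m = proj_m[y0:y1, x0:x1]
            sub_disc = disc
        nuclear_mean = float(proj_r[mask2d].mean())
        rnapii[f] = float(sub_r[sub_disc].sum()) / (nuclear_mean * sub_disc.sum())
        # brightest 2x2 square in the MCP neighborhood
        if min(sub_m.shape) >= 2:
            sums = (sub_m[:-1, :-1] + sub_m[1:, :-1]
                    + sub_m[:-1, 1:] + sub_m[1:, 1:])
            mcp[f] = float(sums.max())
        else:
            mcp[f] = float(sub_m.max())
    if clipped:
        warnings.warn("spot disc clipped at the volume edge", UserWarning,
                      stacklevel=2)
    rnapii = _interpolate_gaps(rnapii, max_gap)
    mcp = _interpolate_gaps(mcp, max_gap)
    time = np.arange(n_frames) * frame_interval
    good = ~(np.isnan(rnapii) | np.isnan(mcp))
    trace = BurstTrace(time=time[good], mcp=mcp[good], rnapii=rnapii[good])
    if smooth:
        trace = BurstTrace(time=trace.time, mcp=smooth_trace(trace.mcp),
                           rnapii=smooth_trace(trace.rnapii), smoothed=True)
    return trace


def smooth_trace(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    v = np.asarray(values, float)
    if v.size < window:
        return v.copy()
    kernel = np.ones(window) / window
    out = np.convolve(v, kernel, mode="same")
    # fix edges where the kernel overhangs
    half = window // 2
    for i in range(half):
        out[i] = v[:i + half + 1].mean()
        out[-(i + 1)] = v[-(i + half + 1):].mean()
    return out


# ---------------------------------------------------------------------------
# burst segmentation
# ---------------------------------------------------------------------------

def segment_bursts(trace: BurstTrace | None = None,
                   min_duration: float = MIN_BURST_DURATION,
                   prominence_frac: float = MINIMA_PROMINENCE_FRAC,
                   time=None, mcp=None, rnapii=None) -> list:
    """Segment bursts between consecutive local minima of the MCP trace.

    Endpoints count as boundaries. Each candidate interval must contain an
    interior rise; bursts not longer than ``min_duration`` are discarded.
    The loading rate is the least-squares slope of the RNAPII trace from the
    burst start to the sample of its maximum.
    """
    if trace is not None:
        time, mcp, rnapii = trace.time, trace.mcp, trace.rnapii
    time = np.asarray(time, float)
    mcp = np.asarray(mcp, float)
    rnapii = np.asarray(rnapii, float)
    if time.size < 5:
        raise ValueError("trace shorter than 5 samples")
    span = float(mcp.max() - mcp.min())
    if span == 0:
        return []
    minima, _ = signal.find_peaks(-mcp, prominence=prominence_frac * span)
    boundaries = np.unique(np.concatenate([[0], minima, [time.size - 1]]))
    bursts = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        if b1 - b0 < 2:
            continue
        seg_m = mcp[b0:b1 + 1]
        peak = int(np.argmax(seg_m))
        # require an actual rise above both boundaries
        if seg_m[peak] <= max(seg_m[0], seg_m[-1]):
            continue
        # trim flat baseline flanks: the burst spans from the last
        # near-baseline sample before the peak to the first one after it
        level = seg_m.min() + prominence_frac * (seg_m.max() - seg_m.min())
        before = np.nonzero(seg_m[:peak + 1] <= level)[0]
        after = np.nonzero(seg_m[peak:] <= level)[0]
        s = int(before[-1]) if before.size else 0
        e = peak + int(after[0]) if after.size else seg_m.size - 1
        i0, i1 = b0 + s, b0 + e
        duration = time[i1] - time[i0]
        if duration <= min_duration:
            continue
        seg_r = rnapii[i0:i1 + 1]
        i_max = int(np.argmax(seg_r))
        if i_max >= 1:
            t_fit = time[i0:i0 + i_max + 1]
            slope = float(np.polyfit(t_fit, seg_r[:i_max + 1], 1)[0])
        else:
            slope = np.nan
        bursts.append(Burst(start=float(time[i0]), end=float(time[i1]),
                            loading_rate=slope, max_rnapii=float(seg_r.max())))
    return bursts


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def cross_correlate(a, b):
    """Full normalized discrete cross-correlation of two equal-length traces.

    Both traces are mean-centered; the correlation is normalized by
    ``n * sd_a * sd_b`` so the lag-0 value equals the Pearson correlation
    coefficient. Positive lags mean b is delayed relative to a. Returns
    ``(lags, cc)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("traces must have equal lengths")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    ac = a - a.mean()
    bc = b - b.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input")
    cc = signal.correlate(bc, ac, mode="full", method="direct") / (n * sa * sb)
    lags = np.arange(-(n - 1), n)
    return lags, cc


def control_sphere_cc(rnapii_stack: np.ndarray, mcp_stack: np.ndarray,
                      spot_track: list, nuclear_mask: np.ndarray,
                      n_controls: int = 10, seed=None,
                      frame_interval: float = 9.0,
                      disc_diameter_px: int = DISC_DIAMETER_PX,
                      max_attempts: int = 1000):
    """Lag-0 correlations of the MCP trace against RNAPII at control regions.

    Control regions are discs of the locus size placed uniformly at random
    within the nuclear mask, not overlapping the tracked locus in any frame.
    Returns the list of lag-0 correlation values (one per control placed);
    fewer than ``n_controls`` placements triggers a warning.
    """
    rng = np.random.default_rng(seed)
    mask2d = nuclear_mask.astype(bool)
    if mask2d.ndim == 3:
        mask2d = mask2d.max(axis=0)
    ys, xs = np.nonzero(mask2d)
    locus_xy = np.array([
        (o.centroid[1], o.centroid[2]) for o in spot_track
        if o is not None and not getattr(o, "missing", False)
    ])
    half = disc_diameter_px // 2
    locus_trace = extract_traces(rnapii_stack, mcp_stack, spot_track,
                                 nuclear_mask, frame_interval,
                                 disc_diameter_px)
    correlations = []
    placed = 0
    attempts = 0
    while placed < n_controls and attempts < max_attempts:
        attempts += 1
        i = rng.integers(ys.size)
        cy, cx = int(ys[i]), int(xs[i])
        if locus_xy.size and np.any(
                np.hypot(locus_xy[:, 0] - cy, locus_xy[:, 1] - cx)
                < disc_diameter_px):
            continue
        if (cy - half < 0 or cx - half < 0
                or cy + half + 1 > mask2d.shape[0]
                or cx + half + 1 > mask2d.shape[1]):
            continue
        control_track = []
        for obs in spot_track:
            if obs is None or getattr(obs, "missing", False):
                control_track.append(obs)
            else:
                control_track.append(SpotObservation(
                    frame=obs.frame, nucleus_id=obs.nucleus_id,
                    centroid=(obs.centroid[0], float(cy), float(cx)),
                    peak_intensity=np.nan))
        ctrace = extract_traces(rnapii_stack, mcp_stack, control_track,
                                nuclear_mask, frame_interval, disc_diameter_px)
        try:
            lags, cc = cross_correlate(locus_trace.mcp, ctrace.rnapii)
        except ValueError:
            continue
        correlations.append(float(cc[lags == 0][0]))
        placed += 1
    if placed < n_controls:
        warnings.warn(f"placed only {placed}/{n_controls} control regions",
                      UserWarning, stacklevel=2)
    return correlations
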