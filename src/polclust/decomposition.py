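"""Bound-fraction decomposition, error propagation, and compositional tests.

The chromatin-bound fraction of RNAPII measured by single-molecule tracking
mixes molecules in different transcription-cycle stages. Blocking initiation
(triptolide) leaves only non-specifically bound molecules; blocking
elongation (α-amanitin) leaves non-specific plus initiating molecules. The
vehicle bound fraction therefore decomposes by subtraction:

    nonspecific = b_triptolide
    initiating  = b_amanitin - b_triptolide
    elongating  = b_vehicle  - b_amanitin

Standard error propagation applies throughout: differences add variances,
ratios add relative variances. Kinetic fractions (bound / intermediate /
fast) live on the simplex, so group comparisons use a centered log-ratio
(CLR) transform before a two-sided Mann-Whitney U test; single components
may be compared on the raw scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Measurement",
    "DecompositionResult",
    "decompose_bound_fraction",
    "fold_change",
    "clr_transform",
    "compare_fractions",
]


@dataclasses.dataclass(frozen=True)
class Measurement:
    """A value with a standard deviation."""

    value: float
    sd: float = 0.0

    def __iter__(self):
        yield self.value
        yield self.sd


def _as_measurement(x) -> Measurement:
    if isinstance(x, Measurement):
        return x
    if np.isscalar(x):
        return Measurement(float(x), 0.0)
    v, s = x
    return Measurement(float(v), float(s))


@dataclasses.dataclass
class DecompositionResult:
    """Bound fraction split into non-specific, initiating, elongating parts."""

    nonspecific: Measurement
    initiating: Measurement
    elongating: Measurement
    label: str | None = None
    negative_components: tuple = ()

    @property
    def total(self) -> float:
        return self.nonspecific.value + self.initiating.value + self.elongating.value


def decompose_bound_fraction(b_vehicle, b_amanitin, b_triptolide,
                             label: str | None = None) -> DecompositionResult:
    """Subtraction decomposition of the vehicle bound fraction.

    Inputs are fractions in [0, 1], given as ``Measurement`` or
    ``(value, sd)`` pairs. The sd of each difference is the quadrature sum of
    the input sds. A negative component (possible when drug effects are
    incomplete or noisy) is returned as-is with its name recorded in
    ``negative_components`` and a warning emitted — never silently clipped.
    """
    bv, ba, bt = (_as_measurement(x) for x in (b_vehicle, b_amanitin, b_triptolide))
    for m in (bv, ba, bt):
        if not 0.0 <= m.value <= 1.0:
            raise ValueError("bound fractions must lie in [0, 1]")
    nonspecific = Measurement(bt.value, bt.sd)
    initiating = Measurement(ba.value - bt.value, float(np.hypot(ba.sd, bt.sd)))
    elongating = Measurement(bv.value - ba.value, float(np.hypot(bv.sd, ba.sd)))
    negative = tuple(
        name for name, m in
        [("nonspecific", nonspecific), ("initiating", initiating),
         ("elongating", elongating)]
        if m.value < 0
    )
    if negative:
        warnings.warn(
            f"negative decomposition component(s): {', '.join(negative)}",
            UserWarning, stacklevel=2,
        )
    return DecompositionResult(nonspecific, initiating, elongating,
                               label=label, negative_components=negative)


def fold_change(a, b) -> Measurement:
    """Ratio a/b with relative-error propagation.

    ``sd_r = r * sqrt((sd_a/a)^2 + (sd_b/b)^2)``; sd terms with a zero
    denominator value are treated as exact only when their sd is also zero.
    """
    ma, mb = _as_measurement(a), _as_measurement(b)
    if mb.value == 0:
        raise ZeroDivisionError("fold change undefined for zero denominator")
    r = ma.value / mb.value
    rel_a = ma.sd / ma.value if ma.value != 0 else 0.0
    rel_b = mb.sd / mb.value
    return Measurement(r, abs(r) * float(np.hypot(rel_a, rel_b)))


# ---------------------------------------------------------------------------
# compositional data analysis
# ---------------------------------------------------------------------------

def clr_transform(composition, zero_replacement: bool = False) -> np.ndarray:
    """Centered log-ratio transform: ``ln(x_i / g(x))`` with g the geometric mean.

    Accepts a 1D composition or a 2D array of row compositions. Rows need not
    be closed to 1 (CLR is scale-invariant). Zero parts are invalid unless
    ``zero_replacement`` is set, in which case each zero is replaced by half
    the smallest nonzero part of its row (multiplicative replacement) before
    the transform.
    """
    x = np.asarray(composition, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x).copy()
    if np.any(x < 0):
        raise ValueError("compositions must be nonnegative")
    zero = x == 0
    if zero.any():
        if not zero_replacement:
            raise ValueError("zero parts require zero_replacement=True")
        for i in range(x.shape[0]):
            row = x[i]
            nz = row[row > 0]
            if nz.size == 0:
                raise ValueError("composition with all parts zero")
            row[row == 0] = 0.5 * nz.min()
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return out[0] if one_d else out


def compare_fractions(group_a: pd.DataFrame, group_b: pd.DataFrame,
                      mode: str = "coda", exact_max_n: int = 10) -> pd.Series:
    """Per-component two-sided rank-sum p-values between two groups of fields.

    Rows are fields of view, columns are kinetic-state fractions. In ``coda``
    mode both tables are CLR-transformed first (with zero replacement); in
    ``raw`` mode the untransformed fractions are tested. The Mann-Whitney U
    test is exact when both groups have at most ``exact_max_n`` fields and no
    ties, otherwise it uses the tie-corrected normal approximation.
    """
    if mode not in ("coda", "raw"):
        raise ValueError("mode must be 'coda' or 'raw'")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need at least 3 fields per group")
    cols = list(group_a.columns)
    if list(group_b.columns) != cols:
        raise ValueError("groups must share the same components")
    a = group_a.to_numpy(float)
    b = group_b.to_numpy(float)
    if mode == "coda":
        a = clr_transform(a, zero_replacement=True)
        b = clr_transform(b, zero_replacement=True)
    pvals = {}
    for j, col in enumerate(cols):
        xa, xb = a[:, j], b[:, j]
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            # fully tied data carries no rank information
            pvals[col] = 1.0
            continue
        ties = np.unique(pooled).size < pooled.size
        small = max(len(xa), len(xb)) <= exact_max_n
        method = "exact" if (small and not ties) else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        pvals[col] = min(1.0, float(res.pvalue))
    return pd.Series(pvals, name="p_value")
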