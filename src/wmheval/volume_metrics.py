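"""Voxel-level overlap metrics and volume agreement.

For a reference segmentation RS and an automated segmentation AS on the same
grid, with TP their voxel-wise intersection:

    DSC         = 2 * TP / (RS + AS)
    sensitivity = TP / RS
    precision   = TP / AS

DSC is the harmonic mean of sensitivity and precision.  Cohort-level
agreement between reference and automated total volumes is quantified with
the intraclass correlation ICC(2,1): two-way random effects, absolute
agreement, single measurement (Shrout & Fleiss).

Degenerate masks follow an explicit missing-value policy: when both masks
are empty the segmentation is perfect (DSC = 1) but sensitivity and
precision are undefined; when exactly one is empty, DSC = 0 and the ratio
whose denominator vanishes is undefined.  Undefined values propagate as NaN
and are excluded (and counted) by :func:`summarize`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import BinaryMask, require_compatible


@dataclass(frozen=True)
class VolumeMetrics:
    """Per-subject voxel-level scores; NaN marks an undefined ratio."""

    rs_vol_ml: float
    as_vol_ml: float
    tp_vol_ml: float
    dsc: float
    sensitivity: float
    precision: float


def volume_overlap(rs: BinaryMask, as_: BinaryMask) -> VolumeMetrics:
    """DSC, sensitivity and precision between reference and automated masks.

    Both masks are expected to be already cluster-filtered.  Computation is
    on voxel counts; volumes are reported in mL via the shared grid.
    """
    require_compatible(rs.grid, as_.grid, "reference and automated masks")
    rs_n = rs.foreground_count
    as_n = as_.foreground_count
    tp_n = int(np.count_nonzero(rs.voxels & as_.voxels))
    vv = rs.grid.voxel_volume_ml

    if rs_n == 0 and as_n == 0:
        dsc, sens, prec = 1.0, math.nan, math.nan
    elif rs_n == 0:
        dsc, sens, prec = 0.0, math.nan, 0.0
    elif as_n == 0:
        dsc, sens, prec = 0.0, 0.0, math.nan
    else:
        dsc = 2.0 * tp_n / (rs_n + as_n)
        sens = tp_n / rs_n
        prec = tp_n / as_n
    return VolumeMetrics(
        rs_vol_ml=rs_n * vv,
        as_vol_ml=as_n * vv,
        tp_vol_ml=tp_n * vv,
        dsc=dsc,
        sensitivity=sens,
        precision=prec,
    )


# ---------------------------------------------------------------------------
# ICC(2,1)


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) with the mean squares of its two-way ANOVA decomposition."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def icc_2_1(pairs: "np.ndarray | list[tuple[float, float]]") -> IccResult:
    """Shrout–Fleiss ICC(2,1) for an n-subjects by k-raters table (k = 2 here).

    Two-way random effects, absolute agreement, single measurement:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the between-subject, between-rater and residual
    mean squares.  A table with zero total variance (identical constant
    ratings) is perfect agreement, ICC = 1.
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("expected an n x k table with k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input must be complete (no missing values)")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"ICC requires at least 3 subjects, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ss_total == 0.0:
        icc = 1.0
    else:
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        icc = 1.0 if denom == 0.0 else (ms_rows - ms_err) / denom
    return IccResult(icc=icc, ms_rows=ms_rows, ms_cols=ms_cols, ms_error=ms_err, n=n, k=k)


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float  # NaN when fewer than 2 values
    n: int
    n_missing: int


def summarize(values) -> SummaryStats:
    """Mean and sample SD (n-1 denominator) over the non-missing values.

    NaN entries are excluded and counted; an all-missing input is an error.
    With a single value the SD is undefined (NaN).
    """
    arr = np.asarray(list(values), dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    n_missing = int(arr.size - finite.size)
    if finite.size == 0:
        raise ValueError("cannot summarize: all values missing")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1)) if finite.size > 1 else math.nan
    return SummaryStats(mean=mean, sd=sd, n=int(finite.size), n_missing=n_missing)
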