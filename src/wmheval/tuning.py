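"""Grid search over scalar segmentation parameters.

Probability maps are binarized by a threshold tuned on a training subset:
every value of an inclusive arithmetic grid (e.g. 0 to 0.95 in steps of
0.05) is applied, the thresholded map is cluster-filtered, and the value
maximizing the mean Dice coefficient against the reference masks is
selected; ties break toward the smaller value for reproducibility.
Thresholding uses a strict comparison (value > t).

Hyperparameters of external tools (a white-matter-mask threshold, the LGA
kappa) are tuned the same way in the abstract: the tuner optimizes over any
family of candidate volumes indexed by a named parameter value; producing
those volumes is the tool's business, not this package's.

``default_thresholds`` records the tuned per-method probability-map
thresholds shipped as configuration defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .components import DEFAULT_MIN_CLUSTER, clean_mask
from .io_core import BinaryMask, ProbabilityVolume, require_compatible
from .volume_metrics import summarize, volume_overlap

#: Tuned probability-map thresholds per method, shipped as defaults.
DEFAULT_PM_THRESHOLDS: dict[str, float] = {
    "BIANCA": 0.60,
    "LST LGA": 0.35,
    "LST LPA": 0.10,
    "LST LPA (T1w+FLAIR)": 0.15,
    "pgs": 0.15,
    "sysu_media (default)": 0.65,
    "sysu_media (retrained)": 0.45,
}


@dataclass(frozen=True)
class GridSpecification:
    """A named scalar parameter with an inclusive arithmetic search grid."""

    name: str
    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.stop < self.start:
            raise ValueError("grid stop must be >= start")

    @property
    def values(self) -> np.ndarray:
        """Inclusive sequence start, start+step, ..., stop (endpoints exact)."""
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        vals = self.start + self.step * np.arange(n)
        return np.round(vals, 9)


#: The standard probability-map threshold grid.
PM_THRESHOLD_GRID = GridSpecification("pm_threshold", 0.0, 0.95, 0.05)
WM_MASK_GRID = GridSpecification("wm_mask_threshold", 0.05, 0.80, 0.05)
KAPPA_GRID = GridSpecification("kappa", 0.10, 0.80, 0.05)


def threshold_probability(p: ProbabilityVolume, t: float) -> BinaryMask:
    """Binarize a probability map: foreground where value > t (strict)."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return BinaryMask(grid=p.grid, voxels=p.values > t)


@dataclass
class TuningResult:
    best_value: float
    objective_per_value: dict[float, tuple[float, float]] = field(repr=False)
    n_subjects: int = 0
    objective: str = "mean_dsc"


def tune_threshold(
    cohort: Sequence[tuple[BinaryMask, ProbabilityVolume]],
    grid: GridSpecification = PM_THRESHOLD_GRID,
    min_size: int = DEFAULT_MIN_CLUSTER,
) -> TuningResult:
    """Select the probability threshold maximizing mean DSC over a cohort.

    For each grid value the probability maps are thresholded, cluster-
    filtered (as are the references, once), and scored against the
    references; the grid value with the highest mean DSC wins, with ties
    resolved toward the smaller value.
    """
    if not cohort:
        raise ValueError("tune_threshold requires a nonempty cohort")
    for rs, p in cohort:
        require_compatible(rs.grid, p.grid, "reference mask and probability map")
    refs = [clean_mask(rs, min_size=min_size) for rs, _ in cohort]

    objective: dict[float, tuple[float, float]] = {}
    best_value: float | None = None
    best_mean = -np.inf
    for t in grid.values:
        t = float(t)
        dscs = []
        for ref, (_, p) in zip(refs, cohort):
            seg = clean_mask(threshold_probability(p, t), min_size=min_size)
            dscs.append(volume_overlap(ref, seg).dsc)
        stats = summarize(dscs)
        objective[t] = (stats.mean, stats.sd)
        if stats.mean > best_mean:  # strict: ties keep the earlier (smaller) value
            best_mean = stats.mean
            best_value = t
    assert best_value is not None
    return TuningResult(best_value=best_value, objective_per_value=objective,
                        n_subjects=len(cohort))


def tune_indexed(
    candidates: dict[float, Sequence[float]],
) -> TuningResult:
    """Tune over precomputed per-value objective samples.

    ``candidates`` maps each parameter value (e.g. a WM-mask threshold or
    kappa already applied by an external tool) to the per-subject DSC values
    obtained with it.  Returns the value with the best mean, smaller value
    on ties.
    """
    if not candidates:
        raise ValueError("no candidate parameter values supplied")
    objective: dict[float, tuple[float, float]] = {}
    best_value: float | None = None
    best_mean = -np.inf
    n = 0
    for value in sorted(candidates):
        stats = summarize(candidates[value])
        objective[float(value)] = (stats.mean, stats.sd)
        n = max(n, stats.n)
        if stats.mean > best_mean:
            best_mean = stats.mean
            best_value = float(value)
    assert best_value is not None
    return TuningResult(best_value=best_value, objective_per_value=objective, n_subjects=n)


def default_thresholds() -> dict[str, float]:
    """Tuned probability-map threshold defaults per method label."""
    return dict(DEFAULT_PM_THRESHOLDS)


def default_threshold_for(method_label: str) -> float:
    try:
        return DEFAULT_PM_THRESHOLDS[method_label]
    except KeyError:
        raise KeyError(
            f"no default threshold recorded for method {method_label!r}; "
            f"known methods: {sorted(DEFAULT_PM_THRESHOLDS)}"
        ) from None
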