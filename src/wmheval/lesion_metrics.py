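"""Lesion-level detection metrics under a double overlap criterion.

A reference lesion r counts as detected (a true positive, TP_lesion) if some
automated lesion a overlaps it in at least ``min_rs_fraction`` of r's voxels
(default 10%) while that overlap covers at most ``max_as_fraction`` of a's
voxels (default 70%).

The second clause admits two readings, both implemented:

* ``literal``  — overlap / |a| <= max_as_fraction, the rule exactly as
  stated.  Note this excludes automated lesions lying entirely inside a
  reference lesion (overlap/|a| = 1), so identical masks do not self-match.
* ``outside``  — (|a| - overlap) / |a| <= max_as_fraction, i.e. at most 70%
  of the automated lesion lies outside the reference lesion (the
  Commowick-style reading).  Identical masks self-match under this rule.

Matching is many-to-many: one automated lesion may validate several
reference lesions and vice versa; TP_lesion is counted on the reference
side.  Consequently precision = TP/AS is reported unclamped and may exceed
1 in pathological cases (a warning is logged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .components import LesionSet
from .io_core import logger, require_compatible

LITERAL = "literal"
OUTSIDE = "outside"


@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds of the double overlap rule; defaults reproduce the stated rule."""

    min_rs_fraction: float = 0.10
    max_as_fraction: float = 0.70
    interpretation: str = LITERAL

    def __post_init__(self) -> None:
        if not (0.0 < self.min_rs_fraction <= 1.0):
            raise ValueError("min_rs_fraction must be in (0, 1]")
        if not (0.0 < self.max_as_fraction <= 1.0):
            raise ValueError("max_as_fraction must be in (0, 1]")
        if self.interpretation not in (LITERAL, OUTSIDE):
            raise ValueError(f"interpretation must be {LITERAL!r} or {OUTSIDE!r}")


@dataclass(frozen=True)
class MatchedPair:
    rs_id: int
    as_id: int
    overlap_voxels: int
    rs_size: int
    as_size: int


@dataclass
class LesionMatchResult:
    detected_rs_ids: frozenset[int]
    matched_pairs: tuple[MatchedPair, ...] = field(repr=False)
    rs_count: int = 0
    as_count: int = 0

    @property
    def tp_lesion(self) -> int:
        return len(self.detected_rs_ids)


def _overlap_pairs(rs: LesionSet, as_: LesionSet) -> list[tuple[int, int, int]]:
    """(rs_id, as_id, overlap voxel count) for every overlapping lesion pair."""
    a = rs.label_volume
    b = as_.label_volume
    both = (a > 0) & (b > 0)
    if not both.any():
        return []
    ra = a[both].astype(np.int64)
    rb = b[both].astype(np.int64)
    width = int(b.max()) + 1
    codes = ra * width + rb
    uniq, counts = np.unique(codes, return_counts=True)
    return [(int(c // width), int(c % width), int(n)) for c, n in zip(uniq, counts)]


def pair_qualifies(overlap: int, rs_size: int, as_size: int, c: MatchCriteria) -> bool:
    """Apply the double overlap rule to a single (reference, automated) pair."""
    if overlap / rs_size < c.min_rs_fraction:
        return False
    if c.interpretation == LITERAL:
        return overlap / as_size <= c.max_as_fraction
    return (as_size - overlap) / as_size <= c.max_as_fraction


def match_lesions(rs: LesionSet, as_: LesionSet, c: MatchCriteria = MatchCriteria()) -> LesionMatchResult:
    """Detect reference lesions under the double overlap criterion."""
    require_compatible(rs.grid, as_.grid, "reference and automated lesion sets")
    rs_sizes = {l.lesion_id: l.size for l in rs.lesions}
    as_sizes = {l.lesion_id: l.size for l in as_.lesions}
    pairs: list[MatchedPair] = []
    detected: set[int] = set()
    for rid, aid, ov in _overlap_pairs(rs, as_):
        if pair_qualifies(ov, rs_sizes[rid], as_sizes[aid], c):
            pairs.append(MatchedPair(rid, aid, ov, rs_sizes[rid], as_sizes[aid]))
            detected.add(rid)
    return LesionMatchResult(
        detected_rs_ids=frozenset(detected),
        matched_pairs=tuple(sorted(pairs, key=lambda p: (p.rs_id, p.as_id))),
        rs_count=rs.count,
        as_count=as_.count,
    )


@dataclass(frozen=True)
class LesionMetrics:
    """Lesion-count scores; NaN marks an undefined ratio."""

    f1: float
    sensitivity: float
    precision: float
    tp_lesion: int
    rs_count: int
    as_count: int


def lesion_scores(m: LesionMatchResult) -> LesionMetrics:
    """Lesion F1 = 2 TP / (RS + AS), sensitivity = TP/RS, precision = TP/AS.

    The empty-count policy mirrors the voxel-level one: both counts zero is
    perfect (F1 = 1, ratios undefined); a zero denominator leaves that ratio
    undefined.
    """
    tp, rs_n, as_n = m.tp_lesion, m.rs_count, m.as_count
    if rs_n == 0 and as_n == 0:
        f1, sens, prec = 1.0, math.nan, math.nan
    elif rs_n == 0:
        f1, sens, prec = 0.0, math.nan, tp / as_n
    elif as_n == 0:
        f1, sens, prec = 0.0, tp / rs_n, math.nan
    else:
        f1 = 2.0 * tp / (rs_n + as_n)
        sens = tp / rs_n
        prec = tp / as_n
    if prec == prec and prec > 1.0:  # many-to-many matching can overshoot
        logger.warning("lesion precision %.3f exceeds 1 (TP=%d, AS=%d); reported unclamped",
                       prec, tp, as_n)
    return LesionMetrics(f1=f1, sensitivity=sens, precision=prec,
                         tp_lesion=tp, rs_count=rs_n, as_count=as_n)
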