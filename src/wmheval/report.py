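"""Cohort-level evaluation and reporting.

Runs the full per-subject evaluation (cluster filter -> voxel metrics ->
lesion matching -> optional regional metrics) over a cohort manifest and
aggregates the per-subject rows into the standard reporting structures:

* a long-format cohort table, one row per (subject, method, region, metric);
* mean +/- SD summary tables per method/region/metric with best-per-column
  flags and an ICC(2,1) of global volumes per method;
* low/high-burden subgroup summaries from an extreme split on reference
  volume (the k smallest vs the k largest subjects, middle excluded);
* qualitative categories: excellent (> 0.90), good (0.75-0.90, endpoints
  included), moderate (0.50 to < 0.75), poor (< 0.50).

Report regeneration is byte-identical across runs given identical inputs:
rows are sorted deterministically and floats serialized with a fixed format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import components, lesion_metrics, tuning, volume_metrics
from .io_core import (
    BinaryMask,
    CohortManifest,
    load_mask,
    load_probability,
    logger,
)
from .lesion_metrics import MatchCriteria
from .regional import Parcellation, load_parcellation, regional_report

GLOBAL_REGION = "global"
VOLUME_METRIC_NAMES = ("dsc", "sensitivity", "precision", "rs_vol_ml", "as_vol_ml", "tp_vol_ml")
LESION_METRIC_NAMES = ("lesion_f1", "lesion_sensitivity", "lesion_precision",
                       "tp_lesion", "rs_lesion_count", "as_lesion_count")
#: Metrics whose per-method column gets a best-performance flag.
FLAGGED_METRICS = ("dsc", "sensitivity", "precision",
                   "lesion_f1", "lesion_sensitivity", "lesion_precision")
CSV_FLOAT_FORMAT = "%.10g"


def categorize(value: float) -> str:
    """Qualitative performance category of an agreement/overlap score.

    excellent above 0.90; good from 0.75 to 0.90 inclusive; moderate from
    0.50 up to (not including) 0.75; poor below 0.50.
    """
    if value != value:  # NaN
        return "missing"
    if value > 0.90:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.50:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class BurdenSplit:
    """Extreme split of a cohort by reference lesion load."""

    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]


def split_by_burden(volumes: Sequence[tuple[str, float]], k: int) -> BurdenSplit:
    """k lowest-burden vs k highest-burden subjects; the middle is excluded.

    Ties in volume break by subject id, so the split does not depend on
    input order.
    """
    n = len(volumes)
    if k < 1 or 2 * k > n:
        raise ValueError(f"need 2k <= n subjects for a burden split, got k={k}, n={n}")
    order = sorted(volumes, key=lambda sv: (sv[1], sv[0]))
    ids = [s for s, _ in order]
    return BurdenSplit(
        low_ids=tuple(sorted(ids[:k])),
        high_ids=tuple(sorted(ids[n - k:])),
        excluded_ids=tuple(sorted(ids[k:n - k])),
    )


def default_burden_k(n: int) -> int:
    """Default subgroup size: the extreme terciles (floor(n/3) each side)."""
    return max(1, n // 3)


# ---------------------------------------------------------------------------
# Per-subject evaluation


def evaluate_masks(
    rs: BinaryMask,
    as_: BinaryMask,
    parcellation: Parcellation | None = None,
    min_cluster: int = components.DEFAULT_MIN_CLUSTER,
    criteria: MatchCriteria = MatchCriteria(),
    filter_reference: bool = True,
) -> dict[str, dict[str, float]]:
    """Evaluate one subject; returns {region: {metric: value}}.

    Both maps get the minimum-cluster-size filter before any metric (the
    reference filter can be disabled for sensitivity analyses).  Lesion
    metrics are global only; regional rows carry voxel metrics.
    """
    rs_ls = components.label_components(rs)
    if filter_reference:
        rs_ls = components.filter_small(rs_ls, min_size=min_cluster)
    as_ls = components.filter_small(components.label_components(as_), min_size=min_cluster)
    rs_f = components.lesionset_to_mask(rs_ls)
    as_f = components.lesionset_to_mask(as_ls)

    vm = volume_metrics.volume_overlap(rs_f, as_f)
    lm = lesion_metrics.lesion_scores(lesion_metrics.match_lesions(rs_ls, as_ls, criteria))

    out: dict[str, dict[str, float]] = {
        GLOBAL_REGION: {
            "dsc": vm.dsc,
            "sensitivity": vm.sensitivity,
            "precision": vm.precision,
            "rs_vol_ml": vm.rs_vol_ml,
            "as_vol_ml": vm.as_vol_ml,
            "tp_vol_ml": vm.tp_vol_ml,
            "lesion_f1": lm.f1,
            "lesion_sensitivity": lm.sensitivity,
            "lesion_precision": lm.precision,
            "tp_lesion": float(lm.tp_lesion),
            "rs_lesion_count": float(lm.rs_count),
            "as_lesion_count": float(lm.as_count),
        }
    }
    if parcellation is not None:
        for region, rvm in regional_report(rs_f, as_f, parcellation):
            out[region] = {
                "dsc": rvm.dsc,
                "sensitivity": rvm.sensitivity,
                "precision": rvm.precision,
                "rs_vol_ml": rvm.rs_vol_ml,
                "as_vol_ml": rvm.as_vol_ml,
                "tp_vol_ml": rvm.tp_vol_ml,
            }
    return out


def evaluate_cohort(
    manifest: CohortManifest,
    min_cluster: int = components.DEFAULT_MIN_CLUSTER,
    criteria: MatchCriteria = MatchCriteria(),
    pm_threshold: float | None = None,
) -> pd.DataFrame:
    """Evaluate every manifest row; returns the long-format cohort table.

    Probability-map predictions are binarized with ``pm_threshold`` if
    given, else with the method's recorded default threshold.
    """
    records: list[dict] = []
    for row in manifest.rows:
        rs = load_mask(row.reference_path)
        if row.prediction_kind == "probability":
            t = pm_threshold if pm_threshold is not None else tuning.default_threshold_for(row.method_label)
            as_ = tuning.threshold_probability(load_probability(row.prediction_path), t)
        else:
            as_ = load_mask(row.prediction_path)
        parc = None
        if row.parcellation_path:
            parc = load_parcellation(row.parcellation_path,
                                     _sibling_region_table(row.parcellation_path))
        logger.info("evaluating subject %s / method %s", row.subject_id, row.method_label)
        per_region = evaluate_masks(rs, as_, parcellation=parc,
                                    min_cluster=min_cluster, criteria=criteria)
        for region, metrics in per_region.items():
            for metric, value in metrics.items():
                records.append({
                    "subject_id": row.subject_id,
                    "method_label": row.method_label,
                    "region": region,
                    "metric_name": metric,
                    "value": value,
                })
    table = pd.DataFrame.from_records(records)
    return sort_cohort_table(table)


def _sibling_region_table(parcellation_path: str) -> str:
    """Region-table CSV conventionally sits next to the label volume."""
    p = Path(parcellation_path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return str(p.with_name(stem + "_regions.csv"))


def sort_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    keys = ["method_label", "region", "metric_name", "subject_id"]
    return table.sort_values(keys, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Aggregation


def _cell_summaries(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (method, region, metric), grp in table.groupby(
        ["method_label", "region", "metric_name"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        if np.isfinite(vals).sum() == 0:
            mean, sd, n, miss = np.nan, np.nan, 0, int(len(vals))
        else:
            s = volume_metrics.summarize(vals)
            mean, sd, n, miss = s.mean, s.sd, s.n, s.n_missing
        rows.append({
            "method_label": method, "region": region, "metric_name": metric,
            "mean": mean, "sd": sd, "n": n, "n_missing": miss,
            "category": categorize(mean) if metric in FLAGGED_METRICS else "",
        })
    return pd.DataFrame(rows)


def method_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (method, region, metric), ICC per method, best flags.

    The ICC(2,1) is computed from the paired global reference/automated
    volumes of each method and appended as metric ``icc`` with its
    category.  For each overlap metric the method with the best mean in a
    region is flagged ``best=True`` (the table's "bold" marker).
    """
    if table.empty:
        raise ValueError("empty cohort table")
    summary = _cell_summaries(table)

    # ICC per method from global volume pairs
    icc_rows = []
    for method, grp in table[table["region"] == GLOBAL_REGION].groupby("method_label", sort=True):
        wide = grp.pivot_table(index="subject_id", columns="metric_name", values="value")
        if {"rs_vol_ml", "as_vol_ml"} <= set(wide.columns) and len(wide) >= 3:
            pairs = wide[["rs_vol_ml", "as_vol_ml"]].dropna().to_numpy()
            icc = volume_metrics.icc_2_1(pairs).icc
            icc_rows.append({
                "method_label": method, "region": GLOBAL_REGION, "metric_name": "icc",
                "mean": icc, "sd": np.nan, "n": len(pairs), "n_missing": 0,
                "category": categorize(icc),
            })
    if icc_rows:
        summary = pd.concat([summary, pd.DataFrame(icc_rows)], ignore_index=True)

    summary["best"] = False
    flagged = summary["metric_name"].isin(FLAGGED_METRICS + ("icc",))
    for (region, metric), grp in summary[flagged].groupby(["region", "metric_name"]):
        if grp["mean"].notna().any():
            summary.loc[grp["mean"].idxmax(), "best"] = True
    return summary.sort_values(["region", "metric_name", "method_label"],
                               kind="mergesort").reset_index(drop=True)


def burden_summary(table: pd.DataFrame, split: BurdenSplit) -> pd.DataFrame:
    """Mean +/- SD per (subgroup, method, metric) on global rows."""
    g = table[table["region"] == GLOBAL_REGION]
    frames = []
    for name, ids in (("low", split.low_ids), ("high", split.high_ids)):
        sub = _cell_summaries(g[g["subject_id"].isin(ids)])
        sub.insert(0, "subgroup", name)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def reference_volumes(table: pd.DataFrame, method_label: str | None = None) -> list[tuple[str, float]]:
    """Per-subject global reference volume (mL) extracted from the table."""
    g = table[(table["region"] == GLOBAL_REGION) & (table["metric_name"] == "rs_vol_ml")]
    if method_label is not None:
        g = g[g["method_label"] == method_label]
    else:
        g = g.drop_duplicates("subject_id")
    return [(str(r.subject_id), float(r.value)) for r in g.itertuples()]


# ---------------------------------------------------------------------------
# Output


def write_report(
    table: pd.DataFrame,
    out_dir: str | Path,
    burden_k: int | None = None,
    criteria: MatchCriteria = MatchCriteria(),
) -> dict[str, Path]:
    """Write the cohort table, summary, burden summary and a text report.

    Outputs are deterministic: identical inputs give byte-identical files.
    Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = sort_cohort_table(table)
    summary = method_summary(table)

    vols = reference_volumes(table)
    k = burden_k if burden_k is not None else default_burden_k(len(vols))
    paths: dict[str, Path] = {}

    paths["cohort"] = out_dir / "cohort_long.csv"
    table.to_csv(paths["cohort"], index=False, float_format=CSV_FLOAT_FORMAT)
    paths["summary"] = out_dir / "summary.csv"
    summary.to_csv(paths["summary"], index=False, float_format=CSV_FLOAT_FORMAT)

    lines = [
        "WMH segmentation evaluation report",
        f"subjects: {len(vols)}; methods: {sorted(table['method_label'].unique())}",
        f"lesion-matching rule: {criteria.interpretation} "
        f"(min RS overlap {criteria.min_rs_fraction:.2f}, max AS coverage {criteria.max_as_fraction:.2f})",
        "",
    ]
    if 2 * k <= len(vols):
        split = split_by_burden(vols, k)
        bsum = burden_summary(table, split)
        paths["burden"] = out_dir / "burden_summary.csv"
        bsum.to_csv(paths["burden"], index=False, float_format=CSV_FLOAT_FORMAT)
        lines.append(f"burden split: {len(split.low_ids)} low / {len(split.high_ids)} high / "
                     f"{len(split.excluded_ids)} excluded")
        lines.append("")

    for row in summary[(summary["region"] == GLOBAL_REGION)
                       & summary["metric_name"].isin(("dsc", "lesion_f1", "icc"))].itertuples():
        sd = "" if row.sd != row.sd else f" +/- {row.sd:.3f}"
        cat = f" [{row.category}]" if row.category else ""
        lines.append(f"{row.method_label:30s} {row.metric_name:10s} {row.mean:.3f}{sd}{cat}")
    paths["text"] = out_dir / "report.txt"
    paths["text"].write_text("\n".join(lines) + "\n")
    return paths
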