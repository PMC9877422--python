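"""Seeded synthetic cohorts for exercising the evaluation pipeline.

Real WMH evaluation data are reference masks drawn by a rater, automated
masks or probability maps from segmentation tools, and a parcellation.
None of that ships with this package, so this module generates cohorts
with the same statistical structure:

* reference masks: tens of compact blob lesions (random ellipsoids) placed
  disjointly inside an ellipsoidal brain support, with per-subject total
  loads spread geometrically so that the extreme terciles of the cohort hit
  configurable group-mean targets (defaults 1.65 and 20.22 mL);
* automated masks: the reference degraded by rigid displacement, boundary
  dilation/erosion, size-biased dropping of small lesions, and insertion of
  false-positive clusters — the error modes of real tools;
* probability maps: a smoothed indicator of the degraded mask, rescaled so
  that binarizing at a planted threshold recovers it, which gives the
  threshold tuner a known optimum;
* a toy parcellation splitting the brain support into contiguous,
  equal-volume slabs with the six canonical region names.

Everything is deterministic under (seed, subject_index): each subject owns
named random sub-streams (burden, placement, degradation, false positives),
so toggling one degradation never shifts the others.  All geometry is
integer; the only floating step (Gaussian smoothing) is quantized before
any threshold comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .components import STRUCTURE_26, label_components
from .io_core import (
    BinaryMask,
    CohortManifest,
    ManifestRow,
    ProbabilityVolume,
    VoxelGrid,
    save_mask,
    save_label_volume,
    save_probability,
    write_manifest,
)
from .regional import CANONICAL_REGIONS, Parcellation

_STREAMS = {"burden": 11, "placement": 12, "degradation": 13, "fp": 14}
#: Probability maps are quantized to this many decimals before thresholding.
PROB_QUANT_DECIMALS = 4


@dataclass(frozen=True)
class DegradationConfig:
    """How an automated segmentation deviates from the reference.

    boundary_dilate_erode > 0 dilates (over-segmentation), < 0 erodes;
    displacement_vox shifts the whole mask rigidly; lesions smaller than
    ``small_size_vox`` are dropped with probability ``p_miss_small`` (larger
    ones with probability scaled down by small_size/size); ``fp_rate`` is
    the expected number of inserted false-positive clusters per subject.
    """

    boundary_dilate_erode: int = 0
    displacement_vox: tuple[int, int, int] = (1, 0, 0)
    p_miss_small: float = 0.3
    small_size_vox: int = 30
    fp_rate: float = 5.0
    fp_radius_mean_vox: float = 1.8
    prob_map_smoothing: float = 1.0
    prob_map_noise_vox: float = 0.5
    planted_threshold: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_miss_small <= 1.0):
            raise ValueError("p_miss_small must be a probability")
        if not (0.0 < self.planted_threshold < 1.0):
            raise ValueError("planted_threshold must lie strictly inside (0, 1)")
        if self.fp_rate < 0 or self.prob_map_smoothing < 0:
            raise ValueError("rates and smoothing must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate the evaluation setting this package targets: 30
    subjects on a scaled-down 64^3 grid at 1.75 mm isotropic, ~40 lesions
    per subject (Poisson), log-normal lesion radii rescaled per subject so
    the cohort's low/high extreme terciles average ``burden_range_ml``
    (defaults 1.65 and 20.22 mL, spanning sub-mL to tens-of-mL loads).
    """

    n_subjects: int = 30
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.75, 1.75, 1.75)
    lesions_per_subject: float = 40.0  # Poisson mean
    lesion_radius_log_mu: float = math.log(2.0)
    lesion_radius_log_sigma: float = 0.55
    burden_range_ml: tuple[float, float] = (1.65, 20.22)
    burden_jitter_sigma: float = 0.10
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.lesions_per_subject <= 0 or self.lesion_radius_log_sigma <= 0:
            raise ValueError("distribution parameters must be positive")
        lo, hi = self.burden_range_ml
        if not (0 < lo <= hi):
            raise ValueError("burden targets must be positive with low <= high")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.grid_shape, voxel_size=self.voxel_size_mm,
                         orientation="RAS")


def subject_rng(cfg_seed: int, subject_index: int, stream: str) -> np.random.Generator:
    """Named, independent random stream for one subject."""
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg_seed) & 0x7FFFFFFF, subject_index, _STREAMS[stream]])
    )


# ---------------------------------------------------------------------------
# Brain support and burden profile


def brain_support(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' support occupying ~90% of each axis."""
    axes = [np.arange(s, dtype=np.float64) - (s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0


def _tercile_ratio(b: float, n: int) -> float:
    p = (np.arange(n) + 0.5) / n
    v = np.exp(b * p)
    k = max(1, n // 3)
    return float(v[-k:].mean() / v[:k].mean())


def burden_targets(cfg: SyntheticConfig) -> np.ndarray:
    """Per-subject target loads (mL), geometric spread + seeded jitter.

    Deterministic in (cfg.seed, n): an exponential profile exp(b*p) over
    cohort quantiles is calibrated by bisection so that the means of its
    extreme terciles sit at the configured low/high targets, then each
    subject gets a small log-normal jitter and the profile is randomly
    assigned to subject indices.
    """
    n = cfg.n_subjects
    lo, hi = cfg.burden_range_ml
    if n < 3 or hi / lo < 1.0000001:
        profile = np.full(n, (lo + hi) / 2.0)
    else:
        target = hi / lo
        b_lo, b_hi = 1e-6, 60.0
        for _ in range(80):
            b_mid = 0.5 * (b_lo + b_hi)
            if _tercile_ratio(b_mid, n) < target:
                b_lo = b_mid
            else:
                b_hi = b_mid
        b = 0.5 * (b_lo + b_hi)
        p = (np.arange(n) + 0.5) / n
        profile = np.exp(b * p)
        k = max(1, n // 3)
        profile *= lo / profile[:k].mean()
    rng = subject_rng(cfg.seed, 0, "burden")
    jitter = np.exp(rng.normal(0.0, cfg.burden_jitter_sigma, size=n)
                    - cfg.burden_jitter_sigma ** 2 / 2.0)
    perm = rng.permutation(n)
    return (profile * jitter)[perm]


# ---------------------------------------------------------------------------
# Lesion geometry


def _ellipsoid_voxels(center: np.ndarray, radii: np.ndarray,
                      shape: tuple[int, int, int]) -> tuple[np.ndarray, ...] | None:
    """Integer voxel indices of an axis-aligned ellipsoid clipped to the grid."""
    lo = np.maximum(np.floor(center - radii).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii).astype(int), np.array(shape) - 1)
    if np.any(lo > hi):
        return None
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d = (((zz - center[0]) / radii[0]) ** 2
         + ((yy - center[1]) / radii[1]) ** 2
         + ((xx - center[2]) / radii[2]) ** 2)
    inside = d <= 1.0
    if not inside.any():
        # guarantee at least the rounded centre voxel
        c = np.clip(np.round(center).astype(int), 0, np.array(shape) - 1)
        return (np.array([c[0]]), np.array([c[1]]), np.array([c[2]]))
    return (zz[inside].ravel(), yy[inside].ravel(), xx[inside].ravel())


def _place_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    support: np.ndarray,
    radii_list: list[np.ndarray],
    occupancy: np.ndarray,
) -> np.ndarray:
    """Place blobs disjointly (with a 1-voxel Chebyshev gap) inside support.

    Mutates and returns ``occupancy``.  Early attempts keep each blob clear
    of the support edge (so it is not clipped and the realized load tracks
    its target); late attempts fall back to edge-clipped placement.  A blob
    that cannot be placed in 150 attempts is skipped.
    """
    support_idx = np.argwhere(support)
    edge_dist = ndimage.distance_transform_edt(support)
    for radii in radii_list:
        rmax = float(np.max(radii))
        placed = False
        for attempt in range(150):
            center = support_idx[rng.integers(len(support_idx))].astype(np.float64)
            if attempt < 100 and edge_dist[tuple(center.astype(int))] + 0.5 < rmax:
                continue
            vox = _ellipsoid_voxels(center, radii, shape)
            if vox is None:
                continue
            inside = support[vox]
            if not inside.all():
                vox = tuple(v[inside] for v in vox)
                if vox[0].size == 0:
                    continue
            # 1-voxel gap: check the blob's dilated footprint against occupancy
            lo = np.maximum(np.array([v.min() for v in vox]) - 1, 0)
            hi = np.minimum(np.array([v.max() for v in vox]) + 1, np.array(shape) - 1)
            patch = np.zeros(tuple(hi - lo + 1), dtype=bool)
            patch[tuple(v - l for v, l in zip(vox, lo))] = True
            grown = ndimage.binary_dilation(patch, structure=STRUCTURE_26)
            occ_patch = occupancy[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
            if (grown & occ_patch).any():
                continue
            occupancy[vox] = True
            placed = True
            break
        if not placed:
            continue
    return occupancy


def generate_reference(cfg: SyntheticConfig, subject_index: int) -> BinaryMask:
    """Reference lesion mask for one subject, deterministic in (seed, index)."""
    if subject_index >= cfg.n_subjects or subject_index < 0:
        raise IndexError(f"subject_index {subject_index} outside cohort of {cfg.n_subjects}")
    shape = cfg.grid_shape
    if any(s < 16 for s in shape):
        raise ValueError("grid too small for lesion synthesis (need >= 16 voxels per axis)")
    rng = subject_rng(cfg.seed, subject_index, "placement")
    target_ml = burden_targets(cfg)[subject_index]
    target_vox = target_ml / cfg.grid.voxel_volume_ml

    n_lesions = max(1, int(rng.poisson(cfg.lesions_per_subject)))
    base_r = rng.lognormal(cfg.lesion_radius_log_mu, cfg.lesion_radius_log_sigma, size=n_lesions)
    aniso = rng.uniform(0.7, 1.3, size=(n_lesions, 3))
    radii = base_r[:, None] * aniso
    # rescale radii so the summed ellipsoid volume matches the burden target
    vol = (4.0 / 3.0) * np.pi * np.prod(radii, axis=1)
    scale = (target_vox / vol.sum()) ** (1.0 / 3.0)
    radii = np.maximum(radii * scale, 0.62)  # keep every lesion at least one voxel

    support = brain_support(shape)
    occupancy = np.zeros(shape, dtype=bool)
    # place large lesions first: improves packing at high loads
    order = np.argsort(-np.prod(radii, axis=1), kind="stable")
    _place_blobs(rng, shape, support, [radii[i] for i in order], occupancy)
    return BinaryMask(grid=cfg.grid, voxels=occupancy)


# ---------------------------------------------------------------------------
# Degradation


def _shift_mask(vox: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Rigid integer shift with zero fill (voxels shifted off the grid vanish)."""
    out = np.zeros_like(vox)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(offset):
        n = vox.shape[ax]
        if abs(off) >= n:
            return out
        if off >= 0:
            src[ax] = slice(0, n - off)
            dst[ax] = slice(off, n)
        else:
            src[ax] = slice(-off, n)
            dst[ax] = slice(0, n + off)
    out[tuple(dst)] = vox[tuple(src)]
    return out


def degrade(rs: BinaryMask, d: DegradationConfig,
            rng: np.random.Generator) -> BinaryMask:
    """Automated-segmentation emulator.

    Applies, in order: rigid displacement, boundary dilation/erosion,
    size-biased dropping of (mostly small) lesions, and false-positive
    cluster insertion.
    """
    vox = rs.voxels.copy()
    if any(d.displacement_vox):
        vox = _shift_mask(vox, d.displacement_vox)
    k = d.boundary_dilate_erode
    if k > 0:
        vox = ndimage.binary_dilation(vox, structure=STRUCTURE_26, iterations=k)
    elif k < 0:
        vox = ndimage.binary_erosion(vox, structure=STRUCTURE_26, iterations=-k)

    if d.p_miss_small > 0 and vox.any():
        ls = label_components(BinaryMask(grid=rs.grid, voxels=vox))
        drop = np.zeros(ls.count + 1, dtype=bool)
        for lesion in ls.lesions:
            if lesion.size < d.small_size_vox:
                p = d.p_miss_small
            else:
                p = d.p_miss_small * d.small_size_vox / lesion.size
            drop[lesion.lesion_id] = rng.random() < p
        vox = vox & ~drop[ls.label_volume]

    if d.fp_rate > 0:
        n_fp = int(rng.poisson(d.fp_rate))
        if n_fp:
            support = brain_support(rs.grid.shape)
            radii = [rng.lognormal(math.log(d.fp_radius_mean_vox), 0.4) * rng.uniform(0.7, 1.3, 3)
                     for _ in range(n_fp)]
            vox = _place_blobs(rng, rs.grid.shape, support, radii, vox)
    return BinaryMask(grid=rs.grid, voxels=vox)


def make_probability_map(rs: BinaryMask, d: DegradationConfig,
                         rng: np.random.Generator) -> ProbabilityVolume:
    """Probability-map emulator with a planted optimal threshold.

    The degraded mask is turned into a smooth confidence ramp from its
    signed distance transform (positive inside).  The integer-valued
    distance field is Gaussian-smoothed — smoothing a signed-distance ramp
    leaves its zero level essentially on the mask boundary while creating
    continuous sub-voxel gradation across it — perturbed by per-voxel
    uniform noise of half-width ``prob_map_noise_vox`` (tool uncertainty at
    the boundary), and mapped through p = logistic(sd / w) with
    w = ``prob_map_smoothing`` voxels.  The 0.5 level of p is then the mask
    boundary, and the monotone power map p -> p**(ln t*/ln 0.5) moves that
    level to the planted threshold t* while preserving level-set ordering;
    other thresholds erode or dilate the mask by a distance offset and
    score strictly worse.  Values are quantized to 1e-4 before any
    downstream comparison, keeping thresholding platform-stable.

    A net boundary dilation/erosion is deliberately zeroed here: a constant
    boundary offset is exactly the error a tuned threshold absorbs, so
    keeping it would move the Dice-optimal threshold away from the planted
    one.  Displacement, lesion dropping and false positives — errors no
    threshold can undo — are kept.
    """
    m = degrade(rs, replace(d, boundary_dilate_erode=0), rng)
    inside = m.voxels
    sd = np.zeros(inside.shape, dtype=np.float64)
    if inside.any():
        sd[inside] = ndimage.distance_transform_edt(inside)[inside] - 0.5
        sd[~inside] = 0.5 - ndimage.distance_transform_edt(~inside)[~inside]
    else:
        sd -= float(max(inside.shape))
    if d.prob_map_smoothing > 0:
        # light smoothing: bridges the integer distance shells without the
        # curvature shrink a stronger kernel would impose on small lesions
        sd = ndimage.gaussian_filter(sd, sigma=0.35 * d.prob_map_smoothing)
    if d.prob_map_noise_vox > 0:
        # boundary noise grows with ramp width: blurrier maps are less certain
        a = d.prob_map_noise_vox * max(d.prob_map_smoothing, 1e-6)
        sd = sd + rng.uniform(-a, a, size=sd.shape)
    w = max(d.prob_map_smoothing, 1e-6)
    p = 1.0 / (1.0 + np.exp(-sd / w))
    alpha = math.log(d.planted_threshold) / math.log(0.5)
    p = np.power(np.clip(p, 0.0, 1.0), alpha)
    p = np.round(p, PROB_QUANT_DECIMALS)
    return ProbabilityVolume(grid=rs.grid, values=p)


# ---------------------------------------------------------------------------
# Parcellation and cohort assembly


def make_toy_parcellation(grid: VoxelGrid, n_regions: int = 6) -> Parcellation:
    """Partition the brain support into contiguous equal-volume slabs.

    With n_regions = 6 the slabs take the six canonical region names; the
    slabs cover the support exactly, so regional conservation holds for any
    mask inside the support.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    support = brain_support(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int16)
    counts = support.sum(axis=(1, 2)).astype(np.int64)
    cum = np.cumsum(counts)
    total = int(cum[-1])
    bounds = [0]
    for r in range(1, n_regions):
        bounds.append(int(np.searchsorted(cum, total * r / n_regions)))
    bounds.append(grid.shape[0])
    names = (list(CANONICAL_REGIONS) if n_regions == 6
             else [f"region_{i + 1}" for i in range(n_regions)])
    table: dict[int, str] = {}
    for r in range(n_regions):
        sl = slice(bounds[r], bounds[r + 1])
        labels[sl][support[sl]] = r + 1
        table[r + 1] = names[r]
    return Parcellation(grid=grid, labels=labels, region_table=table)


@dataclass
class SyntheticSubject:
    subject_id: str
    reference: BinaryMask
    automated: BinaryMask
    probability: ProbabilityVolume


def generate_cohort(cfg: SyntheticConfig) -> list[SyntheticSubject]:
    """Full in-memory cohort: reference, degraded mask and probability map
    per subject.  The automated mask and the probability map use separate
    degradation streams, emulating two independent tools."""
    subjects = []
    for i in range(cfg.n_subjects):
        rs = generate_reference(cfg, i)
        as_ = degrade(rs, cfg.degradation, subject_rng(cfg.seed, i, "degradation"))
        pm = make_probability_map(rs, cfg.degradation, subject_rng(cfg.seed, i, "fp"))
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{i + 1:03d}", reference=rs, automated=as_, probability=pm))
    return subjects


def write_cohort(cfg: SyntheticConfig, out_dir: str | Path,
                 with_parcellation: bool = True) -> Path:
    """Write a ready-to-evaluate cohort to disk.

    Per subject: reference mask, automated mask and probability map as
    NIfTI; plus a toy parcellation with its region table, a manifest CSV
    (one mask-prediction row per subject) and the generating configuration
    as YAML.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc_path = ""
    if with_parcellation:
        parc = make_toy_parcellation(cfg.grid, 6)
        parc_path = str(out / "parcellation.nii.gz")
        save_label_volume(parc.grid, parc.labels, parc_path)
        from .regional import write_region_table

        write_region_table(parc.region_table, out / "parcellation_regions.csv")

    rows = []
    for subj in generate_cohort(cfg):
        ref_p = out / f"{subj.subject_id}_ref.nii.gz"
        seg_p = out / f"{subj.subject_id}_seg.nii.gz"
        prob_p = out / f"{subj.subject_id}_prob.nii.gz"
        save_mask(subj.reference, ref_p)
        save_mask(subj.automated, seg_p)
        save_probability(subj.probability, prob_p)
        rows.append(ManifestRow(
            subject_id=subj.subject_id,
            reference_path=str(ref_p),
            prediction_path=str(seg_p),
            prediction_kind="mask",
            parcellation_path=parc_path or None,
            method_label="synthetic_tool",
        ))
    manifest_path = out / "manifest.csv"
    write_manifest(CohortManifest(rows=rows), manifest_path)

    cfg_dict = asdict(cfg)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return manifest_path
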