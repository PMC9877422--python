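import numpy as np
import pytest
from dataclasses import replace

from wmheval import (
    BinaryMask,
    VoxelGrid,
    DegradationConfig,
    SyntheticConfig,
    degrade,
    generate_reference,
    label_components,
    make_probability_map,
    make_toy_parcellation,
    threshold_probability,
    tune_threshold,
    volume_overlap,
)
from wmheval.regional import CANONICAL_REGIONS
from wmheval.synthetic import brain_support, burden_targets, subject_rng

from conftest import sphere_mask


SMALL = dict(grid_shape=(48, 48, 48))
NO_DEGRADATION = DegradationConfig(
    boundary_dilate_erode=0, displacement_vox=(0, 0, 0), p_miss_small=0.0, fp_rate=0.0
)


class TestGenerateReference:
    def test_deterministic_under_seed_and_index(self):
        cfg = SyntheticConfig(n_subjects=3, seed=42, **SMALL)
        a = generate_reference(cfg, 1)
        b = generate_reference(cfg, 1)
        assert np.array_equal(a.voxels, b.voxels)
        c = generate_reference(cfg, 2)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_lesions_confined_to_brain_support(self):
        cfg = SyntheticConfig(n_subjects=1, seed=3, **SMALL)
        m = generate_reference(cfg, 0)
        assert not (m.voxels & ~brain_support(m.grid.shape)).any()

    def test_mean_lesion_count_tracks_poisson_rate(self):
        cfg = SyntheticConfig(n_subjects=60, seed=11, **SMALL)
        counts = [label_components(generate_reference(cfg, i)).count for i in range(60)]
        se = np.sqrt(cfg.lesions_per_subject / 60)
        assert abs(np.mean(counts) - cfg.lesions_per_subject) < 3 * se

    def test_extreme_tercile_burden_means_near_targets(self):
        cfg = SyntheticConfig(n_subjects=30, seed=12, **SMALL)
        vols = np.sort([generate_reference(cfg, i).volume_ml for i in range(30)])
        lo, hi = cfg.burden_range_ml
        assert vols[:10].mean() == pytest.approx(lo, rel=0.20)
        assert vols[-10:].mean() == pytest.approx(hi, rel=0.20)

    def test_size_spectrum_straddles_cluster_filter(self):
        cfg = SyntheticConfig(n_subjects=4, seed=9, **SMALL)
        sizes = np.concatenate([
            label_components(generate_reference(cfg, i)).sizes for i in range(4)
        ])
        assert (sizes < 10).any() and (sizes >= 10).any()

    def test_degenerate_grid_rejected(self):
        cfg = SyntheticConfig(n_subjects=1, grid_shape=(12, 48, 48))
        with pytest.raises(ValueError):
            generate_reference(cfg, 0)

    def test_burden_profile_deterministic_and_positive(self):
        cfg = SyntheticConfig(n_subjects=30, seed=5)
        t1, t2 = burden_targets(cfg), burden_targets(cfg)
        assert np.array_equal(t1, t2)
        assert (t1 > 0).all()


class TestDegrade:
    def test_identity_when_degradation_disabled(self):
        cfg = SyntheticConfig(n_subjects=1, seed=7, **SMALL)
        rs = generate_reference(cfg, 0)
        out = degrade(rs, NO_DEGRADATION, subject_rng(7, 0, "degradation"))
        assert np.array_equal(out.voxels, rs.voxels)
        assert volume_overlap(rs, out).dsc == 1.0

    def test_certain_miss_of_small_lesions_empties_mask(self):
        cfg = SyntheticConfig(n_subjects=1, seed=8, **SMALL)
        rs = generate_reference(cfg, 0)
        max_size = int(label_components(rs).sizes.max())
        d = replace(NO_DEGRADATION, p_miss_small=1.0, small_size_vox=max_size + 1)
        out = degrade(rs, d, subject_rng(8, 0, "degradation"))
        assert out.foreground_count == 0

    def test_displaced_sphere_matches_analytic_overlap(self):
        # spheres of radius r at distance d: V = pi/12 (4r+d)(2r-d)^2, DSC = V/Vsphere
        r, d = 5.0, 2.0
        sph = sphere_mask((24, 24, 24), (11.5, 11.5, 11.5), r)
        out = degrade(sph, replace(NO_DEGRADATION, displacement_vox=(2, 0, 0)),
                      subject_rng(0, 0, "degradation"))
        analytic = ((np.pi / 12) * (4 * r + d) * (2 * r - d) ** 2) / ((4 / 3) * np.pi * r**3)
        assert volume_overlap(sph, out).dsc == pytest.approx(analytic, abs=0.03)

    def test_dilation_and_erosion_change_volume_in_opposite_directions(self):
        cfg = SyntheticConfig(n_subjects=1, seed=10, **SMALL)
        rs = generate_reference(cfg, 0)
        grown = degrade(rs, replace(NO_DEGRADATION, boundary_dilate_erode=1),
                        subject_rng(0, 0, "degradation"))
        shrunk = degrade(rs, replace(NO_DEGRADATION, boundary_dilate_erode=-1),
                         subject_rng(0, 0, "degradation"))
        assert grown.foreground_count > rs.foreground_count > shrunk.foreground_count
        assert not (rs.voxels & ~grown.voxels).any()

    def test_false_positives_add_new_lesions(self):
        cfg = SyntheticConfig(n_subjects=1, seed=14, **SMALL)
        rs = generate_reference(cfg, 0)
        d = replace(NO_DEGRADATION, fp_rate=8.0)
        out = degrade(rs, d, subject_rng(14, 0, "degradation"))
        assert label_components(out).count > label_components(rs).count
        assert (rs.voxels & ~out.voxels).sum() == 0  # originals untouched


class TestProbabilityMap:
    def test_pure_indicator_reproduces_mask_at_any_threshold(self):
        from wmheval.io_core import ProbabilityVolume

        cfg = SyntheticConfig(n_subjects=1, seed=2, **SMALL)
        rs = generate_reference(cfg, 0)
        p = ProbabilityVolume(grid=rs.grid, values=rs.voxels.astype(float))
        for t in (0.05, 0.5, 0.95):
            assert np.array_equal(threshold_probability(p, t).voxels, rs.voxels)

    def test_thresholding_at_planted_value_recovers_degraded_mask(self):
        cfg = SyntheticConfig(n_subjects=1, seed=4, **SMALL)
        rs = generate_reference(cfg, 0)
        d = replace(cfg.degradation, prob_map_noise_vox=0.0)
        pm = make_probability_map(rs, d, subject_rng(4, 0, "fp"))
        dm = degrade(rs, replace(d, boundary_dilate_erode=0), subject_rng(4, 0, "fp"))
        got = threshold_probability(pm, d.planted_threshold).voxels
        # noise-free ramp: level set at the planted threshold is the mask itself
        mismatch = np.count_nonzero(got ^ dm.voxels)
        assert mismatch <= 0.02 * max(dm.foreground_count, 1)

    def test_values_quantized_and_in_unit_interval(self):
        cfg = SyntheticConfig(n_subjects=1, seed=6, **SMALL)
        rs = generate_reference(cfg, 0)
        pm = make_probability_map(rs, cfg.degradation, subject_rng(6, 0, "fp"))
        assert pm.values.min() >= 0.0 and pm.values.max() <= 1.0
        assert np.allclose(pm.values, np.round(pm.values, 4))

    def test_more_smoothing_lowers_best_attainable_dsc(self):
        cfg = SyntheticConfig(n_subjects=2, seed=13, **SMALL)
        best = []
        for level in (0.5, 1.0, 2.0, 3.0, 4.0):
            d = replace(cfg.degradation, prob_map_smoothing=level)
            cohort = [
                (generate_reference(cfg, i),
                 make_probability_map(generate_reference(cfg, i), d, subject_rng(13, i, "fp")))
                for i in range(2)
            ]
            res = tune_threshold(cohort)
            best.append(max(m for m, _ in res.objective_per_value.values()))
        assert all(a > b for a, b in zip(best, best[1:]))


class TestToyParcellation:
    def test_single_region_covers_support(self):
        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=(1, 1, 1))
        p = make_toy_parcellation(grid, 1)
        assert np.array_equal(p.labels > 0, brain_support(grid.shape))

    def test_six_regions_disjoint_cover_with_canonical_names(self):
        grid = VoxelGrid(shape=(48, 48, 48), voxel_size=(1, 1, 1))
        p = make_toy_parcellation(grid, 6)
        support = brain_support(grid.shape)
        assert np.array_equal(p.labels > 0, support)
        assert tuple(p.region_table[k] for k in sorted(p.region_table)) == CANONICAL_REGIONS
        sizes = [(p.labels == k).sum() for k in range(1, 7)]
        assert min(sizes) > 0.5 * max(sizes)  # roughly equal slabs

    def test_labels_round_trip_through_nifti(self, tmp_path):
        from wmheval.io_core import load_label_volume, save_label_volume

        grid = VoxelGrid(shape=(24, 24, 24), voxel_size=(1, 1, 1))
        p = make_toy_parcellation(grid, 6)
        save_label_volume(grid, p.labels, tmp_path / "parc.nii.gz")
        _, back = load_label_volume(tmp_path / "parc.nii.gz")
        assert np.array_equal(back, p.labels)
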