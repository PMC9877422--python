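import math

import numpy as np
import pytest

from wmheval import icc_2_1, summarize, volume_overlap
from wmheval.io_core import GridCompatibilityError

from _oracles import icc_2_1_regression_oracle
from conftest import mask_from_array, random_mask


def _pair(rs_arr, as_arr, voxel=(1.0, 1.0, 1.0)):
    return mask_from_array(rs_arr, voxel), mask_from_array(as_arr, voxel)


class TestVolumeOverlap:
    def test_identical_masks_score_one(self):
        rng = np.random.default_rng(0)
        arr = rng.random((8, 8, 8)) < 0.3
        vm = volume_overlap(*_pair(arr, arr.copy()))
        assert vm.dsc == vm.sensitivity == vm.precision == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = b[5, 5, 5] = True
        vm = volume_overlap(*_pair(a, b))
        assert vm.dsc == vm.sensitivity == vm.precision == 0.0

    def test_hand_computed_counts(self):
        # RS 100 voxels, AS 80, overlap 60
        rs = np.zeros((10, 10, 10), bool)
        as_ = np.zeros((10, 10, 10), bool)
        rs.ravel()[:100] = True
        as_.ravel()[40:120] = True
        vm = volume_overlap(*_pair(rs, as_))
        assert vm.sensitivity == pytest.approx(0.60)
        assert vm.precision == pytest.approx(0.75)
        assert vm.dsc == pytest.approx(2 * 60 / 180)

    def test_volumes_reported_in_ml(self):
        rs = np.zeros((10, 10, 10), bool)
        rs.ravel()[:500] = True
        vm = volume_overlap(*_pair(rs, rs.copy(), voxel=(1.0, 1.0, 2.0)))
        assert vm.rs_vol_ml == pytest.approx(1.0)
        assert vm.tp_vol_ml == pytest.approx(1.0)

    def test_incompatible_grids_refused(self):
        a = mask_from_array(np.zeros((5, 5, 5), bool))
        b = mask_from_array(np.zeros((6, 6, 6), bool))
        with pytest.raises(GridCompatibilityError):
            volume_overlap(a, b)

    @pytest.mark.parametrize(
        "rs_empty, as_empty, dsc, sens, prec",
        [
            (True, True, 1.0, math.nan, math.nan),
            (True, False, 0.0, math.nan, 0.0),
            (False, True, 0.0, 0.0, math.nan),
        ],
    )
    def test_empty_mask_policy(self, rs_empty, as_empty, dsc, sens, prec):
        full = np.ones((4, 4, 4), bool)
        empty = np.zeros((4, 4, 4), bool)
        vm = volume_overlap(*_pair(empty if rs_empty else full, empty if as_empty else full))
        assert vm.dsc == dsc
        for got, want in ((vm.sensitivity, sens), (vm.precision, prec)):
            assert (got != got) if (want != want) else got == want

    def test_harmonic_mean_identity_and_symmetry(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            a = random_mask(rng, (8, 8, 8), rng.uniform(0.05, 0.6))
            b = random_mask(rng, (8, 8, 8), rng.uniform(0.05, 0.6))
            vm = volume_overlap(a, b)
            wm = volume_overlap(b, a)
            assert vm.dsc == pytest.approx(wm.dsc, abs=1e-15)
            assert vm.sensitivity == pytest.approx(wm.precision, abs=1e-15)
            if vm.sensitivity + vm.precision > 0 and math.isfinite(vm.sensitivity + vm.precision):
                harm = 2 * vm.sensitivity * vm.precision / (vm.sensitivity + vm.precision)
                assert vm.dsc == pytest.approx(harm, abs=1e-12)


class TestIcc21:
    def test_perfect_agreement_is_one(self):
        assert icc_2_1([(1, 1), (2, 2), (3, 3)]).icc == 1.0

    def test_constant_table_defined_as_one(self):
        assert icc_2_1([(2, 2), (2, 2), (2, 2)]).icc == 1.0

    def test_constant_offset_below_one(self):
        res = icc_2_1([(1, 3), (2, 4), (5, 7), (9, 11)])
        assert res.icc < 1.0

    def test_proportional_ratings_match_regression_oracle(self):
        table = [(1, 2), (2, 4), (3, 6), (4, 8)]
        assert icc_2_1(table).icc == pytest.approx(icc_2_1_regression_oracle(table), abs=1e-10)

    def test_matches_regression_oracle_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            table = rng.normal(size=(n, 2)) * rng.uniform(0.5, 5) + rng.uniform(-3, 3)
            assert icc_2_1(table).icc == pytest.approx(
                icc_2_1_regression_oracle(table), abs=1e-10
            )

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 2),
            "raters": np.tile(["a", "b"], 10),
            "y": x.ravel(),
        })
        want = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="y")
        # two-way random absolute-agreement single-rater row, labelled
        # ICC2 or ICC(A,1) depending on pingouin version
        mask = want["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(want.loc[mask, "ICC"].iloc[0])
        assert icc_2_1(x).icc == pytest.approx(icc2, abs=1e-9)

    def test_scale_invariance_voxels_vs_ml(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(size=(12, 2))) * 1000
        assert icc_2_1(x).icc == pytest.approx(icc_2_1(x * 0.003375).icc, abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(9, 2))
        perm = rng.permutation(9)
        assert icc_2_1(x).icc == pytest.approx(icc_2_1(x[perm]).icc, abs=1e-12)

    def test_small_or_incomplete_tables_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1([(1, 2), (3, 4)])
        with pytest.raises(ValueError):
            icc_2_1([(1, 2), (3, math.nan), (5, 6)])

    def test_icc_reproducible_from_stored_mean_squares(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(8, 2))
        r = icc_2_1(x)
        denom = r.ms_rows + (r.k - 1) * r.ms_error + r.k * (r.ms_cols - r.ms_error) / r.n
        assert r.icc == pytest.approx((r.ms_rows - r.ms_error) / denom, abs=1e-12)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        s = summarize([0.5, 0.7])
        assert s.mean == pytest.approx(0.6)
        assert s.sd == pytest.approx(math.sqrt(0.02), abs=1e-12)

    def test_constant_values_have_zero_sd(self):
        assert summarize([3.0, 3.0, 3.0]).sd == 0.0

    def test_single_value_has_missing_sd(self):
        s = summarize([0.6])
        assert s.mean == 0.6 and s.sd != s.sd

    def test_missing_values_excluded_and_counted(self):
        s = summarize([0.5, math.nan, 0.7, math.nan])
        assert s.n == 2 and s.n_missing == 2
        assert s.mean == pytest.approx(0.6)

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            summarize([math.nan, math.nan])
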