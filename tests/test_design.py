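"""Design construction: HRF, regressors, DCT, nuisance expansion, assembly."""
import numpy as np
import pytest

from conftest import make_course
from narrative_encoding import design
from narrative_encoding.containers import NuisanceBundle
from narrative_encoding.errors import (
    EstimationError,
    InvalidParameterError,
    MalformedInputError,
    ShapeMismatchError,
)


class TestCanonicalHRF:
    def test_peak_near_five_seconds_and_normalized(self):
        hrf = design.canonical_hrf(0.23)
        t_peak = hrf.time_s[np.argmax(hrf.values)]
        assert abs(t_peak - 5.0) <= 0.23
        assert hrf.values.max() == pytest.approx(1.0)

    def test_tail_returns_to_baseline(self):
        hrf = design.canonical_hrf(0.5)
        assert abs(hrf.values[-1]) < 0.01

    def test_impulse_convolution_reproduces_kernel(self):
        hrf = design.canonical_hrf(0.23)
        impulse = np.zeros(200)
        impulse[0] = 1.0
        out = np.convolve(impulse, hrf.values)[: hrf.values.size]
        assert np.allclose(out, hrf.values)

    def test_matches_spm_reference_shape(self):
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        hrf = design.canonical_hrf(0.1)
        ref = nilearn_glm.spm_hrf(0.1, oversampling=1)
        n = min(hrf.values.size, ref.size)
        r = np.corrcoef(hrf.values[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_invalid_step(self):
        with pytest.raises(InvalidParameterError):
            design.canonical_hrf(0.0)


class TestInterestRegressor:
    def test_affine_rating_map(self):
        assert design.rating_to_regressor_scale(np.array([0.0, 50.0, 100.0])).tolist() == [
            -1.0,
            0.0,
            1.0,
        ]

    def test_constant_midscale_course_maps_to_zero(self):
        hrf = design.canonical_hrf(0.23)
        reg, missing = design.build_interest_regressor(
            make_course(np.full(200, 50.0)), hrf, tr=0.46
        )
        assert np.allclose(reg, 0.0)
        assert missing.size == 0

    def test_impulse_course_reproduces_decimated_hrf(self):
        hrf = design.canonical_hrf(0.23)
        median = np.full(400, 50.0)
        median[0] = 100.0  # unit impulse after the affine map
        reg, _ = design.build_interest_regressor(make_course(median), hrf, tr=0.46)
        assert np.allclose(reg[: hrf.values[::2].size], hrf.values[::2], atol=1e-12)

    def test_invalid_timepoints_become_missing_volumes(self):
        valid = np.ones(100, bool)
        valid[10:12] = False
        hrf = design.canonical_hrf(0.23)
        reg, missing = design.build_interest_regressor(
            make_course(np.full(100, 80.0), valid=valid), hrf, tr=0.46
        )
        assert missing.tolist() == [5]  # grid samples 10-11 fall in volume 5

    def test_convolution_linearity(self):
        hrf = design.canonical_hrf(0.23)
        a = make_course(np.clip(50 + 30 * np.sin(np.arange(300) * 0.1), 0, 100))
        b = make_course(np.clip(50 + 20 * np.cos(np.arange(300) * 0.07), 0, 100))
        mix = make_course(0.5 * a.median + 0.5 * b.median)
        ra, _ = design.build_interest_regressor(a, hrf, 0.46)
        rb, _ = design.build_interest_regressor(b, hrf, 0.46)
        rm, _ = design.build_interest_regressor(mix, hrf, 0.46)
        assert np.allclose(rm, 0.5 * ra + 0.5 * rb, atol=1e-12)

    def test_grid_mismatch_raises(self):
        hrf = design.canonical_hrf(0.23)
        with pytest.raises(ShapeMismatchError):
            design.build_interest_regressor(make_course(np.full(100, 50.0)), hrf, tr=0.5)

    def test_decimation_matches_direct_construction_at_tr(self):
        slow = np.clip(50 + 30 * np.sin(np.arange(400) * 0.02), 0, 100)
        hrf_fine = design.canonical_hrf(0.23)
        hrf_tr = design.canonical_hrf(0.46)
        fine, _ = design.build_interest_regressor(make_course(slow), hrf_fine, 0.46)
        direct, _ = design.build_interest_regressor(
            make_course(slow[::2], grid_step=0.46), hrf_tr, 0.46
        )
        # same smooth course, built at 230 ms then decimated vs directly at
        # 460 ms; discrete convolution mass scales with 1/step, so compare on
        # the continuous-convolution scale (multiply each by its step)
        resid = 0.23 * fine[: direct.size] - 0.46 * direct
        assert np.max(np.abs(resid)) < 0.05 * np.max(np.abs(0.46 * direct))


class TestTomDemandRegressors:
    def _consensus(self, labels):
        from narrative_encoding.behavior import consensus_annotations

        return consensus_annotations(np.tile(np.asarray(labels)[:, None], (1, 4)))

    def test_boxcars_are_exclusive_and_contrast_is_difference(self):
        hrf = design.canonical_hrf(0.23)
        cons = self._consensus([1, 0, 1])
        timing = [(0.0, 4.6), (4.6, 4.6), (9.2, 4.6)]
        d, nd, contrast = design.build_tom_demand_regressors(cons, timing, hrf, 0.46, 40)
        assert contrast.tolist() == [1.0, -1.0]
        assert contrast @ np.array([3.0, 1.25]) == pytest.approx(1.75)
        # reconstruct the boxcars: deconvolution not needed, peaks must alternate
        assert d[:5].sum() > nd[:5].sum()

    def test_all_zero_demand_flags_degenerate(self):
        hrf = design.canonical_hrf(0.23)
        cons = self._consensus([0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            design.build_tom_demand_regressors(cons, [(0.0, 2.3), (2.3, 2.3)], hrf, 0.46, 20)

    def test_overlapping_parts_raise(self):
        hrf = design.canonical_hrf(0.23)
        cons = self._consensus([1, 0])
        with pytest.raises(MalformedInputError):
            design.build_tom_demand_regressors(cons, [(0.0, 4.6), (2.3, 4.6)], hrf, 0.46, 40)


class TestDCTBasis:
    def test_column_count_convention(self):
        basis = design.dct_basis(256, tr=0.46, cutoff=1.0 / 128.0)
        assert basis.shape == (256, 1)  # floor(2 * 256 * 0.46 / 128) = 1

    def test_all_columns_slower_than_cutoff(self):
        n, tr = 500, 1.0
        basis = design.dct_basis(n, tr, cutoff=1.0 / 128.0)
        for k in range(basis.shape[1]):
            period = 2.0 * n * tr / (k + 1)
            assert period >= 128.0

    def test_columns_orthogonal(self):
        basis = design.dct_basis(400, tr=2.0, cutoff=1.0 / 64.0)
        gram = basis.T @ basis
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-9

    def test_short_run_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            basis = design.dct_basis(10, tr=0.5, cutoff=1.0 / 128.0)
        assert basis.shape == (10, 0)


def _bundle(n=50, runs=1, motion=None, gs=None, fd=None, seed=0):
    rng = np.random.default_rng(seed)
    motion = motion if motion is not None else rng.standard_normal((n, 6)) * 0.1
    gs = gs if gs is not None else rng.standard_normal(n)
    fd = fd if fd is not None else np.abs(rng.standard_normal(n)) * 0.05
    return NuisanceBundle(
        motion=[motion] * runs,
        csf=[rng.standard_normal(n)] * runs,
        global_signal=[gs] * runs,
        fd=[fd] * runs,
    )


class TestBuildNuisance:
    def test_motion_expands_to_24_columns(self):
        out = design.build_nuisance(_bundle())
        assert out["motion24"][0].shape == (50, 24)

    def test_constant_motion_derivatives_and_squares(self):
        out = design.build_nuisance(_bundle(motion=np.full((50, 6), 2.0)))
        m24 = out["motion24"][0]
        assert np.allclose(m24[1:, 6:12], 0.0)  # derivatives
        assert np.allclose(m24[:, 12:18], 4.0)  # squares

    def test_single_large_spike_flagged_once(self):
        gs = np.zeros(50)
        gs[0] = 1e-3  # break exact constancy without creating outliers
        gs[17] = 10.0
        out = design.build_nuisance(_bundle(gs=gs, fd=np.full(50, 0.05)))
        assert out["outlier_volumes"][0].tolist() == [17]

    def test_invalid_threshold(self):
        with pytest.raises(InvalidParameterError):
            design.build_nuisance(_bundle(), z_thresh=0.0)


class TestAssembleDesign:
    def _design(self, n_runs=4, n_vol=40, n_discard=6):
        rng = np.random.default_rng(1)
        interest = {"social": [rng.standard_normal(n_vol) for _ in range(n_runs)]}
        nuis = design.build_nuisance(
            NuisanceBundle(
                motion=[rng.standard_normal((n_vol, 6)) for _ in range(n_runs)],
                csf=[rng.standard_normal(n_vol) for _ in range(n_runs)],
                global_signal=[rng.standard_normal(n_vol) for _ in range(n_runs)],
                fd=[np.abs(rng.standard_normal(n_vol)) for _ in range(n_runs)],
            )
        )
        return design.assemble_design(
            run_lengths=[n_vol] * n_runs,
            tr=0.46,
            interest=interest,
            nuisance=nuis,
            n_discard=n_discard,
        )

    def test_row_count_and_intercept_blocks(self):
        dmat = self._design()
        assert dmat.n_rows == 4 * (40 - 6)
        intercepts = dmat.columns_with_role("intercept")
        assert len(intercepts) == 4
        for r, name in enumerate(intercepts):
            col = dmat.column(name)
            assert np.array_equal(col != 0, dmat.run_id == r)

    def test_per_run_columns_zero_outside_their_run(self):
        dmat = self._design()
        for name, role in zip(dmat.names, dmat.roles):
            if role in ("motion24", "csf", "dct", "outlier", "intercept"):
                run = int(name.rsplit("_run", 1)[1].split("_")[0])
                assert np.allclose(dmat.column(name)[dmat.run_id != run], 0.0)

    def test_interest_column_round_trips(self):
        rng = np.random.default_rng(2)
        per_run = [rng.standard_normal(30) for _ in range(2)]
        dmat = design.assemble_design(
            run_lengths=[30, 30], tr=0.46, interest={"social": per_run}, n_discard=6
        )
        expected = np.concatenate([arr[6:] for arr in per_run])
        assert np.array_equal(dmat.column("social"), expected)

    def test_duplicate_and_all_zero_columns_rejected(self):
        rng = np.random.default_rng(3)
        col = [rng.standard_normal(30)]
        with pytest.raises(MalformedInputError):
            design.assemble_design(
                run_lengths=[30], tr=0.46,
                interest={"intercept_run0": col}, n_discard=0,
            )
        with pytest.raises(EstimationError):
            design.assemble_design(
                run_lengths=[30], tr=0.46, interest={"flat": [np.zeros(30)]}, n_discard=0
            )

    def test_missing_indicator_columns_are_unit_vectors(self):
        rng = np.random.default_rng(4)
        dmat = design.assemble_design(
            run_lengths=[30], tr=0.46,
            interest={"social": [rng.standard_normal(30)]},
            missing_volumes={"social": [np.array([2, 10])]},
            n_discard=6,
        )
        cols = dmat.columns_with_role("missing_indicator")
        assert len(cols) == 1  # volume 2 lies in the discarded head
        col = dmat.column(cols[0])
        assert col.sum() == 1.0 and col[10 - 6] == 1.0


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        n = 128
        t = np.arange(n)
        dmat = design.assemble_design(
            run_lengths=[n], tr=1.0,
            interest={
                "a": [np.sin(2 * np.pi * 3 * t / n)],
                "b": [np.cos(2 * np.pi * 5 * t / n)],
            },
            n_discard=0,
        )
        vifs = design.compute_vif(dmat, ["a", "b"])
        assert all(abs(v - 1.0) < 1e-9 for v in vifs.values())

    def test_known_correlation_gives_closed_form_vif(self):
        n = 200
        u = np.sin(2 * np.pi * np.arange(n) * 4 / n)
        v = np.cos(2 * np.pi * np.arange(n) * 4 / n)
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        x2 = 0.6 * u + 0.8 * v  # exact empirical correlation 0.6 with u
        dmat = design.assemble_design(
            run_lengths=[n], tr=1.0, interest={"a": [u], "b": [x2]}, n_discard=0
        )
        vifs = design.compute_vif(dmat, ["a", "b"])
        assert vifs["a"] == pytest.approx(1.5625, abs=1e-6)
        assert vifs["b"] == pytest.approx(1.5625, abs=1e-6)

    def test_duplicated_column_raises(self):
        n = 50
        col = np.sin(np.arange(n))
        dmat = design.assemble_design(
            run_lengths=[n], tr=1.0, interest={"a": [col], "b": [col.copy()]}, n_discard=0
        )
        with pytest.raises(EstimationError):
            design.compute_vif(dmat, ["a", "b"])
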