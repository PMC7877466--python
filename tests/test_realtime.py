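"""Online loop: streaming preprocessing, cumulative GLM, ROI, feedback."""

import numpy as np
import pandas as pd
import pytest

from nfloop.paradigm import design_to_regressor, make_nf_design
from nfloop.realtime import (
    BaselineState,
    LocalizerError,
    OnlineGlm,
    OnlinePreprocessor,
    RoiSet,
    assign_yoked_sources,
    compute_feedback,
    delineate_sma,
    run_nf_loop,
    smooth_volume,
    update_baseline,
)
from nfloop.simulate import simulate_run
from conftest import make_state, localize_subject


class TestOnlinePreprocessor:
    def test_constant_stream_unchanged(self):
        pre = OnlinePreprocessor(fwhm_mm=8.0, voxel_size_mm=3.0)
        vol = np.full((8, 8, 4), 100.0)
        outs = [pre.process(vol) for _ in range(6)]
        for o in outs:
            np.testing.assert_allclose(o, 100.0, atol=1e-9)

    def test_linear_trend_removed(self):
        pre = OnlinePreprocessor(fwhm_mm=0.0)
        m = 0.7
        outs = [pre.process(np.full((4, 4, 2), m * t)) for t in range(30)]
        # pure zero-intercept ramp: detrended residual ~ 0 once slope is learned
        assert abs(outs[-1]).max() < 1e-8

    def test_smoothing_preserves_mean(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(100, 5, (16, 16, 10))
        sm = smooth_volume(vol, 8.0, 3.0)
        assert abs(sm.mean() - vol.mean()) / vol.mean() < 1e-6
        assert sm.std() < vol.std()  # actually smooths

    def test_shape_mismatch_rejected(self):
        pre = OnlinePreprocessor()
        pre.process(np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="shape"):
            pre.process(np.zeros((4, 4, 3)))


class TestOnlineGlm:
    def test_incremental_equals_batch_at_every_step(self):
        rng = np.random.default_rng(1)
        T, p, shape = 40, 3, (3, 3, 2)
        X = np.column_stack([rng.normal(size=T), np.arange(T) / T, np.ones(T)])
        Y = rng.normal(100, 2, size=(T, *shape))
        glm = OnlineGlm(p)
        for k in range(T):
            glm.update(Y[k], X[k])
            if k + 1 >= p + 2:
                bb, *_ = np.linalg.lstsq(X[: k + 1], Y[: k + 1].reshape(k + 1, -1), rcond=None)
                np.testing.assert_allclose(
                    glm.betas().reshape(p, -1), bb, atol=1e-8, rtol=0
                )
        # t statistic matches batch formula at the end
        beta, *_ = np.linalg.lstsq(X, Y.reshape(T, -1), rcond=None)
        resid = Y.reshape(T, -1) - X @ beta
        s2 = (resid**2).sum(axis=0) / (T - p)
        cvc = np.linalg.inv(X.T @ X)[0, 0]
        t_batch = beta[0] / np.sqrt(s2 * cvc)
        np.testing.assert_allclose(glm.t_map(0).reshape(-1), t_batch, atol=1e-8)

    def test_zero_signal_voxels_give_centered_t(self):
        rng = np.random.default_rng(2)
        T = 120
        X = np.column_stack([rng.normal(size=T), np.ones(T)])
        glm = OnlineGlm(2)
        for k in range(T):
            glm.update(rng.normal(0, 1, (10, 10, 4)), X[k])
        t = glm.t_map(0)
        assert abs(t.mean()) < 3.0 / np.sqrt(t.size)

    def test_duplicate_predictors_flagged_not_raised(self):
        glm = OnlineGlm(2)
        for k in range(10):
            glm.update(np.full((2, 2, 2), float(k)), np.array([1.0, 1.0]))
        assert glm.rank_deficient
        assert glm.t_map(0) is None

    def test_too_few_volumes_flagged(self):
        rng = np.random.default_rng(3)
        glm = OnlineGlm(2)
        glm.update(rng.normal(size=(2, 2, 2)), np.array([1.0, 0.5]))
        assert glm.t_map(0) is None


class TestDelineation:
    def test_subthreshold_map_raises_with_diagnostic(self):
        t_map = np.full((8, 8, 4), 2.0)
        with pytest.raises(LocalizerError, match="max t = 2.000"):
            delineate_sma(t_map, (slice(2, 6), slice(2, 6), slice(1, 3)))

    def test_out_of_box_voxels_excluded(self):
        t_map = np.zeros((8, 8, 4))
        t_map[3:5, 3:5, 1] = 10.0  # inside box
        t_map[0, 0, 0] = 50.0  # outside box
        mask = delineate_sma(t_map, (slice(2, 6), slice(2, 6), slice(0, 3)))
        assert mask.sum() == 4
        assert not mask[0, 0, 0]

    def test_largest_component_kept(self):
        t_map = np.zeros((8, 8, 4))
        t_map[1:4, 1:4, 1] = 10.0  # 9 voxels
        t_map[6, 6, 1] = 10.0  # singleton, face-disconnected
        mask = delineate_sma(t_map, (slice(0, 8), slice(0, 8), slice(0, 4)))
        assert mask.sum() == 9

    def test_clean_localizer_recovers_phantom_sma(self, small_phantom):
        # low noise, no online smoothing: delineation = generative SMA
        state = make_state(sigma=0.02, drift_slope=0.0, cosine_amps=())
        rois = localize_subject(small_phantom, state, fwhm_mm=0.0)
        np.testing.assert_array_equal(rois.sma_mask, small_phantom.masks["SMA"])


class TestBaselineAndFeedback:
    def _rois(self):
        sma = np.zeros((6, 6, 4), bool)
        ref = np.zeros((6, 6, 4), bool)
        sma[2:4, 2:4, 1] = True
        ref[:, :, 3] = True
        return RoiSet(sma_mask=sma, reference_mask=ref)

    def test_constant_baseline(self):
        rois = self._rois()
        vols = [np.full((6, 6, 4), 100.0)] * 5
        base = update_baseline(vols, rois)
        assert base.roi_sma_base == base.roi_ref_base == 100.0

    def test_last_three_volumes_only(self):
        rois = self._rois()
        mk = lambda v: np.full((6, 6, 4), float(v))
        base = update_baseline([mk(500), mk(98), mk(100), mk(102)], rois)
        assert base.roi_sma_base == pytest.approx(100.0)
        base2 = update_baseline([mk(1), mk(98), mk(100), mk(102)], rois)
        assert base2.roi_sma_base == base.roi_sma_base

    def test_too_few_volumes(self):
        with pytest.raises(ValueError, match="3 fixation"):
            update_baseline([np.ones((6, 6, 4))] * 2, self._rois())

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            BaselineState(roi_sma_base=0.0, roi_ref_base=100.0, source_volumes=(0, 1, 2))

    @pytest.mark.parametrize(
        "sma_pct,ref_pct,expected",
        [(0.0, 0.0, 0.0), (2.0, 0.0, 0.02), (3.0, 1.0, 0.02), (-1.0, -1.0, 0.0)],
    )
    def test_feedback_arithmetic(self, sma_pct, ref_pct, expected):
        base = BaselineState(100.0, 200.0, (5, 6, 7))
        height = compute_feedback(100.0 * (1 + sma_pct / 100), 200.0 * (1 + ref_pct / 100), base)
        assert height == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def coupled_run(small_phantom):
    state = make_state(sigma=0.0, drift_slope=0.0, cosine_amps=())
    state.wm_amp = state.vent_amp = 0.0
    design = make_nf_design(2.0)
    rec = simulate_run(small_phantom, state, design, 7)
    rois = RoiSet(
        sma_mask=small_phantom.masks["SMA"],
        reference_mask=small_phantom.masks["REF_SLAB"],
    )
    return rec, rois


class TestNfLoop:

    def test_true_mode_positive_mean_height(self, coupled_run):
        rec, rois = coupled_run
        trace = run_nf_loop(rec, rois)
        fb = trace[trace.block == "feedback"]
        assert fb.height.notna().all()
        assert fb.height.mean() > 0
        assert trace[trace.block == "fixation"].height.isna().all()
        assert len(trace) == 215

    def test_sham_replays_source_heights(self, coupled_run):
        rec, rois = coupled_run
        source = run_nf_loop(rec, rois)
        sham = run_nf_loop(rec, rois, mode="sham", sham_source=source)
        fb = sham.block == "feedback"
        np.testing.assert_array_equal(sham.height[fb], source.height[fb])
        # the subject's own ROI means are still logged
        np.testing.assert_array_equal(sham.sma_mean, source.sma_mean)

    def test_sham_requires_source(self, coupled_run):
        rec, rois = coupled_run
        with pytest.raises(ValueError, match="sham_source"):
            run_nf_loop(rec, rois, mode="sham")

    def test_short_stream_rejected(self, coupled_run):
        rec, rois = coupled_run
        from nfloop.simulate import RunRecording

        short = RunRecording(
            volumes=rec.volumes[:100],
            confounds=rec.confounds.iloc[:100],
            design=rec.design,
            tr=rec.tr,
            n_discarded=115,
        )
        with pytest.raises(ValueError, match="shorter"):
            run_nf_loop(short, rois)

    def test_global_offset_cancelled_by_reference(self, small_phantom):
        # additive global signal g(t), |g|/base < 1%: height shift < 1e-3
        state = make_state(sigma=0.2, drift_slope=0.0, cosine_amps=())
        design = make_nf_design(2.0)
        rec = simulate_run(small_phantom, state, design, 4)
        rois = RoiSet(
            sma_mask=small_phantom.masks["SMA"],
            reference_mask=small_phantom.masks["REF_SLAB"],
        )
        t = np.arange(rec.n_volumes)
        g = 0.8 * np.sin(2 * np.pi * t / 50.0)
        from nfloop.simulate import RunRecording

        shifted = RunRecording(
            volumes=rec.volumes + g[:, None, None, None],
            confounds=rec.confounds,
            design=design,
            tr=rec.tr,
        )
        h0 = run_nf_loop(rec, rois).height
        h1 = run_nf_loop(shifted, rois).height
        diff = (h1 - h0).abs().dropna()
        assert diff.max() < 1e-3

    def test_null_feedback_calibration(self, small_phantom):
        # no coupling: mean height over feedback blocks centered at zero
        design = make_nf_design(2.0)
        rois = RoiSet(
            sma_mask=small_phantom.masks["SMA"],
            reference_mask=small_phantom.masks["REF_SLAB"],
        )
        means = []
        for seed in range(25):
            state = make_state(
                "control", seed=seed, base_amp=0.0, slope=0.0, nonspecific_amp=0.0,
                sigma=0.5,
            )
            rec = simulate_run(small_phantom, state, design, 1)
            trace = run_nf_loop(rec, rois)
            means.append(trace.height.dropna().mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se


class TestYoking:
    def test_single_pool(self):
        m = assign_yoked_sources(["nf0"], ["c0", "c1", "c2"], seed=0)
        assert set(m.values()) == {"nf0"}

    def test_deterministic_and_in_pool(self):
        pool = [f"nf{i}" for i in range(7)]
        controls = [f"c{i}" for i in range(10)]
        a = assign_yoked_sources(pool, controls, seed=3)
        b = assign_yoked_sources(pool, controls, seed=3)
        assert a == b
        assert set(a.values()) <= set(pool)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty pool"):
            assign_yoked_sources([], ["c0"], seed=0)
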