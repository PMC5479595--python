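import numpy as np
import pytest

from capop import signals as sig
from capop import synthgen
from capop.core_model import EventTimeline, MovieStack, ROIMap
from capop.signals import DFFTraces, FluoTraces


@pytest.fixture()
def tiny_movie():
    rng = np.random.default_rng(0)
    data = rng.uniform(10, 20, size=(30, 12, 12))
    return MovieStack(data=data, frame_rate=5.0, pixel_size=1.0)


class TestExtractTraces:
    def test_constant_movie(self):
        mov = MovieStack(data=np.full((8, 6, 6), 7.0), frame_rate=1.0,
                         pixel_size=1.0)
        rois = ROIMap(rois=[[[1, 1], [1, 2]], [[4, 4]]])
        tr = sig.extract_traces(mov, rois)
        assert np.all(tr.F == 7.0)

    def test_single_pixel_roi_equals_pixel_series(self, tiny_movie):
        rois = ROIMap(rois=[[[3, 5]]])
        tr = sig.extract_traces(tiny_movie, rois)
        assert np.array_equal(tr.F[0], tiny_movie.data[:, 3, 5])

    def test_bad_frames_masked(self, tiny_movie):
        tiny_movie.bad_frames = {2, 7}
        tr = sig.extract_traces(tiny_movie, ROIMap(rois=[[[0, 0]]]))
        assert np.isnan(tr.F[0, 2]) and np.isnan(tr.F[0, 7])
        assert np.isfinite(tr.F[0, 3])

    def test_generator_closed_loop(self, disk_cells):
        gt = synthgen.make_activity(15, duration=30, frame_rate=5.0,
                                    background_rate=0.2, noise_sigma=0.02, seed=5)
        res = synthgen.render_movie(disk_cells, gt.observed, frame_rate=5.0,
                                    pixel_size=1.0, pixel_noise=0.5, seed=5)
        tr = sig.extract_traces(res.movie, disk_cells.to_roimap())
        # trace = baseline + gain*(1+dff) (+ small pixel noise):
        rebuilt = (tr.F - res.baseline) / res.cell_gain - 1.0
        assert np.max(np.abs(rebuilt - gt.observed)) < 3 * 0.5 / res.cell_gain * 10


class TestPerisomaticMasks:
    def test_single_roi_disk_minus_self(self):
        rois = ROIMap(rois=[[[20, 20], [20, 21]]])
        masks = sig.perisomatic_masks(rois, (41, 41), radius=5.0, pixel_size=1.0)
        mask_set = set(map(tuple, masks[0]))
        assert (20, 20) not in mask_set and (20, 21) not in mask_set
        # brute force pixel enumeration
        cy, cx = 20.0, 20.5
        brute = {(r, c) for r in range(41) for c in range(41)
                 if (r - cy) ** 2 + (c - cx) ** 2 <= 25.0
                 and (r, c) not in {(20, 20), (20, 21)}}
        assert mask_set == brute

    def test_masks_exclude_all_rois_and_may_overlap(self):
        rois = ROIMap(rois=[[[10, 10]], [[10, 14]]])
        masks = sig.perisomatic_masks(rois, (30, 30), radius=6.0, pixel_size=1.0)
        for m in masks:
            s = set(map(tuple, m))
            assert (10, 10) not in s and (10, 14) not in s
        overlap = set(map(tuple, masks[0])) & set(map(tuple, masks[1]))
        assert overlap  # neighboring masks share neuropil pixels

    def test_physical_units(self):
        rois = ROIMap(rois=[[[25, 25]]])
        m1 = sig.perisomatic_masks(rois, (51, 51), radius=10.0, pixel_size=1.0)
        m2 = sig.perisomatic_masks(rois, (51, 51), radius=10.0, pixel_size=0.5)
        assert len(m2[0]) > 3 * len(m1[0])  # 20 px vs 10 px disk


class TestNeuropilCorrect:
    def test_alpha_zero_identity(self):
        rng = np.random.default_rng(1)
        s = FluoTraces(F=rng.normal(size=(3, 40)))
        n = FluoTraces(F=rng.normal(size=(3, 40)))
        out = sig.neuropil_correct(s, n, alpha=0.0)
        assert np.array_equal(out.F, s.F)
        assert out.source == "corrected"

    def test_constructive_recovery(self):
        rng = np.random.default_rng(2)
        soma_true = rng.normal(10, 1, size=(4, 100))
        npil = rng.normal(5, 1, size=(4, 100))
        measured = FluoTraces(F=soma_true + 0.9 * npil)
        out = sig.neuropil_correct(measured, FluoTraces(F=npil), alpha=0.9)
        assert np.allclose(out.F, soma_true)

    def test_linearity_in_alpha(self):
        rng = np.random.default_rng(3)
        s = FluoTraces(F=rng.normal(size=(2, 30)))
        n = FluoTraces(F=rng.normal(size=(2, 30)))
        once = sig.neuropil_correct(s, n, alpha=0.7)
        twice = sig.neuropil_correct(sig.neuropil_correct(s, n, 0.3), n, 0.4)
        assert np.allclose(once.F, twice.F)

    def test_correction_restores_ground_truth_correlations(self):
        cells = synthgen.make_cells(20, "disk", (128, 128), pixel_size=1.0,
                                    radius=4.0, seed=2)
        gt = synthgen.make_activity(20, duration=100, frame_rate=5.0,
                                    background_rate=0.15, noise_sigma=0.03, seed=2)
        res = synthgen.render_movie(cells, gt.observed, frame_rate=5.0,
                                    pixel_size=1.0, neuropil_gain=400.0,
                                    alpha_true=0.9, seed=2)
        rois = cells.to_roimap()
        soma = sig.extract_traces(res.movie, rois)
        masks = sig.perisomatic_masks(rois, (128, 128), radius=20.0, pixel_size=1.0)
        npil = sig.extract_neuropil_traces(res.movie, masks)
        corr = sig.neuropil_correct(soma, npil, alpha=0.9)

        def offdiag(M):
            return M[np.triu_indices(len(M), 1)].mean()

        c_raw = offdiag(np.corrcoef(soma.F))
        c_cor = offdiag(np.corrcoef(corr.F))
        c_true = offdiag(np.corrcoef(gt.observed))
        assert c_raw > c_true + 0.1          # contamination inflates correlations
        assert abs(c_cor - c_true) <= 0.05   # correction restores them
        r = [np.corrcoef(corr.F[i], gt.observed[i])[0, 1] for i in range(20)]
        assert min(r) >= 0.95


class TestSanityCheck:
    def test_clean_traces_empty_report(self):
        rng = np.random.default_rng(4)
        rep = sig.sanity_check(FluoTraces(F=rng.uniform(5, 10, size=(5, 200))))
        assert rep.is_clean()

    def test_oversubtraction_flagged(self):
        rng = np.random.default_rng(5)
        F = rng.uniform(1, 2, size=(2, 100))
        F[1, :10] = -1.0  # 10% negative
        rep = sig.sanity_check(FluoTraces(F=F))
        assert rep.negative == [1]

    def test_saturation_and_dead_trace_flagged(self):
        F = np.ones((3, 100))
        F[0] = np.linspace(1, 65535, 100)
        F[0, -5:] = 65535.0
        F[2] = np.linspace(1, 2, 100)
        rep = sig.sanity_check(FluoTraces(F=F), sensor_max=65535)
        assert 0 in rep.saturated
        assert rep.zero_variance == [1]


class TestBaselines:
    def test_constant_trace_f0(self):
        tr = FluoTraces(F=np.full((2, 50), 4.0))
        assert np.allclose(sig.estimate_f0_window(tr, 5.0, (0, 10)), 4.0)
        fs = sig.estimate_f_smooth(tr, 5.0, window=4.0)
        assert np.allclose(fs, 4.0)

    def test_two_frame_window_mean(self):
        F = np.zeros((1, 10))
        F[0, 0], F[0, 1] = 4.0, 6.0
        tr = FluoTraces(F=F)
        f0 = sig.estimate_f0_window(tr, frame_rate=1.0, window=(0.0, 2.0))
        assert f0[0] == 5.0

    def test_eventwise_f0_equals_bruteforce_trial_means(self):
        rng = np.random.default_rng(6)
        F = rng.uniform(5, 10, size=(3, 100))
        tr = FluoTraces(F=F)
        ev = EventTimeline(times=[4.0, 8.0], values=[0.0, 1.0])
        f0 = sig.estimate_f0_window(tr, frame_rate=2.0, window=(-2.0, 0.0), events=ev)
        # brute force: [t_ev-2, t_ev) at 2 Hz = 4 frames before the event
        assert np.allclose(f0[:, 0], F[:, 4:8].mean(axis=1))
        assert np.allclose(f0[:, 1], F[:, 12:16].mean(axis=1))

    def test_f_smooth_tracks_drift_ignores_transients(self):
        fr = 5.0
        gt = synthgen.make_activity(3, duration=200, frame_rate=fr,
                                    background_rate=0.05, noise_sigma=0.02,
                                    drift=0.001, seed=7)
        F = 100.0 * (1.0 + gt.observed)
        tr = FluoTraces(F=F)
        fs = sig.estimate_f_smooth(tr, fr, window=30.0)
        quiet = gt.true_dff < 1e-6
        resid = (F - fs)[quiet]
        assert abs(np.median(resid)) < 0.5 * 100 * 0.02

    def test_median_percentile_is_running_median(self):
        rng = np.random.default_rng(8)
        F = rng.normal(0, 1, size=(1, 400)) + 10
        tr = FluoTraces(F=F)
        fs = sig.estimate_f_smooth(tr, frame_rate=1.0, window=40.0, percentile=50)
        assert abs(np.mean(fs) - 10) < 0.3


class TestComputeDff:
    def test_basic_identities(self):
        tr = FluoTraces(F=np.array([[2.0, 4.0, 2.0]]))
        d = sig.compute_dff(tr, np.array([2.0]), f0_method="window")
        assert np.allclose(d.dff, [[0.0, 1.0, 0.0]])

    def test_nonpositive_f0_rejected(self):
        tr = FluoTraces(F=np.ones((1, 5)))
        with pytest.raises(ValueError, match="sanity"):
            sig.compute_dff(tr, np.array([0.0]))

    def test_generator_amplitude_recovered(self):
        gt = synthgen.make_activity(5, duration=60, frame_rate=10.0,
                                    amplitude=0.5, noise_sigma=0.01,
                                    background_rate=0.05, seed=9)
        F0 = 200.0
        F = F0 * (1.0 + gt.observed)
        d = sig.compute_dff(FluoTraces(F=F), np.full(5, F0), f0_method="window")
        spikes = gt.spike_counts == 1
        if spikes.any():
            assert np.allclose(d.dff[spikes], 0.5, atol=0.05)

    def test_smooth_f0_centers_quiet_stretches(self):
        gt = synthgen.make_activity(4, duration=200, frame_rate=5.0,
                                    background_rate=0.03, noise_sigma=0.02, seed=10)
        F = 50.0 * (1.0 + gt.observed)
        tr = FluoTraces(F=F)
        fs = sig.estimate_f_smooth(tr, 5.0, window=30.0)
        d = sig.compute_dff(tr, fs, f0_method="smooth")
        quiet = gt.true_dff < 1e-6
        assert abs(np.median(d.dff[quiet])) < 0.5 * 0.02
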