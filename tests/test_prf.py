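"""Forward model correctness and pRF fitting behavior."""

import numpy as np
import pytest

from neuroreserve import (HRFModel, PRFEstimate, PRFParameterError, SearchGrid,
                          VisualFieldRaster, VoxelTimeSeries, filter_estimates,
                          fit_prf, predict_timeseries)
from neuroreserve.prf import CandidatePredictions
from neuroreserve.stimulus import StimulusAperture


def toy_aperture(n_frames: int = 8, seed: int = 5) -> StimulusAperture:
    """Tiny random binary movie on a 3x3 raster (1-degree pixels)."""
    raster = VisualFieldRaster(half_extent=1.0, step=1.0)
    rng = np.random.default_rng(seed)
    frames = rng.random((n_frames, 3, 3)) < 0.5
    frames[~frames.any(axis=(1, 2))] |= True  # no all-blank frames
    return StimulusAperture(kind="wedge", frames=frames, raster=raster,
                            frame_period=2.0, n_cycles=1)


def brute_force_prediction(x0, y0, sigma, aperture, hrf):
    """Independent oracle: explicit per-pixel summation and loop convolution."""
    xs = aperture.raster.axis
    ys = aperture.raster.axis[::-1]
    drive = []
    for frame in aperture.frames:
        acc = 0.0
        for i, py in enumerate(ys):
            for j, px in enumerate(xs):
                if frame[i, j]:
                    acc += np.exp(-((px - x0) ** 2 + (py - y0) ** 2)
                                  / (2 * sigma ** 2))
        drive.append(acc)
    kernel = hrf.kernel(aperture.frame_period)
    conv = []
    for t in range(len(drive)):
        acc = 0.0
        for lag, k in enumerate(kernel):
            if t - lag >= 0:
                acc += k * drive[t - lag]
        conv.append(acc)
    conv = np.array(conv)
    return conv / np.abs(conv).max()


class TestForwardModel:
    @pytest.mark.parametrize("params", [(0.0, 0.0, 1.0), (0.7, -0.4, 0.6),
                                        (-1.0, 1.0, 2.5)])
    def test_prediction_matches_bruteforce_oracle(self, params):
        ap = toy_aperture()
        hrf = HRFModel()
        got = predict_timeseries(*params, ap, hrf)
        want = brute_force_prediction(*params, ap, hrf)
        assert np.max(np.abs(got - want)) <= 1e-10 * np.max(np.abs(want))

    def test_delta_hrf_returns_raw_drive(self):
        ap = toy_aperture()
        x0, y0, sigma = 0.5, 0.5, 1.0
        got = predict_timeseries(x0, y0, sigma, ap, HRFModel.delta())
        g = np.exp(-((ap.raster.grids()[0] - x0) ** 2
                     + (ap.raster.grids()[1] - y0) ** 2) / (2 * sigma ** 2))
        drive = (ap.frames * g).sum(axis=(1, 2))
        assert np.allclose(got, drive / drive.max())

    def test_distant_gaussian_gives_flat_prediction(self, mapping_aperture, hrf):
        # centre 40 sigma away from every active pixel -> negligible drive
        pred = predict_timeseries(44.9, 44.9, 0.1, mapping_aperture, hrf)
        assert np.allclose(pred, 0.0)

    def test_invalid_sigma_rejected(self, mapping_aperture, hrf):
        with pytest.raises(PRFParameterError):
            predict_timeseries(0.0, 0.0, -1.0, mapping_aperture, hrf)

    def test_centre_outside_raster_rejected(self, mapping_aperture, hrf):
        with pytest.raises(PRFParameterError):
            predict_timeseries(60.0, 0.0, 2.0, mapping_aperture, hrf)


class TestHRF:
    def test_kernel_finite_and_unit_sum(self):
        k = HRFModel().kernel(2.0)
        assert np.all(np.isfinite(k))
        assert np.isclose(k.sum(), 1.0)
        assert k[0] == pytest.approx(0.0, abs=1e-6)  # causal, starts at lag 0

    def test_delta_kernel_is_identity(self):
        assert np.array_equal(HRFModel.delta().kernel(2.0), [1.0])


class TestFit:
    def test_exact_candidate_returns_itself(self, mapping_aperture, hrf, raster1):
        grid = SearchGrid.default(raster1, refine=False)
        cands = CandidatePredictions(grid, mapping_aperture, hrf)
        i = len(grid) // 2
        y = 2.0 * cands.P[i] + 7.0
        est = fit_prf(VoxelTimeSeries("v", y), mapping_aperture, hrf,
                      candidates=cands)
        assert est.variance_explained == pytest.approx(1.0, abs=1e-12)
        assert (est.x0, est.y0, est.sigma) == (grid.x0[i], grid.y0[i],
                                               grid.sigma[i])
        assert est.beta == pytest.approx(2.0)
        assert est.baseline == pytest.approx(7.0)

    def test_noiseless_roundtrip_recovers_parameters(self, mapping_aperture,
                                                     hrf, candidates):
        pred = predict_timeseries(5.0, -5.0, 2.0, mapping_aperture, hrf)
        est = fit_prf(VoxelTimeSeries("v", 1.5 * pred + 3.0),
                      mapping_aperture, hrf, candidates=candidates)
        assert est.variance_explained > 0.99
        assert abs(est.x0 - 5.0) < 0.05
        assert abs(est.y0 + 5.0) < 0.05
        assert abs(est.sigma - 2.0) < 0.05

    def test_returned_rss_not_worse_than_any_candidate(self, mapping_aperture,
                                                       hrf):
        # exhaustive check on a small grid with refinement off
        grid = SearchGrid(x0=[0.0, 5.0, -5.0, 10.0], y0=[0.0, 5.0, 5.0, -10.0],
                          sigma=[1.0, 2.0, 4.0, 8.0], refine=False)
        cands = CandidatePredictions(grid, mapping_aperture, hrf)
        rng = np.random.default_rng(11)
        y = rng.normal(size=mapping_aperture.n_frames)
        est = fit_prf(VoxelTimeSeries("v", y), mapping_aperture, hrf,
                      candidates=cands)
        yd = y - y.mean()
        best_rss = (1 - est.variance_explained) * yd @ yd
        for i in range(len(grid)):
            p = cands.P[i]
            pd = p - p.mean()
            q = pd @ pd
            beta = max((pd @ yd) / q, 0.0) if q > 0 else 0.0
            rss = yd @ yd - 2 * beta * (pd @ yd) + beta ** 2 * q
            assert best_rss <= rss + 1e-9

    def test_fit_invariant_to_affine_rescaling(self, mapping_aperture, hrf,
                                               candidates):
        pred = predict_timeseries(-8.0, 3.0, 3.0, mapping_aperture, hrf)
        rng = np.random.default_rng(3)
        y = pred + rng.normal(0, 0.2, len(pred))
        a = fit_prf(VoxelTimeSeries("a", y), mapping_aperture, hrf,
                    candidates=candidates)
        b = fit_prf(VoxelTimeSeries("b", 3.0 * y + 10.0), mapping_aperture,
                    hrf, candidates=candidates)
        assert (a.x0, a.y0, a.sigma) == pytest.approx((b.x0, b.y0, b.sigma))
        assert a.variance_explained == pytest.approx(b.variance_explained)
        assert b.beta == pytest.approx(3.0 * a.beta)

    def test_flat_series_flagged_degenerate(self, mapping_aperture, hrf,
                                            candidates):
        est = fit_prf(VoxelTimeSeries("v", np.full(mapping_aperture.n_frames,
                                                   4.2)),
                      mapping_aperture, hrf, candidates=candidates)
        assert est.degenerate
        assert est.variance_explained == 0.0

    def test_pure_noise_gives_low_variance_explained(self, mapping_aperture,
                                                     hrf, raster1):
        grid = SearchGrid.default(raster1, refine=False)
        cands = CandidatePredictions(grid, mapping_aperture, hrf)
        rng = np.random.default_rng(123)
        ves = []
        for i in range(100):
            y = rng.normal(size=mapping_aperture.n_frames)
            est = fit_prf(VoxelTimeSeries(i, y), mapping_aperture, hrf,
                          candidates=cands)
            ves.append(est.variance_explained)
        assert np.mean(ves) < 0.2

    def test_length_mismatch_rejected(self, mapping_aperture, hrf, candidates):
        with pytest.raises(ValueError):
            fit_prf(VoxelTimeSeries("v", np.ones(10)), mapping_aperture, hrf,
                    candidates=candidates)


class TestFilter:
    @staticmethod
    def _est(ve):
        return PRFEstimate("v", 0.0, 0.0, 1.0, 1.0, 0.0, ve)

    def test_threshold_is_inclusive(self):
        ests = [self._est(v) for v in (0.05, 0.19, 0.20, 0.90)]
        assert filter_estimates(ests, 0.20).n_retained == 2

    def test_zero_threshold_keeps_everything(self):
        ests = [self._est(v) for v in (0.0, 0.5, 1.0)]
        assert filter_estimates(ests, 0.0).n_retained == 3

    def test_unit_threshold_keeps_only_exact_fits(self):
        ests = [self._est(v) for v in (0.99, 1.0)]
        with np.errstate(all="ignore"):
            res = filter_estimates(ests, 1.0)
        assert [e.variance_explained for e in res.retained] == [1.0]

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            filter_estimates([self._est(0.1)], 0.5)
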