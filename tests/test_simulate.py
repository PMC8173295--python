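"""Synthetic cohort generator: lesions, perimetry, effects, GAS, determinism."""

import numpy as np
import pandas as pd
import pytest

from neuroreserve import (BLIND, RESERVE, SEEN, CohortSpec, Disc, LesionSpec,
                          VoxelTimeSeries, fit_prf, gas_association,
                          hemianopia, quadrantanopia)
from neuroreserve.simulate import (DEFAULT_CHANGED_MEANS, DEFAULT_EFFECT_MEANS,
                                   _draw_effects, choose_eye, random_lesion,
                                   simulate_cohort, simulate_gas,
                                   simulate_patient, simulate_perimetry,
                                   simulate_post_training, simulate_timeseries,
                                   simulate_voxels)


class TestLesionGeometry:
    def test_empty_lesion_removes_nothing(self):
        vox = simulate_voxels(LesionSpec(), 200, seed=0)
        assert vox["survives"].all()

    def test_full_hemifield_scotoma_clears_hemifield(self):
        vox = simulate_voxels(LesionSpec(scotoma=hemianopia("right")), 200,
                              seed=0)
        assert not vox.loc[vox["x0"] > 0, "survives"].any()
        assert vox.loc[vox["x0"] < 0, "survives"].all()

    def test_island_survival_matches_bruteforce_membership(self):
        island = Disc(10.0, 5.0, 3.0)
        lesion = LesionSpec(scotoma=hemianopia("right"), islands=(island,),
                            reserve_margin=2.0)
        vox = simulate_voxels(lesion, 500, seed=1)
        # independent re-derivation: survive unless (x >= margin and
        # outside the island disc)
        in_island = np.hypot(vox.x0 - 10.0, vox.y0 - 5.0) <= 3.0
        in_neural_scotoma = (vox.x0 >= 2.0) & ~in_island
        assert np.array_equal(vox["survives"].to_numpy(),
                              (~in_neural_scotoma).to_numpy())

    def test_island_must_lie_inside_scotoma(self):
        with pytest.raises(ValueError):
            LesionSpec(scotoma=hemianopia("right"),
                       islands=(Disc(-5.0, 0.0, 2.0),))

    def test_quadrant_erosion_shrinks_both_edges(self):
        q = quadrantanopia("right", "upper").erode(3.0)
        assert not q.contains(1.0, 1.0)
        assert q.contains(4.0, 4.0)

    def test_eye_choice_avoids_scotoma(self):
        assert choose_eye(LesionSpec(scotoma=hemianopia("right"))) == "left"
        assert choose_eye(LesionSpec(scotoma=hemianopia("left"))) == "right"


class TestPerimetrySimulation:
    def test_intact_field_decreases_with_eccentricity(self):
        pmap = simulate_perimetry(LesionSpec())
        ecc = pmap.grid.eccentricity()
        keep = ~pmap.grid.blind_spot
        order = np.argsort(ecc[keep])
        eccs, sens = ecc[keep][order], pmap.sensitivity[keep][order]
        distinct = np.diff(eccs) > 1e-9
        assert np.all(np.diff(sens)[distinct] < 0)

    def test_hemifield_scotoma_zeroes_38_locations(self):
        lesion = LesionSpec(scotoma=hemianopia("right"))
        pmap = simulate_perimetry(lesion)
        zero = pmap.sensitivity == 0.0
        assert zero[~pmap.grid.blind_spot].sum() == 38
        assert zero[pmap.grid.blind_spot].all()

    def test_same_seed_identical_maps(self):
        lesion = LesionSpec(scotoma=hemianopia("left"))
        a = simulate_perimetry(lesion, noise_sd=1.5, seed=3)
        b = simulate_perimetry(lesion, noise_sd=1.5, seed=3)
        assert np.array_equal(a.sensitivity, b.sensitivity)


class TestTrainingEffects:
    def test_zero_effects_leave_map_unchanged(self):
        pre = simulate_perimetry(LesionSpec(scotoma=hemianopia("right")))
        cats = np.full(76, SEEN, dtype=object)
        post, eff = simulate_post_training(
            pre, cats, {SEEN: 0.0, RESERVE: 0.0, BLIND: 0.0},
            mode="gaussian", gaussian_sd=0.0, seed=0)
        assert np.array_equal(post.sensitivity, pre.sensitivity)
        assert not eff.any()

    def test_deterministic_reserve_gain(self):
        lesion = LesionSpec(scotoma=hemianopia("right"))
        pre = simulate_perimetry(lesion)
        cats = np.where(pre.sensitivity == 0, RESERVE, SEEN).astype(object)
        post, _ = simulate_post_training(
            pre, cats, {RESERVE: 10.0, SEEN: 0.0, BLIND: 0.0},
            mode="gaussian", gaussian_sd=0.0, seed=0)
        change = post.sensitivity - pre.sensitivity
        reserve = (cats == RESERVE) & ~pre.grid.blind_spot
        assert np.all(change[reserve] == 10.0)
        assert not change[~reserve].any()

    def test_mixture_hits_category_and_changed_means(self):
        rng = np.random.default_rng(12)
        cats = np.full(10_000, RESERVE, dtype=object)
        eff = _draw_effects(cats, rng, DEFAULT_EFFECT_MEANS, "mixture",
                            DEFAULT_CHANGED_MEANS, 1.0, 1.5)
        assert np.mean(eff) == pytest.approx(DEFAULT_EFFECT_MEANS[RESERVE],
                                             abs=0.2)
        changed = eff[eff >= 1.0]
        assert changed.mean() == pytest.approx(DEFAULT_CHANGED_MEANS[RESERVE],
                                               abs=0.2)
        assert not eff[(eff > 0) & (eff < 1.0)].size  # zero-inflated at < 1 dB

    def test_floor_keeps_db_physical(self):
        pre = simulate_perimetry(LesionSpec(), noise_sd=0.0)
        cats = np.full(76, SEEN, dtype=object)
        post, _ = simulate_post_training(
            pre, cats, {SEEN: -100.0, RESERVE: 0.0, BLIND: 0.0},
            mode="gaussian", gaussian_sd=0.0, seed=0)
        assert np.all(post.sensitivity == 0.0)


class TestTimeseries:
    def test_infinite_snr_roundtrip_recovers_exactly(self, mapping_aperture,
                                                     hrf, candidates):
        vox = pd.DataFrame({"voxel_id": ["v0"], "x0": [6.0], "y0": [-4.0],
                            "sigma": [1.8], "survives": [True]})
        series = simulate_timeseries(vox, mapping_aperture, hrf, snr=np.inf,
                                     seed=0)
        est = fit_prf(series[0], mapping_aperture, hrf, candidates=candidates)
        assert est.variance_explained > 0.999
        assert abs(est.x0 - 6.0) < 0.05
        assert abs(est.y0 + 4.0) < 0.05
        assert abs(est.sigma - 1.8) < 0.05

    def test_fixed_seed_bit_identical(self, mapping_aperture, hrf):
        vox = simulate_voxels(LesionSpec(), 5, seed=2)
        a = simulate_timeseries(vox, mapping_aperture, hrf, snr=3.0, seed=9)
        b = simulate_timeseries(vox, mapping_aperture, hrf, snr=3.0, seed=9)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_run_averaging_shrinks_noise(self, mapping_aperture, hrf):
        vox = simulate_voxels(LesionSpec(), 40, seed=2)
        one = simulate_timeseries(vox, mapping_aperture, hrf, snr=3.0,
                                  n_runs=1, seed=9)
        four = simulate_timeseries(vox, mapping_aperture, hrf, snr=3.0,
                                   n_runs=4, seed=9)
        clean = simulate_timeseries(vox, mapping_aperture, hrf, snr=np.inf,
                                    seed=9)
        res1 = np.std([o.values - c.values for o, c in zip(one, clean)])
        res4 = np.std([o.values - c.values for o, c in zip(four, clean)])
        assert res4 == pytest.approx(res1 / 2.0, rel=0.1)


class TestGASSimulation:
    def test_zero_noise_is_exactly_collinear(self):
        gas = simulate_gas([0, 2, 4, 6, 8], noise_sd=0.0, seed=0)
        res = gas_association([0, 2, 4, 6, 8], gas)
        assert abs(res.r) == pytest.approx(1.0)

    def test_zero_slope_gives_null_association(self):
        rng = np.random.default_rng(0)
        rs = []
        for rep in range(60):
            counts = rng.integers(0, 15, 10)
            gas = simulate_gas(counts, slope=0.0, noise_sd=0.5, seed=rep)
            rs.append(gas_association(counts, gas).r)
        assert abs(np.mean(rs)) < 0.1

    def test_scores_clipped_to_scale(self):
        gas = simulate_gas([0, 1000], slope=1.0, noise_sd=0.0, seed=0)
        for rec in gas:
            assert all(-3.0 <= s <= 2.0 for s in rec.goal_scores)


class TestCohort:
    def test_cohort_is_deterministic_under_master_seed(self):
        spec = CohortSpec(n_patients=3, seed=5, raster_step=1.5)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert [p.seed for p in a.patients] == [p.seed for p in b.patients]

    def test_truth_labels_align_with_grid_and_effects(self):
        patient = simulate_patient(CohortSpec(raster_step=1.5), "p0", seed=3)
        assert len(patient.truth.category) == 76
        assert len(patient.true_effects) == 76
        # effects are only drawn for categorised (non-excluded) locations
        assert not patient.true_effects[~patient.truth.included].any()

    def test_random_lesion_reproducible(self):
        a = random_lesion(np.random.default_rng(7))
        b = random_lesion(np.random.default_rng(7))
        assert a == b
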