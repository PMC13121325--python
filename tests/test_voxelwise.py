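"""Basis-function / NNLS voxel fitting, delay maps, clustering, map assembly."""

import numpy as np
import pytest
from scipy.optimize import nnls

from lafovkin.kinetics_water import OneTCMParams, fit_onetcm, onetcm_forward
from lafovkin.petdata import TAC, DynamicImage, roi_tac
from lafovkin.voxelwise import (
    assemble_maps,
    build_basis,
    cluster_parametric,
    fit_voxels_basis,
    parametric_fdg,
    parametric_water,
    voxel_delay_map,
    voxel_fit_basis,
    voxel_fit_nnls3,
)


class TestBuildBasis:
    def test_grid_spacing(self, bolus_input):
        basis = build_basis(bolus_input, n=500, k2_range=(0.0, 6.0))
        assert basis.k2_grid[1] - basis.k2_grid[0] == pytest.approx(6.0 / 499)
        assert basis.k2_grid.size == 500
        assert np.all(np.diff(basis.k2_grid) > 0)

    def test_k2_zero_basis_is_running_integral(self, bolus_input):
        from lafovkin._numerics import dense_grid, frame_average, \
            resample_dense, running_integral

        basis = build_basis(bolus_input, n=3, k2_range=(0.0, 2.0))
        t = dense_grid(bolus_input.schedule, 1.0)
        c = resample_dense(bolus_input, t)
        expected = frame_average(running_integral(c, 1.0), t,
                                 bolus_input.schedule)
        np.testing.assert_allclose(basis.basis_frames[0], expected,
                                   atol=1e-12)

    def test_constant_input_closed_form(self):
        from lafovkin.petdata import FrameSchedule, InputFunction

        sched = FrameSchedule.from_durations([1.0] * 600)
        inp = InputFunction(TAC(sched, np.ones(600)))
        basis = build_basis(inp, n=2, k2_range=(2.0, 4.0))
        t_min = sched.mid_s / 60.0
        late = t_min > 0.75  # clear of the (0,0) onset ramp
        np.testing.assert_allclose(
            basis.basis_frames[0][late],
            (1.0 - np.exp(-2.0 * t_min[late])) / 2.0, rtol=0.005)

    def test_nonnegative_for_nonnegative_input(self, bolus_input):
        basis = build_basis(bolus_input, n=20)
        assert basis.basis_frames.min() >= -1e-12

    def test_too_few_bases_rejected(self, bolus_input):
        with pytest.raises(ValueError):
            build_basis(bolus_input, n=1)


class TestBasisFit:
    def test_all_zero_tac(self, bolus_input):
        basis = build_basis(bolus_input, n=50)
        tac = TAC(bolus_input.schedule,
                  np.zeros(bolus_input.schedule.n_frames))
        params, rss = voxel_fit_basis(tac, basis)
        assert params.K1 == 0.0 and params.VA == 0.0 and rss == 0.0

    def test_noiseless_recovery(self, bolus_input):
        truth = OneTCMParams(K1=0.4, k2=1.5, VA=0.03)
        y = onetcm_forward(truth, bolus_input)
        basis = build_basis(bolus_input, n=500)
        params, _ = voxel_fit_basis(y, basis)
        step = basis.k2_grid[1] - basis.k2_grid[0]
        assert abs(params.k2 - truth.k2) <= step
        assert params.K1 == pytest.approx(truth.K1, rel=0.02)

    def test_matches_per_basis_nnls_brute_force(self, bolus_input):
        y = onetcm_forward(OneTCMParams(0.4, 1.5, 0.03), bolus_input)
        basis = build_basis(bolus_input, n=10, k2_range=(0.1, 3.0))
        w = bolus_input.schedule.duration_s \
            / bolus_input.schedule.duration_s.sum()
        sw = np.sqrt(w)
        best = None
        for j in range(10):
            A = np.column_stack([basis.basis_frames[j], basis.input_frames])
            theta, rnorm = nnls(A * sw[:, None], y.values * sw)
            if best is None or rnorm ** 2 < best[0]:
                best = (rnorm ** 2, j, theta)
        params, rss = voxel_fit_basis(y, basis)
        assert params.k2 == pytest.approx(basis.k2_grid[best[1]])
        assert params.K1 == pytest.approx(best[2][0], abs=1e-9)
        assert params.VA == pytest.approx(best[2][1], abs=1e-9)
        assert rss == pytest.approx(best[0], abs=1e-9)

    def test_nonnegativity_and_grid_optimality(self, bolus_input, rng):
        basis = build_basis(bolus_input, n=40, k2_range=(0.0, 4.0))
        clean = onetcm_forward(OneTCMParams(0.5, 1.0, 0.1),
                               bolus_input).values
        Y = clean + rng.standard_normal((20, clean.size)) * 0.1 * clean.max()
        res = fit_voxels_basis(Y, basis)
        assert np.all(res["K1"] >= 0) and np.all(res["VA"] >= 0)
        # winning RSS no worse than any fixed-k2 NNLS solution
        w = bolus_input.schedule.duration_s \
            / bolus_input.schedule.duration_s.sum()
        sw = np.sqrt(w)
        for v in range(0, 20, 5):
            for j in (0, 13, 39):
                A = np.column_stack([basis.basis_frames[j],
                                     basis.input_frames])
                _, rnorm = nnls(A * sw[:, None], Y[v] * sw)
                assert res["rss"][v] <= rnorm ** 2 + 1e-10


class TestNnls3:
    def test_noiseless_recovery(self, bolus_input):
        truth = OneTCMParams(K1=0.4, k2=1.5, VA=0.03)
        y = onetcm_forward(truth, bolus_input)
        params, _ = voxel_fit_nnls3(y, bolus_input)
        assert params.K1 == pytest.approx(truth.K1, rel=0.03)
        assert params.k2 == pytest.approx(truth.k2, rel=0.03)
        assert params.VA == pytest.approx(truth.VA, rel=0.03)

    def test_blood_only_voxel(self, bolus_input):
        y = onetcm_forward(OneTCMParams(0.0, 0.0, 0.4), bolus_input)
        params, _ = voxel_fit_nnls3(y, bolus_input)
        assert params.K1 <= 1e-4
        assert params.VA == pytest.approx(0.4, rel=0.02)

    def test_zero_input_rejected(self, bolus_input):
        zeros = bolus_input.with_values(np.zeros(bolus_input.values.size))
        y = TAC(bolus_input.schedule, np.ones(bolus_input.values.size))
        with pytest.raises(ValueError):
            voxel_fit_nnls3(y, zeros)

    def test_agrees_with_basis_method_on_noiseless_voxels(self, bolus_input):
        basis = build_basis(bolus_input, n=500)
        for k1, k2, va in [(0.4, 1.5, 0.03), (1.0, 1.2, 0.1),
                           (0.1, 0.4, 0.02)]:
            y = onetcm_forward(OneTCMParams(k1, k2, va), bolus_input)
            pb, _ = voxel_fit_basis(y, basis)
            pn, _ = voxel_fit_nnls3(y, bolus_input)
            assert pn.K1 == pytest.approx(pb.K1, rel=0.05)


class TestDelayMapAndMaps:
    def _mini_image(self, bolus_input, params_list, shape=(3, 2, 1)):
        n = int(np.prod(shape))
        vox = np.zeros(shape + (bolus_input.schedule.n_frames,))
        flat = vox.reshape(n, -1)
        for i in range(n):
            p = params_list[i % len(params_list)]
            flat[i] = onetcm_forward(p, bolus_input).values
        return DynamicImage(vox, np.array([3.0, 3.0, 3.0]),
                            bolus_input.schedule)

    def test_injected_delay_recovered_modally(self, bolus_input):
        img = self._mini_image(
            bolus_input, [OneTCMParams(0.5, 1.0, 0.05, delay_s=4.0)])
        mask = np.ones(img.shape3, bool)
        dmap = voxel_delay_map(img, bolus_input, mask,
                               delay_grid=[0.0, 2.0, 4.0, 6.0], n_basis=200)
        vals, counts = np.unique(dmap[mask], return_counts=True)
        assert vals[np.argmax(counts)] == 4.0

    def test_zero_delay_phantom_gives_zero(self, bolus_input):
        img = self._mini_image(bolus_input, [OneTCMParams(0.5, 1.0, 0.05)])
        mask = np.ones(img.shape3, bool)
        dmap = voxel_delay_map(img, bolus_input, mask,
                               delay_grid=[0.0, 2.0, 4.0], n_basis=200)
        assert np.all(dmap[mask] == 0.0)

    def test_liver_voxels_inherit_roi_delay(self, bolus_input):
        img = self._mini_image(bolus_input, [OneTCMParams(0.5, 1.0, 0.05)])
        mask = np.ones(img.shape3, bool)
        liver = np.zeros(img.shape3, bool)
        liver[0, 0, 0] = True
        maps = parametric_water(img, bolus_input, mask,
                                delay_grid=[0.0, 2.0], n_basis=100,
                                liver_mask=liver, liver_input=bolus_input,
                                liver_delay_s=7.5)
        assert maps["delay"][0, 0, 0] == 7.5
        assert np.all(maps["delay"][~liver & mask] != 7.5)

    def test_roi_mean_matches_roi_fit(self, water_phantom):
        img, seg, truth = water_phantom
        mask = seg.mask("spleen")
        maps = parametric_water(img, truth.input, mask,
                                delay_grid=[0.0, 3.0, 6.0], n_basis=500)
        roi_fit = fit_onetcm(roi_tac(img, seg, "spleen"), truth.input,
                             n_starts=30, delay_grid=[0.0, 3.0, 6.0], seed=0)
        assert maps.roi_mean("K1", mask) == pytest.approx(roi_fit.params.K1,
                                                          rel=0.02)
        assert maps.roi_mean("h2o_flow", mask) == pytest.approx(
            roi_fit.h2o_flow, rel=0.02)

    def test_assemble_maps_rules(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        maps = assemble_maps({"K1": np.array([0.7]),
                              "VA": np.array([0.0])}, (2, 2, 2), mask)
        assert maps["K1"][0, 0, 0] == 0.7
        assert np.isnan(maps["K1"][1, 1, 1])
        np.testing.assert_array_equal(maps["h2o_flow"][mask],
                                      maps["K1"][mask])
        with pytest.raises(ValueError):
            assemble_maps({"K1": np.ones(5)}, (2, 2, 2), mask)


class TestParametricFdg:
    def test_voxel_patlak_matches_regional(self, fdg_plasma):
        from lafovkin.kinetics_fdg import patlak
        from lafovkin.phantom import twotcm_irreversible_forward

        tac = twotcm_irreversible_forward(0.1, 0.15, 0.05, fdg_plasma)
        vox = np.tile(tac.values, (2, 2, 1, 1)).reshape(2, 2, 1, -1)
        img = DynamicImage(vox, np.ones(3), fdg_plasma.schedule)
        mask = np.ones((2, 2, 1), bool)
        maps = parametric_fdg(img, fdg_plasma, mask, t_star_min=20.0)
        regional = patlak(tac, fdg_plasma, t_star_min=20.0)
        assert maps.roi_mean("Ki", mask) == pytest.approx(regional.Ki,
                                                          rel=1e-6)
        assert maps.roi_mean("V", mask) == pytest.approx(regional.V,
                                                         rel=1e-4)


class TestClustering:
    def _map_and_mask(self, values):
        vol = np.zeros((len(values), 1, 1))
        vol[:, 0, 0] = values
        return vol, np.ones_like(vol, bool)

    def test_separable_three_way_partition(self, rng):
        vals = np.concatenate([rng.normal(1.0, 0.1, 100),
                               rng.normal(5.0, 0.1, 100),
                               rng.normal(9.0, 0.1, 100)])
        vol, mask = self._map_and_mask(vals)
        lab = cluster_parametric(vol, mask, k=3)
        got = lab.labels[mask]
        means = [vals[got == i].mean() for i in (1, 2, 3)]
        assert [int((got == i).sum()) for i in (1, 2, 3)] == [100, 100, 100]
        assert means[0] < means[1] < means[2]

    def test_permutation_invariance(self, rng):
        vals = np.concatenate([rng.normal(1.0, 0.1, 60),
                               rng.normal(5.0, 0.1, 60),
                               rng.normal(9.0, 0.1, 60)])
        perm = rng.permutation(vals.size)
        vol1, mask = self._map_and_mask(vals)
        vol2, _ = self._map_and_mask(vals[perm])
        lab1 = cluster_parametric(vol1, mask, k=3).labels[mask]
        lab2 = cluster_parametric(vol2, mask, k=3).labels[mask]
        np.testing.assert_array_equal(lab1[perm], lab2)

    def test_constant_map_paths(self):
        vol, mask = self._map_and_mask(np.full(10, 2.0))
        with pytest.raises(ValueError, match="constant"):
            cluster_parametric(vol, mask, k=3)
        with pytest.warns(UserWarning):
            lab = cluster_parametric(vol, mask, k=3, on_constant="single")
        assert set(np.unique(lab.labels[mask])) == {1}

    def test_fewer_voxels_than_clusters(self):
        vol, mask = self._map_and_mask(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="fewer"):
            cluster_parametric(vol, mask, k=3)

    def test_kidney_cortex_mean_exceeds_medulla(self, water_phantom, rng):
        img, seg, truth = water_phantom
        kidney = seg.mask("kidney_cortex") | seg.mask("kidney_medulla")
        # perfusion map from truth K1 plus mild estimation-like scatter
        k1 = np.zeros(seg.labels.shape)
        k1[seg.mask("kidney_cortex")] = 2.5
        k1[seg.mask("kidney_medulla")] = 0.8
        k1 += rng.normal(0.0, 0.05, k1.shape)
        lab = cluster_parametric(k1, kidney, k=2)
        m1 = k1[lab.labels == 1].mean()
        m2 = k1[lab.labels == 2].mean()
        assert m2 > m1
        # the high cluster is the cortex
        cortex_frac = seg.mask("kidney_cortex")[lab.labels == 2].mean()
        assert cortex_frac > 0.9
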