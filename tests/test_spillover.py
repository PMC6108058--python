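import numpy as np
import pytest

from neuropil.spillover_sim import (DiffusionParams, KineticScheme,
                                    SchemeError, build_geometry,
                                    check_receptor_pair, receptor_response,
                                    simulate, stc_metrics)


class TestGeometry:
    @pytest.mark.parametrize("r,expected", [(0.05, 0.05 / 3), (0.30, 0.10),
                                            (0.45, 0.15)])
    def test_psd_radius_rule(self, r, expected):
        geom = build_geometry(r)
        assert geom.r_psd == pytest.approx(expected)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            build_geometry(0.0)
        with pytest.raises(ValueError):
            build_geometry(0.6)

    def test_region_partitions(self):
        geom = build_geometry(0.2)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.4, 0.4, (20000, 3))
        cleft = geom.in_cleft(pts)
        term = geom.in_terminal(pts)
        extra = geom.in_extrasyn(pts)
        psd = geom.in_psd_cylinder(pts)
        assert not (cleft & term).any()
        assert (psd <= cleft).all() and (extra <= cleft).all()
        assert not (psd & extra).any()
        # transporter space excludes cleft, terminals and the 50-nm collar
        trans = geom.in_transporter_space(pts)
        assert not (trans & cleft).any() and not (trans & term).any()
        assert not (trans & (geom.dist_to_terminal_surface(pts)
                             <= geom.extrasyn_width)).any()

    def test_volumes(self):
        geom = build_geometry(0.3)
        assert geom.psd_cleft_volume == pytest.approx(
            np.pi * 0.1 ** 2 * 0.02)
        assert geom.extrasyn_volume == pytest.approx(
            np.pi * (0.3 ** 2 - 0.1 ** 2) * 0.02)


class TestKineticSchemes:
    def test_builtin_schemes_load_and_validate(self):
        for name in ("glt1", "glua", "glun"):
            scheme = KineticScheme.builtin(name)
            A, B = scheme.rate_matrices()
            assert np.allclose(A.sum(axis=1), 0, atol=1e-12)
            assert np.allclose(B.sum(axis=1), 0, atol=1e-12)

    def test_q10_correction(self):
        glt1 = KineticScheme.builtin("glt1")
        assert glt1.q10_factor(36.5) == pytest.approx(3 ** 1.35)
        assert glt1.q10_factor(glt1.t_ref_celsius) == pytest.approx(1.0)

    def test_receptor_pair_property(self):
        glua = KineticScheme.builtin("glua")
        glun = KineticScheme.builtin("glun")
        assert check_receptor_pair(glun, glua)
        with pytest.raises(SchemeError):
            check_receptor_pair(glua, glun)  # reversed roles must fail

    def test_steady_state_is_stationary(self):
        glua = KineticScheme.builtin("glua")
        ss = glua.steady_state(100.0)
        A, B = glua.rate_matrices()
        assert np.abs((A + 100.0 * B).T @ ss).max() < 1e-12


class TestReceptorResponse:
    def test_zero_waveform(self):
        glua = KineticScheme.builtin("glua")
        po = receptor_response(np.zeros(500), glua)
        assert (po == 0).all()

    def test_constant_drive_reaches_null_space_steady_state(self):
        glua = KineticScheme.builtin("glua")
        c = 1000.0  # μM, saturating
        po = receptor_response(np.full(6000, c), glua, dt=5.0,
                               quantize=0)  # 30 s reaches the slow manifold
        target = glua.steady_state(c)
        open_ss = target[[glua.states.index(s)
                          for s in glua.open_states]].sum()
        assert po[-1] == pytest.approx(open_ss, abs=1e-8)

    def test_glun_outlasts_glua(self):
        glua = KineticScheme.builtin("glua")
        glun = KineticScheme.builtin("glun")
        wave = np.zeros(8000)
        wave[:1000] = 1000.0  # 1 ms pulse, then washout
        halves = {}
        for name, scheme in (("glua", glua), ("glun", glun)):
            po = receptor_response(wave, scheme)
            pk = po.argmax()
            below = np.flatnonzero(po[pk:] <= 0.5 * po[pk])
            halves[name] = below[0] if len(below) else len(po)
        assert halves["glun"] > halves["glua"]

    def test_occupancy_stays_normalised(self):
        glun = KineticScheme.builtin("glun")
        rng = np.random.default_rng(0)
        wave = rng.uniform(0, 5000, 2000)
        receptor_response(wave, glun)  # raises if occupancy leaks > 1e-9


class TestSTCMetrics:
    def test_single_bin(self):
        flux = np.zeros(5000)
        flux[1999] = 4.0  # all flux at t = 2 ms
        m = stc_metrics(flux, dt=1e-3)
        assert m["centroid"] == pytest.approx(2.0)

    def test_two_equal_bins(self):
        flux = np.zeros(5000)
        flux[999] = flux[2999] = 1.0
        assert stc_metrics(flux, dt=1e-3)["centroid"] == pytest.approx(2.0)

    def test_asymmetric(self):
        flux = np.zeros(4000)
        flux[[999, 1999, 2999]] = [1.0, 2.0, 1.0]
        assert stc_metrics(flux, dt=1e-3)["centroid"] == pytest.approx(2.0)
        flux[[999, 1999, 2999]] = [1.0, 1.0, 2.0]
        assert stc_metrics(flux, dt=1e-3)["centroid"] == pytest.approx(2.25)

    def test_all_zero_flagged(self):
        m = stc_metrics(np.zeros(100))
        assert not m["defined"] and np.isnan(m["centroid"])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stc_metrics(np.array([1.0, -0.5]))


class TestSimulation:
    def test_conservation_every_step(self):
        geom = build_geometry(0.15)
        params = DiffusionParams(n_steps=600)
        res = simulate(geom, params, seed=4)
        assert res.conservation_error() == 0

    def test_frozen_diffusion_keeps_molecules_in_cleft(self):
        geom = build_geometry(0.2)
        params = DiffusionParams(D_cleft=1e-12, n_steps=300)
        res = simulate(geom, params, seed=0)
        # all molecules stay at the release point above the PSD
        expected = params.n_molecules / (geom.psd_cleft_volume * 602.214)
        np.testing.assert_allclose(res.glu_cleft, expected, rtol=1e-12)

    def test_msd_free_diffusion(self):
        geom = build_geometry(0.15)
        params = DiffusionParams(n_steps=1000)
        res = simulate(geom, params, seed=7, free_diffusion=True,
                       record_msd=True)
        slope = (res.msd * res.time).sum() / (res.time ** 2).sum()
        assert slope == pytest.approx(6 * params.D_out, rel=0.02)

    def test_dt_warning(self):
        geom = build_geometry(0.1)
        params = DiffusionParams(dt=0.05, n_steps=10)
        res = simulate(geom, params, seed=0)
        assert any("RMS" in w for w in res.warnings)

    def test_batched_repeats_match_singles_in_expectation(self):
        geom = build_geometry(0.1)
        params = DiffusionParams(n_steps=400)
        batched = simulate(geom, params, seed=1, n_repeats=3)
        assert batched.n_total == 3 * params.n_molecules
        single = simulate(geom, params, seed=2, n_repeats=1)
        # same scale of cleft concentration (loose, stochastic)
        assert batched.glu_cleft.max() == pytest.approx(
            single.glu_cleft.max(), rel=0.1)
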