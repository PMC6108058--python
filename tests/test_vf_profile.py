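import numpy as np
import pytest

from neuropil.equidistant_vf import contact_fraction, vf_profile
from neuropil.mesh_core import NeuropilScene, SceneObject
from neuropil.synthetic_neuropil import make_sphere, make_spine, wrap_astro


class TestShellRecovery:
    def test_known_shell_profile(self, shell_scene):
        """Astro shell at surface distances [0.05, 0.10] -> VF 1 in the
        covered bin, VF_max at 0.075."""
        p = vf_profile(shell_scene, "sp", "object_surface", d_max=0.3,
                       n_samples=80_000, seed=1)
        assert p.vf[2] == pytest.approx(1.0, abs=0.02)   # bin [0.06, 0.09)
        assert p.vf[5] == pytest.approx(0.0, abs=0.01)   # far bin
        assert p.d_at_vf_max == pytest.approx(0.075)
        assert np.nanmax(p.vf) <= 1.0 and np.nanmin(p.vf) >= 0.0

    def test_no_astrocyte_gives_zero(self, shell_scene):
        bare = NeuropilScene([shell_scene.get("sp")], shell_scene.block_bounds)
        p = vf_profile(bare, "sp", "object_surface", d_max=0.3,
                       n_samples=20_000, seed=0)
        assert np.nanmax(p.vf) == 0.0 and p.vf_max == 0.0

    def test_coverage_fraction_recovered(self):
        mesh, mt = make_sphere(0.2, subdivisions=3, label="sp")
        wrap, wt = wrap_astro((0, 0, 0), 0.2, offset=0.06, thickness=0.06,
                              coverage=0.5)
        scene = NeuropilScene(
            [SceneObject("sp", mesh, "spine", truth=mt),
             SceneObject("w", wrap, "astrocyte", truth=wt)],
            [[-2, -2, -2], [2, 2, 2]])
        p = vf_profile(scene, "sp", "object_surface", d_max=0.3,
                       n_samples=120_000, seed=2)
        # bin [0.06, 0.09) lies fully inside the partial shell
        assert p.vf[2] == pytest.approx(0.5, abs=0.05)

    def test_standard_error_reported(self, shell_scene):
        p = vf_profile(shell_scene, "sp", "object_surface", d_max=0.3,
                       n_samples=80_000, seed=1)
        ok = np.isfinite(p.vf_se)
        assert (p.vf_se[ok] >= 0).all()
        covered = p.n_points > 500
        assert (p.vf_se[covered] <= 0.05).all()

    def test_sparse_sampling_gives_missing_not_zero(self, shell_scene):
        p = vf_profile(shell_scene, "sp", "object_surface", d_max=0.9,
                       n_samples=60, seed=3)
        assert np.isnan(p.vf).any(), "empty shells must be NaN, never 0"

    def test_class_split_sums_to_total(self, shell_scene):
        p = vf_profile(shell_scene, "sp", "object_surface", d_max=0.3,
                       n_samples=60_000, seed=4, by_class=True)
        ok = np.isfinite(p.vf)
        total = np.nan_to_num(p.vf_leaflet[ok]) + \
            np.nan_to_num(p.vf_branchlet[ok])
        assert (total <= p.vf[ok] + 1e-9).all()


@pytest.fixture(scope="module")
def spine_scene():
    spine, psd, truth = make_spine(0.2, neck_len=0.3, neck_radius=0.06,
                                   n_theta=32, n_arc=24)
    wrap, wt = wrap_astro(truth["head_center"], 0.2, offset=0.0,
                          thickness=0.05, coverage=0.5,
                          cap_axis=-truth["axis"], n_theta=32, n_arc=20)
    return NeuropilScene(
        [SceneObject("spine0", spine, "spine", truth=truth),
         SceneObject("psd0", psd, "psd", parent="spine0"),
         SceneObject("w", wrap, "astrocyte", truth=wt)],
        [[-2, -2, -2], [2, 2, 2]]), truth


class TestModes:
    def test_psd_center_peak_reflects_head_radius(self, spine_scene):
        scene, truth = spine_scene
        p_c = vf_profile(scene, "spine0", "psd_center", d_max=0.6,
                         n_samples=60_000, seed=5)
        p_s = vf_profile(scene, "spine0", "spine_surface", d_max=0.6,
                         n_samples=60_000, seed=5)
        # membrane-hugging coverage: spine_surface peak sits in the first
        # bins; the psd_center peak is pushed out by roughly the head size
        assert p_s.d_at_vf_max <= 3 * 0.03 + 1e-9
        assert p_c.d_at_vf_max - p_s.d_at_vf_max >= 0.8 * truth["head_radius"]

    def test_psd_edge_mode_runs(self, spine_scene):
        scene, _ = spine_scene
        p = vf_profile(scene, "spine0", "psd_edge", d_max=0.6,
                       n_samples=60_000, seed=6)
        assert np.nanmax(p.vf) > 0

    def test_unknown_mode(self, spine_scene):
        scene, _ = spine_scene
        with pytest.raises(ValueError, match="unknown mode"):
            vf_profile(scene, "spine0", "sideways")


class TestContactFraction:
    def test_constructed_contact_percentage(self):
        objs = []
        n_contact, n_total = 4, 6
        for i in range(n_total):
            c = np.array([i * 1.2, 0.0, 0.0])
            mesh, mt = make_sphere(0.15, center=c, label=f"s{i}")
            objs.append(SceneObject(f"s{i}", mesh, "spine", truth=mt))
            if i < n_contact:
                wrap, wt = wrap_astro(c, 0.15, offset=0.02, thickness=0.04,
                                      coverage=0.4)
                objs.append(SceneObject(f"w{i}", wrap, "astrocyte",
                                        process_class="leaflet", truth=wt))
        scene = NeuropilScene(objs, [[-1, -1, -1], [7, 1, 1]])
        res = contact_fraction(scene, "leaflet", d_contact=0.05,
                               n_samples=800, seed=0)
        assert res["percentage"] == pytest.approx(100 * n_contact / n_total,
                                                  abs=1e-9)

    def test_process_beyond_threshold_not_counted(self):
        mesh, mt = make_sphere(0.15, label="s0")
        wrap, wt = wrap_astro((0, 0, 0), 0.15, offset=0.06, thickness=0.04,
                              coverage=0.5)
        scene = NeuropilScene(
            [SceneObject("s0", mesh, "spine", truth=mt),
             SceneObject("w0", wrap, "astrocyte", process_class="leaflet",
                         truth=wt)],
            [[-1, -1, -1], [1, 1, 1]])
        res = contact_fraction(scene, "leaflet", d_contact=0.05,
                               n_samples=800, seed=0)
        assert res["percentage"] == 0.0
        # but it appears in the distance curve at larger thresholds
        grid = res["distance_grid"]
        assert res["percentage_curve"][grid >= 0.08].max() == 100.0

    def test_no_spines_errors(self):
        wrap, wt = wrap_astro((0, 0, 0), 0.15, 0.02, 0.04, 0.5)
        scene = NeuropilScene([SceneObject("w", wrap, "astrocyte", truth=wt)],
                              [[-1, -1, -1], [1, 1, 1]])
        with pytest.raises(ValueError, match="no spines"):
            contact_fraction(scene, "leaflet")
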