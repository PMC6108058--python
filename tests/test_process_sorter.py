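import numpy as np
import pandas as pd
import pytest

from neuropil.process_sorter import (Leaflet, cluster_svr, leaflet_stats,
                                     nn_distance_mixture,
                                     nn_volume_correlation, paint_and_segment,
                                     secant_samples)
from neuropil.synthetic_neuropil import (make_astro_arbor, make_tube,
                                         primitive_contains)


class PrimitiveAstro:
    """Adapter exposing a mesh + analytic inside test to the sorter."""

    def __init__(self, mesh, prim):
        self.composite = mesh
        self._prim = prim

    def contains(self, pts):
        return primitive_contains(self._prim, pts)


class TestSecantSamples:
    def test_plate_limit(self):
        from neuropil.synthetic_neuropil import make_sheet
        sheet, st = make_sheet((2.0, 2.0, 0.05), (0, 0, 0), max_edge=0.2)
        s = secant_samples(PrimitiveAstro(sheet, st["primitive"]), seed=0,
                           point_density=10)
        central = s[(s.x.abs() < 0.5) & (s.y.abs() < 0.5)]
        assert central.svr.median() == pytest.approx(2 / 0.05, rel=0.10)

    def test_rod_limit_thin(self):
        tube, tt = make_tube(0.05, 6.0)
        s = secant_samples(PrimitiveAstro(tube, tt["primitive"]), seed=0,
                           point_density=30)
        central = s[s.x.abs() < 2.0]
        assert central.svr.median() == pytest.approx(2 / 0.05, rel=0.10)

    def test_rod_limit_wide_secant(self):
        """With the larger 600-nm secant sphere a 0.2-μm rod reaches its
        asymptotic SVR of 2/rho = 10 /μm."""
        tube, tt = make_tube(0.2, 6.0)
        s = secant_samples(PrimitiveAstro(tube, tt["primitive"]),
                           sphere_radius=0.6, seed=0, point_density=20)
        central = s[s.x.abs() < 2.0]
        assert central.svr.median() == pytest.approx(10.0, rel=0.10)

    def test_radius_below_resolution_rejected(self):
        tube, tt = make_tube(0.2, 6.0)
        with pytest.raises(ValueError, match="resolution"):
            secant_samples(PrimitiveAstro(tube, tt["primitive"]),
                           sphere_radius=0.002)

    def test_invariants(self):
        arb = make_astro_arbor(seed=2)
        s = secant_samples(arb, seed=2)
        assert (s.local_volume > 0).all()
        assert (s.svr > 0).all()


class TestClusterSVR:
    def test_two_population_accuracy(self):
        arb = make_astro_arbor(seed=1)
        s = secant_samples(arb, seed=1)
        lab, summary = cluster_svr(s, seed=0)
        fc, _ = paint_and_segment(arb, lab)
        truth = np.where(arb.face_class == 1, "leaflet", "branchlet")
        assert (fc == truth).mean() >= 0.95
        assert summary["mean_svr_leaflet"] > summary["mean_svr_branchlet"]

    def test_identical_samples_error(self):
        df = pd.DataFrame({"x": [0, 0], "y": [0, 0], "z": [0, 0],
                           "face": [0, 0], "local_area": [1.0, 1.0],
                           "local_volume": [0.5, 0.5], "svr": [2.0, 2.0]})
        with pytest.raises(ValueError, match="distinct"):
            cluster_svr(df)

    def test_duplication_invariance(self):
        arb = make_astro_arbor(seed=3)
        s = secant_samples(arb, seed=3)
        lab1, _ = cluster_svr(s, seed=0)
        doubled = pd.concat([s, s], ignore_index=True)
        lab2, _ = cluster_svr(doubled, seed=0)
        assert (lab1["cluster"].to_numpy()
                == lab2["cluster"].to_numpy()[:len(s)]).all()


def truth_labelled_samples(arb, seed=0):
    """Secant samples labelled by construction truth (bypasses clustering)."""
    s = secant_samples(arb, seed=seed)
    s = s.copy()
    s["cluster"] = np.where(arb.face_class[s["face"]] == 1, "leaflet",
                            "branchlet")
    return s


class TestPaintAndSegment:
    def test_five_sheets_one_parent(self):
        # spacing comfortably above the secant radius so the majority vote
        # cannot bridge neighbouring sheets across the tube surface
        arb = make_astro_arbor(n_sheets=5, spacing=0.45, seed=4,
                               sheet_extents=(0.04, 0.35, 0.4), angles=0.0)
        fc, leaflets = paint_and_segment(arb, truth_labelled_samples(arb))
        assert len(leaflets) == 5
        assert len({lf.parent for lf in leaflets}) == 1
        assert not any(lf.orphan for lf in leaflets)
        nn = np.array([lf.nn_distance for lf in leaflets])
        # attachment centroids are blurred by the vote radius; spacing is
        # still recovered well within half the secant diameter
        np.testing.assert_allclose(nn, 0.45, atol=0.12)
        assert nn.mean() == pytest.approx(0.45, abs=0.05)

    def test_area_conservation(self):
        arb = make_astro_arbor(seed=5)
        fc, _ = paint_and_segment(arb, truth_labelled_samples(arb))
        tri = arb.composite.vertices[arb.composite.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        total = arb.composite.area
        split = areas[fc == "leaflet"].sum() + areas[fc == "branchlet"].sum()
        assert split == pytest.approx(total, rel=1e-12)

    def test_all_branchlet_surface(self):
        arb = make_astro_arbor(n_sheets=0, spacings=[], seed=6)
        s = secant_samples(arb, seed=6).copy()
        s["cluster"] = "branchlet"
        fc, leaflets = paint_and_segment(arb, s)
        assert len(leaflets) == 0 and (fc == "branchlet").all()

    def test_detached_sheet_is_orphan(self):
        from neuropil.mesh_core import TriMesh
        from neuropil.synthetic_neuropil import make_sheet
        tube, tt = make_tube(0.25, 3.0)
        sheet, st = make_sheet((0.04, 0.4, 0.4), (0.0, 0.0, 1.2))  # far away
        verts = np.concatenate([tube.vertices, sheet.vertices])
        faces = np.concatenate([tube.faces,
                                sheet.faces + len(tube.vertices)])

        class Arb:
            composite = TriMesh(verts, faces, clean=False)
            face_class = np.concatenate([np.zeros(len(tube.faces), np.int8),
                                         np.ones(len(sheet.faces), np.int8)])

            def contains(self, pts):
                return (primitive_contains(tt["primitive"], pts)
                        | primitive_contains(st["primitive"], pts))

        arb = Arb()
        fc, leaflets = paint_and_segment(arb, truth_labelled_samples(arb))
        assert len(leaflets) == 1
        assert leaflets[0].orphan and leaflets[0].parent is None

    def test_leaflet_morphology_matches_truth(self):
        arb = make_astro_arbor(n_sheets=3, spacing=0.6, seed=7,
                               sheet_extents=(0.05, 0.5, 0.5))
        fc, leaflets = paint_and_segment(arb, truth_labelled_samples(arb))
        assert len(leaflets) == 3
        for lf in leaflets:
            # a 0.05 x 0.5 x 0.5 box sheet: volume 0.0125, SVR ~ 44
            assert lf.volume == pytest.approx(0.0125, rel=0.25)
            assert 30 < lf.svr < 60


class TestLeafletStats:
    def _leaflet(self, i=0, vol=0.0125, surf=0.6):
        return Leaflet(i, None, 0, vol, surf, surf / vol, np.zeros(3),
                       nn_distance=0.25)

    def test_table_and_skewness(self):
        rng = np.random.default_rng(0)
        lfs = [self._leaflet(i, vol=float(v))
               for i, v in enumerate(rng.lognormal(-4, 0.5, 30))]
        df = leaflet_stats(lfs)
        assert len(df) == 30
        assert df.attrs["skewness"]["volume"] > 0  # lognormal is right-skewed

    def test_empty_list(self):
        df = leaflet_stats([])
        assert len(df) == 0

    def test_duplicate_rows_identical(self):
        df = leaflet_stats([self._leaflet(0), self._leaflet(0)])
        assert df.iloc[0].equals(df.iloc[1])


class TestNNDistanceMixture:
    def test_two_gaussian_recovery(self):
        rng = np.random.default_rng(5)
        pick = rng.uniform(size=500) < 0.5
        d = np.where(pick, rng.normal(0.23, 0.05, 500),
                     rng.normal(0.58, 0.05, 500))
        fit = nn_distance_mixture(d, seed=0)
        assert fit["means"][0] == pytest.approx(0.23, abs=0.02)
        assert fit["means"][1] == pytest.approx(0.58, abs=0.02)

    def test_replicate_recovery_within_posterior_sd(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            pick = rng.uniform(size=400) < 0.5
            d = np.where(pick, rng.normal(0.23, 0.05, 400),
                         rng.normal(0.58, 0.05, 400))
            fit = nn_distance_mixture(d, seed=rep)
            se = fit["sds"] / np.sqrt(400 * fit["weights"])
            ok = (abs(fit["means"][0] - 0.23) < 3 * se[0]
                  and abs(fit["means"][1] - 0.58) < 3 * se[1])
            hits += ok
        assert hits == 20

    def test_single_component_flagged_or_collapsed(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 0.05, 300)
        fit = nn_distance_mixture(d, seed=0)
        near_equal = abs(fit["means"][1] - fit["means"][0]) < 0.1
        assert fit["degenerate"] or near_equal

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            nn_distance_mixture([0.1, 0.2, 0.3], k=2)

    def test_null_volume_correlation(self):
        rng = np.random.default_rng(2)
        lfs = [Leaflet(i, None, 0, float(v), 1.0, 1.0 / v, np.zeros(3),
                       nn_distance=float(d))
               for i, (v, d) in enumerate(zip(rng.lognormal(-4, 0.4, 500),
                                              rng.normal(0.4, 0.1, 500)))]
        r, p = nn_volume_correlation(lfs)
        assert abs(r) < 0.15
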