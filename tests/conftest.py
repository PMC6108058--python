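import numpy as np
import pytest
import trimesh

from neuropil.mesh_core import NeuropilScene, SceneObject, TriMesh
from neuropil.synthetic_neuropil import make_sphere, wrap_astro
from helpers import icosphere  # noqa: F401  (re-exported for tests)


@pytest.fixture
def unit_cube():
    box = trimesh.creation.box(extents=(1, 1, 1))
    return TriMesh(box.vertices, box.faces, label="cube")




@pytest.fixture
def sphere_mesh():
    return icosphere(1.0, 3)


@pytest.fixture
def shell_scene():
    """Spherical 'spine' of radius 0.2 wrapped by an astrocytic shell at
    surface distances [0.05, 0.10] — the canonical VF recovery fixture."""
    mesh, mt = make_sphere(0.2, subdivisions=3, label="sp")
    wrap, wt = wrap_astro((0, 0, 0), 0.2, offset=0.05, thickness=0.05,
                          coverage=1.0)
    return NeuropilScene(
        [SceneObject("sp", mesh, "spine", truth=mt),
         SceneObject("w", wrap, "astrocyte", process_class="leaflet",
                     truth=wt)],
        [[-2, -2, -2], [2, 2, 2]])


@pytest.fixture(scope="session")
def sweep():
    """Full spillover radius sweep (9 radii x 5 repeats x 2000 molecules x
    10^4 steps), shared by the simulator trend and optimum tests."""
    from neuropil.spillover_sim import radius_sweep
    return radius_sweep(seed=1)
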