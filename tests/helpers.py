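import numpy as np
import trimesh

from neuropil.mesh_core import TriMesh


def icosphere(radius=1.0, subdivisions=3, center=(0, 0, 0), label="sphere"):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(s.vertices + np.asarray(center, float), s.faces, label=label)
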