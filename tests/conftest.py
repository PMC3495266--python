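import numpy as np
import pytest
import trimesh

from hippomorph.mesh import TriangleMesh
from hippomorph.synthetic import CohortConfig, generate_cohort


def icosphere_mesh(level: int, radius: float = 1.0, hemisphere: str = "left") -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=level, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, float), np.asarray(ico.faces, np.int64),
                        hemisphere=hemisphere)


@pytest.fixture
def tetra() -> TriangleMesh:
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture
def cube2() -> TriangleMesh:
    box = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
    return TriangleMesh(np.asarray(box.vertices, float), np.asarray(box.faces, np.int64))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast default-physiology cohort: 8 subjects/group at resolution 2."""
    cfg = CohortConfig(group_sizes={"CON": 8, "OLZ": 8, "HAL": 8},
                       template_resolution=2, seed=11)
    return generate_cohort(cfg)
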