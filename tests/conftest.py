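import numpy as np
import pytest

from epialign import geometry as G
from epialign import polar_field as PF
from epialign import synthetic as S


@pytest.fixture(scope="session")
def unit_sphere_geom():
    """Two hemispheres of the unit sphere (C = 0 on both caps)."""
    return G.CapGeometry(1.0, 0.0, 1.0, 0.0)


@pytest.fixture(scope="session")
def ref_geom():
    """Late-stage-like two-cap geometry rescaled to units of R0."""
    g = G.CapGeometry(1.0, 0.2, 1.1, 0.5)
    return g.scaled(1.0 / g.R0)


@pytest.fixture(scope="session")
def ref_mesh(ref_geom):
    return G.generate_mesh(ref_geom, 0.05)


@pytest.fixture(scope="session")
def ref_solution(ref_geom, ref_mesh):
    """Surface-dominated heterogeneous-anchoring minimizer (xi=0.2, lambda=5)."""
    return PF.minimize(ref_geom, PF.MaterialParams(0.2, 5.0), mesh=ref_mesh)


@pytest.fixture(scope="session")
def spherical_embryo():
    """Synthetic embryo on a spherical tissue with exactly radial cells."""
    geom = G.CapGeometry(1.0, 0.0, 1.0, 0.0).scaled(22.0)
    spec = S.SyntheticSpec(geometry=geom, n_cells=50, seed=7,
                           orientation_source="radial",
                           angular_noise_kappa=np.inf,
                           eta_range=(0.5, 0.7))
    return S.generate_embryo(spec)


@pytest.fixture(scope="session")
def default_embryo():
    """An embryo under the default study conditions (60 cells, kappa=20)."""
    return S.generate_embryo(S.SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def quantified_spherical(spherical_embryo):
    from epialign import orientation as O
    vol, ann, truth = spherical_embryo
    table, shapes, tissue = O.quantify_cells(vol)
    frame = O.determine_axis(ann, tissue.centroid)
    return table, shapes, tissue, frame, truth
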