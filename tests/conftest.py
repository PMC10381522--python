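import numpy as np
import pytest
import trimesh

from enamelmap import SurfaceMesh
from enamelmap import synthetic_tooth as st


@pytest.fixture(scope="session")
def sphere_shell():
    """Concentric sphere shell R=1.1, r=1.0 with closed-form truth."""
    return st.make_sphere_shell(1.1, 1.0, subdivisions=4)


@pytest.fixture(scope="session")
def hemi_shell():
    """Open hemispherical cup R=2.0, r=1.99 with stitched cervical rim."""
    return st.make_hemisphere_shell(2.0, 1.99, n_theta=256, n_phi=48)


@pytest.fixture(scope="session")
def crown():
    """Default two-cusp crown, uniform 0.5 mm enamel."""
    return st.make_two_cusp_crown(st.SyntheticToothSpec())


@pytest.fixture(scope="session")
def crown_truth_mesh():
    """Crown with dense-quadrature volume/area truth (fine-mesh oracle)."""
    return st.make_two_cusp_crown(st.SyntheticToothSpec(), with_truth_mesh=True)


@pytest.fixture(scope="session")
def prismatic_band():
    return st.make_prismatic_band()


@pytest.fixture()
def unit_cube():
    """Closed unit cube with corner at the origin (12 faces)."""
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    return SurfaceMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces),
                       provenance="unit cube")


def parallel_plates(nx=21, ny=31, lx=2.0, ly=3.0, gap=0.5):
    """Two stacked rectangular sheets: OES at z=gap above the EDJ at z=0."""
    from enamelmap.cap_segmentation import EnamelCap

    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)

    def sheet(z, flip):
        vs = np.array([[x, y, z] for x in xs for y in ys])
        fs = []
        for i in range(nx - 1):
            for j in range(ny - 1):
                p = i * ny + j
                q = (i + 1) * ny + j
                fs.append([p, q, q + 1])
                fs.append([p, q + 1, p + 1])
        fs = np.array(fs)
        return vs, (fs[:, ::-1] if flip else fs)

    v_top, f_top = sheet(gap, flip=False)
    v_bot, f_bot = sheet(0.0, flip=True)
    v = np.vstack([v_top, v_bot])
    f = np.vstack([f_top, f_bot + len(v_top)])
    mesh = SurfaceMesh(v, f, provenance="parallel plates")
    cap = EnamelCap(mesh, np.arange(len(f_top)),
                    len(f_top) + np.arange(len(f_bot)))
    return cap


@pytest.fixture()
def plates():
    return parallel_plates()


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
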