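import numpy as np
import pytest

from fishtrack3d.morphology import (
    build_body_model,
    capsule_spec,
    cylinder_surface_mesh,
    default_zebrafish_model,
    zebrafish_larva_spec,
)


@pytest.fixture(scope="session")
def zebrafish_model():
    return default_zebrafish_model()


@pytest.fixture(scope="session")
def small_zebrafish_model():
    """Coarser model for fast optimisation tests."""
    return default_zebrafish_model(P=24, M=31)


@pytest.fixture(scope="session")
def capsule_model():
    """Cylinder with hemispherical caps built through the section pipeline."""
    return build_body_model(capsule_spec(1.25, 5.0, n_cap_rows=10), P=64,
                            M=61, length=5.0, stiff_fraction=0.0)


def column_volume_oracle(tm, n_xy: int = 100):
    """Independent volume/centroid oracle by vertical-ray parity casting.

    For every (x, y) grid column the z-crossings with all triangles are
    collected and paired; the volume is the summed column extent times the
    cell area (exact in z, discretised in x-y only).
    """
    lo, hi = tm.bounds
    eps = 1e-7 * max(hi - lo)
    xs = np.linspace(lo[0] + eps, hi[0] - eps, n_xy) + 0.37 * (hi[0] - lo[0]) / n_xy / n_xy
    ys = np.linspace(lo[1] + eps, hi[1] - eps, n_xy) + 0.41 * (hi[1] - lo[1]) / n_xy / n_xy
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    tris = tm.triangles
    cols: dict[tuple[int, int], list[float]] = {}
    for tri in tris:
        xmin, ymin = tri[:, 0].min(), tri[:, 1].min()
        xmax, ymax = tri[:, 0].max(), tri[:, 1].max()
        i0, i1 = np.searchsorted(xs, [xmin, xmax])
        j0, j1 = np.searchsorted(ys, [ymin, ymax])
        if i0 == i1 or j0 == j1:
            continue
        X, Y = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri
        det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(det) < 1e-14:
            continue
        l0 = ((y1 - y2) * (X - x2) + (x2 - x1) * (Y - y2)) / det
        l1 = ((y2 - y0) * (X - x2) + (x0 - x2) * (Y - y2)) / det
        l2 = 1.0 - l0 - l1
        inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        zs = l0 * z0 + l1 * z1 + l2 * z2
        ii, jj = np.nonzero(inside)
        for a, b, z in zip(ii + i0, jj + j0, zs[inside]):
            cols.setdefault((a, b), []).append(z)
    vol = 0.0
    zmom = 0.0
    xmom = 0.0
    ymom = 0.0
    for (a, b), zs in cols.items():
        zs = sorted(zs)
        if len(zs) % 2:            # grazing hit; drop the unpaired crossing
            zs = zs[:-1]
        for k in range(0, len(zs), 2):
            h = zs[k + 1] - zs[k]
            vol += h
            zmom += 0.5 * (zs[k + 1] ** 2 - zs[k] ** 2)
            xmom += h * xs[a]
            ymom += h * ys[b]
    cell = dx * dy
    volume = vol * cell
    centroid = np.array([xmom, ymom, zmom]) * cell / volume
    return volume, centroid


@pytest.fixture(scope="session")
def cylinder_mesh():
    return cylinder_surface_mesh(1.25, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
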