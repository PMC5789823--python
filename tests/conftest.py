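import numpy as np
import pytest

from wmhshape.lesion_extraction import LesionMesh, build_lesion_mesh, label_components
from wmhshape.synthetic_data import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def sphere10():
    """Digital ball of radius 10 mm on a 1 mm isotropic grid + its mesh."""
    grid = make_phantom(PhantomSpec(kind="sphere", size_mm=(10.0,), grid_shape=(32, 32, 32)))
    lesion = label_components(grid)[0]
    mesh = build_lesion_mesh(lesion, grid)
    return grid, lesion, mesh


@pytest.fixture(scope="session")
def ellipsoid_21_5_5():
    """Digital ellipsoid with semi-axes (21, 5, 5) mm, 1 mm isotropic."""
    grid = make_phantom(
        PhantomSpec(kind="ellipsoid", size_mm=(21.0, 5.0, 5.0), grid_shape=(56, 24, 24))
    )
    lesion = label_components(grid)[0]
    mesh = build_lesion_mesh(lesion, grid)
    return grid, lesion, mesh


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Hand-built closed unit cube: 8 vertices, 12 outward triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    # index = 4x + 2y + z
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0, outward -x
            [4, 7, 5], [4, 6, 7],  # x = 1
            [0, 5, 1], [0, 4, 5],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ]
    )
    return LesionMesh(vertices=v, faces=f)


def brute_force_components_26(mask: np.ndarray) -> set[frozenset]:
    """Flood-fill oracle: partition of foreground voxels under 26-connectivity."""
    fg = {tuple(v) for v in np.argwhere(mask > 0)}
    seen: set = set()
    comps = set()
    for start in sorted(fg):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            p = stack.pop()
            if p in comp:
                continue
            comp.add(p)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        q = (p[0] + di, p[1] + dj, p[2] + dk)
                        if q in fg and q not in comp:
                            stack.append(q)
        seen |= comp
        comps.add(frozenset(comp))
    return comps
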