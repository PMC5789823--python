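"""Per-lesion 3D shape features.

The feature set quantifies lesion geometry beyond volume:

* ``eccentricity`` = diameter_max / diameter_min, where diameter_max is the
  largest 3D caliper diameter of the mesh and diameter_min the smallest
  projected extent orthogonal to it. 1 means spherical, large means
  strongly ellipsoidal. Translation-, scale- and rotation-invariant.
* ``compactness1`` = volume^2 / area^3 (bounded above by the isoperimetric
  constant 1/(36*pi), attained by the sphere);
  ``compactness2`` = volume / (dim_x * dim_y * dim_z);
  ``compactness3`` = volume / dim_max^3, with dim_x/y/z the mesh
  bounding-box extents along the image axes and dim_max their maximum.
* ``fractal_dimension``: box-counting dimension of the lesion's boundary
  voxels — a measure of topological complexity.
* ``shape_index`` = (2/pi) * atan((k1 + k2) / (k1 - k2)) and
  ``curvedness`` = sqrt(k1^2 + k2^2), from the principal curvatures k1 >= k2
  of the image isophotes, computed with Gaussian derivatives at scale
  sigma = 1 voxel; the per-lesion value is the median over lesion voxels.

Curvatures are computed in index space with sigma in voxels, so curvedness
carries voxel^-1 units and is not corrected for anisotropy; by default the
"image" is the lesion's own binary mask, optionally the co-registered MRI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .lesion_extraction import LesionMesh, LesionVoxelSet, mesh_surface_area, mesh_volume
from .volume_io import VolumeGrid

__all__ = [
    "ShapeFeatureSet",
    "CurvaturePair",
    "max_diameter",
    "min_orthogonal_diameter",
    "eccentricity",
    "compactness_features",
    "fractal_dimension",
    "principal_curvatures",
    "principal_curvature_field",
    "shape_index_from_curvatures",
    "shape_index_curvedness",
    "compute_shape_features",
    "ISOPERIMETRIC_BOUND",
]

#: Upper bound of compactness1 for closed surfaces, attained by the sphere.
ISOPERIMETRIC_BOUND = 1.0 / (36.0 * math.pi)


@dataclass
class ShapeFeatureSet:
    """All shape features of one lesion.

    ``surface_area_icv`` is surface area (mm^2) divided by intracranial
    volume (ml) — dimensionless up to that fixed unit convention. Features
    that cannot be computed (e.g. fractal dimension with fewer than three
    usable scales) are NaN.
    """

    volume_ml: float
    surface_area_mm2: float
    surface_area_icv: float
    eccentricity: float
    compactness1: float
    compactness2: float
    compactness3: float
    fractal_dimension: float
    shape_index: float
    curvedness: float
    max_diameter_mm: float
    bbox_dims_mm: tuple[float, float, float]


@dataclass
class CurvaturePair:
    """Principal curvatures at one voxel, ordered k1 >= k2.

    ``defined`` is False where the gradient magnitude vanishes and the
    isophote orientation (hence curvature) is undefined.
    """

    k1: float
    k2: float
    defined: bool = True


def _hull_points(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convex-hull vertex subset (points, original indices); falls back to all."""
    if len(verts) > 10:
        try:
            hull = ConvexHull(verts)
            idx = np.asarray(hull.vertices, dtype=np.int64)
            return verts[idx], idx
        except QhullError:
            pass
    return verts, np.arange(len(verts), dtype=np.int64)


def max_diameter(mesh: LesionMesh) -> tuple[float, np.ndarray]:
    """Largest 3D caliper diameter of the mesh.

    Returns (length in mm, unit direction vector). The maximum pairwise
    vertex distance is searched exhaustively over the convex hull vertices
    (every diameter endpoint lies on the hull); ties are broken by the
    lexicographically smallest pair of original vertex indices.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if len(verts) < 4:
        raise ValueError("max_diameter requires >= 4 vertices")
    pts, orig = _hull_points(verts)
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(d2 >= best - 1e-12)
    pairs = sorted(
        (tuple(sorted((int(orig[a]), int(orig[b])))) for a, b in zip(ii, jj) if a != b)
    )
    i, j = pairs[0]
    vec = verts[j] - verts[i]
    length = float(np.linalg.norm(vec))
    return length, vec / length


def _orthonormal_plane(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = np.asarray(axis, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    v /= np.linalg.norm(v)
    return u, v


def min_orthogonal_diameter(
    mesh: LesionMesh,
    axis: np.ndarray,
    step_deg: float = 1.0,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Smallest projected extent of the mesh orthogonal to ``axis``.

    Vertices are projected onto the plane orthogonal to ``axis``; the
    extent (max - min scalar projection) is evaluated on a grid of
    in-plane directions theta in {0, step_deg, ...} < 180 degrees and the
    minimum returned. ``basis`` optionally fixes the two in-plane basis
    vectors (e.g. to co-rotate the angular grid with a rotated mesh);
    by default a deterministic basis is derived from ``axis``.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be unit-norm")
    pts, _ = _hull_points(np.asarray(mesh.vertices, dtype=float))
    u, v = _orthonormal_plane(axis) if basis is None else basis
    pu = pts @ u
    pv = pts @ v
    if max(np.ptp(pu), np.ptp(pv)) < 1e-12:
        raise ValueError("degenerate lesion: all vertices collinear with axis")
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    proj = np.outer(pu, np.cos(theta)) + np.outer(pv, np.sin(theta))
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.min())


def eccentricity(mesh: LesionMesh, step_deg: float = 1.0) -> float:
    """diameter_max / diameter_min of the lesion mesh (>= 1 for any body)."""
    length, direction = max_diameter(mesh)
    dmin = min_orthogonal_diameter(mesh, direction, step_deg=step_deg)
    if dmin <= 0:
        raise ValueError("degenerate lesion with zero orthogonal diameter")
    return length / dmin


def compactness_features(mesh: LesionMesh) -> tuple[float, float, float]:
    """(compactness1, compactness2, compactness3) of a closed mesh.

    Volume in mm^3 and area in mm^2; dim_x/y/z are the vertex bounding-box
    extents along the image axes.
    """
    vol = mesh_volume(mesh) * 1000.0  # mm^3
    area = mesh_surface_area(mesh)
    dims = np.ptp(np.asarray(mesh.vertices, dtype=float), axis=0)
    if np.any(dims <= 0):
        raise ValueError(f"zero bounding-box extent: {tuple(dims)}")
    c1 = vol**2 / area**3
    c2 = vol / float(np.prod(dims))
    c3 = vol / float(dims.max() ** 3)
    return float(c1), float(c2), float(c3)


def _boundary_voxels(lesion: LesionVoxelSet) -> np.ndarray:
    """Lesion voxels with at least one 6-connected background neighbor."""
    lo, hi = lesion.bbox()
    shape = tuple(hi - lo + 3)
    arr = np.zeros(shape, dtype=bool)
    idx = lesion.voxels - lo + 1
    arr[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    eroded = ndimage.binary_erosion(arr, structure=ndimage.generate_binary_structure(3, 1))
    boundary = arr & ~eroded
    return np.argwhere(boundary) + lo - 1


def fractal_dimension(lesion: LesionVoxelSet) -> float:
    """Box-counting fractal dimension of the lesion boundary.

    Boundary voxels are covered by grids of cubic boxes anchored at the
    bounding-box corner, with sides 1, 2, 4, ... voxels, strictly below
    half the maximum bounding-box extent (coarser boxes comparable to the
    object itself saturate the count). The dimension is the least-squares
    slope of log N(s) against log(1/s). With fewer than three usable
    scales the value is undefined and NaN is returned.
    """
    if lesion.n_voxels < 5:
        return math.nan
    boundary = _boundary_voxels(lesion)
    coords = boundary - boundary.min(axis=0)
    max_extent = int(coords.max()) + 1
    sizes = []
    s = 1
    while s < max_extent / 2.0:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        return math.nan
    counts = []
    for s in sizes:
        boxes = coords // s
        counts.append(len(np.unique(boxes, axis=0)))
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def _gaussian_derivatives(image: np.ndarray, sigma: float):
    """Gaussian-smoothed gradient and Hessian of a 3D image, index space."""
    img = np.asarray(image, dtype=float)
    g = [ndimage.gaussian_filter(img, sigma, order=tuple(int(i == a) for i in range(3))) for a in range(3)]
    H = np.empty((3, 3) + img.shape)
    for a in range(3):
        for b in range(a, 3):
            order = tuple(int(i == a) + int(i == b) for i in range(3))
            H[a, b] = ndimage.gaussian_filter(img, sigma, order=order)
            H[b, a] = H[a, b]
    return np.stack(g), H


def principal_curvature_field(image: np.ndarray, sigma: float = 1.0, grad_eps: float = 1e-8):
    """Principal curvatures of the isophotes of a 3D image, per voxel.

    The image is blurred with a Gaussian of scale ``sigma`` (in voxels);
    mean curvature H and Gaussian curvature K of the level sets follow the
    implicit-surface formulas from the gradient g and Hessian Hs:

        H = (g' Hs g - |g|^2 tr Hs) / (2 |g|^3),   K = (g' adj(Hs) g) / |g|^4

    and k1,2 = H +/- sqrt(max(H^2 - K, 0)). Returns (k1, k2, defined)
    arrays; ``defined`` is False where |g| < ``grad_eps``. Sign convention:
    a bright ball of radius r has k1 = k2 = +1/r on its surface.
    """
    g, H = _gaussian_derivatives(image, sigma)
    g2 = np.einsum("i...,i...->...", g, g)
    gm = np.sqrt(g2)
    defined = gm > grad_eps
    gm_safe = np.where(defined, gm, 1.0)
    g2_safe = np.where(defined, g2, 1.0)
    gHg = np.einsum("i...,ij...,j...->...", g, H, g)
    trH = H[0, 0] + H[1, 1] + H[2, 2]
    # adjugate of the symmetric Hessian
    adj = np.empty_like(H)
    a, b, c = H[0, 0], H[0, 1], H[0, 2]
    d, e, f = H[1, 1], H[1, 2], H[2, 2]
    adj[0, 0] = d * f - e * e
    adj[1, 1] = a * f - c * c
    adj[2, 2] = a * d - b * b
    adj[0, 1] = adj[1, 0] = c * e - b * f
    adj[0, 2] = adj[2, 0] = b * e - c * d
    adj[1, 2] = adj[2, 1] = b * c - a * e
    gAg = np.einsum("i...,ij...,j...->...", g, adj, g)
    mean_curv = (gHg - g2_safe * trH) / (2.0 * gm_safe**3)
    gauss_curv = gAg / g2_safe**2
    disc = np.sqrt(np.maximum(mean_curv**2 - gauss_curv, 0.0))
    return mean_curv + disc, mean_curv - disc, defined


def principal_curvatures(
    image: VolumeGrid, at: tuple[int, int, int], sigma: float = 1.0
) -> CurvaturePair:
    """Principal curvatures (k1 >= k2) of the image isophote at one voxel."""
    i, j, k = at
    shape = image.shape
    if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
        raise ValueError(f"voxel {at} outside image of shape {shape}")
    k1, k2, defined = principal_curvature_field(np.asarray(image.data, dtype=float), sigma)
    return CurvaturePair(k1=float(k1[i, j, k]), k2=float(k2[i, j, k]), defined=bool(defined[i, j, k]))


def shape_index_from_curvatures(k1, k2, eps: float = 1e-9):
    """Shape index (2/pi) atan((k1+k2)/(k1-k2)), with the k1 = k2 limit.

    When k1 == k2 the denominator vanishes; the analytic limit is sign(k1)
    (a perfect cap/cup), and 0 when both curvatures vanish.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    diff = k1 - k2
    umbilic = np.abs(diff) < eps
    diff_safe = np.where(umbilic, 1.0, diff)
    si = (2.0 / math.pi) * np.arctan((k1 + k2) / diff_safe)
    limit = np.where(np.abs(k1) < eps, 0.0, np.sign(k1))
    return np.where(umbilic, limit, si)


def shape_index_curvedness(
    lesion: LesionVoxelSet,
    image: VolumeGrid | None = None,
    sigma: float = 1.0,
) -> tuple[float, float]:
    """Median shape index and curvedness over the lesion's voxels.

    By default the curvature image is the lesion's own binary mask; passing
    a co-registered scalar MRI substitutes it. Voxels with vanishing
    gradient (undefined isophote) are skipped; with no defined voxel at
    all both medians are NaN.
    """
    lo, hi = lesion.bbox()
    pad = int(math.ceil(4 * sigma)) + 2
    if image is None:
        shape = tuple(hi - lo + 1 + 2 * pad)
        arr = np.zeros(shape, dtype=float)
        idx = lesion.voxels - lo + pad
        arr[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    else:
        img = np.asarray(image.data, dtype=float)
        lo_c = np.maximum(lo - pad, 0)
        hi_c = np.minimum(hi + pad + 1, img.shape)
        arr = img[lo_c[0] : hi_c[0], lo_c[1] : hi_c[1], lo_c[2] : hi_c[2]]
        idx = lesion.voxels - lo_c
    k1, k2, defined = principal_curvature_field(arr, sigma)
    sel = defined[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not np.any(sel):
        return math.nan, math.nan
    k1v = k1[idx[sel, 0], idx[sel, 1], idx[sel, 2]]
    k2v = k2[idx[sel, 0], idx[sel, 1], idx[sel, 2]]
    si = shape_index_from_curvatures(k1v, k2v)
    curv = np.sqrt(k1v**2 + k2v**2)
    return float(np.median(si)), float(np.median(curv))


def compute_shape_features(
    lesion: LesionVoxelSet,
    mesh: LesionMesh,
    icv_ml: float,
    curvature_image: VolumeGrid | None = None,
    sigma: float = 1.0,
    step_deg: float = 1.0,
) -> ShapeFeatureSet:
    """Assemble the full per-lesion feature record."""
    if icv_ml <= 0:
        raise ValueError("icv_ml must be positive")
    vol_ml = mesh_volume(mesh)
    area = mesh_surface_area(mesh)
    length, direction = max_diameter(mesh)
    dmin = min_orthogonal_diameter(mesh, direction, step_deg=step_deg)
    c1, c2, c3 = compactness_features(mesh)
    fd = fractal_dimension(lesion)
    si, curv = shape_index_curvedness(lesion, image=curvature_image, sigma=sigma)
    dims = np.ptp(np.asarray(mesh.vertices, dtype=float), axis=0)
    return ShapeFeatureSet(
        volume_ml=vol_ml,
        surface_area_mm2=area,
        surface_area_icv=area / icv_ml,
        eccentricity=length / dmin,
        compactness1=c1,
        compactness2=c2,
        compactness3=c3,
        fractal_dimension=fd,
        shape_index=si,
        curvedness=curv,
        max_diameter_mm=length,
        bbox_dims_mm=(float(dims[0]), float(dims[1]), float(dims[2])),
    )
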