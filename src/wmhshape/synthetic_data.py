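"""Synthetic inputs: shape phantoms, a toy atlas, and two-group cohorts.

Everything the pipeline consumes can be generated here, so the method is
exercised end-to-end without any imaging data:

* analytic phantoms (sphere, ellipsoid, box, rod, blob) with known
  geometry, used as ground truth for the shape features;
* a toy atlas with two paramedian slab "ventricles" and a block
  parcellation into frontal/parietal/temporal/occipital plus a basal
  ganglia region and cerebellum;
* whole cohorts of lesion masks with injected group effects. Patients and
  controls share the punctuate lesion rate; patients carry more
  non-punctuate lesions (rate ratio ~1.5) and a positive shift of the
  punctuate log-elongation distribution — the direction of the real
  cohort findings. Elongation is lognormal (eccentricity is >= 1 and
  right-skewed) and the group effect is additive on the log scale.

The default grid is 128 x 128 x 64 voxels at (1, 1, 3) mm, a cheap stand-in
for the thick-slice FLAIR regime, so anisotropy is always exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .location_features import AtlasBundle, ventricle_distance_map
from .volume_io import SubjectMeta, VolumeGrid

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "CohortResult",
    "make_phantom",
    "make_toy_atlas",
    "make_cohort",
    "simulate_subject_summaries",
]


@dataclass
class PhantomSpec:
    """Analytic description of one binary phantom.

    ``size_mm`` semantics by kind: sphere (r,), ellipsoid (a, b, c)
    semi-axes, box (lx, ly, lz) full extents, rod (length, radius), blob
    (base_radius,). ``orientation`` is a 3x3 rotation applied to the local
    frame; ``center_mm`` defaults to the grid center. ``seed`` only
    affects the blob's random bumps.
    """

    kind: str
    size_mm: tuple[float, ...]
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] | None = None
    orientation: np.ndarray | None = None
    seed: int = 0


@dataclass
class CohortSpec:
    """Generative model for a two-group lesion cohort.

    Rates are Poisson means per subject; ``count_effect`` is the patient
    rate ratio for non-punctuate lesions; ``eccentricity_effect`` shifts
    the patient punctuate log-elongation additively. The lesion-level
    elongation is lognormal(mu, sigma) with a per-subject random effect of
    SD ``subject_log_sd`` on the log scale.
    """

    n_per_group: int = 60
    seed: int = 0
    punctuate_rate: float = 12.0
    nonpunctuate_rate: float = 26.0
    count_effect: float = 40.0 / 26.0
    eccentricity_effect: float = 0.141  # ln(2.06 / 1.79)
    elongation_log_mu: float = 0.59
    elongation_log_sigma: float = 0.28
    subject_log_sd: float = 0.08
    volume_log_mu: float = math.log(0.19)
    volume_log_sigma: float = 1.3
    age_mean: float = 71.0
    age_sd: float = 4.5
    age_range: tuple[float, float] = (65.0, 80.0)
    male_fraction: float = 0.58
    icv_mean: float = 1450.0
    icv_sd: float = 110.0
    grid_shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.punctuate_rate <= 0 or self.nonpunctuate_rate <= 0:
            raise ValueError("lesion rates must be positive")


@dataclass
class CohortResult:
    """Generated cohort: one mask per subject plus atlas, metadata, truth.

    ``truth`` maps subject_id to the intended lesions: per punctuate
    lesion its center voxel, minor radius and (possibly clipped) intended
    elongation; plus the placed counts per class.
    """

    masks: list[VolumeGrid]
    atlas: AtlasBundle
    metas: list[SubjectMeta]
    truth: dict


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return axes


def make_phantom(spec: PhantomSpec) -> VolumeGrid:
    """Voxelize an analytic shape: a voxel is foreground iff its center
    satisfies the shape inequality under the spec's orientation."""
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)
    center = spec.center_mm
    if center is None:
        center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    R = np.eye(3) if spec.orientation is None else np.asarray(spec.orientation, dtype=float)
    ax, ay, az = _voxel_centers_mm(shape, spacing)
    X, Y, Z = np.meshgrid(ax - center[0], ay - center[1], az - center[2], indexing="ij")
    P = np.stack([X, Y, Z], axis=-1) @ R  # world offsets into local frame
    px, py, pz = P[..., 0], P[..., 1], P[..., 2]

    kind, size = spec.kind, spec.size_mm
    if kind == "sphere":
        (r,) = size
        inside = px**2 + py**2 + pz**2 <= r**2
        half = np.full(3, r)
    elif kind == "ellipsoid":
        a, b, c = size
        inside = (px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2 <= 1.0
        half = np.sqrt((R * np.asarray(size)) ** 2 @ np.ones(3))
    elif kind == "box":
        lx, ly, lz = size
        inside = (np.abs(px) <= lx / 2) & (np.abs(py) <= ly / 2) & (np.abs(pz) <= lz / 2)
        half = np.abs(R) @ (np.asarray(size) / 2.0)
    elif kind == "rod":
        length, r = size
        inside = (np.abs(px) <= length / 2) & (py**2 + pz**2 <= r**2)
        half = np.abs(R) @ np.array([length / 2.0, r, r])
    elif kind == "blob":
        (r0,) = size
        rng = np.random.default_rng(spec.seed)
        inside = px**2 + py**2 + pz**2 <= r0**2
        for _ in range(4):
            off = rng.normal(scale=r0 * 0.6, size=3)
            rb = rng.uniform(0.4, 0.8) * r0
            inside |= (px - off[0]) ** 2 + (py - off[1]) ** 2 + (pz - off[2]) ** 2 <= rb**2
        half = np.full(3, r0 * 2.3)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    extent_mm = [(n - 1) * s for n, s in zip(shape, spacing)]
    for c, e, s, h in zip(center, extent_mm, spacing, half):
        if c - h < 2 * s or c + h > e - 2 * s:
            raise ValueError("phantom does not fit in grid with a 2-voxel margin")
    return VolumeGrid(data=inside.astype(np.uint8), spacing=spacing, is_binary=True)


def make_toy_atlas(
    grid_shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> AtlasBundle:
    """Toy atlas: paramedian slab ventricles + block lobe parcellation.

    Axis convention: x = left-right, y = posterior-anterior, z =
    inferior-superior (all in mm via spacing). Inside a brain ellipsoid,
    the parcellation is: a central basal-ganglia box, a
    posterior-inferior cerebellum wedge, then frontal (anterior-superior),
    parietal (posterior-superior), temporal (anterior-inferior) and
    occipital (posterior-inferior) blocks. Ventricles carry lobe label 0,
    so labels + ventricles + background tile the grid exactly.
    """
    if any(n < 32 for n in grid_shape):
        raise ValueError("toy atlas needs a grid of at least 32 voxels per axis")
    shape = tuple(grid_shape)
    spacing = tuple(spacing)
    ax, ay, az = _voxel_centers_mm(shape, spacing)
    center = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(ax - center[0], ay - center[1], az - center[2], indexing="ij")

    semi = [max((n - 1) * s / 2.0 - 2 * s, 8 * s) for n, s in zip(shape, spacing)]
    brain = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0

    vent = (
        brain
        & (np.abs(np.abs(X) - 6.0) <= 3.0)
        & (np.abs(Y) <= 25.0)
        & (np.abs(Z) <= 12.0)
    )

    labels = np.zeros(shape, dtype=np.int16)
    bg_box = (np.abs(X) <= 14.0) & (np.abs(Y) <= 14.0) & (np.abs(Z) <= 9.0)
    cerebellum = (Z < -16.0) & (Y < -16.0)
    sup = Z >= 0
    ant = Y >= 0
    labels[brain & sup & ant] = 1  # frontal
    labels[brain & sup & ~ant] = 2  # parietal
    labels[brain & ~sup & ant] = 3  # temporal
    labels[brain & ~sup & ~ant] = 4  # occipital
    labels[brain & bg_box] = 5
    labels[brain & cerebellum] = 6
    labels[vent] = 0

    return AtlasBundle(
        ventricle_mask=VolumeGrid(vent.astype(np.uint8), spacing=spacing, is_binary=True),
        lobe_labels=VolumeGrid(labels, spacing=spacing),
    )


def _inplane_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation placing the ellipsoid major axis at a random in-plane angle.

    Punctuate lesions are generated with their long axis in the slice
    plane: on thick-slice grids a through-plane long axis is quantized
    away, which would decouple measured eccentricity from the intended
    elongation.
    """
    theta = rng.uniform(0.0, math.pi)
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _stamp_ellipsoid(mask, center_idx, semi_axes_mm, R, spacing):
    """Set voxels whose centers satisfy the rotated ellipsoid inequality."""
    spacing = np.asarray(spacing)
    center_mm = np.asarray(center_idx) * spacing
    rad = max(semi_axes_mm)
    lo = np.maximum(np.floor((center_mm - rad) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + rad) / spacing).astype(int) + 1, mask.shape)
    axes = [np.arange(lo[d], hi[d]) * spacing[d] - center_mm[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1) @ R
    q = sum((P[..., d] / semi_axes_mm[d]) ** 2 for d in range(3))
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= q <= 1.0
    return int((q <= 1.0).sum())


def _sample_meta(rng: np.random.Generator, spec: CohortSpec, subject_id: str, group: str) -> SubjectMeta:
    age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), *spec.age_range))
    sex = "M" if rng.random() < spec.male_fraction else "F"
    icv = float(max(rng.normal(spec.icv_mean, spec.icv_sd), 900.0))
    dur = float(max(rng.normal(10.6, 8.7), 1.0)) if group == "patient" else None
    return SubjectMeta(
        subject_id=subject_id,
        group=group,
        age=age,
        sex=sex,
        icv=icv,
        gm_volume=float(rng.normal(38.0 if group == "patient" else 39.1, 2.2)),
        wm_volume=float(rng.normal(29.8 if group == "patient" else 30.2, 2.7)),
        diabetes_duration=dur,
    )


def make_cohort(spec: CohortSpec) -> CohortResult:
    """Generate per-subject lesion masks with known ground truth.

    Punctuate-deep candidates are ellipsoids (minor radius ~2 mm,
    elongation lognormal, clipped so the lesion stays under the 15 mm
    diameter criterion with margin) placed where the ventricle distance
    exceeds the 10 mm criterion with margin; non-punctuate lesions are
    multi-sphere blobs seeded at the ventricle boundary. Overlapping
    placements merge by voxel union, which downstream extraction sees as
    one lesion; the returned truth records every intended placement, so
    merges are detectable. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = make_toy_atlas(spec.grid_shape, spec.spacing)
    distmap = ventricle_distance_map(atlas)
    labels = np.asarray(atlas.lobe_labels.data)
    spacing = np.asarray(spec.spacing)
    shape = np.asarray(spec.grid_shape)

    margin_vox = np.ceil(np.array([8.0, 8.0, 8.0]) / spacing).astype(int) + 1
    interior = np.zeros(tuple(shape), dtype=bool)
    interior[
        margin_vox[0] : shape[0] - margin_vox[0],
        margin_vox[1] : shape[1] - margin_vox[1],
        margin_vox[2] : shape[2] - margin_vox[2],
    ] = True

    deep_pool = np.argwhere(interior & (labels > 0) & (distmap > 17.0))
    peri_pool = np.argwhere(interior & (labels > 0) & (distmap > 0) & (distmap < 3.5))
    if len(deep_pool) == 0 or len(peri_pool) == 0:
        raise ValueError("grid too small to place lesions; use a larger grid")

    masks: list[VolumeGrid] = []
    metas: list[SubjectMeta] = []
    truth: dict = {"seed": spec.seed, "subjects": {}}
    sid = 0
    for group in ("patient", "control"):
        is_patient = group == "patient"
        for _ in range(spec.n_per_group):
            sid += 1
            subject_id = f"S{sid:03d}"
            metas.append(_sample_meta(rng, spec, subject_id, group))
            mask = np.zeros(tuple(shape), dtype=bool)
            subj_truth = {"group": group, "punctuate": [], "n_punctuate": 0, "n_nonpunctuate": 0}
            u = rng.normal(0.0, spec.subject_log_sd)

            n_p = rng.poisson(spec.punctuate_rate)
            for _ in range(n_p):
                b = rng.uniform(1.9, 2.3)
                shift = spec.eccentricity_effect if is_patient else 0.0
                elong = math.exp(rng.normal(spec.elongation_log_mu + shift + u, spec.elongation_log_sigma))
                elong = float(np.clip(elong, 1.1, 5.6 / b))
                a = b * elong
                placed = False
                for _try in range(60):
                    c = deep_pool[rng.integers(len(deep_pool))]
                    if distmap[tuple(c)] > 11.0 + a:
                        placed = True
                        break
                if not placed:
                    raise ValueError("could not place punctuate lesion; use a larger grid")
                R = _inplane_rotation(rng)
                n_vox = _stamp_ellipsoid(mask, c, (a, b, b), R, spacing)
                if n_vox < 5:
                    # widen slightly so the lesion survives the size filter
                    n_vox = _stamp_ellipsoid(mask, c, (max(a, 2.6), max(b, 2.2), max(b, 2.2)), R, spacing)
                subj_truth["punctuate"].append(
                    {"center_index": [int(x) for x in c], "elongation": elong, "minor_radius_mm": b}
                )
            subj_truth["n_punctuate"] = n_p

            rate = spec.nonpunctuate_rate * (spec.count_effect if is_patient else 1.0)
            n_np = rng.poisson(rate)
            for _ in range(n_np):
                c = peri_pool[rng.integers(len(peri_pool))].astype(float)
                for _sub in range(rng.integers(2, 5)):
                    r = rng.uniform(3.0, 6.0)
                    _stamp_ellipsoid(mask, c, (r, r, r), np.eye(3), spacing)
                    c = c + rng.normal(scale=2.5, size=3) / spacing
                    c = np.clip(c, margin_vox, shape - margin_vox - 1)
            subj_truth["n_nonpunctuate"] = int(n_np)

            truth["subjects"][subject_id] = subj_truth
            masks.append(
                VolumeGrid(mask.astype(np.uint8), spacing=tuple(spec.spacing), is_binary=True)
            )
    return CohortResult(masks=masks, atlas=atlas, metas=metas, truth=truth)


def simulate_subject_summaries(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, list[SubjectMeta]]:
    """Draw per-subject lesion summaries directly from the cohort model.

    Samples the same generative quantities as :func:`make_cohort` — counts,
    lesion elongations, volumes — without voxelizing lesions, giving the
    statistics layer exact control over the injected effects at negligible
    cost. The frame matches :func:`wmhshape.cohort_stats.summaries_to_frame`.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    metas: list[SubjectMeta] = []
    sid = 0
    for group in ("patient", "control"):
        is_patient = group == "patient"
        for _ in range(spec.n_per_group):
            sid += 1
            meta = _sample_meta(rng, spec, f"S{sid:03d}", group)
            metas.append(meta)
            u = rng.normal(0.0, spec.subject_log_sd)
            n_p = int(rng.poisson(spec.punctuate_rate))
            n_np = int(rng.poisson(spec.nonpunctuate_rate * (spec.count_effect if is_patient else 1.0)))
            shift = spec.eccentricity_effect if is_patient else 0.0
            e_p = np.exp(rng.normal(spec.elongation_log_mu + shift + u, spec.elongation_log_sigma, size=n_p))
            # non-punctuate lesions are larger/more elongated but carry no group effect
            e_np = np.exp(rng.normal(spec.elongation_log_mu + 0.12 + u, spec.elongation_log_sigma, size=n_np))
            vol_np = float(np.exp(rng.normal(spec.volume_log_mu, spec.volume_log_sigma)))
            vol_p = float(np.exp(rng.normal(spec.volume_log_mu - 2.5, spec.volume_log_sigma)))
            rows.append(
                {
                    "subject_id": meta.subject_id,
                    "group": group,
                    "age": meta.age,
                    "sex": meta.sex,
                    "icv": meta.icv,
                    "gm_volume": meta.gm_volume,
                    "wm_volume": meta.wm_volume,
                    "diabetes_duration": meta.diabetes_duration,
                    "all_n": n_p + n_np,
                    "all_volume_pct_icv": vol_np + vol_p,
                    "all_median_eccentricity": float(np.median(np.concatenate([e_p, e_np]))) if n_p + n_np else None,
                    "non_punctuate_n": n_np,
                    "non_punctuate_volume_pct_icv": vol_np,
                    "non_punctuate_median_eccentricity": float(np.median(e_np)) if n_np else None,
                    "punctuate_deep_n": n_p,
                    "punctuate_deep_volume_pct_icv": vol_p,
                    "punctuate_deep_median_eccentricity": float(np.median(e_p)) if n_p else None,
                }
            )
    return pd.DataFrame(rows), metas
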