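"""Lesion location: punctuate-deep classification, lobes, eccentricity maps.

A lesion is *punctuate deep* when it lies strictly more than 10 mm from the
ventricles and its maximum 3D diameter is strictly below 15 mm; everything
else (periventricular and early-confluent lesions) forms the single
*non-punctuate* group, whose lobe is not determined because such lesions
often span several lobes. Automatic classifications can be overridden by a
manual-correction list (mirroring visual checking of the automatic rule).

Lesion-to-ventricle distance is the minimum over the lesion's voxels of an
anisotropy-aware Euclidean distance transform of the ventricle mask, so the
physical 1.0 cm threshold is honored on thick-slice grids. Lobes come from
a label map in the same (atlas) space by majority vote over lesion voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lesion_extraction import LesionVoxelSet
from .shape_features import ShapeFeatureSet
from .volume_io import GridMismatchError, VolumeGrid, check_same_grid

__all__ = [
    "AtlasBundle",
    "LesionRecord",
    "LOBE_LABELS",
    "LOBE_PRIORITY",
    "PUNCTUATE_DEEP",
    "NON_PUNCTUATE",
    "ventricle_distance_map",
    "ventricle_distance",
    "classify_lesion",
    "apply_overrides",
    "assign_lobe",
    "eccentricity_atlas_map",
]

logger = logging.getLogger(__name__)

PUNCTUATE_DEEP = "punctuate_deep"
NON_PUNCTUATE = "non_punctuate"

#: Integer label -> lobe name of the lobe label map (0 is background).
LOBE_LABELS = {
    0: "background",
    1: "frontal",
    2: "parietal",
    3: "temporal",
    4: "occipital",
    5: "basal_ganglia_region",
    6: "cerebellum",
}

#: Fixed tie-break order for majority votes.
LOBE_PRIORITY = [
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "basal_ganglia_region",
    "cerebellum",
]


@dataclass
class AtlasBundle:
    """Ventricle mask and lobe label map sharing one (atlas) grid."""

    ventricle_mask: VolumeGrid
    lobe_labels: VolumeGrid
    label_names: dict[int, str] = field(default_factory=lambda: dict(LOBE_LABELS))

    def __post_init__(self) -> None:
        check_same_grid(self.ventricle_mask, self.lobe_labels)
        if not np.any(self.ventricle_mask.data):
            raise ValueError("ventricle mask is empty")


@dataclass
class LesionRecord:
    """Shape features plus location class of one lesion.

    ``lobe`` is present only for punctuate-deep lesions. ``voxels`` keeps
    the source voxel indices for map building and is excluded from
    equality comparison and CSV round trips.
    """

    subject_id: str
    lesion_id: int
    n_voxels: int
    features: ShapeFeatureSet
    lesion_class: str
    lobe: str | None
    min_ventricle_distance_mm: float
    override_applied: bool = False
    voxels: np.ndarray | None = field(default=None, repr=False, compare=False)


def ventricle_distance_map(atlas: AtlasBundle) -> np.ndarray:
    """Distance (mm) from every voxel to the nearest ventricle voxel."""
    vent = np.asarray(atlas.ventricle_mask.data) > 0
    if not np.any(vent):
        raise ValueError("ventricle mask is empty")
    return ndimage.distance_transform_edt(~vent, sampling=atlas.ventricle_mask.spacing)


def ventricle_distance(
    lesion: LesionVoxelSet,
    atlas: AtlasBundle,
    distance_map: np.ndarray | None = None,
) -> float:
    """Minimum distance (mm) from any lesion voxel to the ventricles.

    The minimum-over-voxels rule reads "located > 1.0 cm from the
    ventricles" conservatively: the whole lesion must be beyond the
    threshold. A precomputed ``distance_map`` avoids recomputing the
    transform per lesion.
    """
    if distance_map is None:
        distance_map = ventricle_distance_map(atlas)
    v = lesion.voxels
    return float(distance_map[v[:, 0], v[:, 1], v[:, 2]].min())


def classify_lesion(
    distance_mm: float,
    max_diameter_mm: float,
    distance_threshold_mm: float = 10.0,
    diameter_threshold_mm: float = 15.0,
) -> str:
    """Punctuate-deep iff distance > 10 mm AND max diameter < 15 mm (strict)."""
    if distance_mm > distance_threshold_mm and max_diameter_mm < diameter_threshold_mm:
        return PUNCTUATE_DEEP
    return NON_PUNCTUATE


def apply_overrides(
    records: list[LesionRecord],
    overrides: list[tuple[str, int, str]],
) -> list[LesionRecord]:
    """Apply manual class corrections (subject_id, lesion_id, lesion_class).

    The class is replaced and ``override_applied`` set — also when the
    override equals the current class, recording the explicit decision.
    All other fields are untouched. Unknown keys raise, listing them.
    """
    index = {(r.subject_id, r.lesion_id): r for r in records}
    unmatched = [(s, l) for s, l, _ in overrides if (s, l) not in index]
    if unmatched:
        raise KeyError(f"overrides reference unknown lesions: {unmatched}")
    n = 0
    for subject_id, lesion_id, new_class in overrides:
        if new_class not in (PUNCTUATE_DEEP, NON_PUNCTUATE):
            raise ValueError(f"invalid lesion class {new_class!r}")
        rec = index[(subject_id, lesion_id)]
        rec.lesion_class = new_class
        if new_class != PUNCTUATE_DEEP:
            rec.lobe = None
        rec.override_applied = True
        n += 1
    if n:
        logger.info("applied %d manual class override(s)", n)
    return records


def assign_lobe(lesion: LesionVoxelSet, atlas: AtlasBundle) -> str:
    """Majority lobe label over the lesion's voxels.

    Background voxels do not vote. Ties go to the fixed order
    frontal > parietal > temporal ... (:data:`LOBE_PRIORITY`); a lesion
    lying entirely in background takes the label of its nearest labeled
    voxel.
    """
    labels = np.asarray(atlas.lobe_labels.data)
    present = set(int(v) for v in np.unique(labels)) - {0}
    if not present:
        raise ValueError("atlas lobe map contains no labels")
    v = lesion.voxels
    votes = labels[v[:, 0], v[:, 1], v[:, 2]]
    votes = votes[votes > 0]
    if len(votes) == 0:
        # nearest labeled voxel via distance transform with indices
        _, (ii, jj, kk) = ndimage.distance_transform_edt(
            labels == 0, sampling=atlas.lobe_labels.spacing, return_indices=True
        )
        v0 = lesion.voxels[0]
        lab = int(labels[ii[v0[0], v0[1], v0[2]], jj[v0[0], v0[1], v0[2]], kk[v0[0], v0[1], v0[2]]])
        return atlas.label_names[lab]
    counts: dict[str, int] = {}
    for lab in votes:
        name = atlas.label_names[int(lab)]
        counts[name] = counts.get(name, 0) + 1
    best = max(counts.values())
    for name in LOBE_PRIORITY:
        if counts.get(name, 0) == best:
            return name
    # label names outside the canonical list: deterministic alphabetical
    return sorted(k for k, c in counts.items() if c == best)[0]


def eccentricity_atlas_map(
    records: list[LesionRecord], reference: VolumeGrid
) -> VolumeGrid:
    """Per-voxel mean eccentricity of the lesions covering each voxel.

    Eccentricities are summed per voxel and divided by the lesion count
    per voxel; voxels covered by no lesion are 0. Records must carry their
    voxel sets on the reference grid.
    """
    sums = np.zeros(reference.shape, dtype=float)
    counts = np.zeros(reference.shape, dtype=np.int64)
    for rec in records:
        if rec.voxels is None:
            raise ValueError(f"record {rec.lesion_id} lacks voxel coordinates")
        v = np.asarray(rec.voxels)
        if np.any(v < 0) or np.any(v >= np.asarray(reference.shape)):
            raise GridMismatchError("lesion voxels fall outside the reference grid")
        sums[v[:, 0], v[:, 1], v[:, 2]] += rec.features.eccentricity
        counts[v[:, 0], v[:, 1], v[:, 2]] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return VolumeGrid(data=mean, spacing=reference.spacing, affine=reference.affine)
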