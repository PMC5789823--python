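"""End-to-end wiring: mask -> lesion records -> cohort report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .lesion_extraction import (
    build_lesion_mesh,
    filter_small_lesions,
    label_components,
)
from .location_features import (
    NON_PUNCTUATE,
    PUNCTUATE_DEEP,
    AtlasBundle,
    LesionRecord,
    assign_lobe,
    classify_lesion,
    ventricle_distance,
    ventricle_distance_map,
)
from .shape_features import compute_shape_features
from .volume_io import SubjectMeta, VolumeGrid, check_same_grid

__all__ = ["RunConfig", "extract_lesions", "cohort_report"]

logger = logging.getLogger(__name__)

#: Lobes reported in the per-lobe comparison table (basal ganglia region
#: and cerebellum lesions are counted elsewhere but not tabulated).
TABLE_LOBES = ["frontal", "temporal", "parietal", "occipital"]


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the method's stated values.

    min_voxels: lesions below this voxel count are excluded (5).
    ventricle_distance_mm / max_punctuate_diameter_mm: the punctuate-deep
    rule (> 10 mm from the ventricles, < 15 mm diameter).
    sigma_voxels: Gaussian scale of the curvature derivatives (1 voxel).
    angular_grid_deg: angular resolution of the orthogonal-diameter search.
    """

    min_voxels: int = 5
    ventricle_distance_mm: float = 10.0
    max_punctuate_diameter_mm: float = 15.0
    sigma_voxels: float = 1.0
    angular_grid_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.min_voxels,
            self.ventricle_distance_mm,
            self.max_punctuate_diameter_mm,
            self.sigma_voxels,
            self.angular_grid_deg,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


def extract_lesions(
    mask: VolumeGrid,
    atlas: AtlasBundle,
    meta: SubjectMeta,
    config: RunConfig | None = None,
    curvature_image: VolumeGrid | None = None,
) -> list[LesionRecord]:
    """Run labeling -> filtering -> meshing -> features -> classification.

    Returns one record per surviving lesion, carrying its voxel set for
    map building.
    """
    config = config or RunConfig()
    check_same_grid(mask, atlas.ventricle_mask)
    lesions = label_components(mask)
    kept = filter_small_lesions(lesions, min_voxels=config.min_voxels)
    logger.info(
        "subject %s: %d component(s), %d after size filter",
        meta.subject_id,
        len(lesions),
        len(kept),
    )
    if not kept:
        return []
    distmap = ventricle_distance_map(atlas)
    records = []
    for lesion in kept:
        mesh = build_lesion_mesh(lesion, mask)
        features = compute_shape_features(
            lesion,
            mesh,
            icv_ml=meta.icv,
            curvature_image=curvature_image,
            sigma=config.sigma_voxels,
            step_deg=config.angular_grid_deg,
        )
        dist = ventricle_distance(lesion, atlas, distance_map=distmap)
        cls = classify_lesion(
            dist,
            features.max_diameter_mm,
            distance_threshold_mm=config.ventricle_distance_mm,
            diameter_threshold_mm=config.max_punctuate_diameter_mm,
        )
        lobe = assign_lobe(lesion, atlas) if cls == PUNCTUATE_DEEP else None
        records.append(
            LesionRecord(
                subject_id=meta.subject_id,
                lesion_id=lesion.lesion_id,
                n_voxels=lesion.n_voxels,
                features=features,
                lesion_class=cls,
                lobe=lobe,
                min_ventricle_distance_mm=dist,
                voxels=lesion.voxels,
            )
        )
    return records


FEATURE_COLUMNS = [
    "surface_area_icv",
    "eccentricity",
    "compactness1",
    "compactness2",
    "compactness3",
    "fractal_dimension",
    "shape_index",
    "curvedness",
]


def _per_lesion_frame(records_by_subject: dict[str, list[LesionRecord]]) -> pd.DataFrame:
    rows = []
    for sid, recs in records_by_subject.items():
        for r in recs:
            rows.append(
                {
                    "subject_id": sid,
                    "lesion_class": r.lesion_class,
                    "lobe": r.lobe,
                    "eccentricity": r.features.eccentricity,
                    "surface_area_icv": r.features.surface_area_icv,
                    "compactness1": r.features.compactness1,
                    "compactness2": r.features.compactness2,
                    "compactness3": r.features.compactness3,
                    "fractal_dimension": r.features.fractal_dimension,
                    "shape_index": r.features.shape_index,
                    "curvedness": r.features.curvedness,
                }
            )
    return pd.DataFrame(rows)


def cohort_report(
    records_by_subject: dict[str, list[LesionRecord]],
    metas: list[SubjectMeta],
) -> dict[str, pd.DataFrame]:
    """Build the three report tables from per-subject lesion records.

    ``feature_distributions``: per-lesion mean/min/max/skewness/KS of every
    shape feature over the combined cohort. ``group_differences``: per
    stratum (all / non-punctuate / punctuate-deep) and outcome (volume,
    number, median eccentricity) the adjusted B and Beta with CIs; volumes
    and counts log-transformed, subjects without lesions in a stratum
    excluded there. ``lobe_comparison``: punctuate-deep counts, percentages
    and per-lobe chi-square / Mann-Whitney p-values.
    """
    meta_by_id = {m.subject_id: m for m in metas}
    missing = [s for s in records_by_subject if s not in meta_by_id]
    if missing:
        raise ValueError(f"no metadata for subjects: {missing}")

    lesions = _per_lesion_frame(records_by_subject)

    # feature distribution table over all lesions, both groups combined
    feat_rows = []
    for feat in FEATURE_COLUMNS:
        vals = lesions[feat].dropna().to_numpy() if len(lesions) else np.array([])
        if len(vals) >= 3:
            s = cs.feature_distribution_summary(vals)
            feat_rows.append(
                {
                    "feature": feat,
                    "mean": s.mean,
                    "minimum": s.minimum,
                    "maximum": s.maximum,
                    "skewness": s.skewness,
                    "ks_p": s.ks_p,
                }
            )
    table_features = pd.DataFrame(feat_rows)

    # per-subject strata regressions
    summaries = [
        cs.subject_summary(records_by_subject.get(m.subject_id, []), m) for m in metas
    ]
    frame = cs.summaries_to_frame(summaries, metas)
    reg_rows = []
    for stratum in cs.STRATA:
        for outcome, transform in (
            (f"{stratum}_volume_pct_icv", "nl_volume"),
            (f"{stratum}_n", "nl_count"),
            (f"{stratum}_median_eccentricity", "raw"),
        ):
            sub = frame[frame[f"{stratum}_n"] > 0].dropna(subset=[outcome])
            sub_metas = [meta_by_id[s] for s in sub["subject_id"]]
            if len(sub) < 10 or len({m.group for m in sub_metas}) < 2:
                continue
            y = sub[outcome].to_numpy(dtype=float)
            if transform == "nl_volume":
                y = cs.nl_transform(y / 100.0, scale=10000.0)  # %ICV -> fraction
            elif transform == "nl_count":
                y = cs.nl_transform(y, scale=1.0)
            res = cs.group_regression(y, sub_metas)
            reg_rows.append(
                {
                    "stratum": stratum,
                    "outcome": outcome,
                    "transform": transform,
                    "n_patients": sum(m.group == "patient" for m in sub_metas),
                    "n_controls": sum(m.group == "control" for m in sub_metas),
                    "b": res.b,
                    "b_lo": res.b_ci[0],
                    "b_hi": res.b_ci[1],
                    "beta": res.beta,
                    "beta_lo": res.beta_ci[0],
                    "beta_hi": res.beta_ci[1],
                    "p": res.p,
                }
            )
    table_groups = pd.DataFrame(reg_rows)

    # per-lobe punctuate-deep comparison
    if len(lesions):
        punct = lesions[lesions["lesion_class"] == PUNCTUATE_DEEP].copy()
        punct["group"] = punct["subject_id"].map(lambda s: meta_by_id[s].group)
    else:
        punct = pd.DataFrame(columns=["group", "lobe", "eccentricity"])
    p_counts = {l: int(((punct["group"] == "patient") & (punct["lobe"] == l)).sum()) for l in TABLE_LOBES}
    c_counts = {l: int(((punct["group"] == "control") & (punct["lobe"] == l)).sum()) for l in TABLE_LOBES}
    if sum(p_counts.values()) > 0 and sum(c_counts.values()) > 0:
        table_lobes = cs.lobe_chi2(p_counts, c_counts)
        mwu = cs.lobe_mwu(
            {l: punct[(punct["group"] == "patient") & (punct["lobe"] == l)]["eccentricity"].to_numpy() for l in TABLE_LOBES},
            {l: punct[(punct["group"] == "control") & (punct["lobe"] == l)]["eccentricity"].to_numpy() for l in TABLE_LOBES},
        )
        table_lobes["mwu_p"] = table_lobes["lobe"].map(mwu)
    else:
        table_lobes = pd.DataFrame()

    return {
        "feature_distributions": table_features,
        "group_differences": table_groups,
        "lobe_comparison": table_lobes,
    }
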