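"""Cohort-level statistics on per-subject lesion summaries.

Per subject and per lesion class (all / non-punctuate / punctuate-deep) the
summaries are total lesion volume as %ICV, lesion count, and the median
per-lesion eccentricity. Group comparisons are ordinary least squares of
the outcome on a patient/control indicator adjusted for age and sex,
reported as the unstandardized coefficient B with 95% CI and the
standardized Beta = B * SD(indicator)/SD(outcome) with identically scaled
CI. Volumes and counts are natural-log transformed first (volumes scaled
by 10000 so the transformed range stays above 0 and the direction of
effect is retained); subjects with zero lesions in a stratum drop out of
that stratum's regression since log 0 is undefined.

Per-lobe comparisons of punctuate-deep lesions use 2x2 chi-square tests on
counts (lobe vs all other lobes, patients vs controls) and two-sided
Mann-Whitney U tests on per-lesion eccentricities. Per-lesion feature
distributions are described by mean/min/max/skewness plus a
Kolmogorov-Smirnov test against a normal with the sample moments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .location_features import NON_PUNCTUATE, PUNCTUATE_DEEP, LesionRecord
from .volume_io import SubjectMeta

__all__ = [
    "StratumSummary",
    "SubjectSummary",
    "RegressionResult",
    "FeatureSummary",
    "STRATA",
    "subject_summary",
    "summaries_to_frame",
    "nl_transform",
    "group_regression",
    "secondary_association",
    "lobe_chi2",
    "lobe_mwu",
    "feature_distribution_summary",
    "round_half_up",
]

logger = logging.getLogger(__name__)

STRATA = ("all", NON_PUNCTUATE, PUNCTUATE_DEEP)


@dataclass
class StratumSummary:
    """Per-subject lesion burden within one lesion class."""

    n_lesions: int
    wmh_volume_pct_icv: float
    median_eccentricity: float | None


@dataclass
class SubjectSummary:
    subject_id: str
    all: StratumSummary
    non_punctuate: StratumSummary
    punctuate_deep: StratumSummary

    def stratum(self, name: str) -> StratumSummary:
        return {"all": self.all, NON_PUNCTUATE: self.non_punctuate, PUNCTUATE_DEEP: self.punctuate_deep}[name]


@dataclass
class RegressionResult:
    """Adjusted group/covariate effect from an OLS fit.

    ``b`` is the unstandardized coefficient of the predictor of interest
    with its 95% CI; ``beta`` the standardized coefficient (CI scaled by
    the same factor); ``n`` the subjects used; ``p`` the two-sided p-value.
    """

    b: float
    b_ci: tuple[float, float]
    beta: float
    beta_ci: tuple[float, float]
    n: int
    p: float


@dataclass
class FeatureSummary:
    mean: float
    minimum: float
    maximum: float
    skewness: float
    ks_p: float


def subject_summary(records: list[LesionRecord], meta: SubjectMeta) -> SubjectSummary:
    """Summarize one subject's lesions for the three analysis strata."""
    if meta.icv <= 0:
        raise ValueError("ICV must be positive")
    for r in records:
        if r.subject_id != meta.subject_id:
            raise ValueError(f"record {r.lesion_id} belongs to {r.subject_id}, not {meta.subject_id}")

    def summarize(recs: list[LesionRecord]) -> StratumSummary:
        n = len(recs)
        vol = sum(r.features.volume_ml for r in recs)
        med = float(np.median([r.features.eccentricity for r in recs])) if n else None
        return StratumSummary(n_lesions=n, wmh_volume_pct_icv=vol / meta.icv * 100.0, median_eccentricity=med)

    return SubjectSummary(
        subject_id=meta.subject_id,
        all=summarize(records),
        non_punctuate=summarize([r for r in records if r.lesion_class == NON_PUNCTUATE]),
        punctuate_deep=summarize([r for r in records if r.lesion_class == PUNCTUATE_DEEP]),
    )


def summaries_to_frame(summaries: list[SubjectSummary], metas: list[SubjectMeta]) -> pd.DataFrame:
    """Flatten summaries + demographics into one analysis DataFrame."""
    meta_by_id = {m.subject_id: m for m in metas}
    rows = []
    for s in summaries:
        m = meta_by_id[s.subject_id]
        row = {
            "subject_id": s.subject_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "icv": m.icv,
            "gm_volume": m.gm_volume,
            "wm_volume": m.wm_volume,
            "diabetes_duration": m.diabetes_duration,
        }
        for name in STRATA:
            st = s.stratum(name)
            row[f"{name}_n"] = st.n_lesions
            row[f"{name}_volume_pct_icv"] = st.wmh_volume_pct_icv
            row[f"{name}_median_eccentricity"] = st.median_eccentricity
        rows.append(row)
    return pd.DataFrame(rows)


def nl_transform(values, scale: float = 10000.0) -> np.ndarray:
    """Natural log of ``values * scale``; strictly monotone.

    For volumes (%ICV fractions) the default scale of 10000 lifts the
    range above 1 so the sign of group effects is retained; counts use
    scale 1.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("nl_transform requires strictly positive values")
    return np.log(values * scale)


def _design_frame(
    metas: list[SubjectMeta],
    predictor: np.ndarray,
    predictor_name: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    extra: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame({predictor_name: predictor})
    if "age" in covariates:
        df["age"] = [m.age for m in metas]
    if "sex" in covariates:
        df["sex"] = [1.0 if m.sex == "M" else 0.0 for m in metas]
    if extra:
        for k, v in extra.items():
            df[k] = np.asarray(v, dtype=float)
    return df


def _fit_ols(outcome: np.ndarray, design: pd.DataFrame, of_interest: str) -> RegressionResult:
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(design.to_numpy().T)
        cols = design.columns.tolist()
        collinear = sorted(
            {cols[i] for i in range(len(cols)) for j in range(i + 1, len(cols)) if abs(corr[i, j]) > 1 - 1e-9}
            | {c for c in cols if design[c].std() == 0}
        )
        raise ValueError(f"singular design matrix; collinear columns: {collinear or cols}")
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[of_interest])
    ci = fit.conf_int().loc[of_interest]
    sd_x = float(np.std(design[of_interest].to_numpy(), ddof=1))
    sd_y = float(np.std(y, ddof=1))
    factor = sd_x / sd_y if sd_y > 0 else 0.0
    return RegressionResult(
        b=b,
        b_ci=(float(ci[0]), float(ci[1])),
        beta=b * factor,
        beta_ci=(float(ci[0]) * factor, float(ci[1]) * factor),
        n=len(y),
        p=float(fit.pvalues[of_interest]),
    )


def group_regression(
    outcome,
    metas: list[SubjectMeta],
    covariates: tuple[str, ...] = ("age", "sex"),
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> RegressionResult:
    """Patient-vs-control difference in ``outcome``, adjusted for age and sex.

    ``outcome`` is aligned with ``metas``. The group indicator is 1 for
    patients, 0 for controls; with ``covariates=()`` the coefficient
    reduces to the difference in group means.
    """
    outcome = np.asarray(outcome, dtype=float)
    if len(outcome) != len(metas):
        raise ValueError("outcome and metas must align")
    if len(metas) < 10:
        raise ValueError("need at least 10 subjects")
    groups = {m.group for m in metas}
    if groups != {"patient", "control"}:
        raise ValueError(f"both groups must be represented, got {sorted(groups)}")
    indicator = np.array([1.0 if m.group == "patient" else 0.0 for m in metas])
    design = _design_frame(metas, indicator, "group", covariates, extra_covariates)
    return _fit_ols(outcome, design, "group")


def secondary_association(
    outcome,
    covariate: str,
    metas: list[SubjectMeta],
    outcome_is_volume: bool = False,
) -> RegressionResult:
    """Association of a lesion feature with a continuous covariate.

    ``covariate`` is one of wm_volume, gm_volume, diabetes_duration; the
    fit is adjusted for age and sex, with ICV added to the design exactly
    when the outcome is a volume. Intended for the patient group (the
    caller selects the subjects).
    """
    if covariate not in ("wm_volume", "gm_volume", "diabetes_duration"):
        raise ValueError(f"unsupported covariate {covariate!r}")
    vals = [getattr(m, covariate) for m in metas]
    if any(v is None for v in vals):
        missing = [m.subject_id for m, v in zip(metas, vals) if v is None]
        raise ValueError(f"covariate {covariate} missing for subjects: {missing}")
    extra = {"icv": np.array([m.icv for m in metas])} if outcome_is_volume else None
    design = _design_frame(metas, np.asarray(vals, dtype=float), covariate, extra=extra)
    return _fit_ols(np.asarray(outcome, dtype=float), design, covariate)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero-half-up."""
    return int(math.floor(x + 0.5))


def lobe_chi2(patient_counts: dict[str, int], control_counts: dict[str, int]) -> pd.DataFrame:
    """Per-lobe 2x2 chi-square comparison of lesion location distributions.

    Each lobe is tested as lobe vs all-other-lobes against patient vs
    control, without continuity correction. Percentages (count / group
    total x 100) are reported at full precision and rounded half-up.
    """
    lobes = list(patient_counts)
    if set(control_counts) != set(lobes):
        raise ValueError("patient and control counts must cover the same lobes")
    pt = sum(patient_counts.values())
    ct = sum(control_counts.values())
    if pt <= 0 or ct <= 0:
        raise ValueError("each group needs at least one lesion")
    if any(c < 0 for c in list(patient_counts.values()) + list(control_counts.values())):
        raise ValueError("counts must be nonnegative")
    rows = []
    for lobe in lobes:
        p_n, c_n = patient_counts[lobe], control_counts[lobe]
        if p_n == 0 and c_n == 0:
            chi2, p = 0.0, 1.0
        else:
            table = np.array([[p_n, pt - p_n], [c_n, ct - c_n]])
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "lobe": lobe,
                "patient_n": p_n,
                "patient_pct": p_n / pt * 100.0,
                "patient_pct_rounded": round_half_up(p_n / pt * 100.0),
                "control_n": c_n,
                "control_pct": c_n / ct * 100.0,
                "control_pct_rounded": round_half_up(c_n / ct * 100.0),
                "chi2": float(chi2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def lobe_mwu(
    patient_values: dict[str, np.ndarray], control_values: dict[str, np.ndarray]
) -> dict[str, float]:
    """Two-sided Mann-Whitney U p-value per lobe.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (no continuity
    correction, so identical samples give p = 1). Lobes with an empty side
    are skipped with a warning.
    """
    out: dict[str, float] = {}
    for lobe in patient_values:
        x = np.asarray(patient_values[lobe], dtype=float)
        y = np.asarray(control_values.get(lobe, []), dtype=float)
        if len(x) == 0 or len(y) == 0:
            logger.warning("lobe %s skipped: empty group", lobe)
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (not has_ties and min(len(x), len(y)) <= 8) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
        out[lobe] = float(res.pvalue)
    return out


def feature_distribution_summary(values) -> FeatureSummary:
    """Mean, min, max, Fisher skewness g1 and KS normality p of a feature.

    The KS test compares against a normal with the sample mean and SD
    (estimated parameters, so the p-value is approximate in the Lilliefors
    sense). Requires >= 3 values for skewness and >= 8 for the KS test; a
    constant sample has undefined (NaN) skewness.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    mean = float(values.mean())
    if np.ptp(values) == 0:
        skew = math.nan
    else:
        skew = float(stats.skew(values, bias=True))
    if len(values) >= 8:
        sd = float(values.std(ddof=1))
        ks_p = float(stats.kstest(values, "norm", args=(mean, sd)).pvalue)
    else:
        ks_p = math.nan
    return FeatureSummary(
        mean=mean,
        minimum=float(values.min()),
        maximum=float(values.max()),
        skewness=skew,
        ks_p=ks_p,
    )
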