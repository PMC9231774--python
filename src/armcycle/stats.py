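"""Descriptive and association statistics for the cohort stage.

The study design is descriptive: per-measure median (IQR) summaries of
clinical measures and movement-profile features, ordinary-least-squares R²
for the function–strength–exertion pairs, and a pairwise-complete Pearson
correlation matrix of the strength battery. No inferential tests are
computed anywhere.

Quantiles use the linear-interpolation definition (numpy's default), i.e.
the 25th/75th percentiles interpolate between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .marker_io import AssessmentRecord, assessments_to_frame
from .profiles import MovementProfile

__all__ = [
    "median_iqr",
    "linear_r2",
    "R2Result",
    "pearson_matrix",
    "aggregate_cohort",
    "CohortSummary",
]


def median_iqr(values) -> tuple[float, float, float]:
    """(median, 25th percentile, 75th percentile); NaNs dropped.

    Raises :class:`ValidationError` when nothing finite remains.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("median_iqr: no finite values")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), float(q25), float(q75)


@dataclass
class R2Result:
    """OLS fit of y on x: coefficient of determination with provenance."""

    r2: float
    slope: float
    intercept: float
    n: int
    undefined: bool = False


def linear_r2(x, y) -> R2Result:
    """Coefficient of determination of the simple OLS regression of y on x.

    Equals the squared Pearson correlation for this one-predictor model.
    Pairs with a missing member are dropped; a constant predictor yields an
    ``undefined`` flag rather than a number.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 complete (x, y) pairs")
    if np.ptp(x) == 0:
        return R2Result(r2=float("nan"), slope=float("nan"),
                        intercept=float("nan"), n=int(x.size), undefined=True)
    fit = sps.linregress(x, y)
    return R2Result(r2=float(fit.rvalue**2), slope=float(fit.slope),
                    intercept=float(fit.intercept), n=int(x.size))


def pearson_matrix(strength_table: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise-complete Pearson correlation matrix of strength measures.

    Parameters
    ----------
    strength_table
        One row per participant, one column per strength measure.

    Returns
    -------
    (corr, n, flagged)
        ``corr`` — symmetric matrix with unit diagonal; ``n`` — pairwise
        complete count behind each coefficient; ``flagged`` — measures with
        zero variance, whose rows/columns are NaN (undefined).
    """
    df = strength_table.astype(float)
    if df.shape[1] < 2:
        raise ValidationError("need at least two measures")
    if (df.notna().sum() < 3).any():
        raise ValidationError("each measure needs >= 3 observations")
    corr = df.corr(method="pearson", min_periods=3)
    notna = df.notna().astype(int)
    n = pd.DataFrame(notna.T.values @ notna.values, index=df.columns,
                     columns=df.columns)
    flagged = [c for c in df.columns if np.ptp(df[c].dropna().to_numpy()) == 0]
    for c in flagged:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, [np.nan if c in flagged else 1.0
                                   for c in df.columns])
    return corr, n, flagged


@dataclass
class CohortSummary:
    """Median/IQR tables in the study's reporting layout.

    ``profile_features`` — rows (feature, effort_index) with median, q25,
    q75, n; ``clinical`` — rows (measure, joint, side, movement) likewise;
    ``exclusions`` — per-feature counts of flagged (undefined) profiles.
    """

    profile_features: pd.DataFrame
    clinical: pd.DataFrame
    n_cohort: int
    exclusions: dict = field(default_factory=dict)


_SUMMARY_FEATURES = (
    "cadence_cpm", "time_lag_s", "mean_phase_angle_deg", "signal_correlation",
    "shoulder_min_deg", "shoulder_max_deg", "shoulder_range_deg",
    "elbow_min_deg", "elbow_max_deg", "elbow_range_deg",
    "shoulder_max_velocity", "elbow_max_velocity",
)


def aggregate_cohort(profiles: list[MovementProfile],
                     records: list[AssessmentRecord]) -> CohortSummary:
    """Cohort-level median (IQR) of movement features and clinical measures.

    Profile participant identifiers must resolve against the assessment
    records; undefined (NaN / flagged) feature values are excluded with
    their counts reported in ``exclusions``.
    """
    if not profiles:
        raise ValidationError("no profiles to aggregate")
    known = {rec.participant_id for rec in records}
    for prof in profiles:
        if prof.participant_id not in known:
            raise ValidationError(
                f"profile participant {prof.participant_id!r} has no assessment record")

    rows = []
    exclusions: dict[str, int] = {}
    prof_df = pd.DataFrame([p.to_row() for p in profiles])
    for effort, group in prof_df.groupby("effort_index"):
        for feature in _SUMMARY_FEATURES:
            vals = group[feature].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            dropped = int((~finite).sum())
            if dropped:
                exclusions[f"{feature}@effort{effort}"] = dropped
            if finite.any():
                med, q25, q75 = median_iqr(vals[finite])
                rows.append({"feature": feature, "effort_index": effort,
                             "median": med, "q25": q25, "q75": q75,
                             "n": int(finite.sum())})
    profile_features = pd.DataFrame(rows)

    clin_rows = []
    adf = assessments_to_frame(records)
    oss = adf[adf["measure"] == "oss"]["value"]
    if len(oss):
        med, q25, q75 = median_iqr(oss)
        clin_rows.append({"measure": "oss", "joint": "", "side": "", "movement": "",
                          "median": med, "q25": q25, "q75": q75, "n": int(len(oss))})
    for measure in ("prom", "strength"):
        sub = adf[adf["measure"] == measure]
        for (joint, side, movement), grp in sub.groupby(["joint", "side", "movement"]):
            med, q25, q75 = median_iqr(grp["value"])
            clin_rows.append({"measure": measure, "joint": joint, "side": side,
                              "movement": movement, "median": med, "q25": q25,
                              "q75": q75, "n": int(len(grp))})
    rpe = adf[adf["measure"] == "rpe"]
    for effort, grp in rpe.groupby("effort"):
        med, q25, q75 = median_iqr(grp["value"])
        clin_rows.append({"measure": "rpe", "joint": "", "side": "",
                          "movement": f"effort{int(effort)}", "median": med,
                          "q25": q25, "q75": q75, "n": int(len(grp))})
    clinical = pd.DataFrame(clin_rows)
    return CohortSummary(
        profile_features=profile_features,
        clinical=clinical,
        n_cohort=len(records),
        exclusions=exclusions,
    )
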