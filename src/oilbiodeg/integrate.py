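"""Evidence integration: co-occurrence groups, stratified detection
summaries, and the transformed ridge regression.

Three per-sample detection booleans — Ca. Methanoliparum 16S rRNA genes,
acrA transcripts, and alkyl-CoM metabolites — grade the support for in
situ alkylotrophic methanogenesis into four characteristic co-occurrence
groups (all three markers; DNA and metabolite but no transcript;
metabolite only; none).  Detection proportions are summarized by
degradation degree and by oilfield.  Finally, a ridge regression on
log-transformed FPKM covariates and logit-transformed degrees quantifies
whether the archaeal (acrA) or the pooled bacterial fumarate-addition
term tracks degradation more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge, RidgeCV

from .synthetic import degree_to_logit

__all__ = [
    "EvidenceProfile",
    "TransformedXY",
    "RidgeFit",
    "classify_evidence",
    "classify_profiles",
    "detection_summary",
    "transform_xy",
    "fit_ridge",
    "select_lambda",
]

# The four described co-occurrence patterns, as
# (has_16S, has_acrA_transcript, has_alkylcom) -> group label.
_GROUP_TABLE: dict[tuple[bool, bool, bool], int] = {
    (True, True, True): 1,
    (True, False, True): 2,
    (False, False, True): 3,
    (False, False, False): 4,
}


@dataclass(frozen=True)
class EvidenceProfile:
    """Per-sample marker detections entering co-occurrence classification."""

    sample_id: str
    has_16s: bool
    has_acra_transcript: bool
    has_alkylcom: bool
    degradation_degree: int | None = None


def classify_evidence(p: EvidenceProfile) -> int | str:
    """Assign the co-occurrence group 1-4, or ``"other"``.

    Group 1: all three markers present (clearly positive for alkylotrophic
    methanogenesis); group 2: organism and metabolite present but acrA not
    expressed; group 3: metabolite only; group 4: nothing detected.  The
    remaining boolean combinations are not among the described patterns
    and map to ``"other"``.  Undefined (None) booleans are refused.
    """
    flags = (p.has_16s, p.has_acra_transcript, p.has_alkylcom)
    if any(f is None for f in flags):
        raise ValueError(f"sample {p.sample_id}: undefined detection flag")
    return _GROUP_TABLE.get(tuple(bool(f) for f in flags), "other")


def classify_profiles(evidence: pd.DataFrame) -> pd.Series:
    """Vectorized classification of a table with boolean columns
    ``has_16s, has_acra_transcript, has_alkylcom``."""
    cols = ["has_16s", "has_acra_transcript", "has_alkylcom"]
    if evidence[cols].isna().any().any():
        raise ValueError("undefined detection flags present")
    return evidence.apply(
        lambda r: _GROUP_TABLE.get((bool(r.has_16s), bool(r.has_acra_transcript),
                                    bool(r.has_alkylcom)), "other"),
        axis=1,
    ).rename("evidence_group")


def detection_summary(
    samples: pd.DataFrame,
    detected_col: str = "detected",
    strata: tuple[str, ...] = ("degree", "oilfield"),
) -> pd.DataFrame:
    """Detection proportions per stratum.

    For each stratifying column (degradation degree, oilfield, ...) and
    each occupied level, reports the number of samples, the number
    detected, and the detected fraction.  Empty strata simply do not
    appear — a proportion is never reported as 0/0.
    """
    if detected_col not in samples:
        raise ValueError(f"missing column {detected_col!r}")
    out = []
    for col in strata:
        if col not in samples:
            raise ValueError(f"missing stratum column {col!r}")
        grouped = samples.groupby(col, dropna=True)[detected_col]
        tab = grouped.agg(n_total="size", n_detected="sum").reset_index(names="stratum")
        tab.insert(0, "stratum_type", col)
        out.append(tab)
    summary = pd.concat(out, ignore_index=True)
    summary["proportion"] = summary["n_detected"] / summary["n_total"]
    return summary


@dataclass(frozen=True)
class TransformedXY:
    """Design matrix and response on the regression scale.

    ``x`` holds natural-log FPKM values (column 1: pooled bacterial
    fumarate-addition genes; column 2: archaeal acrA), ``y`` the
    logit-transformed degradation degree, computed as
    logit((degree + 0.5)/5) so every integer degree maps to a finite
    value.  ``n_excluded`` counts rows dropped for an indeterminate
    degree.
    """

    x: np.ndarray
    y: np.ndarray
    pseudocount: float
    feature_names: tuple[str, ...]
    n_excluded: int = 0


@dataclass(frozen=True)
class RidgeFit:
    """Result of the (optionally intercept-free) ridge fit
    ``argmin ||y - X beta - b||^2 + lambda ||beta||^2``."""

    beta: np.ndarray
    intercept: float
    penalty: float
    residuals: np.ndarray
    feature_names: tuple[str, ...]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.beta + self.intercept


def transform_xy(
    fpkm: pd.DataFrame,
    degrees: np.ndarray | pd.Series,
    pseudocount: float = 1.0,
) -> TransformedXY:
    """Log/logit transform of the regression inputs.

    X = ln(FPKM + pseudocount) per gene column; Y = logit((d + 0.5)/5).
    Rows whose degree is missing/indeterminate (NaN or None) are excluded
    and counted.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (fpkm.to_numpy(float) < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    d = pd.Series(list(degrees), index=fpkm.index, dtype="float")
    keep = d.notna()
    x = np.log(fpkm.loc[keep].to_numpy(float) + pseudocount)
    y = degree_to_logit(d[keep].to_numpy())
    return TransformedXY(
        x=x, y=np.asarray(y, float), pseudocount=float(pseudocount),
        feature_names=tuple(fpkm.columns), n_excluded=int((~keep).sum()),
    )


def fit_ridge(t: TransformedXY, penalty: float = 0.0, fit_intercept: bool = True) -> RidgeFit:
    """Ridge regression of Y on X with L2 penalty on the slopes only.

    With ``penalty=0`` the solution coincides with ordinary least squares
    (rank-deficiency then raises, directing the user to a positive
    penalty).  ``fit_intercept=False`` pins the intercept at zero, the
    centered-data convention; the default estimates it, matching the
    reported fitted form with its constant term.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    x, y = t.x, t.y
    n, p = x.shape
    if penalty == 0:
        if n < p + (1 if fit_intercept else 0):
            raise ValueError("too few rows for an unpenalized fit")
        xc = np.column_stack([x, np.ones(n)]) if fit_intercept else x
        if np.linalg.matrix_rank(xc) < xc.shape[1]:
            raise ValueError("design matrix is rank deficient; use penalty > 0")
        model = LinearRegression(fit_intercept=fit_intercept)
    else:
        model = Ridge(alpha=penalty, fit_intercept=fit_intercept)
    model.fit(x, y)
    beta = np.asarray(model.coef_, float)
    intercept = float(model.intercept_) if fit_intercept else 0.0
    residuals = y - (x @ beta + intercept)
    return RidgeFit(beta=beta, intercept=intercept, penalty=float(penalty),
                    residuals=residuals, feature_names=t.feature_names)


def select_lambda(
    t: TransformedXY,
    grid: np.ndarray | None = None,
    fit_intercept: bool = True,
) -> float:
    """Ridge penalty chosen by efficient leave-one-out cross-validation
    over a log-spaced grid."""
    grid = np.logspace(-4, 2, 25) if grid is None else np.asarray(grid, float)
    cv = RidgeCV(alphas=grid, fit_intercept=fit_intercept)
    cv.fit(t.x, t.y)
    return float(cv.alpha_)
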