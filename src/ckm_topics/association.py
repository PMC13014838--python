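"""Association of profile loadings with covariates and disease status.

Loadings are rank-transformed and regressed jointly on demographics,
anthropometrics and self-reported disease indicators by ordinary least
squares (one regression per topic); per-coefficient two-sided t-tests are
Bonferroni-corrected over the whole (topic x predictor) family.  A topic
simultaneously, significantly and positively associated with kidney
disease, type-2 diabetes and cardiovascular disease is called a candidate
cardiovascular-kidney-metabolic (CKM) subtype; all-negative gives a
protective profile.  Subtype prevalence is counted with a loading
threshold rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "rank_transform",
    "associate",
    "classify_subtypes",
    "prevalence",
    "AssociationError",
    "CKM_DISEASES",
]

#: the three disease indicators that define a candidate CKM subtype
CKM_DISEASES = ("kidney_disease", "t2dm", "cvd")


class AssociationError(ValueError):
    pass


def rank_transform(scores: np.ndarray, inverse_normal: bool = False) -> np.ndarray:
    """Fractional-rank transform to (0, 1), optionally inverse-normal.

    Average ranks for ties, mapped by (r - 0.5)/n; ``inverse_normal=True``
    additionally applies the standard-normal quantile function (RINT).
    Invariant under any strictly monotone re-scoring.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise AssociationError("scores must be nonempty and finite")
    if np.all(x == x.flat[0]):
        warnings.warn("all scores equal; rank transform returns 0.5 everywhere")
    r = rankdata(x, method="average")
    u = (r - 0.5) / x.size
    return ndtri(u) if inverse_normal else u


def _dummy_code(design: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical columns (drop-first) and coerce to float."""
    out = pd.get_dummies(design, drop_first=True, dtype=float)
    return out.astype(float)


def associate(theta_mean: np.ndarray, design: pd.DataFrame,
              family_size: int | None = None, alpha_family: float = 0.05,
              inverse_normal: bool = False) -> pd.DataFrame:
    """Per-topic OLS of rank-transformed loadings on all predictors jointly.

    Complete-case: rows with any missing predictor are dropped before
    ranking.  Bonferroni family defaults to topics x predictors.

    Returns a table with one row per (topic, predictor): beta, se, p,
    p_bonf, significant, direction.
    """
    theta_mean = np.asarray(theta_mean, dtype=float)
    n, K = theta_mean.shape
    if len(design) != n:
        raise AssociationError("design length does not match loadings")
    complete = ~design.isna().any(axis=1).to_numpy()
    X = _dummy_code(design.loc[complete])
    Xmat = sm.add_constant(X.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(Xmat)
    if rank < Xmat.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        cols = ["const"] + list(X.columns)
        for j in range(1, Xmat.shape[1]):
            if np.linalg.matrix_rank(Xmat[:, : j + 1]) == np.linalg.matrix_rank(Xmat[:, :j]):
                bad.append(cols[j])
        raise AssociationError(f"design is rank-deficient; collinear columns: {bad}")
    preds = list(X.columns)
    m_tests = family_size if family_size is not None else K * len(preds)
    rows = []
    for k in range(K):
        y = rank_transform(theta_mean[complete, k], inverse_normal=inverse_normal)
        fit = sm.OLS(y, Xmat).fit()
        for j, pred in enumerate(preds, start=1):
            p = float(fit.pvalues[j])
            rows.append({
                "topic": k,
                "predictor": pred,
                "beta": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "p": p,
                "p_bonf": min(1.0, p * m_tests),
                "significant": bool(p <= alpha_family / m_tests),
                "direction": int(np.sign(fit.params[j])),
            })
    return pd.DataFrame(rows)


def classify_subtypes(assoc: pd.DataFrame,
                      diseases: tuple[str, ...] = CKM_DISEASES) -> pd.DataFrame:
    """Call each topic candidate_CKM / protective / neither.

    candidate_CKM: all three disease coefficients positive and significant
    after correction; protective: all three negative and significant.
    """
    calls = []
    for topic, grp in assoc.groupby("topic"):
        sub = grp.set_index("predictor")
        missing = [d for d in diseases if d not in sub.index]
        if missing:
            raise AssociationError(f"missing disease columns in association table: {missing}")
        sig = sub.loc[list(diseases), "significant"].to_numpy(dtype=bool)
        sign = sub.loc[list(diseases), "direction"].to_numpy()
        if sig.all() and (sign > 0).all():
            call = "candidate_CKM"
        elif sig.all() and (sign < 0).all():
            call = "protective"
        else:
            call = "neither"
        calls.append({"topic": topic, "call": call})
    return pd.DataFrame(calls)


@dataclass
class PrevalenceReport:
    threshold: float
    per_topic_cases: dict[int, int]
    per_topic_fraction: dict[int, float]
    overall_cases: int
    overall_fraction: float
    sensitivity: pd.DataFrame  # threshold x (overall_cases, overall_fraction)


def prevalence(theta_mean: np.ndarray, topic_ids, threshold: float = 0.5,
               sweep=(0.5, 0.4, 0.3)) -> PrevalenceReport:
    """Subtype-positive case counts under a loading-threshold rule.

    A participant is a case for topic k when theta_k >= threshold; an
    overall case when the summed loading over ``topic_ids`` meets the
    threshold.  ``sweep`` adds a sensitivity table over thresholds.
    """
    if not (0.0 < threshold <= 1.0):
        raise AssociationError("threshold must be in (0, 1]")
    theta_mean = np.asarray(theta_mean, dtype=float)
    n = theta_mean.shape[0]
    topic_ids = [int(t) for t in topic_ids]
    per_cases = {t: int((theta_mean[:, t] >= threshold).sum()) for t in topic_ids}
    per_frac = {t: per_cases[t] / n for t in topic_ids}
    summed = theta_mean[:, topic_ids].sum(axis=1)
    overall = int((summed >= threshold).sum())
    rows = []
    for thr in sweep:
        if not (0.0 < thr <= 1.0):
            raise AssociationError("sweep thresholds must be in (0, 1]")
        oc = int((summed >= thr).sum())
        row = {"threshold": thr, "overall_cases": oc, "overall_fraction": oc / n}
        for t in topic_ids:
            row[f"topic_{t}_cases"] = int((theta_mean[:, t] >= thr).sum())
        rows.append(row)
    return PrevalenceReport(
        threshold=threshold,
        per_topic_cases=per_cases,
        per_topic_fraction=per_frac,
        overall_cases=overall,
        overall_fraction=overall / n,
        sensitivity=pd.DataFrame(rows),
    )
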