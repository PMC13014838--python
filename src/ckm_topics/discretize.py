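"""Sex-stratified quantile discretization of continuous biomarkers.

Continuous biomarkers are cut into five ordinal levels at the empirical
10th, 30th, 70th and 90th percentiles of each sex's observed distribution,
giving nominal bin occupancies of 10/20/40/20/10%.  The asymmetric cuts
keep resolution at the distribution tails, where clinically extreme values
live, without exploding the number of categories.  Blood pressure is the
exception: it is mapped onto the 2017 ACC/AHA categories (normal, elevated,
hypertensive) rather than cohort quantiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BinSpec",
    "BinnedCohort",
    "QuantileBinner",
    "fit_bins",
    "apply_bins",
    "categorize_bp",
    "BP_LEVELS",
]

#: percentile cut points, in percent
DEFAULT_PERCENTILES = (10.0, 30.0, 70.0, 90.0)

#: ordinal codes for blood-pressure categories
BP_LEVELS = {"normal": 0, "elevated": 1, "hypertensive": 2}

#: number of ordinal levels for a quantile-binned feature
N_QUANTILE_LEVELS = 5


class DiscretizationError(ValueError):
    """Raised when bins cannot be fitted or applied."""


@dataclass
class BinSpec:
    """Per-(feature, sex) percentile thresholds.

    ``thresholds[feature][sex]`` is a nondecreasing array of four cut
    points.  ``guideline_features`` lists features that bypass quantile
    binning (blood pressure).
    """

    thresholds: dict[str, dict[str, np.ndarray]]
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    guideline_features: tuple[str, ...] = ()

    @property
    def features(self) -> list[str]:
        return list(self.thresholds)

    def to_json(self) -> str:
        obj = {
            "percentiles": list(self.percentiles),
            "guideline_features": list(self.guideline_features),
            "thresholds": {
                f: {s: [float(x) for x in t] for s, t in per_sex.items()}
                for f, per_sex in self.thresholds.items()
            },
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BinSpec":
        obj = json.loads(text)
        thr = {
            f: {s: np.asarray(t, dtype=float) for s, t in per_sex.items()}
            for f, per_sex in obj["thresholds"].items()
        }
        return cls(
            thresholds=thr,
            percentiles=tuple(obj["percentiles"]),
            guideline_features=tuple(obj["guideline_features"]),
        )


@dataclass
class BinnedCohort:
    """Participant x feature ordinal level matrix with an observed mask.

    ``levels`` holds integer codes (0-4 for quantile features, 0-2 for
    blood pressure); entries where ``mask`` is False are undefined and set
    to -1 by convention.
    """

    participant_ids: np.ndarray
    feature_names: list[str]
    levels: np.ndarray  # (n, F) int8, -1 where unobserved
    mask: np.ndarray  # (n, F) bool
    sex: np.ndarray  # (n,) labels
    n_levels: np.ndarray = field(default=None)  # per-feature level count

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise DiscretizationError("levels and mask shapes differ")
        if self.n_levels is None:
            self.n_levels = np.full(len(self.feature_names), N_QUANTILE_LEVELS, dtype=int)
        self.n_levels = np.asarray(self.n_levels, dtype=int)
        obs = self.levels[self.mask]
        if obs.size and (obs.min() < 0 or (self.levels >= self.n_levels[None, :]).any()):
            raise DiscretizationError("observed level out of range")
        if ((self.levels < 0) & self.mask).any():
            raise DiscretizationError("mask true but level undefined")

    @property
    def n_participants(self) -> int:
        return self.levels.shape[0]

    @property
    def n_features(self) -> int:
        return self.levels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.levels.astype(float), columns=self.feature_names,
        )
        df[~pd.DataFrame(self.mask, columns=self.feature_names)] = np.nan
        df.insert(0, "participant_id", self.participant_ids)
        df.insert(1, "sex", self.sex)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_levels: np.ndarray | None = None) -> "BinnedCohort":
        feats = [c for c in df.columns if c not in ("participant_id", "sex")]
        vals = df[feats].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        levels = np.where(mask, np.nan_to_num(vals), -1).astype(np.int8)
        return cls(
            participant_ids=df["participant_id"].to_numpy(),
            feature_names=feats,
            levels=levels,
            mask=mask,
            sex=df["sex"].to_numpy(),
            n_levels=n_levels,
        )


def fit_bins(
    values: pd.DataFrame,
    sex: np.ndarray,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    guideline_features: tuple[str, ...] = (),
) -> BinSpec:
    """Fit per-sex percentile thresholds on observed values only.

    Parameters
    ----------
    values : DataFrame of continuous biomarkers (NaN = missing).
    sex : per-participant sex labels (stratification variable).
    percentiles : cut points in percent; linear-interpolation definition.
    guideline_features : columns to exclude from quantile fitting.

    Raises
    ------
    DiscretizationError
        If a feature has no observed value for some sex.
    """
    sex = np.asarray(sex)
    thresholds: dict[str, dict[str, np.ndarray]] = {}
    for feat in values.columns:
        if feat in guideline_features:
            continue
        per_sex = {}
        for s in np.unique(sex):
            v = values.loc[sex == s, feat].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                raise DiscretizationError(
                    f"feature {feat!r} has no observed values for sex {s!r}"
                )
            per_sex[str(s)] = np.percentile(v, percentiles, method="linear")
        thresholds[feat] = per_sex
    return BinSpec(
        thresholds=thresholds,
        percentiles=tuple(percentiles),
        guideline_features=tuple(guideline_features),
    )


def apply_bins(cohort: pd.DataFrame, spec: BinSpec, sex_col: str = "sex",
               id_col: str = "participant_id") -> BinnedCohort:
    """Discretize a cohort table with a fitted :class:`BinSpec`.

    The level of a value is the number of thresholds strictly below it, so
    a value exactly equal to a threshold falls in the lower bin.  Missing
    values stay missing.
    """
    sex = cohort[sex_col].to_numpy()
    n = len(cohort)
    feats = spec.features
    for feat in feats:
        if feat not in cohort.columns:
            raise DiscretizationError(f"feature {feat!r} not in cohort table")
    levels = np.full((n, len(feats)), -1, dtype=np.int8)
    mask = np.zeros((n, len(feats)), dtype=bool)
    for j, feat in enumerate(feats):
        v = cohort[feat].to_numpy(dtype=float)
        obs = ~np.isnan(v)
        for s, thr in spec.thresholds[feat].items():
            sel = obs & (sex.astype(str) == s)
            # level = count of thresholds strictly below the value
            levels[sel, j] = np.searchsorted(thr, v[sel], side="left")
        mask[:, j] = obs
    ids = cohort[id_col].to_numpy() if id_col in cohort.columns else np.arange(n)
    return BinnedCohort(
        participant_ids=ids,
        feature_names=list(feats),
        levels=levels,
        mask=mask,
        sex=sex,
        n_levels=np.full(len(feats), len(spec.percentiles) + 1, dtype=int),
    )


def categorize_bp(systolic, diastolic):
    """Categorize blood pressure per the 2017 ACC/AHA thresholds.

    normal: SBP < 120 and DBP < 80; elevated: 120 <= SBP <= 129 and
    DBP < 80; hypertensive: SBP >= 130 or DBP >= 80.  Missing components
    yield a missing category (-1).
    """
    sbp = np.asarray(systolic, dtype=float)
    dbp = np.asarray(diastolic, dtype=float)
    scalar = sbp.ndim == 0
    sbp, dbp = np.atleast_1d(sbp), np.atleast_1d(dbp)
    out = np.full(sbp.shape, -1, dtype=np.int8)
    obs = ~(np.isnan(sbp) | np.isnan(dbp))
    hyp = obs & ((sbp >= 130) | (dbp >= 80))
    elev = obs & ~hyp & (sbp >= 120)
    norm = obs & ~hyp & ~elev
    out[norm] = BP_LEVELS["normal"]
    out[elev] = BP_LEVELS["elevated"]
    out[hyp] = BP_LEVELS["hypertensive"]
    return int(out[0]) if scalar else out


class QuantileBinner(BaseEstimator, TransformerMixin):
    """Sex-stratified quantile discretizer, sklearn-style.

    Parameters
    ----------
    percentiles : cut points in percent (default 10/30/70/90).
    sex_col, id_col : column names in the input DataFrame.
    guideline_features : features that are not quantile-binned.

    Attributes
    ----------
    spec_ : BinSpec
        Fitted per-(feature, sex) thresholds.
    """

    def __init__(self, percentiles=DEFAULT_PERCENTILES, sex_col="sex",
                 id_col="participant_id", guideline_features=()):
        self.percentiles = percentiles
        self.sex_col = sex_col
        self.id_col = id_col
        self.guideline_features = guideline_features

    def fit(self, X: pd.DataFrame, y=None):
        value_cols = [
            c for c in X.columns
            if c not in (self.sex_col, self.id_col)
            and pd.api.types.is_numeric_dtype(X[c])
        ]
        self.spec_ = fit_bins(
            X[value_cols], X[self.sex_col].to_numpy(),
            percentiles=tuple(self.percentiles),
            guideline_features=tuple(self.guideline_features),
        )
        return self

    def transform(self, X: pd.DataFrame) -> BinnedCohort:
        return apply_bins(X, self.spec_, sex_col=self.sex_col, id_col=self.id_col)
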