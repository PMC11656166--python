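"""Covariate-adjusted w-scores against the control group.

A w-score is a z-score computed against what a control population predicts
for a subject's covariates: per region, regional values are regressed on age,
sex, education and APOE e4 carriership in controls; a subject's w-score is
(observed - predicted) / residual SD.  By default scores are reversed so that
higher w-scores mean greater neurodegeneration (lower volume or uptake).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RoiMatrix, SubjectMeta

logger = logging.getLogger("corticolimbic")

DEFAULT_COVARIATES = ("age", "sex", "education", "apoe4_carrier")


def _design_matrix(meta: SubjectMeta, ids: list[str],
                   covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; sex and APOE enter as 0/1 indicators."""
    cols: list[np.ndarray] = [np.ones(len(ids))]
    names = ["intercept"]
    t = meta.table.loc[ids]
    for cov in covariates:
        if cov not in t.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        if cov == "sex":
            x = (t[cov] == "M").to_numpy(float)
        else:
            x = t[cov].to_numpy(float)
        if np.isnan(x).any():
            bad = list(t.index[np.isnan(x)])
            raise ValueError(f"missing covariate {cov!r} for subject(s): {bad}")
        cols.append(x)
        names.append(cov)
    return np.column_stack(cols), names


@dataclass
class WScoreModel:
    """Per-region control regression: coefficients and residual SD.

    ``coef`` is regions x terms (intercept first); ``covariates`` lists the
    retained covariate names in design order.
    """

    coef: pd.DataFrame
    residual_sd: pd.Series
    covariates: tuple[str, ...]
    n_fit: int
    state: str

    def predict(self, meta: SubjectMeta, ids: list[str]) -> pd.DataFrame:
        X, _ = _design_matrix(meta, ids, self.covariates)
        pred = X @ self.coef.to_numpy().T
        return pd.DataFrame(pred, index=ids, columns=self.coef.index)


def fit_wscore_model(values_cn: RoiMatrix, meta_cn: SubjectMeta,
                     covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> WScoreModel:
    """Fit the per-region control regression of value on covariates.

    Degenerate (zero-variance) covariates in the control sample are dropped
    with a warning; a near-zero residual SD in any region is a hard error
    since w-scores would be unbounded.
    """
    ids = values_cn.subjects
    kept = []
    t = meta_cn.table.loc[ids]
    for cov in covariates:
        x = (t[cov] == "M").to_numpy(float) if cov == "sex" else t[cov].to_numpy(float)
        if np.std(x) == 0:
            logger.warning("fit_wscore_model: covariate %r is constant in controls; dropped", cov)
            continue
        kept.append(cov)
    covariates = tuple(kept)
    X, names = _design_matrix(meta_cn, ids, covariates)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"control sample size {n} must exceed number of model terms {k}")
    Y = values_cn.values.to_numpy(float)
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < k:
        raise ValueError("collinear covariates in the control design matrix")
    resid = Y - X @ coef
    dof = n - k
    sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    if (sd <= np.sqrt(np.finfo(float).eps)).any():
        bad = [r for r, s in zip(values_cn.regions, sd) if s <= np.sqrt(np.finfo(float).eps)]
        raise ValueError(f"degenerate fit (residual SD ~ 0) for region(s): {bad}")
    return WScoreModel(
        coef=pd.DataFrame(coef.T, index=values_cn.regions, columns=names),
        residual_sd=pd.Series(sd, index=values_cn.regions),
        covariates=covariates,
        n_fit=n,
        state=values_cn.state,
    )


def compute_wscores(values: RoiMatrix, meta: SubjectMeta, model: WScoreModel,
                    reverse: bool = True) -> RoiMatrix:
    """w = (observed - predicted) / residual SD, optionally sign-reversed.

    With ``reverse=True`` (the default, for both modalities) higher w-scores
    correspond to greater neurodegeneration.
    """
    if list(values.regions) != list(model.coef.index):
        raise ValueError("model regions do not match matrix regions")
    ids = values.subjects
    pred = model.predict(meta, ids)
    w = (values.values - pred) / model.residual_sd
    if reverse:
        w = -w
    return values.evolve(w, units="w-score", state="w-score")


def subtype_mean_map(w: RoiMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-subtype per-region mean w-score, in long format.

    Returns columns (subtype, region_id, mean_w, n); empty subtypes are
    excluded with a warning.  This is the plottable analogue of the
    subtype neurodegeneration brain maps.
    """
    missing = [s for s in labels.index if s not in set(w.subjects)]
    if missing:
        raise ValueError(f"labelled subject(s) missing from w-score matrix: {missing}")
    rows = []
    for subtype, ids in labels.groupby(labels).groups.items():
        ids = list(ids)
        if not ids:
            logger.warning("subtype_mean_map: empty subtype %r excluded", subtype)
            continue
        means = w.values.loc[ids].mean(axis=0)
        for region, m in means.items():
            rows.append({"subtype": subtype, "region_id": region,
                         "mean_w": float(m), "n": len(ids)})
    return pd.DataFrame(rows, columns=["subtype", "region_id", "mean_w", "n"])
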