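"""Value transformations applied before subtyping.

Regional grey-matter volumes are adjusted for head size with the residual
approach: a per-region ordinary-least-squares slope of volume on intracranial
volume (ICV), fitted in controls only, is used to remove the ICV-predicted
component from every subject:

    volume_adj = volume_raw - beta * (ICV_raw - ICV_mean)

Regional uptake values are intensity-normalized by each subject's global mean
uptake (for clustering) or scaled by the mean of the reference regions, pons,
(for w-score neurodegeneration maps).  A simple regression-residual QC screen
flags subjects whose total regional volume is grossly inconsistent with their
ICV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RoiAtlas, RoiMatrix, SubjectMeta

logger = logging.getLogger("corticolimbic")


@dataclass
class IcvModel:
    """Per-region OLS slope of volume on ICV, fitted on controls.

    ``beta`` has units of volume per mm^3 of ICV; ``icv_mean`` is the mean
    ICV of the control fitting sample.
    """

    beta: pd.Series
    icv_mean: float
    n_fit: int


def fit_icv_model(volumes_cn: RoiMatrix, meta_cn: SubjectMeta) -> IcvModel:
    """Fit the head-size adjustment model on the control sample.

    beta per region is the OLS slope of region volume on ICV:
    sum((x - xbar)(y - ybar)) / sum((x - xbar)^2).
    """
    ids = volumes_cn.subjects
    if len(ids) < 3:
        raise ValueError("need >= 3 control subjects to fit the ICV model")
    icv = meta_cn.table.loc[ids, "icv"].to_numpy(float)
    xc = icv - icv.mean()
    ssx = float(xc @ xc)
    if ssx <= 0:
        raise ValueError("zero ICV variance in the control fitting sample")
    y = volumes_cn.values.to_numpy(float)
    beta = (xc @ (y - y.mean(axis=0))) / ssx
    return IcvModel(beta=pd.Series(beta, index=volumes_cn.regions),
                    icv_mean=float(icv.mean()), n_fit=len(ids))


def apply_icv_adjustment(volumes: RoiMatrix, meta: SubjectMeta, model: IcvModel) -> RoiMatrix:
    """Remove the ICV-predicted component from every subject's volumes.

    The control-derived model is applied identically to all groups.
    """
    missing = [r for r in volumes.regions if r not in model.beta.index]
    if missing:
        raise ValueError(f"region(s) missing from ICV model: {missing}")
    ids = volumes.subjects
    icv = meta.table.loc[ids, "icv"].to_numpy(float)
    beta = model.beta.loc[volumes.regions].to_numpy(float)
    adj = volumes.values.to_numpy(float) - np.outer(icv - model.icv_mean, beta)
    out = pd.DataFrame(adj, index=ids, columns=volumes.regions)
    return volumes.evolve(out, state="icv-adjusted")


def normalize_global_mean(uptake: RoiMatrix, atlas: RoiAtlas) -> RoiMatrix:
    """Divide each subject's row by that subject's global mean uptake.

    The global mean is taken over all non-reference atlas regions, so this
    scaling stays independent of the reference-region scaling.  Output rows
    have mean 1 over the non-reference regions.
    """
    vals = uptake.values
    if (vals.to_numpy() <= 0).any():
        raise ValueError("global-mean normalization requires strictly positive values")
    global_mean = vals[atlas.non_reference_ids].mean(axis=1)
    out = vals.div(global_mean, axis=0)
    return uptake.evolve(out, units="dimensionless", state="global-normalized")


def scale_by_reference(uptake: RoiMatrix, atlas: RoiAtlas) -> RoiMatrix:
    """Divide each row by the mean of that subject's reference-region values.

    Reference regions are dropped from the output: after scaling they carry
    no information (a single reference region becomes identically 1) and
    would only produce degenerate downstream fits.
    """
    vals = uptake.values
    ref = vals[atlas.reference_ids].mean(axis=1)
    if (ref <= 0).any():
        bad = list(ref.index[ref <= 0])
        raise ValueError(f"non-positive reference value for subject(s): {bad}")
    keep = [r for r in vals.columns if r not in set(atlas.reference_ids)]
    out = vals[keep].div(ref, axis=0)
    return uptake.evolve(out, units="SUVR", state="reference-scaled")


def qc_screen(volumes: RoiMatrix, meta: SubjectMeta, threshold_sd: float = 4.0) -> pd.Series:
    """Flag subjects whose total regional volume is off the ICV regression line.

    Regresses each subject's summed regional volume on ICV and flags subjects
    whose residual exceeds ``threshold_sd`` residual standard deviations.
    Flags are advisory; exclusion is a pipeline configuration choice.
    """
    ids = volumes.subjects
    empty = pd.Series(False, index=ids, name="qc_flag")
    if len(ids) < 10:
        logger.warning("qc_screen: fewer than 10 subjects; returning no flags")
        return empty
    total = volumes.values.sum(axis=1).to_numpy(float)
    icv = meta.table.loc[ids, "icv"].to_numpy(float)
    xc = icv - icv.mean()
    ssx = float(xc @ xc)
    if ssx <= 0:
        logger.warning("qc_screen: zero ICV variance; returning no flags")
        return empty
    slope = float(xc @ (total - total.mean())) / ssx
    resid = total - total.mean() - slope * xc
    sd = resid.std(ddof=2)
    if sd <= 0:
        logger.warning("qc_screen: zero residual spread; returning no flags")
        return empty
    flags = pd.Series(np.abs(resid) > threshold_sd * sd, index=ids, name="qc_flag")
    if flags.any():
        logger.warning("qc_screen: flagged subject(s): %s", list(flags.index[flags]))
    return flags
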