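"""Hippocampus-to-cortex ratio subtyping and the typicality/severity axes.

The hypothesis-driven classifier groups patients by the ratio of mean
hippocampal to mean cortical-association values, echoing the
neuropathologically defined corticolimbic subtypes: a low ratio marks
limbic-predominant neurodegeneration (disproportionate hippocampal damage),
a high ratio marks cortical-predominant ("hippocampal-sparing") damage.
Classification is a two-step rule: quartile cut on the ratio, then
confirmation against the sample medians of the hippocampal and cortical
composites so that only genuinely discordant profiles leave the middle
("Typical") group.

The same ratio serves as the "typicality" coordinate of a two-axis subtype
framework; "severity" is total grey-matter volume (MRI) or mean cortical
uptake (FDG-PET).  Both are min-max normalized over the patient sample, with
severity reversed so that higher normalized values mean greater overall
neurodegeneration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RoiAtlas, RoiMatrix

logger = logging.getLogger("corticolimbic")

LABEL_LP = "Limbic Predominant"
LABEL_CP = "Cortical Predominant"
LABEL_TYPICAL = "Typical"


def hippocampus_cortex_ratio(values: RoiMatrix, atlas: RoiAtlas) -> pd.Series:
    """Mean over hippocampus regions divided by mean over cortical-association regions."""
    hip = atlas.hippocampus_ids
    cortex = atlas.cortical_association_ids
    if not hip or not cortex:
        raise ValueError("atlas must define hippocampus and cortical-association regions")
    ratio = values.values[hip].mean(axis=1) / values.values[cortex].mean(axis=1)
    ratio.name = "hippocampus_cortex_ratio"
    return ratio


@dataclass
class HypothesisLabels:
    """Two-step classifier output with all intermediate quantities.

    ``thresholds`` records the ratio quartiles and composite medians actually
    used, so alternative rules can be compared against the same sample.
    """

    labels: pd.Series
    ratio: pd.Series
    hippocampal_composite: pd.Series
    cortical_composite: pd.Series
    thresholds: dict[str, float]


def classify_hypothesis_driven(values: RoiMatrix, atlas: RoiAtlas) -> HypothesisLabels:
    """Quartile-plus-median two-step corticolimbic classification.

    Step 1: ratios strictly below the 25th percentile are provisionally
    limbic-predominant; strictly above the 75th, cortical-predominant.
    Step 2: a provisional label is confirmed only if the discordance is real
    — limbic-predominant needs the hippocampal composite below the sample
    median AND the cortical composite above it; cortical-predominant needs
    the reverse.  Unconfirmed cases revert to Typical.  Ties exactly at a
    threshold stay on the Typical-ward side and are logged.
    """
    ids = values.subjects
    if len(ids) < 8:
        raise ValueError("need >= 8 subjects for meaningful quartiles")
    ratio = hippocampus_cortex_ratio(values, atlas)
    hip = values.values[atlas.hippocampus_ids].mean(axis=1)
    cortex = values.values[atlas.cortical_association_ids].mean(axis=1)
    q25, q75 = np.percentile(ratio, [25, 75])
    med_hip, med_cortex = float(hip.median()), float(cortex.median())

    ties = ratio.index[(ratio == q25) | (ratio == q75)]
    if len(ties):
        logger.info("classify_hypothesis_driven: ratio exactly at a quartile for %s "
                    "(assigned Typical-ward)", list(ties))

    labels = pd.Series(LABEL_TYPICAL, index=ratio.index, name="hypothesis_label")
    lp = (ratio < q25) & (hip < med_hip) & (cortex > med_cortex)
    cp = (ratio > q75) & (hip > med_hip) & (cortex < med_cortex)
    labels[lp] = LABEL_LP
    labels[cp] = LABEL_CP
    return HypothesisLabels(
        labels=labels,
        ratio=ratio,
        hippocampal_composite=hip,
        cortical_composite=cortex,
        thresholds={"ratio_q25": float(q25), "ratio_q75": float(q75),
                    "hippocampal_median": med_hip, "cortical_median": med_cortex},
    )


@dataclass
class AxisCoordinates:
    """Per-subject typicality/severity coordinates for both modalities.

    ``fdg`` and ``mri`` are DataFrames with columns ``typicality``,
    ``severity``, ``normalized_typicality``, ``normalized_severity``.
    Normalization is min-max over the patient analysis sample; severity is
    reversed (1 = most neurodegeneration).
    """

    fdg: pd.DataFrame
    mri: pd.DataFrame


def _minmax(x: pd.Series, reverse: bool = False) -> pd.Series:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError(f"min-max normalization undefined: constant measure {x.name!r}")
    out = (x - lo) / (hi - lo)
    return 1.0 - out if reverse else out


def compute_axes(values_fdg: RoiMatrix, values_mri: RoiMatrix, atlas: RoiAtlas,
                 ad_ids: list[str]) -> AxisCoordinates:
    """Typicality and severity coordinates over the patient sample.

    Typicality is the modality-specific hippocampus-to-cortex ratio.
    Severity is the summed non-reference region volume (MRI) or the mean
    uptake over cortical regions (FDG).  Raw coordinates are kept alongside
    the normalized ones.
    """
    if len(ad_ids) < 2:
        raise ValueError("min-max normalization needs >= 2 subjects")
    fdg = values_fdg.subset(ad_ids)
    mri = values_mri.subset(ad_ids)

    typ_fdg = hippocampus_cortex_ratio(fdg, atlas)
    typ_mri = hippocampus_cortex_ratio(mri, atlas)
    sev_fdg = fdg.values[atlas.cortical_ids].mean(axis=1)
    sev_mri = mri.values[[r for r in atlas.ids if r not in set(atlas.reference_ids)]].sum(axis=1)
    sev_fdg.name, sev_mri.name = "severity", "severity"

    def frame(typ: pd.Series, sev: pd.Series) -> pd.DataFrame:
        return pd.DataFrame({
            "typicality": typ,
            "severity": sev,
            "normalized_typicality": _minmax(typ),
            "normalized_severity": _minmax(sev, reverse=True),
        })

    return AxisCoordinates(fdg=frame(typ_fdg, sev_fdg), mri=frame(typ_mri, sev_mri))


def subtype_axis_summary(coords: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-subtype mean normalized coordinates (one modality), long format."""
    rows = []
    for subtype, ids in labels.groupby(labels).groups.items():
        ids = [s for s in ids if s in coords.index]
        if not ids:
            logger.warning("subtype_axis_summary: empty subtype %r excluded", subtype)
            continue
        sub = coords.loc[ids]
        rows.append({
            "subtype": subtype,
            "mean_normalized_typicality": float(sub["normalized_typicality"].mean()),
            "mean_normalized_severity": float(sub["normalized_severity"].mean()),
            "n": len(ids),
        })
    return pd.DataFrame(rows)


def axis_correlations(coords_fdg: pd.DataFrame, coords_mri: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations for the four axis pairings.

    Rows: (FDG typicality, FDG severity), (MRI typicality, MRI severity),
    (FDG severity, MRI severity), (FDG typicality, MRI typicality); columns
    r, r_squared, p_value.  Zero-variance measures yield missing rows.
    """
    common = coords_fdg.index.intersection(coords_mri.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired subjects for correlations")
    pairs = [
        ("FDG typicality vs FDG severity",
         coords_fdg.loc[common, "typicality"], coords_fdg.loc[common, "severity"]),
        ("MRI typicality vs MRI severity",
         coords_mri.loc[common, "typicality"], coords_mri.loc[common, "severity"]),
        ("FDG severity vs MRI severity",
         coords_fdg.loc[common, "severity"], coords_mri.loc[common, "severity"]),
        ("FDG typicality vs MRI typicality",
         coords_fdg.loc[common, "typicality"], coords_mri.loc[common, "typicality"]),
    ]
    rows = []
    for name, x, y in pairs:
        if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            logger.warning("axis_correlations: zero variance in %s; reported missing", name)
            rows.append({"pairing": name, "r": np.nan, "r_squared": np.nan,
                         "p_value": np.nan, "n": len(common)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"pairing": name, "r": float(r), "r_squared": float(r) ** 2,
                     "p_value": float(p), "n": len(common)})
    return pd.DataFrame(rows).set_index("pairing")


def method_agreement(data_driven: pd.Series, hypothesis: pd.Series,
                     equivalence_map: dict[str, str]) -> pd.DataFrame:
    """Per-class agreement between data-driven and hypothesis-driven labels.

    ``equivalence_map`` maps each label (of either method) to a shared class
    (e.g. "limbic" / "cortical" / "other").  For each class the agreement is
    the percentage of data-driven members that also carry the class under the
    hypothesis-driven method.  Classes absent under the data-driven method are
    reported missing.
    """
    common = data_driven.index.intersection(hypothesis.index)
    dd = data_driven.loc[common].map(lambda lab: equivalence_map.get(lab, lab))
    hy = hypothesis.loc[common].map(lambda lab: equivalence_map.get(lab, lab))
    rows = []
    for cls in sorted(set(equivalence_map.values())):
        denom = int((dd == cls).sum())
        if denom == 0:
            logger.warning("method_agreement: class %r absent under data-driven labels", cls)
            rows.append({"class": cls, "agreement_pct": np.nan,
                         "n_both": 0, "n_data_driven": 0})
            continue
        both = int(((dd == cls) & (hy == cls)).sum())
        rows.append({"class": cls, "agreement_pct": 100.0 * both / denom,
                     "n_both": both, "n_data_driven": denom})
    return pd.DataFrame(rows).set_index("class")
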