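"""Shared data model and delimited-text I/O for regional imaging tables.

The pipeline operates on three aligned objects: a region atlas describing the
role of each region of interest (ROI), per-subject metadata carrying the
covariates that drive sample selection and w-score adjustment, and one
subjects x regions value matrix per modality (FDG-PET uptake, MRI grey-matter
volume).  Everything downstream — preprocessing, clustering, w-scores,
hypothesis-driven subtyping — consumes these objects.

All tables are comma-delimited UTF-8 text with a header row; value matrices
round-trip at full float precision (shortest-round-trip decimal repr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("corticolimbic")

MODALITIES = ("FDG", "MRI")
MATRIX_STATES = ("raw", "global-normalized", "reference-scaled", "icv-adjusted", "w-score")
PATTERN_CLASSES = ("limbic", "cortical-association", "other")
TISSUE_CLASSES = ("cortical", "subcortical")
HEMISPHERE_SCOPES = ("bilateral-merged", "left", "right")
DIAGNOSES = ("CN", "MCI", "AD")


class CohortError(ValueError):
    """Raised for structurally invalid cohort inputs (duplicates, unknown regions)."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass
class RoiAtlas:
    """Per-region metadata table, indexed by ``region_id``.

    Columns: ``region_name``, ``hemisphere_scope``, ``tissue_class``,
    ``pattern_class``, ``is_hippocampus``, ``is_reference`` and (optionally)
    ``lobe``.  The pattern class separates limbic from cortical-association
    regions, which drives both the synthetic templates and the
    hippocampus-to-cortex ratios; reference regions (pons-like) exist only
    for uptake scaling and never enter disease patterns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "region_id":
            if "region_id" in t.columns:
                t = t.set_index("region_id")
            else:
                raise CohortError("atlas table must carry a region_id column or index")
        if t.index.duplicated().any():
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise CohortError(f"duplicated region_id(s) in atlas: {dups}")
        for col in ("region_name", "hemisphere_scope", "tissue_class",
                    "pattern_class", "is_hippocampus", "is_reference"):
            if col not in t.columns:
                raise CohortError(f"atlas table missing column {col!r}")
        t = t.copy()
        t["is_hippocampus"] = t["is_hippocampus"].astype(bool)
        t["is_reference"] = t["is_reference"].astype(bool)
        bad = set(t["pattern_class"]) - set(PATTERN_CLASSES)
        if bad:
            raise CohortError(f"unknown pattern_class values: {sorted(bad)}")
        bad = set(t["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise CohortError(f"unknown tissue_class values: {sorted(bad)}")
        if not t["is_hippocampus"].any():
            raise CohortError("atlas must flag at least one hippocampus region")
        if not t["is_reference"].any():
            raise CohortError("atlas must flag at least one reference region")
        if (t["is_hippocampus"] & t["is_reference"]).any():
            raise CohortError("reference regions cannot be hippocampus regions")
        if not (t["pattern_class"] == "cortical-association").any():
            raise CohortError("atlas must contain cortical-association regions")
        self.table = t

    # -- region sets ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def hippocampus_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_hippocampus"]])

    @property
    def reference_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_reference"]])

    @property
    def non_reference_ids(self) -> list[str]:
        return list(self.table.index[~self.table["is_reference"]])

    @property
    def cortical_association_ids(self) -> list[str]:
        return list(self.table.index[self.table["pattern_class"] == "cortical-association"])

    @property
    def cortical_ids(self) -> list[str]:
        """All cortical tissue regions (used for total average cortical uptake)."""
        return list(self.table.index[self.table["tissue_class"] == "cortical"])

    @property
    def limbic_ids(self) -> list[str]:
        return list(self.table.index[self.table["pattern_class"] == "limbic"])

    def pattern_ids(self, pattern_class: str) -> list[str]:
        return list(self.table.index[self.table["pattern_class"] == pattern_class])

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


# ---------------------------------------------------------------------------
# Subject metadata
# ---------------------------------------------------------------------------

REQUIRED_META = ("diagnosis", "age", "sex", "education", "apoe4_carrier", "icv", "amyloid_status")


@dataclass
class SubjectMeta:
    """Per-subject covariates and group-defining fields, indexed by subject_id.

    Required columns: diagnosis (CN/MCI/AD), age, sex (F/M), education,
    apoe4_carrier (bool), icv (mm^3), amyloid_status (positive/negative, may
    be missing).  Optional: wmh_volume, days_between_scans, plus any clinical
    variables used in group comparisons.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "subject_id":
            if "subject_id" in t.columns:
                t = t.set_index("subject_id")
            else:
                raise CohortError("metadata table must carry a subject_id column or index")
        if t.index.duplicated().any():
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise CohortError(f"duplicated subject_id(s): {dups}")
        missing = [c for c in REQUIRED_META if c not in t.columns]
        if missing:
            raise CohortError(f"metadata missing column(s): {missing}")
        t = t.copy()
        t["apoe4_carrier"] = t["apoe4_carrier"].astype(bool)
        for col in ("age", "education", "icv"):
            vals = pd.to_numeric(t[col])
            if (vals <= 0).any():
                bad = list(t.index[vals <= 0])
                raise CohortError(f"{col} must be strictly positive; offending subjects: {bad}")
            t[col] = vals
        bad = set(t["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise CohortError(f"unknown diagnosis values: {sorted(bad)}")
        self.table = t

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, ids: Iterable[str]) -> "SubjectMeta":
        return SubjectMeta(self.table.loc[list(ids)].copy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubjectMeta":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


# ---------------------------------------------------------------------------
# ROI value matrix
# ---------------------------------------------------------------------------

@dataclass
class RoiMatrix:
    """A subjects x regions value matrix for one modality.

    ``state`` tracks the processing stage; raw matrices must be strictly
    positive, and state transitions happen only through the preprocessing and
    w-score operations (each returns a new matrix with an updated tag).
    """

    modality: str
    units: str
    state: str
    values: pd.DataFrame  # index: subject_id, columns: region_id

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise CohortError(f"unknown modality {self.modality!r}")
        if self.state not in MATRIX_STATES:
            raise CohortError(f"unknown matrix state {self.state!r}")
        v = self.values
        if v.isna().any().any():
            raise CohortError("ROI matrix contains missing values")
        if self.state == "raw" and (v.to_numpy() <= 0).any():
            raise CohortError("raw ROI values must be strictly positive")
        if v.index.name != "subject_id":
            self.values = v.rename_axis(index="subject_id")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    def evolve(self, values: pd.DataFrame, *, units: str | None = None,
               state: str | None = None) -> "RoiMatrix":
        """Return a new matrix in a new processing state (same modality)."""
        return RoiMatrix(
            modality=self.modality,
            units=self.units if units is None else units,
            state=self.state if state is None else state,
            values=values,
        )

    def subset(self, ids: Iterable[str]) -> "RoiMatrix":
        return replace(self, values=self.values.loc[list(ids)].copy())


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _load_matrix(path: str | Path, modality: str, units: str, atlas: RoiAtlas) -> RoiMatrix:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise CohortError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
        raise CohortError(f"{path}: duplicated subject_id(s): {dups}")
    df = df.set_index("subject_id")
    unknown = [c for c in df.columns if c not in set(atlas.ids)]
    if unknown:
        raise CohortError(f"{path}: region(s) not in atlas: {unknown}")
    missing = [r for r in atlas.ids if r not in df.columns]
    if missing:
        raise CohortError(f"{path}: atlas region(s) missing from matrix: {missing}")
    return RoiMatrix(modality=modality, units=units, state="raw",
                     values=df[atlas.ids].astype(float))


def read_cohort(meta_path: str | Path, fdg_path: str | Path, mri_path: str | Path,
                atlas_path: str | Path) -> tuple[SubjectMeta, RoiMatrix, RoiMatrix, RoiAtlas]:
    """Load and align a cohort from four CSV tables.

    Matrices are row-aligned to the metadata order and column-aligned to the
    atlas.  Subjects present in the metadata but missing from a modality's
    matrix are logged and dropped from that modality; duplicated subject ids
    or regions unknown to the atlas are hard errors.
    """
    atlas = RoiAtlas.from_csv(atlas_path)
    meta = SubjectMeta.from_csv(meta_path)
    out: list[RoiMatrix] = []
    for path, modality, units in ((fdg_path, "FDG", "SUVR"), (mri_path, "MRI", "mm^3")):
        mat = _load_matrix(path, modality, units, atlas)
        extra = [s for s in mat.subjects if s not in set(meta.ids)]
        if extra:
            logger.warning("%s: dropping %d subject(s) absent from metadata: %s",
                           path, len(extra), extra)
        keep = [s for s in meta.ids if s in set(mat.subjects)]
        dropped = [s for s in meta.ids if s not in set(mat.subjects)]
        if dropped:
            logger.warning("%s: %d subject(s) in metadata have no %s row and are dropped "
                           "from that modality: %s", path, len(dropped), modality, dropped)
        out.append(mat.subset(keep))
    return meta, out[0], out[1], atlas


def write_cohort(outdir: str | Path, meta: SubjectMeta, fdg: RoiMatrix, mri: RoiMatrix,
                 atlas: RoiAtlas, truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write a cohort as CSV tables under ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "meta": outdir / "subjects.csv",
        "fdg": outdir / "fdg_suvr.csv",
        "mri": outdir / "mri_volumes.csv",
        "atlas": outdir / "atlas.csv",
    }
    meta.to_csv(paths["meta"])
    fdg.values.to_csv(paths["fdg"])
    mri.values.to_csv(paths["mri"])
    atlas.to_csv(paths["atlas"])
    if truth is not None:
        paths["truth"] = outdir / "truth_labels.csv"
        truth.to_csv(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Analysis-sample selection
# ---------------------------------------------------------------------------

@dataclass
class SamplePartition:
    """Exhaustive, disjoint partition of a cohort into analysis groups.

    AD and MCI subjects enter only if amyloid positive; controls only if
    amyloid negative; everything else (including missing amyloid status) is
    excluded with a recorded reason.
    """

    ad_abeta_pos: list[str]
    mci_abeta_pos: list[str]
    cn_abeta_neg: list[str]
    excluded: list[str]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "AD_abeta_pos": len(self.ad_abeta_pos),
            "MCI_abeta_pos": len(self.mci_abeta_pos),
            "CN_abeta_neg": len(self.cn_abeta_neg),
            "excluded": len(self.excluded),
        }

    def as_series(self) -> pd.Series:
        labels = {}
        for sid in self.ad_abeta_pos:
            labels[sid] = "AD_abeta_pos"
        for sid in self.mci_abeta_pos:
            labels[sid] = "MCI_abeta_pos"
        for sid in self.cn_abeta_neg:
            labels[sid] = "CN_abeta_neg"
        for sid in self.excluded:
            labels[sid] = "excluded"
        return pd.Series(labels, name="analysis_group")


def select_analysis_sample(meta: SubjectMeta) -> SamplePartition:
    """Partition subjects into the amyloid-gated analysis groups."""
    part = SamplePartition([], [], [], [])
    for sid, row in meta.table.iterrows():
        status = row.get("amyloid_status")
        dx = row["diagnosis"]
        if not isinstance(status, str) or status not in ("positive", "negative"):
            part.excluded.append(sid)
            part.reasons[sid] = "missing amyloid_status"
            logger.warning("subject %s excluded: missing amyloid_status", sid)
            continue
        if dx == "AD" and status == "positive":
            part.ad_abeta_pos.append(sid)
        elif dx == "MCI" and status == "positive":
            part.mci_abeta_pos.append(sid)
        elif dx == "CN" and status == "negative":
            part.cn_abeta_neg.append(sid)
        else:
            part.excluded.append(sid)
            part.reasons[sid] = f"diagnosis {dx} with amyloid {status}"
    logger.info("analysis sample: %s", part.sizes)
    return part


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration.

    ``n_trees`` defaults to a desk-scale 2000; the published analyses used
    20 000 trees and 100 stability runs, reachable by configuration.
    """

    seed: int = 0
    n_trees: int = 2000
    mtry_grid: list[int] | None = None          # None -> auto grid from n_regions
    nodesize_grid: list[int] = field(default_factory=lambda: [1, 5, 10])
    n_stability_runs: int = 10
    mds_dims: int = 3
    k_range: tuple[int, int] = (2, 8)
    alpha: float = 0.05
    manual_k: int | None = None                  # override index-based k selection
    # stage toggles
    tune_hyperparameters: bool = True
    run_stability: bool = False
    proximity_oob_only: bool = False
    sqrt_dissimilarity: bool = True
    reverse_wscores: bool = True
    qc_exclude: bool = False
    qc_threshold_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mds_dims < 1:
            raise ValueError("mds_dims must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        k_lo, k_hi = self.k_range
        if k_lo < 2 or k_hi < k_lo:
            raise ValueError("k_range must satisfy 2 <= k_lo <= k_hi")
        self.k_range = (int(k_lo), int(k_hi))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: Mapping = yaml.safe_load(fh) or {}
        if "k_range" in raw:
            raw = dict(raw)
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def auto_mtry_grid(n_regions: int) -> list[int]:
    """Default mtry grid: sqrt(p), p/3 and p/2, deduplicated and clipped."""
    cand = {max(1, int(round(np.sqrt(n_regions)))),
            max(1, n_regions // 3),
            max(1, n_regions // 2)}
    return sorted(min(c, n_regions) for c in cand)
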