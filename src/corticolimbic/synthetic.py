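"""Synthetic two-modality cohorts with planted corticolimbic subtype structure.

The generator emulates the statistical structure the subtyping pipeline
assumes: a cognitively normal (CN) control group whose regional values depend
on age, sex, education, APOE e4 carriership and (for volumes) intracranial
volume, plus an Alzheimer's disease (AD) group drawn from a small set of
spatial neurodegeneration templates — limbic-predominant, cortical-predominant,
diffuse and minimal patterns — with configurable effect sizes in control-SD
units.  Subtype membership is coupled across the two modalities through a
concordance probability, so cross-modality agreement has a known ground truth.

Volumes carry additive Gaussian region noise and scale with head size (ICV);
uptake rows additionally carry a subject-level multiplicative log-normal
factor, so global-mean intensity normalization has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import RoiAtlas, RoiMatrix, SubjectMeta

__all__ = [
    "SubtypeTemplate", "GeneratorConfig", "default_atlas",
    "volume_templates", "uptake_templates", "separated_templates", "generate_cohort",
    "planted_effect_check", "simulate_study", "Cohort",
]


# ---------------------------------------------------------------------------
# Default atlas: 44 bilateral-merged regions (FreeSurfer-style names)
# ---------------------------------------------------------------------------

# (region_id, tissue_class, pattern_class, lobe, is_hippocampus, is_reference)
_ATLAS_ROWS = [
    # reference region for uptake scaling
    ("pons",                    "subcortical", "other",                "brainstem", False, True),
    # limbic / medial temporal
    ("hippocampus",             "subcortical", "limbic",               "temporal",  True,  False),
    ("amygdala",                "subcortical", "limbic",               "temporal",  False, False),
    ("entorhinal",              "cortical",    "limbic",               "temporal",  False, False),
    ("parahippocampal",         "cortical",    "limbic",               "temporal",  False, False),
    # cortical association
    ("superior_frontal",        "cortical", "cortical-association", "frontal",   False, False),
    ("rostral_middle_frontal",  "cortical", "cortical-association", "frontal",   False, False),
    ("caudal_middle_frontal",   "cortical", "cortical-association", "frontal",   False, False),
    ("pars_opercularis",        "cortical", "cortical-association", "frontal",   False, False),
    ("pars_triangularis",       "cortical", "cortical-association", "frontal",   False, False),
    ("pars_orbitalis",          "cortical", "cortical-association", "frontal",   False, False),
    ("lateral_orbitofrontal",   "cortical", "cortical-association", "frontal",   False, False),
    ("medial_orbitofrontal",    "cortical", "cortical-association", "frontal",   False, False),
    ("frontal_pole",            "cortical", "cortical-association", "frontal",   False, False),
    ("rostral_anterior_cingulate", "cortical", "cortical-association", "frontal", False, False),
    ("caudal_anterior_cingulate",  "cortical", "cortical-association", "frontal", False, False),
    ("superior_parietal",       "cortical", "cortical-association", "parietal",  False, False),
    ("inferior_parietal",       "cortical", "cortical-association", "parietal",  False, False),
    ("supramarginal",           "cortical", "cortical-association", "parietal",  False, False),
    ("precuneus",               "cortical", "cortical-association", "parietal",  False, False),
    ("posterior_cingulate",     "cortical", "cortical-association", "parietal",  False, False),
    ("isthmus_cingulate",       "cortical", "cortical-association", "parietal",  False, False),
    ("superior_temporal",       "cortical", "cortical-association", "temporal",  False, False),
    ("middle_temporal",         "cortical", "cortical-association", "temporal",  False, False),
    ("inferior_temporal",       "cortical", "cortical-association", "temporal",  False, False),
    ("fusiform",                "cortical", "cortical-association", "temporal",  False, False),
    ("banks_sts",               "cortical", "cortical-association", "temporal",  False, False),
    ("temporal_pole",           "cortical", "cortical-association", "temporal",  False, False),
    ("insula",                  "cortical", "cortical-association", "temporal",  False, False),
    ("lateral_occipital",       "cortical", "cortical-association", "occipital", False, False),
    # primary / other cortex
    ("precentral",              "cortical", "other", "frontal",   False, False),
    ("paracentral",             "cortical", "other", "frontal",   False, False),
    ("postcentral",             "cortical", "other", "parietal",  False, False),
    ("cuneus",                  "cortical", "other", "occipital", False, False),
    ("pericalcarine",           "cortical", "other", "occipital", False, False),
    ("lingual",                 "cortical", "other", "occipital", False, False),
    ("transverse_temporal",     "cortical", "other", "temporal",  False, False),
    # other subcortical
    ("thalamus",                "subcortical", "other", "subcortical", False, False),
    ("caudate",                 "subcortical", "other", "subcortical", False, False),
    ("putamen",                 "subcortical", "other", "subcortical", False, False),
    ("pallidum",                "subcortical", "other", "subcortical", False, False),
    ("accumbens",               "subcortical", "other", "subcortical", False, False),
    ("ventral_dc",              "subcortical", "other", "subcortical", False, False),
    ("cerebellum_cortex",       "subcortical", "other", "subcortical", False, False),
]


def default_atlas() -> RoiAtlas:
    """Bilateral-merged ROI atlas with limbic / cortical-association classes."""
    df = pd.DataFrame(
        _ATLAS_ROWS,
        columns=["region_id", "tissue_class", "pattern_class", "lobe",
                 "is_hippocampus", "is_reference"],
    )
    df["region_name"] = df["region_id"].str.replace("_", " ")
    df["hemisphere_scope"] = "bilateral-merged"
    return RoiAtlas(df[["region_id", "region_name", "hemisphere_scope", "tissue_class",
                        "pattern_class", "lobe", "is_hippocampus", "is_reference"]])


# ---------------------------------------------------------------------------
# Subtype templates
# ---------------------------------------------------------------------------

@dataclass
class SubtypeTemplate:
    """A planted spatial neurodegeneration pattern.

    ``region_effects`` maps keys to mean shifts in control-SD units (negative
    = neurodegeneration).  Keys are resolved in order of increasing
    specificity: ``"all"``, a pattern class (``limbic``,
    ``cortical-association``, ``other``), ``"lobe:<name>"``, then an explicit
    region id.  Reference regions are always left untouched.
    """

    name: str
    region_effects: Mapping[str, float]
    prevalence: float
    severity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.severity_scale <= 0:
            raise ValueError("severity_scale must be > 0")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")

    def effect_vector(self, atlas: RoiAtlas) -> pd.Series:
        eff = pd.Series(0.0, index=atlas.table.index)
        if "all" in self.region_effects:
            eff[:] = self.region_effects["all"]
        for cls in ("limbic", "cortical-association", "other"):
            if cls in self.region_effects:
                eff[atlas.table["pattern_class"] == cls] = self.region_effects[cls]
        for key, val in self.region_effects.items():
            if key.startswith("lobe:"):
                if "lobe" not in atlas.table.columns:
                    raise ValueError("atlas has no lobe column; cannot resolve " + key)
                eff[atlas.table["lobe"] == key[5:]] = val
        for key, val in self.region_effects.items():
            if key in atlas.table.index:
                eff[key] = val
        eff[atlas.table["is_reference"]] = 0.0
        return eff * self.severity_scale


def volume_templates() -> list[SubtypeTemplate]:
    """Atrophy-side template set: corticolimbic contrast plus a severity axis.

    Prevalences follow the published five atrophy subtypes collapsed to four
    (the two diffuse groups merged): limbic-predominant 27%, diffuse 35%,
    cortical-predominant 19%, minimal 19%.
    """
    return [
        SubtypeTemplate("Limbic Predominant",
                        {"limbic": -2.0, "cortical-association": -0.5, "other": -0.3}, 0.27),
        SubtypeTemplate("Cortical Predominant",
                        {"cortical-association": -2.0, "limbic": -0.5, "other": -0.3}, 0.19),
        SubtypeTemplate("Diffuse",
                        {"all": -1.2, "limbic": -1.5, "cortical-association": -1.5}, 0.35),
        SubtypeTemplate("Minimal", {"all": -0.2}, 0.19),
    ]


def separated_templates(effect: float = 2.4) -> list[SubtypeTemplate]:
    """Four spatially distinct broad patterns for cluster-recovery studies.

    Forest-proximity dissimilarity keys on multi-region dependence structure,
    so recoverable planted subtypes must differ over broad region sets:
    each template here carries a strong (``effect`` control-SD) signature on
    its own lobe-defined set, and every pairwise contrast spans at least a
    dozen regions.  Contrasts confined to a handful of regions (e.g. a
    hippocampus-only difference between a limbic and a minimal pattern) sit
    below the method's sensitivity regardless of their magnitude.
    """
    return [
        SubtypeTemplate("Limbic Predominant",
                        {"lobe:temporal": -effect, "limbic": -effect}, 0.30),
        SubtypeTemplate("Cortical Predominant frontal", {"lobe:frontal": -effect}, 0.25),
        SubtypeTemplate("Cortical Predominant posterior",
                        {"lobe:parietal": -effect, "lobe:occipital": -effect}, 0.25),
        SubtypeTemplate("Diffuse", {"all": -0.8 * effect}, 0.20),
    ]


def uptake_templates() -> list[SubtypeTemplate]:
    """Hypometabolism-side template set: pattern contrasts only.

    Global-mean intensity normalization removes any spatially uniform
    component of an uptake pattern, so the uptake templates differ in spatial
    contrast (limbic vs cortical, frontal vs posterior) rather than uniform
    severity.  Prevalences follow the published five hypometabolism subtypes
    collapsed to four (the two widespread cortical groups merged): limbic 36%,
    cortical 43%, limbic-frontal 13%, cortical-posterior 8%.
    """
    return [
        SubtypeTemplate("Limbic Predominant",
                        {"limbic": -2.0, "cortical-association": -0.4}, 0.36),
        SubtypeTemplate("Cortical Predominant",
                        {"cortical-association": -2.0, "limbic": -0.4}, 0.43),
        SubtypeTemplate("Limbic Predominant frontal",
                        {"limbic": -2.0, "lobe:frontal": -1.6}, 0.13),
        SubtypeTemplate("Cortical Predominant posterior",
                        {"lobe:parietal": -2.0, "lobe:occipital": -2.0, "limbic": -0.4}, 0.08),
    ]


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Cohort generator settings (defaults encode the study-scale conditions).

    Covariate effects are expressed as fractions of a region's baseline value
    per natural covariate unit (years, 0/1 indicators); ``icv_slope`` is the
    fraction of a region's volume that scales proportionally with relative
    head-size deviation.  ``concordance`` is the probability that a subject's
    planted MRI template matches (is paired with) its FDG template.
    """

    n_cn: int = 176
    n_ad: int = 180
    seed: int = 0
    concordance: float = 0.6
    # demographics (plausible ranges for an elderly AD study population)
    age_mean: float = 74.0
    age_sd: float = 7.0
    education_mean: float = 16.0
    education_sd: float = 3.0
    female_rate: float = 0.46
    apoe4_rate_cn: float = 0.2
    apoe4_rate_ad: float = 0.7
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    # covariate effect sizes (fraction of baseline per unit)
    age_frac_mri: float = -0.004
    age_frac_fdg: float = -0.002
    sex_frac_mri: float = 0.03       # male offset beyond head size
    sex_frac_fdg: float = -0.01
    education_frac_mri: float = 0.0
    education_frac_fdg: float = 0.002
    apoe4_frac_mri: float = -0.01
    apoe4_frac_fdg: float = -0.01
    icv_slope: float = 0.6
    # noise
    residual_sd_mri: float = 0.06    # fraction of baseline, additive
    residual_sd_fdg: float = 0.08
    global_scale_sd: float = 0.1     # log-SD of subject-level uptake multiplier

    def __post_init__(self) -> None:
        if self.n_cn < 0 or self.n_ad < 0:
            raise ValueError("cohort counts must be >= 0")
        if not (0.0 <= self.concordance <= 1.0):
            raise ValueError("concordance must lie in [0, 1]")
        for name in ("residual_sd_mri", "residual_sd_fdg", "global_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _region_baselines(atlas: RoiAtlas) -> tuple[pd.Series, pd.Series]:
    """Deterministic per-region baseline volumes (mm^3) and uptake values.

    Drawn once from a fixed generator so baselines depend only on the atlas
    (not on the cohort seed); magnitudes sit in realistic FreeSurfer / SUVR
    ranges (hippocampus ~3.5 cm^3, cortical ROIs 2-25 cm^3, uptake ~5-7).
    """
    rng = np.random.default_rng(20240826)
    t = atlas.table
    vol = pd.Series(0.0, index=t.index)
    upt = pd.Series(0.0, index=t.index)
    for rid, row in t.iterrows():
        if row["is_reference"]:
            vol[rid] = 14000.0
            upt[rid] = 5.0 * rng.uniform(0.97, 1.03)
        elif row["is_hippocampus"]:
            vol[rid] = 3500.0 * rng.uniform(0.95, 1.05)
            upt[rid] = 5.5 * rng.uniform(0.95, 1.05)
        elif row["tissue_class"] == "subcortical":
            vol[rid] = rng.uniform(1200.0, 8000.0)
            upt[rid] = rng.uniform(5.0, 6.5)
        else:
            vol[rid] = rng.uniform(3000.0, 25000.0)
            upt[rid] = rng.uniform(6.0, 7.5)
    return vol, upt


@dataclass
class Cohort:
    """Bundle returned by :func:`simulate_study`."""

    meta: SubjectMeta
    fdg: RoiMatrix
    mri: RoiMatrix
    atlas: RoiAtlas
    truth: pd.DataFrame  # columns: template_fdg, template_mri
    config: GeneratorConfig
    templates_fdg: list[SubtypeTemplate] = field(default_factory=list)
    templates_mri: list[SubtypeTemplate] = field(default_factory=list)


def _draw_meta(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cn + cfg.n_ad
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    dx = ["CN"] * cfg.n_cn + ["AD"] * cfg.n_ad
    apoe_rate = np.where(np.asarray(dx) == "AD", cfg.apoe4_rate_ad, cfg.apoe4_rate_cn)
    meta = pd.DataFrame({
        "subject_id": ids,
        "diagnosis": dx,
        "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 50.0, 95.0),
        "sex": np.where(rng.random(n) < cfg.female_rate, "F", "M"),
        "education": np.clip(rng.normal(cfg.education_mean, cfg.education_sd, n), 6.0, 24.0),
        "apoe4_carrier": rng.random(n) < apoe_rate,
        "icv": np.clip(rng.normal(cfg.icv_mean, cfg.icv_sd, n), 9e5, 2.2e6),
        "amyloid_status": np.where(np.asarray(dx) == "AD", "positive", "negative"),
    })
    return meta.set_index("subject_id")


def generate_cohort(cfg: GeneratorConfig,
                    templates_fdg: Sequence[SubtypeTemplate],
                    templates_mri: Sequence[SubtypeTemplate],
                    atlas: RoiAtlas,
                    ) -> tuple[SubjectMeta, RoiMatrix, RoiMatrix, pd.DataFrame]:
    """Generate an aligned synthetic cohort with planted subtype structure.

    CN values = baseline * (1 + covariate effects) [+ ICV term for volumes]
    + region noise; AD subjects additionally receive their template's mean
    shift, expressed in empirical CN-SD units per region.  The FDG template is
    drawn by prevalence; the MRI template is the position-paired template with
    probability ``concordance`` and an independent prevalence-weighted redraw
    otherwise.  Fully reproducible from ``cfg.seed``.
    """
    for tset, label in ((templates_fdg, "FDG"), (templates_mri, "MRI")):
        total = sum(t.prevalence for t in tset)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"{label} template prevalences must sum to 1 (got {total})")
    if not atlas.limbic_ids or not atlas.cortical_association_ids:
        raise ValueError("degenerate atlas: needs limbic and cortical-association regions")

    rng = np.random.default_rng(cfg.seed)
    meta_df = _draw_meta(cfg, rng)
    is_ad = (meta_df["diagnosis"] == "AD").to_numpy()
    n, p = len(meta_df), atlas.n_regions

    base_vol, base_upt = _region_baselines(atlas)
    age_c = (meta_df["age"] - cfg.age_mean).to_numpy()[:, None]
    male = (meta_df["sex"] == "M").to_numpy(float)[:, None]
    edu_c = (meta_df["education"] - cfg.education_mean).to_numpy()[:, None]
    apoe = meta_df["apoe4_carrier"].to_numpy(float)[:, None]
    icv_rel = ((meta_df["icv"] - cfg.icv_mean) / cfg.icv_mean).to_numpy()[:, None]

    vol_mean = base_vol.to_numpy()[None, :] * (
        1.0
        + cfg.age_frac_mri * age_c
        + cfg.sex_frac_mri * male
        + cfg.education_frac_mri * edu_c
        + cfg.apoe4_frac_mri * apoe
        + cfg.icv_slope * icv_rel
    )
    upt_mean = base_upt.to_numpy()[None, :] * (
        1.0
        + cfg.age_frac_fdg * age_c
        + cfg.sex_frac_fdg * male
        + cfg.education_frac_fdg * edu_c
        + cfg.apoe4_frac_fdg * apoe
    )

    vol = vol_mean + rng.normal(0.0, 1.0, (n, p)) * (cfg.residual_sd_mri * base_vol.to_numpy())
    upt = upt_mean + rng.normal(0.0, 1.0, (n, p)) * (cfg.residual_sd_fdg * base_upt.to_numpy())

    # empirical CN SD per region defines the unit of the planted effects
    cn_sd_vol = vol[~is_ad].std(axis=0, ddof=1) if (~is_ad).sum() >= 2 else \
        cfg.residual_sd_mri * base_vol.to_numpy()
    cn_sd_upt = upt[~is_ad].std(axis=0, ddof=1) if (~is_ad).sum() >= 2 else \
        cfg.residual_sd_fdg * base_upt.to_numpy()

    # planted template membership, coupled across modalities by position
    prev_fdg = np.array([t.prevalence for t in templates_fdg])
    prev_mri = np.array([t.prevalence for t in templates_mri])
    idx_fdg = rng.choice(len(templates_fdg), size=int(is_ad.sum()), p=prev_fdg)
    redraw = rng.random(int(is_ad.sum())) >= cfg.concordance
    idx_mri = idx_fdg.copy()
    if len(templates_mri) != len(templates_fdg):
        raise ValueError("template lists must have equal length for position pairing")
    idx_mri[redraw] = rng.choice(len(templates_mri), size=int(redraw.sum()), p=prev_mri)

    eff_fdg = np.stack([t.effect_vector(atlas).to_numpy() for t in templates_fdg])
    eff_mri = np.stack([t.effect_vector(atlas).to_numpy() for t in templates_mri])
    vol[is_ad] += eff_mri[idx_mri] * cn_sd_vol
    upt[is_ad] += eff_fdg[idx_fdg] * cn_sd_upt

    # subject-level multiplicative uptake factor (scanner/global metabolism)
    upt *= np.exp(rng.normal(0.0, cfg.global_scale_sd, n))[:, None]

    vol = np.clip(vol, 1.0, None)
    upt = np.clip(upt, 1e-3, None)

    truth = pd.DataFrame(index=meta_df.index,
                         data={"template_fdg": "CN", "template_mri": "CN"})
    truth.loc[is_ad, "template_fdg"] = [templates_fdg[i].name for i in idx_fdg]
    truth.loc[is_ad, "template_mri"] = [templates_mri[i].name for i in idx_mri]

    meta = SubjectMeta(meta_df)
    fdg = RoiMatrix("FDG", "SUVR", "raw",
                    pd.DataFrame(upt, index=meta_df.index, columns=atlas.ids))
    mri = RoiMatrix("MRI", "mm^3", "raw",
                    pd.DataFrame(vol, index=meta_df.index, columns=atlas.ids))
    return meta, fdg, mri, truth


def simulate_study(seed: int = 0, *, config: GeneratorConfig | None = None,
                   atlas: RoiAtlas | None = None,
                   templates_fdg: Sequence[SubtypeTemplate] | None = None,
                   templates_mri: Sequence[SubtypeTemplate] | None = None) -> Cohort:
    """One-call generation of a full study cohort with default conditions."""
    cfg = config if config is not None else GeneratorConfig(seed=seed)
    if config is None:
        cfg.seed = seed
    atlas = atlas if atlas is not None else default_atlas()
    tf = list(templates_fdg) if templates_fdg is not None else uptake_templates()
    tm = list(templates_mri) if templates_mri is not None else volume_templates()
    meta, fdg, mri, truth = generate_cohort(cfg, tf, tm, atlas)
    return Cohort(meta=meta, fdg=fdg, mri=mri, atlas=atlas, truth=truth,
                  config=cfg, templates_fdg=tf, templates_mri=tm)


def planted_effect_check(raw: RoiMatrix, truth: pd.DataFrame, meta: SubjectMeta,
                         atlas: RoiAtlas, template_name: str) -> pd.Series:
    """Realized per-region effect sizes: (template mean - CN mean) / CN SD.

    Used by tests to confirm the generator honours its region effects.
    """
    col = "template_fdg" if raw.modality == "FDG" else "template_mri"
    cn_ids = [s for s in meta.ids if meta.table.loc[s, "diagnosis"] == "CN"]
    grp_ids = [s for s in truth.index if truth.loc[s, col] == template_name]
    if len(cn_ids) < 2 or len(grp_ids) < 2:
        raise ValueError("need >= 2 subjects in both compared groups")
    cn = raw.values.loc[cn_ids]
    grp = raw.values.loc[grp_ids]
    return (grp.mean(axis=0) - cn.mean(axis=0)) / cn.std(axis=0, ddof=1)
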