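"""Hippocampus-to-cortex classifier, typicality/severity axes, agreement."""

import numpy as np
import pandas as pd
import pytest

import corticolimbic as cl
from corticolimbic.hypothesis import LABEL_CP, LABEL_LP, LABEL_TYPICAL

import _oracles
from conftest import make_matrix


def monotone_cohort(tiny_atlas, n=16):
    """Hippocampal values rise, cortical fall: ratio strictly increasing."""
    hip = np.linspace(2.0, 6.0, n)
    ctx = np.linspace(30.0, 20.0, n)
    vals = np.column_stack([hip, ctx, ctx, np.full(n, 5.0), np.full(n, 5.0)])
    return make_matrix(vals, tiny_atlas.ids, state="icv-adjusted")


def reference_two_step(ratio, hip, ctx):
    """Independent enumeration of the stated two-step rule."""
    q25, q75 = np.percentile(ratio, [25, 75])
    med_h, med_c = np.median(hip), np.median(ctx)
    out = []
    for r, h, c in zip(ratio, hip, ctx):
        if r < q25 and h < med_h and c > med_c:
            out.append(LABEL_LP)
        elif r > q75 and h > med_h and c < med_c:
            out.append(LABEL_CP)
        else:
            out.append(LABEL_TYPICAL)
    return out


class TestRatio:
    def test_direct_division(self, tiny_atlas):
        vals = np.array([[4.0, 22.0, 18.0, 1.0, 1.0]])
        m = make_matrix(vals, tiny_atlas.ids, state="icv-adjusted")
        assert cl.hippocampus_cortex_ratio(m, tiny_atlas).iloc[0] == pytest.approx(0.2)

    def test_equal_means_give_unity(self, tiny_atlas):
        vals = np.array([[7.0, 7.0, 7.0, 1.0, 1.0]])
        m = make_matrix(vals, tiny_atlas.ids, state="icv-adjusted")
        assert cl.hippocampus_cortex_ratio(m, tiny_atlas).iloc[0] == pytest.approx(1.0)

    def test_volume_ratio_in_plausible_band(self, small_cohort):
        """AD hippocampus-to-cortex volume ratios should sit near published means."""
        part = cl.select_analysis_sample(small_cohort.meta)
        icv = cl.fit_icv_model(small_cohort.mri.subset(part.cn_abeta_neg),
                               small_cohort.meta)
        adj = cl.apply_icv_adjustment(small_cohort.mri, small_cohort.meta, icv)
        ratio = cl.hippocampus_cortex_ratio(adj.subset(part.ad_abeta_pos),
                                            small_cohort.atlas)
        assert 0.05 < ratio.mean() < 0.6


class TestTwoStepClassifier:
    def test_monotone_cohort_matches_enumeration(self, tiny_atlas):
        m = monotone_cohort(tiny_atlas)
        res = cl.classify_hypothesis_driven(m, tiny_atlas)
        expected = reference_two_step(res.ratio.to_numpy(),
                                      res.hippocampal_composite.to_numpy(),
                                      res.cortical_composite.to_numpy())
        assert list(res.labels) == expected
        assert expected[:4] == [LABEL_LP] * 4
        assert expected[-4:] == [LABEL_CP] * 4
        assert set(expected[4:-4]) == {LABEL_TYPICAL}

    def test_identical_subjects_all_typical(self, tiny_atlas):
        vals = np.tile([3.0, 20.0, 22.0, 5.0, 5.0], (10, 1))
        m = make_matrix(vals, tiny_atlas.ids, state="icv-adjusted")
        res = cl.classify_hypothesis_driven(m, tiny_atlas)
        assert (res.labels == LABEL_TYPICAL).all()

    def test_step_two_veto_reverts_to_typical(self, tiny_atlas):
        m = monotone_cohort(tiny_atlas)
        vals = m.values.copy()
        # lowest-ratio subject, but hippocampal composite pushed above the median
        vals.loc["S0", "hip"] = 5.9
        vals.loc["S0", "ctx_a"] = vals.loc["S0", "ctx_a"] * 3.2
        vals.loc["S0", "ctx_b"] = vals.loc["S0", "ctx_b"] * 3.2
        m2 = cl.RoiMatrix("MRI", "mm^3", "icv-adjusted", vals)
        res = cl.classify_hypothesis_driven(m2, tiny_atlas)
        assert res.ratio["S0"] < res.thresholds["ratio_q25"]
        assert res.labels["S0"] == LABEL_TYPICAL

    def test_scale_invariance(self, tiny_atlas):
        m = monotone_cohort(tiny_atlas)
        scaled = cl.RoiMatrix("MRI", "mm^3", "icv-adjusted", m.values * 7.0)
        a = cl.classify_hypothesis_driven(m, tiny_atlas)
        b = cl.classify_hypothesis_driven(scaled, tiny_atlas)
        assert list(a.labels) == list(b.labels)

    def test_labels_partition_sample(self, tiny_atlas):
        m = monotone_cohort(tiny_atlas, n=23)
        res = cl.classify_hypothesis_driven(m, tiny_atlas)
        assert len(res.labels) == 23
        assert res.labels.isin([LABEL_LP, LABEL_CP, LABEL_TYPICAL]).all()

    def test_small_sample_rejected(self, tiny_atlas):
        m = monotone_cohort(tiny_atlas, n=7)
        with pytest.raises(ValueError, match="quartiles"):
            cl.classify_hypothesis_driven(m, tiny_atlas)

    def test_planted_templates_enrich_matching_classes(self, atlas):
        from corticolimbic.synthetic import SubtypeTemplate
        tm = [
            SubtypeTemplate("limbic", {"limbic": -2.0, "cortical-association": -0.5}, 0.5),
            SubtypeTemplate("cortical", {"cortical-association": -2.0, "limbic": -0.5}, 0.5),
        ]
        hits = 0
        for seed in range(5):
            cfg = cl.GeneratorConfig(n_cn=100, n_ad=120, seed=seed)
            meta, _, mri, truth = cl.generate_cohort(cfg, tm, tm, atlas)
            part = cl.select_analysis_sample(meta)
            icv = cl.fit_icv_model(mri.subset(part.cn_abeta_neg), meta)
            adj = cl.apply_icv_adjustment(mri, meta, icv).subset(part.ad_abeta_pos)
            res = cl.classify_hypothesis_driven(adj, atlas)
            t = truth.loc[part.ad_abeta_pos, "template_mri"]
            lp_in_limbic = ((res.labels == LABEL_LP) & (t == "limbic")).sum()
            lp_in_cortical = ((res.labels == LABEL_LP) & (t == "cortical")).sum()
            cp_in_cortical = ((res.labels == LABEL_CP) & (t == "cortical")).sum()
            cp_in_limbic = ((res.labels == LABEL_CP) & (t == "limbic")).sum()
            if lp_in_limbic > lp_in_cortical and cp_in_cortical > cp_in_limbic:
                hits += 1
        assert hits >= 4


class TestAxes:
    @pytest.fixture()
    def coords(self, small_cohort):
        part = cl.select_analysis_sample(small_cohort.meta)
        fdg = cl.normalize_global_mean(small_cohort.fdg, small_cohort.atlas)
        icv = cl.fit_icv_model(small_cohort.mri.subset(part.cn_abeta_neg),
                               small_cohort.meta)
        mri = cl.apply_icv_adjustment(small_cohort.mri, small_cohort.meta, icv)
        return cl.compute_axes(fdg, mri, small_cohort.atlas, part.ad_abeta_pos)

    def test_normalized_values_span_unit_interval(self, coords):
        for frame in (coords.fdg, coords.mri):
            for col in ("normalized_typicality", "normalized_severity"):
                assert frame[col].min() == pytest.approx(0.0)
                assert frame[col].max() == pytest.approx(1.0)
                assert frame[col].between(0, 1).all()

    def test_severity_reversed_lowest_volume_scores_one(self, coords):
        worst = coords.mri["severity"].idxmin()
        assert coords.mri.loc[worst, "normalized_severity"] == pytest.approx(1.0)

    def test_two_subjects_forced_endpoints(self, small_cohort):
        part = cl.select_analysis_sample(small_cohort.meta)
        ids = part.ad_abeta_pos[:2]
        fdg = cl.normalize_global_mean(small_cohort.fdg, small_cohort.atlas)
        icv = cl.fit_icv_model(small_cohort.mri.subset(part.cn_abeta_neg),
                               small_cohort.meta)
        mri = cl.apply_icv_adjustment(small_cohort.mri, small_cohort.meta, icv)
        coords = cl.compute_axes(fdg, mri, small_cohort.atlas, ids)
        assert sorted(coords.mri["normalized_severity"]) == [0.0, 1.0]

    def test_single_subject_rejected(self, small_cohort):
        part = cl.select_analysis_sample(small_cohort.meta)
        fdg = cl.normalize_global_mean(small_cohort.fdg, small_cohort.atlas)
        with pytest.raises(ValueError):
            cl.compute_axes(fdg, small_cohort.mri, small_cohort.atlas,
                            part.ad_abeta_pos[:1])

    def test_axis_summary_means_in_unit_interval(self, coords):
        labels = pd.Series("A", index=coords.mri.index)
        labels.iloc[: len(labels) // 2] = "B"
        out = cl.subtype_axis_summary(coords.mri, labels)
        assert out["mean_normalized_typicality"].between(0, 1).all()
        assert out["mean_normalized_severity"].between(0, 1).all()
        whole = cl.subtype_axis_summary(coords.mri, pd.Series("all", index=coords.mri.index))
        assert whole["mean_normalized_typicality"].iloc[0] == pytest.approx(
            coords.mri["normalized_typicality"].mean())


class TestCorrelations:
    def test_identical_vectors_unit_correlation(self):
        idx = [f"S{i}" for i in range(10)]
        x = pd.DataFrame({"typicality": np.arange(10.0), "severity": np.arange(10.0)},
                         index=idx)
        out = cl.axis_correlations(x, x)
        assert out.loc["FDG typicality vs FDG severity", "r"] == pytest.approx(1.0)
        assert out.loc["FDG typicality vs FDG severity", "r_squared"] == pytest.approx(1.0)

    def test_five_point_hand_oracle(self):
        idx = list("abcde")
        typ = np.array([0.2, 0.5, 0.1, 0.9, 0.4])
        sev = np.array([1.0, 3.0, 0.5, 4.0, 2.0])
        fdg = pd.DataFrame({"typicality": typ, "severity": sev}, index=idx)
        mri = pd.DataFrame({"typicality": sev[::-1], "severity": typ[::-1]}, index=idx)
        out = cl.axis_correlations(fdg, mri)
        assert out.loc["FDG typicality vs FDG severity", "r"] == pytest.approx(
            _oracles.pearson_r(typ, sev))

    def test_independent_measures_near_zero_r2(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(500)]
        fdg = pd.DataFrame({"typicality": rng.normal(size=500),
                            "severity": rng.normal(size=500)}, index=idx)
        mri = pd.DataFrame({"typicality": rng.normal(size=500),
                            "severity": rng.normal(size=500)}, index=idx)
        out = cl.axis_correlations(fdg, mri)
        assert (out["r_squared"] < 0.02).all()

    def test_zero_variance_reported_missing(self):
        idx = list("abcd")
        fdg = pd.DataFrame({"typicality": [1.0] * 4, "severity": range(4)}, index=idx)
        mri = pd.DataFrame({"typicality": range(4), "severity": range(4)}, index=idx)
        out = cl.axis_correlations(fdg, mri)
        assert np.isnan(out.loc["FDG typicality vs FDG severity", "r"])


class TestMethodAgreement:
    EQUIV = {LABEL_LP: "limbic", LABEL_CP: "cortical", LABEL_TYPICAL: "other"}

    def test_identical_labels_full_agreement(self):
        labels = pd.Series([LABEL_LP] * 4 + [LABEL_CP] * 4 + [LABEL_TYPICAL] * 2,
                           index=[f"S{i}" for i in range(10)])
        out = cl.method_agreement(labels, labels, self.EQUIV)
        assert (out["agreement_pct"] == 100.0).all()

    def test_disjoint_labels_zero_agreement(self):
        idx = [f"S{i}" for i in range(6)]
        dd = pd.Series([LABEL_LP] * 3 + [LABEL_CP] * 3, index=idx)
        hy = pd.Series([LABEL_CP] * 3 + [LABEL_LP] * 3, index=idx)
        out = cl.method_agreement(dd, hy, self.EQUIV)
        assert out.loc["limbic", "agreement_pct"] == 0.0
        assert out.loc["cortical", "agreement_pct"] == 0.0

    def test_constructed_partial_overlap(self):
        idx = [f"S{i}" for i in range(10)]
        dd = pd.Series([LABEL_LP] * 8 + [LABEL_CP] * 2, index=idx)
        hy = pd.Series([LABEL_LP] * 6 + [LABEL_TYPICAL] * 2 + [LABEL_CP] * 2, index=idx)
        out = cl.method_agreement(dd, hy, self.EQUIV)
        assert out.loc["limbic", "agreement_pct"] == pytest.approx(75.0)
        assert out.loc["cortical", "agreement_pct"] == pytest.approx(100.0)

    def test_absent_class_reported_missing(self):
        idx = list("abc")
        dd = pd.Series([LABEL_TYPICAL] * 3, index=idx)
        hy = pd.Series([LABEL_LP] * 3, index=idx)
        out = cl.method_agreement(dd, hy, self.EQUIV)
        assert np.isnan(out.loc["limbic", "agreement_pct"])
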