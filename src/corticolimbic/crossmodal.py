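"""Cross-modality subtype crossover and group-comparison statistics.

Subtype allocations from the two modalities are compared at the individual
level through a contingency ("crossover") table with row-normalized
percentages and an alluvial edge list, plus an overall agreement percentage
after mapping modality-specific subtype names to shared corticolimbic
classes.  Demographic and clinical variables are compared across subtypes
with chi-squared tests (categorical) and Kruskal-Wallis tests (continuous),
family-wise adjusted by the Holm-Sidak step-down procedure; post hoc
pairwise tests run only where the omnibus survives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import SubjectMeta

logger = logging.getLogger("corticolimbic")


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------

@dataclass
class CrossoverTable:
    """FDG (rows) x MRI (columns) subtype contingency with percentages."""

    counts: pd.DataFrame
    percentages: pd.DataFrame      # row-normalized, sums to 100 per row
    edges: pd.DataFrame            # columns: fdg_label, mri_label, count

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def crossover(fdg_labels: pd.Series, mri_labels: pd.Series) -> CrossoverTable:
    """Contingency counts and row percentages over the paired subject set."""
    common = fdg_labels.index.intersection(mri_labels.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between the two label sets")
    f = fdg_labels.loc[common]
    m = mri_labels.loc[common]
    counts = pd.crosstab(f, m)
    counts.index.name, counts.columns.name = "fdg_subtype", "mri_subtype"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    edges = counts.stack().reset_index(name="count")
    edges.columns = ["fdg_label", "mri_label", "count"]
    edges = edges[edges["count"] > 0].reset_index(drop=True)
    return CrossoverTable(counts=counts, percentages=pct, edges=edges)


def overall_agreement(fdg_labels: pd.Series, mri_labels: pd.Series,
                      equivalence_map: dict[str, str]) -> float:
    """Percentage of paired subjects whose mapped classes coincide."""
    common = fdg_labels.index.intersection(mri_labels.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between the two label sets")

    def mapped(series: pd.Series) -> pd.Series:
        out = {}
        for sid, lab in series.loc[common].items():
            if lab not in equivalence_map:
                raise ValueError(f"label {lab!r} missing from equivalence map")
            out[sid] = equivalence_map[lab]
        return pd.Series(out)

    f, m = mapped(fdg_labels), mapped(mri_labels)
    return float((f == m).mean() * 100.0)


# ---------------------------------------------------------------------------
# Holm-Sidak adjustment
# ---------------------------------------------------------------------------

def holm_sidak(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values.

    Order raw p ascending; adjusted_i = max_{j<=i} 1 - (1 - p_j)^(m - j + 1),
    capped at 1, returned in the original order.
    """
    p = np.asarray(pvals, float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonTable:
    """Omnibus and post hoc test results across subtype groups."""

    table: pd.DataFrame        # per variable: test, statistic, p_raw, p_adjusted, flag
    posthoc: pd.DataFrame      # pairwise results for significant variables
    alpha: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def group_compare(data: pd.DataFrame, labels: pd.Series,
                  variables: dict[str, str], alpha: float = 0.05) -> GroupComparisonTable:
    """Compare variables across label groups with a Holm-Sidak family.

    ``variables`` maps column names in ``data`` to "categorical" or
    "continuous".  Categorical variables get a chi-squared test on the
    contingency table; continuous ones a Kruskal-Wallis test.  All raw
    p-values form one Holm-Sidak family; post hoc pairwise tests (pairwise
    Kruskal-Wallis / chi-squared with their own Holm-Sidak family per
    variable) run only where the omnibus adjusted p < alpha.
    """
    common = data.index.intersection(labels.index)
    labels = labels.loc[common]
    data = data.loc[common]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    rows = []
    for var, kind in variables.items():
        x = data[var]
        mask = x.notna()
        flag = ""
        try:
            if kind == "categorical":
                tab = pd.crosstab(x[mask], labels[mask])
                stat, p, _, expected = stats.chi2_contingency(tab)
                if (expected < 1).any():
                    flag = "low expected counts"
                    logger.warning("group_compare: %s has expected cell counts < 1", var)
                test = "chi2"
            elif kind == "continuous":
                samples = [x[mask][labels[mask] == g].to_numpy(float) for g in groups]
                samples = [s for s in samples if len(s) > 0]
                stat, p = stats.kruskal(*samples)
                test = "kruskal-wallis"
            else:
                raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        except ValueError as exc:  # degenerate contingency/constant data
            logger.warning("group_compare: %s test failed (%s)", var, exc)
            stat, p, test, flag = np.nan, np.nan, kind, f"test failed: {exc}"
        rows.append({"variable": var, "type": kind, "test": test,
                     "statistic": stat, "p_raw": p, "flag": flag})
    table = pd.DataFrame(rows).set_index("variable")

    valid = table["p_raw"].notna()
    adj = pd.Series(np.nan, index=table.index)
    if valid.any():
        adj[valid] = holm_sidak(table.loc[valid, "p_raw"].to_numpy())
    table["p_adjusted"] = adj

    posthoc_rows = []
    for var in table.index[valid & (table["p_adjusted"] < alpha)]:
        kind = variables[var]
        x = data[var]
        mask = x.notna()
        pair_p, pair_names = [], []
        for g1, g2 in itertools.combinations(groups, 2):
            try:
                if kind == "continuous":
                    a = x[mask][labels[mask] == g1].to_numpy(float)
                    b = x[mask][labels[mask] == g2].to_numpy(float)
                    if len(a) == 0 or len(b) == 0:
                        continue
                    _, p = stats.kruskal(a, b)
                else:
                    sub = labels[mask].isin([g1, g2])
                    tab = pd.crosstab(x[mask][sub], labels[mask][sub])
                    if tab.shape[0] < 2 or tab.shape[1] < 2:
                        continue
                    _, p, _, _ = stats.chi2_contingency(tab)
            except ValueError:
                continue
            pair_p.append(p)
            pair_names.append((g1, g2))
        if pair_p:
            adj_p = holm_sidak(pair_p)
            for (g1, g2), p, ap in zip(pair_names, pair_p, adj_p):
                posthoc_rows.append({"variable": var, "group_1": g1, "group_2": g2,
                                     "p_raw": p, "p_adjusted": ap,
                                     "significant": ap < alpha})
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["variable", "group_1", "group_2", "p_raw", "p_adjusted", "significant"])
    sizes = labels.value_counts().to_dict()
    return GroupComparisonTable(table=table, posthoc=posthoc, alpha=alpha,
                                group_sizes={str(k): int(v) for k, v in sizes.items()})


# ---------------------------------------------------------------------------
# Demographics summary
# ---------------------------------------------------------------------------

def demographics_table(meta: SubjectMeta | pd.DataFrame, labels: pd.Series,
                       variables: dict[str, str],
                       reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subtype summary: n (%), mean (SD) or count (%) per variable.

    Continuous variables report "mean (sd)" with the sample SD (n-1); binary
    or categorical variables report "count (pct%)" of the modal/true level.
    An optional control reference sample is appended as its own column.
    """
    data = meta.table if isinstance(meta, SubjectMeta) else meta
    common = data.index.intersection(labels.index)
    data, labels = data.loc[common], labels.loc[common]
    groups = sorted(labels.unique())
    total = len(common)

    def summarize(sub: pd.DataFrame) -> dict[str, str]:
        out = {}
        for var, kind in variables.items():
            x = sub[var].dropna()
            if kind == "continuous":
                if len(x) == 0:
                    out[var] = "-"
                else:
                    sd = x.std(ddof=1) if len(x) > 1 else 0.0
                    out[var] = f"{x.mean():.3g} ({sd:.3g})"
            else:
                if x.dtype == bool or set(x.unique()) <= {0, 1, True, False}:
                    cnt = int(x.astype(bool).sum())
                else:
                    top = x.mode().iloc[0]
                    cnt = int((x == top).sum())
                pct = 100.0 * cnt / len(x) if len(x) else 0.0
                out[var] = f"{cnt} ({pct:.0f}%)"
        return out

    cols = {}
    for g in groups:
        sub = data[labels == g]
        col = {"n (%)": f"{len(sub)} ({100.0 * len(sub) / total:.0f}%)"}
        col.update(summarize(sub))
        cols[str(g)] = col
    if reference is not None:
        col = {"n (%)": f"{len(reference)} (ref)"}
        col.update(summarize(reference))
        cols["CN (reference)"] = col
    return pd.DataFrame(cols)
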