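"""Group-level neural statistics.

Differential scalp maps compare the directly exposed group against everyone
else (indirectly exposed and non-exposed combined into "other"). Per
electrode a two-sample pooled-variance t is computed; electrodes exceeding a
two-sided cluster-forming threshold are grouped into connected, same-sign
clusters under the montage adjacency graph; each cluster's mass (sum of |t|)
is referred to the null distribution of the maximum cluster mass over label
permutations, which controls the family-wise error rate within a map.
Benjamini-Hochberg FDR is then applied across the family of maps (3 bands x
3 periods = 9 by default).

Neurobehavioral models regress Win-Stay on group, a neural scalar, their
interaction, and covariates (age, ethnicity, anxiety), with FDR over the
electrode x period model family; within-group Spearman correlations follow
up significant interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import ModelResult, _zscore, robust_linear_fit
from .montage import Montage, PARIETAL_CLUSTER

DIRECT = "directly_exposed"

#: Covariates for the neurobehavioral interaction models.
NEURO_COVARIATES = ("age", "ethnicity", "gad7")


def direct_vs_other(covariates: pd.DataFrame) -> pd.Series:
    """Boolean contrast: True for the directly exposed group, False otherwise."""
    return (covariates.set_index("subject_id")["group"] == DIRECT).rename("direct")


@dataclass
class ClusterInfo:
    channels: tuple[str, ...]
    mass: float
    pvalue: float
    sign: int


@dataclass
class MapStatResult:
    """Permutation-cluster statistics for one band x period scalp map."""

    band: str
    period: str
    ch_names: tuple[str, ...]
    tvals: np.ndarray  # per electrode; NaN where excluded
    dfs: np.ndarray  # per-electrode degrees of freedom
    clusters: list[ClusterInfo]
    sig_mask: np.ndarray  # electrodes in clusters below the mark threshold
    map_pvalue: float  # min cluster p (1.0 if no cluster formed)
    fdr_significant: bool | None = None
    fdr_pvalue: float | None = None

    def to_frame(self) -> pd.DataFrame:
        cluster_id = np.full(len(self.ch_names), -1)
        cluster_p = np.full(len(self.ch_names), np.nan)
        for ci, cl in enumerate(self.clusters):
            for ch in cl.channels:
                i = self.ch_names.index(ch)
                cluster_id[i] = ci
                cluster_p[i] = cl.pvalue
        return pd.DataFrame(
            {
                "band": self.band,
                "period": self.period,
                "channel": list(self.ch_names),
                "tval": self.tvals,
                "df": self.dfs,
                "cluster_id": cluster_id,
                "cluster_pvalue": cluster_p,
                "significant": self.sig_mask,
            }
        )


def _pooled_t_matrix(
    values: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t for many label assignments at once.

    ``values``: subjects x electrodes (NaN allowed); ``masks``: assignments x
    subjects, True for group 1. Returns (t, df, valid) each assignments x
    electrodes (df collapses to electrodes; it does not vary with labels).
    """
    finite = np.isfinite(values)
    V = np.where(finite, values, 0.0)
    V2 = V * V
    C = finite.astype(float)
    M = masks.astype(float)
    W = 1.0 - M

    n1 = M @ C
    n2 = W @ C
    s1 = M @ V
    s2 = W @ V
    q1 = M @ V2
    q2 = W @ V2

    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        ss1 = q1 - n1 * m1**2
        ss2 = q2 - n2 * m2**2
        df = n1 + n2 - 2
        sp2 = (ss1 + ss2) / df
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    valid = (n1 >= 2) & (n2 >= 2) & (sp2 > 0)
    t = np.where(valid, t, np.nan)
    return t, df[0] if df.ndim == 2 else df, valid


def _connected_clusters(
    supra: np.ndarray, signs: np.ndarray, adjacency: list[list[int]]
) -> list[list[int]]:
    """Connected components of suprathreshold electrodes with a common sign."""
    seen = np.zeros(len(supra), dtype=bool)
    clusters = []
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in adjacency[node]:
                if supra[nb] and not seen[nb] and signs[nb] == signs[start]:
                    seen[nb] = True
                    comp.append(nb)
                    queue.append(nb)
        clusters.append(sorted(comp))
    return clusters


def _max_cluster_mass(
    t_row: np.ndarray, tcrit: np.ndarray, adjacency: list[list[int]]
) -> float:
    absd = np.abs(t_row)
    supra = np.isfinite(t_row) & (absd > tcrit)
    if not supra.any():
        return 0.0
    signs = np.sign(t_row)
    best = 0.0
    for comp in _connected_clusters(supra, signs, adjacency):
        best = max(best, float(absd[comp].sum()))
    return best


def permutation_cluster_map(
    scalars: pd.DataFrame,
    contrast: pd.Series,
    montage: Montage,
    n_perm: int = 10_000,
    cluster_alpha: float = 0.05,
    mark_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    band: str = "",
    period: str = "",
) -> MapStatResult:
    """Permutation-cluster test of a group contrast over one scalp map.

    ``scalars``: subjects x electrodes (index = subject_id, NaN allowed and
    excluded per electrode). ``contrast``: boolean per subject (True = group
    1). Cluster-forming threshold: per-electrode two-sided p < cluster_alpha.
    Cluster p-values are ``(1 + #{null max mass >= mass}) / (n_perm + 1)``;
    electrodes in clusters with p < ``mark_alpha`` are flagged in
    ``sig_mask``. Zero-variance electrodes are excluded with NaN t.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    montage.require(())
    ch_names = tuple(scalars.columns)
    if set(ch_names) - set(montage.ch_names):
        raise ValueError("scalars contain channels absent from the montage")
    adjacency_full = montage.adjacency_lists()
    remap = {montage.index(c): i for i, c in enumerate(ch_names)}
    adjacency = [
        [remap[j] for j in adjacency_full[montage.index(c)] if j in remap]
        for c in ch_names
    ]
    rng = np.random.default_rng(rng)

    values = scalars.to_numpy(dtype=float)
    labels = contrast.reindex(scalars.index).to_numpy(dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 subjects per side")

    t_obs, df, _ = _pooled_t_matrix(values, labels[None, :])
    t_obs = t_obs[0]
    tcrit = stats.t.ppf(1 - cluster_alpha / 2, np.maximum(df, 1))

    # observed clusters
    absd = np.abs(t_obs)
    supra = np.isfinite(t_obs) & (absd > tcrit)
    signs = np.sign(np.nan_to_num(t_obs))
    comps = _connected_clusters(supra, signs, adjacency)

    # null distribution of the max cluster mass
    n_subj = len(labels)
    n1 = int(labels.sum())
    perm_masks = np.zeros((n_perm, n_subj), dtype=bool)
    for p in range(n_perm):
        perm_masks[p, rng.choice(n_subj, size=n1, replace=False)] = True
    t_null, _, _ = _pooled_t_matrix(values, perm_masks)
    null_max = np.array(
        [_max_cluster_mass(t_null[p], tcrit, adjacency) for p in range(n_perm)]
    )

    clusters = []
    for comp in comps:
        mass = float(absd[comp].sum())
        pval = (1 + int(np.sum(null_max >= mass))) / (n_perm + 1)
        clusters.append(
            ClusterInfo(
                channels=tuple(ch_names[i] for i in comp),
                mass=mass,
                pvalue=pval,
                sign=int(signs[comp[0]]),
            )
        )

    sig_mask = np.zeros(len(ch_names), dtype=bool)
    for cl in clusters:
        if cl.pvalue < mark_alpha:
            for ch in cl.channels:
                sig_mask[ch_names.index(ch)] = True
    map_p = min((cl.pvalue for cl in clusters), default=1.0)
    return MapStatResult(
        band=band, period=period, ch_names=ch_names, tvals=t_obs,
        dfs=np.asarray(df, dtype=float), clusters=clusters,
        sig_mask=sig_mask, map_pvalue=float(map_p),
    )


def fdr_across_maps(
    pvalues: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of map p-values.

    Returns (reject flags, adjusted p-values).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def cluster_ttest(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Two-sample pooled-variance t-test with Cohen's d.

    ``x`` and ``y`` are per-subject scalars for the two sides of the
    contrast; NaNs are dropped. d = (mean_x - mean_y) / pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per side")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    diff = x.mean() - y.mean()
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "p": float(p), "df": int(df),
            "cohen_d": float(diff / np.sqrt(sp2)), "n1": n1, "n2": n2}


def neurobehavioral_model(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    neural: pd.Series,
    outcome: str = "win_stay_expt",
    covariate_terms: Sequence[str] = NEURO_COVARIATES,
) -> ModelResult:
    """Robust model of behavior on group, a neural scalar, and their interaction.

    Design: outcome ~ group(direct vs other) + neural + group x neural +
    covariates, all continuous variables z-scored. ``neural`` is a per-subject
    Series (index = subject_id), e.g. parietal-cluster or single-electrode
    alpha for one period; subjects with NaN anywhere are dropped.
    """
    data = metrics.merge(covariates, on="subject_id", validate="one_to_one")
    data = data.set_index("subject_id")
    data["neural"] = neural.reindex(data.index)
    data = data.dropna(subset=[outcome, "neural", *[c for c in covariate_terms]])
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete cases, have {len(data)}")

    y = _zscore(data[outcome].to_numpy())
    z_neural = _zscore(data["neural"].to_numpy())
    direct = (data["group"] == DIRECT).astype(float).to_numpy()
    cols: dict[str, np.ndarray] = {
        "Intercept": np.ones(len(data)),
        "group[direct]": direct,
        "neural": z_neural,
        "group[direct]:neural": direct * z_neural,
    }
    for term in covariate_terms:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col):
            cols[term] = _zscore(col.to_numpy())
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (col.astype(str) == level).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    dup = X.T.duplicated()
    if dup.any():
        raise ValueError(f"rank-deficient design; duplicate columns: {list(X.columns[dup])}")
    result = robust_linear_fit(y, X)
    result.outcome = outcome
    return result


def neurobehavioral_family(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    neural_table: Mapping[tuple[str, str], pd.Series],
    q: float = 0.05,
    interaction_term: str = "group[direct]:neural",
) -> pd.DataFrame:
    """Fit the interaction model per (electrode, period) with FDR over the family.

    ``neural_table`` maps (electrode, period) to a per-subject scalar Series.
    Returns one row per model with the interaction beta/p and BH-adjusted p
    across the whole family (4 electrodes x 3 periods = 12 in the default
    analysis).
    """
    rows = []
    for (electrode, period), series in neural_table.items():
        res = neurobehavioral_model(metrics, covariates, series)
        term = res.term(interaction_term)
        rows.append(
            {
                "electrode": electrode,
                "period": period,
                "interaction_beta": term["beta"],
                "interaction_se": term["se"],
                "interaction_t": term["tstat"],
                "interaction_p": term["pvalue"],
                "model_adj_r2": res.adj_r2,
                "model_fstat": res.fstat,
                "model_p": res.model_pvalue,
                "n": res.n_used,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_across_maps(out["interaction_p"].to_numpy(), q=q)
    out["interaction_p_fdr"] = p_adj
    out["significant_fdr"] = reject
    return out


def within_group_spearman(
    metrics: pd.DataFrame,
    neural: pd.Series,
    covariates: pd.DataFrame,
    group: str | Sequence[str],
    outcome: str = "win_stay_expt",
) -> dict[str, float]:
    """Spearman correlation of behavior with a neural scalar inside one group.

    ``group`` may be a single label or a set of labels (e.g. the combined
    "other" group). Constant input yields NaN rho, reported as such.
    """
    groups = (group,) if isinstance(group, str) else tuple(group)
    subj = covariates.loc[covariates["group"].isin(groups), "subject_id"]
    data = metrics.set_index("subject_id").loc[metrics["subject_id"].isin(subj).to_numpy()]
    pairs = pd.DataFrame({"behavior": data[outcome], "neural": neural}).dropna()
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 pairs, have {len(pairs)}")
    if pairs["behavior"].nunique() == 1 or pairs["neural"].nunique() == 1:
        return {"rho": float("nan"), "p": float("nan"), "n": len(pairs)}
    rho, p = stats.spearmanr(pairs["behavior"], pairs["neural"])
    return {"rho": float(rho), "p": float(p), "n": len(pairs)}


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def demographic_comparison(
    covariates: pd.DataFrame,
    contrast: pd.Series | None = None,
    categorical: Sequence[str] = ("gender", "ethnicity"),
    numeric: Sequence[str] = ("age", "ses", "gad7", "phq9", "recent_trauma"),
    min_count: int = 1,
) -> pd.DataFrame:
    """Two-group demographic comparisons (direct vs other by default).

    Rank-sum (Wilcoxon) tests for ordinal/continuous variables; chi-square
    contingency tests for gender and ethnicity (levels with fewer than
    ``min_count`` observations overall are collapsed into "other" with a
    warning). Stars follow the p < 0.01 (**) and p < 0.001 (***) convention.
    """
    import warnings

    if contrast is None:
        contrast = direct_vs_other(covariates)
    labels = contrast.reindex(covariates["subject_id"]).to_numpy(dtype=bool)
    rows = []
    for var in numeric:
        x = covariates.loc[labels, var].astype(float)
        y = covariates.loc[~labels, var].astype(float)
        stat, p = stats.ranksums(x, y)
        rows.append({"variable": var, "test": "ranksum", "statistic": float(stat),
                     "pvalue": float(p), "stars": _stars(p)})
    for var in categorical:
        col = covariates[var].astype(str)
        counts = col.value_counts()
        rare = counts[counts < min_count].index
        if len(rare):
            warnings.warn(f"collapsing sparse {var} levels {list(rare)} into 'other'")
            col = col.where(~col.isin(rare), "other")
        table = pd.crosstab(col, labels)
        chi2, p, _, _ = stats.chi2_contingency(table)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "pvalue": float(p), "stars": _stars(p)})
    return pd.DataFrame(rows)
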