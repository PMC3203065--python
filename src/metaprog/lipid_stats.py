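"""Per-lipid cohort statistics, FDR estimation and clustering.

Covers the routine statistical layer of a longitudinal lipidomics study:
Wilcoxon rank-sum comparisons between groups, Storey q-values for the
resulting battery of 154 tests, median-ratio log2 fold differences,
correlation-based distances with Ward clustering for lipid heatmaps,
reference-normalized profile matrices with Euclidean/complete-linkage
clustering, and the HOMA-IR insulin-resistance index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import LongitudinalDataset

#: combined sample size at or below which the exact rank-sum null is used
EXACT_WILCOXON_MAX_N = 12


def wilcoxon_per_lipid(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for combined n <= 12 with untied data; otherwise
    the normal approximation with tie and continuity corrections, matching
    the R ``wilcox.test`` defaults.  Without the continuity correction the
    discrete null p-distribution has too little mass near 1, which biases
    the downstream null-proportion (pi0) estimate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def test_table(
    dataset: LongitudinalDataset,
    group_col: str = "group",
    high_label: str = "progressor",
    low_label: str = "non-progressor",
) -> pd.DataFrame:
    """Per-metabolite p, q and log2 fold difference between two groups.

    All visits of all individuals in a group are pooled per metabolite, as
    when screening a lipid panel for group differences.
    """
    meta = dataset.meta.set_index("individual")[group_col]
    rec = dataset.records.copy()
    rec["grp"] = rec["individual"].map(meta)
    rows = []
    for lipid in dataset.metabolite_index:
        sub = rec[rec["metabolite"] == lipid]
        hi = sub.loc[sub["grp"] == high_label, "concentration"].to_numpy()
        lo = sub.loc[sub["grp"] == low_label, "concentration"].to_numpy()
        rows.append(
            {
                "metabolite": lipid,
                "p_value": wilcoxon_per_lipid(hi, lo),
                "log2_fold": fold_difference(hi, lo),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = estimate_qvalues(out["p_value"].to_numpy())
    return out[["metabolite", "p_value", "q_value", "log2_fold"]]


def estimate_pi0(p_values: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Proportion of true nulls, estimated from the p-value distribution tail.

    For small batteries (m < 100) a single fixed lambda = 0.5 is used — the
    smoother is unstable there.  Otherwise pi0(lambda) over the grid
    0, 0.05, ..., 0.90 is smoothed with a cubic fit and read off at the
    largest lambda, mirroring the standard q-value estimator.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < 100:
        lam = 0.5
        pi0 = np.sum(p > lam) / (m * (1 - lam))
        return float(min(pi0, 1.0))
    grid = np.arange(0.0, 0.95, 0.05) if lambda_grid is None else np.asarray(lambda_grid)
    pi0_lam = np.array([np.sum(p > lam) / (m * (1 - lam)) for lam in grid])
    coef = np.polyfit(grid, pi0_lam, deg=3)
    pi0 = np.polyval(coef, grid.max())
    return float(min(max(pi0, 1.0 / m), 1.0))


def estimate_qvalues(
    p_values: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values: q_i = min over {j: p_j >= p_i} of pi0 * m * p_j / rank(p_j).

    Monotone non-decreasing in p and bounded by 1; with pi0 forced to 1 this
    reduces to the Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_difference(high: np.ndarray, low: np.ndarray) -> float:
    """log2 of the ratio of group medians (positive = up in the high group)."""
    med_low = float(np.median(low))
    med_high = float(np.median(high))
    if med_low <= 0:
        raise ValueError("low-group median must be positive")
    return float(np.log2(med_high / med_low))


def corr_distance(x: np.ndarray, y: np.ndarray, absolute: bool = False) -> float:
    """Correlation-based distance: 1 - r (range [0, 2]) or 1 - |r| with
    ``absolute`` (range [0, 1])."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - abs(r) if absolute else 1.0 - r


@dataclass
class ClusterTree:
    """Hierarchical merge structure (scipy linkage encoding) over ``labels``."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick text of the merge structure, branch lengths from heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        special = set("():;,[] '\t\n")

        def quoted(label: str) -> str:
            if any(ch in special for ch in label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def node(i: int) -> str:
            if i < n:
                return quoted(self.labels[i])
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            return f"({node(a)}:{la:g},{node(b)}:{lb:g})"

        for row in range(len(self.linkage)):
            heights[n + row] = float(self.linkage[row, 2])
        return node(n + len(self.linkage) - 1) + ";"


def _pairwise_corr_distance(matrix: np.ndarray, absolute: bool = False) -> np.ndarray:
    """Condensed correlation-distance vector over the rows of ``matrix``."""
    if np.any(np.ptp(matrix, axis=1) == 0):
        raise ValueError("correlation undefined for a constant row")
    R = np.corrcoef(matrix)
    D = 1.0 - (np.abs(R) if absolute else R)
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return squareform((D + D.T) / 2.0, checks=False)


def ward_cluster(
    matrix: np.ndarray,
    labels: list[str] | None = None,
    absolute: bool = False,
) -> ClusterTree:
    """Ward hierarchical clustering of rows under the correlation distance.

    scipy's agglomeration is deterministic; equal-distance merges resolve to
    the pair encountered first (lower indices).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(_pairwise_corr_distance(matrix, absolute), method="ward")
    labels = labels if labels is not None else [str(i) for i in range(len(matrix))]
    return ClusterTree(Z, labels)


def ratio_heatmap_matrix(
    dataset: LongitudinalDataset,
    group_a: str = "progressor",
    group_b: str = "non-progressor",
    age_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Metabolites x age-bins matrix of log2 ratios of group mean
    concentrations, rows ordered by Ward clustering of lipid profiles.

    Bins where either group has no visits come back as NaN.  Lipids are
    clustered on their concentration profiles across all samples.
    """
    meta = dataset.meta.set_index("individual")["group"]
    rec = dataset.records.copy()
    rec["grp"] = rec["individual"].map(meta)
    ages = np.sort(rec["age"].unique()) if age_bins is None else np.asarray(age_bins)
    rec["bin"] = ages[np.abs(rec["age"].to_numpy()[:, None] - ages[None, :]).argmin(axis=1)]
    mean_tab = rec.pivot_table(
        index="metabolite", columns=["bin", "grp"], values="concentration", aggfunc="mean"
    )
    out = pd.DataFrame(index=dataset.metabolite_index, columns=ages, dtype=float)
    for b in ages:
        try:
            a_col = mean_tab[(b, group_a)]
            b_col = mean_tab[(b, group_b)]
        except KeyError:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            out[b] = np.log2(a_col / b_col).reindex(out.index)
    # row order: Ward clustering of per-sample lipid profiles
    profiles = rec.pivot_table(
        index="metabolite", columns=["individual", "age"], values="concentration"
    ).reindex(dataset.metabolite_index)
    filled = profiles.to_numpy(dtype=float)
    keep = ~np.isnan(filled).all(axis=1)
    if keep.sum() >= 2 and np.all(np.nan_to_num(np.ptp(filled[keep], axis=1)) > 0):
        tree = ward_cluster(filled[keep], [m for m, k in zip(out.index, keep) if k])
        ordered = [tree.labels[i] for i in tree.leaf_order()]
        out = out.reindex(ordered + [m for m, k in zip(dataset.metabolite_index, keep) if not k])
    return out


def profile_heatmap(
    profiles: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
) -> tuple[pd.DataFrame, ClusterTree]:
    """Reference-normalized, log2, unit-variance profile matrix plus its
    column clustering (Euclidean metric, complete linkage).

    Each variable (column) is divided by its mean in the reference group,
    log2-transformed, then scaled to unit variance.  Rows are samples.
    """
    ref = profiles.loc[groups == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = ref.mean(axis=0)
    bad = ref_mean.index[ref_mean <= 0]
    if len(bad):
        raise ValueError(f"non-positive reference mean for variable {bad[0]!r}")
    norm = np.log2(profiles / ref_mean)
    sd = norm.std(axis=0, ddof=0)
    sd = sd.replace(0, np.nan)
    scaled = norm / sd
    data = scaled.to_numpy(dtype=float).T  # variables as items
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    return scaled, ClusterTree(Z, list(profiles.columns))


def homa_ir(fasting_insulin_uIU_ml: float, fasting_glucose_mmol_l: float) -> float:
    """HOMA-IR insulin-resistance index: insulin (µIU/ml) x glucose (mmol/l) / 22.5."""
    insulin = np.asarray(fasting_insulin_uIU_ml, dtype=float)
    glucose = np.asarray(fasting_glucose_mmol_l, dtype=float)
    if np.any(insulin <= 0) or np.any(glucose <= 0):
        raise ValueError("fasting insulin and glucose must be positive")
    return insulin * glucose / 22.5
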