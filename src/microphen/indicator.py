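"""Indicator-OTU analysis.

The indicator value of an OTU for a sample group combines specificity
(A: its mean abundance in the group as a share of the summed per-group
means) with fidelity (B: the fraction of group samples where it occurs);
the statistic is sqrt(A*B), with inference by permutation of group labels.
Also provides Venn-style set intersections across treatment groups and the
log2 fold-change-vs-control matrix with hierarchical row ordering used for
indicator heat maps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class IndValResult:
    otu_id: str
    group: str
    A: float
    B: float
    stat: float
    p_value: float


def indval_stat(abundance_vector, groups, target_group) -> tuple[float, float, float]:
    """(A, B, stat) of one OTU for one group.

    A = mean abundance in the target group over the sum of all group
    means; B = occurrence fraction within the target group; stat =
    sqrt(A*B).
    """
    x = np.asarray(abundance_vector, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if target_group not in levels:
        raise ValueError(f"target group {target_group!r} absent")
    if not x.any():
        warnings.warn("OTU absent from every sample; stat set to 0")
        return 0.0, 0.0, 0.0
    means = np.array([x[g == lv].mean() for lv in levels])
    tgt = list(levels).index(target_group)
    denom = means.sum()
    a = means[tgt] / denom if denom > 0 else 0.0
    b = float((x[g == target_group] > 0).mean())
    return float(a), b, float(np.sqrt(a * b))


def _group_matrices(g: np.ndarray, levels, combinations: bool):
    """Boolean membership masks for groups (and pairs when enabled)."""
    masks = {str(lv): g == lv for lv in levels}
    if combinations:
        for l1, l2 in itertools.combinations(levels, 2):
            masks[f"{l1}+{l2}"] = (g == l1) | (g == l2)
    return masks


def _max_stat(x_mat: np.ndarray, g: np.ndarray, levels, masks) -> tuple[np.ndarray, np.ndarray]:
    """Per-OTU max IndVal statistic over candidate groups, vectorized.

    ``x_mat`` is samples x OTUs. Group means use the base (single) levels;
    a combination's specificity uses the mean over its pooled samples.
    """
    base_means = np.stack([x_mat[g == lv].mean(axis=0) for lv in levels])  # L x O
    denom = base_means.sum(axis=0)
    denom[denom == 0] = np.inf
    best = np.full(x_mat.shape[1], -1.0)
    best_idx = np.zeros(x_mat.shape[1], dtype=int)
    level_of = {str(lv): i for i, lv in enumerate(levels)}
    names = list(masks)
    for k, name in enumerate(names):
        m = masks[name]
        if "+" in name:
            # combination specificity: summed member-group means over the
            # total; fidelity over the pooled samples
            idx = [level_of[p] for p in name.split("+")]
            a = base_means[idx].sum(axis=0) / denom
        else:
            a = base_means[level_of[name]] / denom
        b = (x_mat[m] > 0).mean(axis=0)
        stat = np.sqrt(np.clip(a, 0, None) * b)
        upd = stat > best
        best[upd] = stat[upd]
        best_idx[upd] = k
    return best, best_idx


def indval_test(
    table: pd.DataFrame,
    groups: pd.Series,
    n_perm: int | str = 999,
    seed: int = 0,
    combinations: bool = False,
) -> pd.DataFrame:
    """IndVal analysis of every OTU with permutation p-values.

    For each OTU the statistic is its maximum over groups (and over group
    pairs when ``combinations``); the p-value is the fraction of label
    permutations whose max statistic reaches the observed one, with the
    (1+b)/(1+m) estimator. ``n_perm="exact"`` enumerates all distinct
    label orderings (small n only).
    """
    g = groups.loc[table.index].to_numpy()
    levels = pd.unique(g)
    counts = pd.Series(g).value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 samples")
    if n_perm != "exact" and int(n_perm) < 99:
        warnings.warn(f"n_perm={n_perm} is low for stable p-values")
    x = table.to_numpy(float)
    masks = _group_matrices(g, levels, combinations)
    obs, obs_idx = _max_stat(x, g, levels, masks)

    rng = np.random.default_rng(seed)
    if n_perm == "exact":
        perm_labels = set(itertools.permutations(g))
        perm_list = [np.asarray(p) for p in sorted(perm_labels)]
    else:
        perm_list = [rng.permutation(g) for _ in range(int(n_perm))]

    exceed = np.zeros(x.shape[1])
    m_eff = 0
    for gp in perm_list:
        if n_perm == "exact" and (gp == g).all():
            continue  # identity handled by the +1 smoothing
        masks_p = _group_matrices(gp, levels, combinations)
        stat_p, _ = _max_stat(x, gp, levels, masks_p)
        exceed += stat_p >= obs - 1e-12
        m_eff += 1
    pvals = (1 + exceed) / (1 + m_eff)

    names = list(masks)
    return pd.DataFrame(
        {
            "otu_id": table.columns,
            "group": [names[i] for i in obs_idx],
            "stat": obs,
            "p_value": pvals,
        }
    ).set_index("otu_id")


def indicator_sets(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-group significant OTU sets and Venn-style subset counts."""
    sig = results[results["p_value"] < alpha]
    sets: dict[str, set] = {}
    for grp, sub in sig.groupby("group"):
        sets[str(grp)] = set(sub.index)
    names = sorted(sets)
    counts = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set.union(*(sets[c] for c in names if c not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    return {"sets": sets, "exclusive_counts": counts}


def fold_change_vs_control(
    rel_abundance: pd.DataFrame,
    indicator_otus,
    control_sample_ids,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """log2 fold-change of each indicator OTU vs the control median.

    ``value = log2((x + c) / (median_control + c))`` with pseudocount ``c``
    defaulting to half the smallest nonzero relative abundance in the
    matrix (keeps the log finite with minimal distortion).
    """
    missing = [o for o in indicator_otus if o not in rel_abundance.columns]
    if missing:
        raise KeyError(f"indicator OTU(s) missing from the table: {missing}")
    control = rel_abundance.loc[list(control_sample_ids), list(indicator_otus)]
    if control.empty:
        raise ValueError("control sample set is empty")
    if pseudocount is None:
        vals = rel_abundance[list(indicator_otus)].to_numpy()
        nz = vals[vals > 0]
        pseudocount = float(nz.min() / 2) if nz.size else 1.0
    med = control.median(axis=0)
    x = rel_abundance[list(indicator_otus)]
    fc = np.log2((x + pseudocount).div(med + pseudocount, axis=1))
    return fc.T  # indicator OTUs x samples, heat-map orientation


def cluster_order(
    matrix: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> list:
    """Dendrogram leaf order of the rows (agglomerative clustering).

    Rows are pre-sorted by label so equal-distance merges break ties
    deterministically.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN cells")
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    m = matrix.sort_index()
    z = hierarchy.linkage(pdist(m.to_numpy(float), metric=metric), method=linkage)
    leaves = hierarchy.leaves_list(z)
    return [m.index[i] for i in leaves]
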