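"""Community summary statistics.

Shannon diversity, Bray-Curtis dissimilarity, and a permutational
multivariate ANOVA (PERMANOVA) with sequential multi-term partitioning of
the Gower-centered distance matrix, per-term partial R² and permutation
p-values. "Partial correlation" in this pipeline's reports means partial
R² = SS_term / SS_total, the conventional output of distance-based
permutational ANOVA.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of one sample."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    if p.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return float(entropy(p))  # scipy normalizes and uses natural log


def shannon_per_sample(table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [shannon(row) for row in table.to_numpy()], index=table.index, name="shannon"
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v)."""
    x = table.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = table.index[zero].tolist()
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_designs(metadata: pd.DataFrame, terms: list[str]) -> list[tuple[str, np.ndarray]]:
    """Expand term labels (``A``, ``A:B``, with ``A*B`` -> A, B, A:B) into
    dummy-coded design blocks, in sequential order."""
    expanded: list[str] = []
    for t in terms:
        if "*" in t:
            parts = [p.strip() for p in t.split("*")]
            expanded.extend(parts)
            for r in range(2, len(parts) + 1):
                for combo in itertools.combinations(parts, r):
                    expanded.append(":".join(combo))
        else:
            expanded.append(t.strip())
    # drop duplicates, keep order
    seen: list[str] = []
    for t in expanded:
        if t not in seen:
            seen.append(t)
    designs = []
    for t in seen:
        cols = t.split(":")
        for c in cols:
            if c not in metadata.columns:
                raise KeyError(f"metadata has no column {c!r}")
            if metadata[c].nunique() < 2:
                raise ValueError(f"term {c!r} has fewer than 2 levels")
        combo = metadata[cols].astype(str).agg(":".join, axis=1)
        d = pd.get_dummies(combo, drop_first=True, dtype=float).to_numpy()
        designs.append((t, d))
    return designs


def _cumulative_bases(designs, n: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Orthonormal bases of the cumulative design spaces (intercept first).

    SVD handles the rank deficiency of overlapping dummy blocks. Returns
    one basis per term plus the per-term degrees of freedom.
    """
    x = np.ones((n, 1))
    bases = []
    dfs = np.empty(len(designs), dtype=int)
    prev_rank = 1
    for k, (_, cols) in enumerate(designs):
        x = np.column_stack([x, cols])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        basis = u[:, s > s[0] * 1e-10]
        bases.append(basis)
        dfs[k] = basis.shape[1] - prev_rank
        prev_rank = basis.shape[1]
    return bases, dfs


def _sequential_distance_ss(g: np.ndarray, bases: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Sequential SS per term from projections of the Gower matrix."""
    total = float(np.trace(g))
    ss = np.empty(len(bases))
    prev_tr = 0.0
    for k, basis in enumerate(bases):
        cur = float(np.einsum("ij,ik,kj->", basis, g, basis))
        ss[k] = cur - prev_tr
        prev_tr = cur
    return ss, total


def permanova(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str] | str,
    n_perm: int | str = 1000,
    seed: int = 0,
    strata: str | None = None,
) -> pd.DataFrame:
    """Multi-term PERMANOVA on a distance matrix.

    Sequential (type-I) partitioning: SS per term from cumulative
    projections of the Gower-centered matrix, pseudo-F against the
    full-model residual, p-values from free permutation of sample labels
    (or within ``strata``). ``n_perm="exact"`` enumerates every distinct
    sample-label permutation (feasible for small n). p-values use the
    (1 + b) / (1 + m) estimator; partial R² is SS_term / SS_total.
    """
    if isinstance(terms, str):
        terms = [terms]
    ids = list(dist.index)
    meta = metadata.loc[ids]
    d = dist.to_numpy(float)
    g = _gower_center(d)
    designs = _term_designs(meta, terms)
    bases, dfs = _cumulative_bases(designs, len(ids))
    ss, total = _sequential_distance_ss(g, bases)
    ss_resid = total - ss.sum()
    df_resid = len(ids) - 1 - dfs.sum()
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    f_obs = (ss / dfs) / ms_resid

    rng = np.random.default_rng(seed)
    n = len(ids)
    if n_perm == "exact":
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        perms = perms[1:]  # identity excluded; added back via the +1 estimator
    else:
        if strata is None:
            perms = [rng.permutation(n) for _ in range(int(n_perm))]
        else:
            groups = meta[strata].to_numpy()
            idx = np.arange(n)
            perms = []
            for _ in range(int(n_perm)):
                p = idx.copy()
                for gl in np.unique(groups):
                    m = idx[groups == gl]
                    p[m] = rng.permutation(m)
                perms.append(p)

    exceed = np.zeros(len(designs))
    for p in perms:
        gp = g[np.ix_(p, p)]
        ss_p, _ = _sequential_distance_ss(gp, bases)
        ms_resid_p = (total - ss_p.sum()) / df_resid
        f_p = (ss_p / dfs) / ms_resid_p
        exceed += f_p >= f_obs - 1e-9 * np.abs(f_obs) - 1e-12
    pvals = (1 + exceed) / (1 + len(perms))

    rows = []
    for k, (name, _) in enumerate(designs):
        rows.append(
            dict(term=name, ss=ss[k], df=int(dfs[k]), pseudo_f=f_obs[k],
                 partial_r2=ss[k] / total, p_value=pvals[k], n_perm=len(perms))
        )
    rows.append(
        dict(term="residual", ss=ss_resid, df=int(df_resid), pseudo_f=np.nan,
             partial_r2=ss_resid / total, p_value=np.nan, n_perm=len(perms))
    )
    return pd.DataFrame(rows)


def exact_permutation_count(labels) -> int:
    """Number of distinct orderings of a label multiset."""
    labels = list(labels)
    c = pd.Series(labels).value_counts()
    out = math.factorial(len(labels))
    for v in c:
        out //= math.factorial(int(v))
    return out
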