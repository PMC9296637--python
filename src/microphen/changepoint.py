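"""Hinge (change-point) regression of plant phenotypes on OTU abundance.

The model is ``y = alpha + beta * max(0, x - tau) + error``: the phenotype
is unaffected by the OTU until its calibrated abundance ``x`` crosses the
threshold ``tau``, then trends linearly with slope ``beta``. ``tau`` is
estimated by least squares over a grid of observed abundances (10th-90th
percentile band, ties broken toward the smaller threshold, samples exactly
at the threshold belong to the flat segment); ``beta`` inference is by
case-resampling bootstrap (an asymptotic t-test at fixed tau-hat is
available but anti-conservative because it ignores threshold estimation).
An OTU is a hit when both phenotypes give a significant slope of the same
sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ChangePointFit:
    otu_id: str
    phenotype: str
    tau: float
    intercept: float
    slope: float
    r_squared: float
    n_above: int
    p_slope: float | None = None


def _candidate_taus(x: np.ndarray, min_above: int, lo: float = 0.10, hi: float = 0.90) -> np.ndarray:
    q_lo, q_hi = np.quantile(x, [lo, hi])
    taus = np.unique(x)
    taus = taus[(taus >= q_lo) & (taus <= q_hi)]
    if taus.size:
        n_above = (x[:, None] > taus[None, :]).sum(axis=0)
        taus = taus[n_above >= min_above]
    return taus


def _hinge_ls(x: np.ndarray, y: np.ndarray, taus: np.ndarray):
    """Closed-form least squares of y ~ 1 + max(0, x - tau) for every tau.

    Returns (slope, rss, syy_centered) arrays over the tau grid.
    """
    n = len(x)
    h = np.maximum(0.0, x[:, None] - taus[None, :])
    sh = h.sum(axis=0)
    shh = (h * h).sum(axis=0)
    shy = (h * y[:, None]).sum(axis=0)
    sy = y.sum()
    syy_c = float(((y - y.mean()) ** 2).sum())
    shh_c = shh - sh * sh / n
    shy_c = shy - sh * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(shh_c > 1e-12, shy_c / np.where(shh_c > 0, shh_c, 1.0), 0.0)
    rss = syy_c - slope * shy_c
    return slope, rss, syy_c


def fit_hinge(
    x,
    y,
    grid: str = "observed",
    min_above: int = 5,
    otu_id: str = "",
    phenotype: str = "",
) -> ChangePointFit:
    """Least-squares hinge fit with threshold chosen on the observed grid.

    Candidate thresholds are the unique observed abundances in the 10-90
    percentile band with at least ``min_above`` samples above; the RSS
    minimizer wins, ties going to the smaller threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    if len(x) < 2 * min_above:
        raise ValueError(f"need n >= {2 * min_above} observations")
    if np.unique(x).size == 1:
        raise ValueError("no variation in abundance: all x identical")
    taus = _candidate_taus(x, min_above)
    if taus.size == 0:
        raise ValueError("no candidate threshold satisfies the min_above rule")
    slope, rss, syy_c = _hinge_ls(x, y, taus)
    best = int(np.argmin(rss))  # taus ascending -> ties resolve to smaller tau
    tau = float(taus[best])
    b = float(slope[best])
    h = np.maximum(0.0, x - tau)
    a = float(y.mean() - b * h.mean())
    r2 = 0.0 if syy_c <= 0 else float(max(0.0, 1.0 - rss[best] / syy_c))
    return ChangePointFit(
        otu_id=otu_id,
        phenotype=phenotype,
        tau=tau,
        intercept=a,
        slope=b,
        r_squared=r2,
        n_above=int((x > tau).sum()),
    )


def _bootstrap_slopes(
    x: np.ndarray,
    y: np.ndarray,
    taus: np.ndarray,
    min_above: int,
    n_boot: int,
    rng: np.random.Generator,
    chunk: int = 200,
) -> tuple[np.ndarray, int]:
    """Vectorized case-resampling: refit the hinge on each resample.

    The candidate grid is the original observed-value grid masked to each
    resample's own 10-90 percentile band and ``min_above`` rule. Returns
    the bootstrap slope distribution and the count of degenerate resamples
    (no valid threshold; their slope contributes 0, which is conservative).
    """
    n = len(x)
    h0 = np.maximum(0.0, x[:, None] - taus[None, :])  # n x T
    slopes = np.empty(n_boot)
    n_degen = 0
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xb = x[idx]
        yb = y[idx]
        hb = h0[idx]                      # b x n x T
        sh = hb.sum(axis=1)
        shh = np.einsum("bnt,bnt->bt", hb, hb)
        shy = np.einsum("bnt,bn->bt", hb, yb)
        sy = yb.sum(axis=1)
        syy = (yb * yb).sum(axis=1)
        shh_c = shh - sh * sh / n
        shy_c = shy - sh * sy[:, None] / n
        syy_c = syy - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            sl = np.where(shh_c > 1e-12, shy_c / np.where(shh_c > 0, shh_c, 1.0), 0.0)
        rss = syy_c[:, None] - sl * shy_c
        q = np.quantile(xb, [0.10, 0.90], axis=1)
        n_above = (hb > 0).sum(axis=1)
        valid = (
            (taus[None, :] >= q[0][:, None])
            & (taus[None, :] <= q[1][:, None])
            & (n_above >= min_above)
            & (shh_c > 1e-12)
        )
        rss = np.where(valid, rss, np.inf)
        best = np.argmin(rss, axis=1)
        sl_best = sl[np.arange(b), best]
        degen = ~valid.any(axis=1)
        sl_best[degen] = 0.0
        n_degen += int(degen.sum())
        slopes[done : done + b] = sl_best
        done += b
    return slopes, n_degen


def slope_test(
    fit: ChangePointFit,
    x,
    y,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    min_above: int = 5,
) -> float:
    """Two-sided p-value for the post-threshold slope.

    ``bootstrap`` (default): percentile p from case-resampled hinge refits,
    with the (1+b)/(1+B) smoothing on each tail. ``asymptotic``: t-test on
    the slope at the estimated threshold (anti-conservative; it treats
    tau-hat as known).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if int((x > fit.tau).sum()) < min_above:
        raise ValueError("fewer than min_above points above the fitted threshold")
    if method == "asymptotic":
        import scipy.stats as st

        h = np.maximum(0.0, x - fit.tau)
        n = len(x)
        hc = h - h.mean()
        shh = float(hc @ hc)
        resid = y - fit.intercept - fit.slope * h
        dof = n - 2
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 / shh)
        t = fit.slope / se
        return float(2 * st.t.sf(abs(t), dof))
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    taus = _candidate_taus(x, min_above)
    slopes, n_degen = _bootstrap_slopes(x, y, taus, min_above, n_boot, rng)
    if n_degen >= 0.1 * n_boot:
        warnings.warn(
            f"{n_degen}/{n_boot} degenerate bootstrap resamples; p is conservative"
        )
    lo = (1 + (slopes <= 0).sum()) / (1 + n_boot)
    hi = (1 + (slopes >= 0).sum()) / (1 + n_boot)
    return float(min(1.0, 2 * min(lo, hi)))


def fit_with_test(
    x, y, otu_id="", phenotype="", min_above=5, n_boot=1000, seed=0, method="bootstrap"
) -> ChangePointFit:
    fit = fit_hinge(x, y, min_above=min_above, otu_id=otu_id, phenotype=phenotype)
    fit.p_slope = slope_test(
        fit, x, y, method=method, n_boot=n_boot, seed=seed, min_above=min_above
    )
    return fit


def changepoint_scan(
    abundance: pd.DataFrame,
    phenotypes: pd.DataFrame,
    pheno_cols: tuple[str, ...] | None = None,
    min_above: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
) -> pd.DataFrame:
    """Hinge fit + slope test for every (OTU, phenotype) pair.

    Returns a tidy frame (otu_id, phenotype, tau, intercept, slope,
    r_squared, n_above, p_slope). OTUs without a valid threshold grid
    (e.g. almost always absent) are skipped.
    """
    if not abundance.index.equals(phenotypes.index):
        phenotypes = phenotypes.loc[abundance.index]
    pheno_cols = tuple(pheno_cols or phenotypes.columns)
    rows = []
    rng = np.random.default_rng(seed)
    for otu in abundance.columns:
        x = abundance[otu].to_numpy(float)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for k, ph in enumerate(pheno_cols):
            y = phenotypes[ph].to_numpy(float)
            try:
                fit = fit_with_test(
                    x, y, otu_id=otu, phenotype=ph, min_above=min_above,
                    n_boot=n_boot, seed=sub_seed + k, method=method,
                )
            except ValueError:
                continue
            rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def call_hits(
    fits_phenotype1: pd.DataFrame,
    fits_phenotype2: pd.DataFrame,
    alpha: float = 0.05,
    taxonomy: pd.DataFrame | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Dual-phenotype hit rule.

    An OTU is a hit iff its post-threshold slope is significant
    (p < alpha) for *both* phenotypes *and* the two slopes share a sign;
    the shared sign is the hit direction. Mixed-sign OTUs are excluded.
    With ``adjust="bh"`` the per-OTU minimum p is additionally
    Benjamini-Hochberg adjusted across the scan and must clear ``alpha``.
    """
    f1 = fits_phenotype1.set_index("otu_id") if "otu_id" in fits_phenotype1 else fits_phenotype1
    f2 = fits_phenotype2.set_index("otu_id") if "otu_id" in fits_phenotype2 else fits_phenotype2
    common = f1.index.intersection(f2.index)
    dropped = set(f1.index).symmetric_difference(f2.index)
    if dropped:
        warnings.warn(f"{len(dropped)} OTU(s) missing one phenotype; excluded")
    min_p_adj = None
    if adjust == "bh":
        from .diffabund import bh_adjust

        min_p = np.minimum(
            f1.loc[common, "p_slope"].to_numpy(float),
            f2.loc[common, "p_slope"].to_numpy(float),
        )
        min_p_adj = pd.Series(bh_adjust(min_p), index=common)
    elif adjust is not None:
        raise ValueError(f"unknown adjust {adjust!r}")
    rows = []
    for otu in common:
        p1, p2 = float(f1.at[otu, "p_slope"]), float(f2.at[otu, "p_slope"])
        b1, b2 = float(f1.at[otu, "slope"]), float(f2.at[otu, "slope"])
        if min_p_adj is not None and min_p_adj.at[otu] >= alpha:
            continue
        if p1 < alpha and p2 < alpha and np.sign(b1) == np.sign(b2) != 0:
            rec = dict(
                otu_id=otu,
                direction="positive" if b1 > 0 else "negative",
                **{f"p_{f1.at[otu, 'phenotype']}": p1, f"p_{f2.at[otu, 'phenotype']}": p2},
            )
            if taxonomy is not None and otu in taxonomy.index:
                for rank in ("phylum", "genus"):
                    if rank in taxonomy.columns:
                        rec[rank] = taxonomy.at[otu, rank]
            rows.append(rec)
    cols = ["otu_id", "direction"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
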