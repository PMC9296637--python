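"""Differential-abundance testing.

Per-OTU zero-inflated negative-binomial (ZINB) regression for treatment
enrichment/depletion with a log library-size offset, phylum-level plain-NB
contrasts, and Benjamini-Hochberg FDR control. The mean model is NB2
(variance mu + mu^2/theta) with a log link; zero inflation is a single
structural-zero probability pi (intercept-only logit). Block enters the
design as a fixed covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.discrete_model import NegativeBinomialP
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ZinbFit:
    taxon_id: str
    mu_coefs: dict[str, float]
    mu_se: dict[str, float]
    theta: float
    pi: float
    loglik: float
    converged: bool
    pvalues: dict[str, float] = field(default_factory=dict)


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical columns (drop-first), keep numerics, add
    intercept."""
    parts = [pd.Series(1.0, index=design.index, name="intercept")]
    for col in design.columns:
        s = design[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
        elif s.dtype.kind in "ifu" and s.nunique() > 2:
            parts.append(s.astype(float))
        else:
            d = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
            parts.append(d)
    return pd.concat(parts, axis=1)


def fit_zinb(
    counts_vector: pd.Series,
    design: pd.DataFrame,
    offset: np.ndarray | None = None,
    maxiter: int = 200,
) -> ZinbFit:
    """Maximum-likelihood ZINB fit of one taxon's counts.

    ``offset`` defaults to zero (pass ``np.log(library_size)`` to model
    relative abundance). Optimization is multi-start: the default
    statsmodels start, then a plain-NB warm start; the convergence flag is
    honest and non-converged fits should have their p-values ignored
    downstream.
    """
    y = counts_vector.to_numpy()
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if not y.any():
        raise ValueError(f"all counts zero for {counts_vector.name!r}")
    x = _design_matrix(design.loc[counts_vector.index])
    if len(y) < 2 * x.shape[1]:
        raise ValueError("need n >= 2 x number of coefficients")
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, float)

    names = list(x.columns)
    xm = x.to_numpy()
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        starts: list[np.ndarray | None] = [None]
        try:
            nb = NegativeBinomialP(y, xm, offset=offset).fit(disp=0, maxiter=maxiter)
            # [infl-logit, mean coefs..., alpha]; start pi near 0
            starts.append(np.concatenate([[-3.0], nb.params]))
        except Exception:
            nb = None
        for sp in starts:
            try:
                model = ZeroInflatedNegativeBinomialP(
                    y, xm, exog_infl=np.ones((len(y), 1)), offset=offset, p=2
                )
                res = model.fit(start_params=sp, disp=0, maxiter=maxiter, method="bfgs")
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf + 1e-6):
                best = res

    if best is None:
        # honest failure: report the NB fallback if any, flagged unconverged
        if nb is not None:
            alpha = float(nb.params[-1])
            return ZinbFit(
                taxon_id=str(counts_vector.name),
                mu_coefs=dict(zip(names, nb.params[:-1])),
                mu_se=dict(zip(names, nb.bse[:-1])),
                theta=1.0 / alpha if alpha > 0 else np.inf,
                pi=0.0,
                loglik=float(nb.llf),
                converged=False,
                pvalues=dict(zip(names, nb.pvalues[:-1])),
            )
        raise RuntimeError(f"ZINB fit failed for {counts_vector.name!r}")

    params = np.asarray(best.params)
    infl = params[0]
    mu = params[1 : 1 + len(names)]
    alpha = params[-1]
    se = np.asarray(best.bse)[1 : 1 + len(names)]
    pv = np.asarray(best.pvalues)[1 : 1 + len(names)]
    pi = float(1.0 / (1.0 + np.exp(-infl)))
    return ZinbFit(
        taxon_id=str(counts_vector.name),
        mu_coefs=dict(zip(names, mu)),
        mu_se=dict(zip(names, se)),
        theta=float(1.0 / alpha) if alpha > 0 else np.inf,
        pi=pi,
        loglik=float(best.llf),
        converged=bool(best.mle_retvals.get("converged", True)),
        pvalues=dict(zip(names, pv)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _term_column(x_cols: list[str], term: str) -> str:
    hits = [c for c in x_cols if c.startswith(f"{term}_")] + (
        [term] if term in x_cols else []
    )
    if not hits:
        raise KeyError(f"term {term!r} not in design columns {x_cols}")
    return hits[0]


def test_differential(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = ("block",),
    alpha: float = 0.05,
    group_col: str | None = None,
    min_prevalence: float = 0.1,
    ref_level: str | None = "well_watered",
    library_size: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-OTU ZINB Wald test of the ``term`` coefficient.

    ``ref_level`` fixes the reference level of the tested factor (default
    the well-watered arm when present, so positive coefficients mean
    drought enrichment). ``library_size`` supplies the per-sample offset
    totals — pass the *full* sample depths when ``table`` holds only a
    subset of OTUs; it defaults to the table's row sums. BH adjustment is
    applied across OTUs, within each level of ``group_col`` (e.g.
    compartment) when given. OTUs observed in fewer than
    ``min_prevalence`` of samples are skipped. Non-converged fits get
    p = 1. Returns a tidy frame (taxon, lfc, p, p_adj, direction).
    """
    meta = metadata.loc[table.index]
    cov = [c for c in covariates if c in meta.columns]
    design = meta[[term] + cov].copy()
    levels = list(pd.unique(design[term].astype(str)))
    if ref_level in levels:
        design[term] = pd.Categorical(
            design[term].astype(str),
            categories=[ref_level] + [lv for lv in sorted(levels) if lv != ref_level],
        )
    if library_size is None:
        library_size = table.sum(axis=1)
    libsize = library_size.loc[table.index].to_numpy(float)
    offset = np.log(np.maximum(libsize, 1.0))
    groups = meta[group_col] if group_col else pd.Series("all", index=meta.index)

    frames = []
    for glabel in pd.unique(groups):
        sub = table.loc[groups == glabel]
        rows = []
        for otu in sub.columns:
            y = sub[otu]
            if (y > 0).mean() < min_prevalence:
                continue
            try:
                fit = fit_zinb(y, design.loc[sub.index], offset=offset[(groups == glabel).to_numpy()])
            except (ValueError, RuntimeError):
                continue
            col = _term_column(list(fit.mu_coefs), term)
            lfc = fit.mu_coefs[col]
            p = fit.pvalues.get(col, 1.0)
            if not fit.converged or not np.isfinite(p):
                p = 1.0
            rows.append(dict(taxon_id=otu, group=glabel, log_fold_change=lfc, p_value=p))
        if not rows:
            continue
        res = pd.DataFrame(rows)
        res["p_adj"] = bh_adjust(res["p_value"].to_numpy())
        res["direction"] = np.where(
            res["p_adj"] < alpha,
            np.where(res["log_fold_change"] > 0, "enriched", "depleted"),
            "ns",
        )
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["taxon_id", "group", "log_fold_change", "p_value", "p_adj", "direction"]
        )
    return pd.concat(frames, ignore_index=True)


def phylum_enrichment(
    aggregated_table: pd.DataFrame,
    metadata: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = ("block",),
    alpha: float = 0.05,
    ref_level: str | None = "well_watered",
) -> pd.DataFrame:
    """Plain-NB (no zero inflation) treatment contrasts per phylum.

    Pairwise contrasts of each non-reference level against the reference
    (``ref_level`` when present among the term's levels); BH adjustment
    across all (phylum, contrast) tests.
    """
    meta = metadata.loc[aggregated_table.index]
    cov = [c for c in covariates if c in meta.columns]
    raw = meta[[term] + cov].copy()
    levels = list(pd.unique(raw[term].astype(str)))
    if ref_level in levels:
        raw[term] = pd.Categorical(
            raw[term].astype(str),
            categories=[ref_level] + [lv for lv in sorted(levels) if lv != ref_level],
        )
    design = _design_matrix(raw)
    libsize = aggregated_table.sum(axis=1).to_numpy(float)
    offset = np.log(np.maximum(libsize, 1.0))
    term_cols = [c for c in design.columns if c.startswith(f"{term}_")]

    rows = []
    for phylum in aggregated_table.columns:
        y = aggregated_table[phylum].to_numpy()
        if not y.any():
            warnings.warn(f"phylum {phylum!r} all-zero; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = NegativeBinomialP(y, design.to_numpy(), offset=offset).fit(
                    disp=0, maxiter=200
                )
            except Exception:
                continue
        for col in term_cols:
            j = list(design.columns).index(col)
            rows.append(
                dict(
                    taxon_id=phylum,
                    contrast=col.replace(f"{term}_", f"{term}:"),
                    log_fold_change=float(res.params[j]),
                    p_value=float(res.pvalues[j]) if np.isfinite(res.pvalues[j]) else 1.0,
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["taxon_id", "contrast", "log_fold_change", "p_value", "p_adj", "direction"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.where(
        out["p_adj"] < alpha,
        np.where(out["log_fold_change"] > 0, "enriched", "depleted"),
        "ns",
    )
    return out
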