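"""Soil/spatial/genotype calibration of phenotypes and OTU abundances.

Field measurements carry structured nuisance variation: soil chemistry
gradients, smooth spatial trends across the trial, and genotype effects.
Calibration regresses each response on the first few soil principal
components plus a spatial term and keeps the raw residuals ("calibrated"
values); genotype adjustment then removes per-genotype means. Cook's
distance flags gross outliers, and a sequential ANOVA partitions response
variance among design terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class SoilPCs:
    """Per-plot scores on the leading soil-chemistry principal components."""

    scores: pd.DataFrame                     # plots x k, columns PC1..PCk
    explained_variance: np.ndarray           # fractions, non-increasing

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class CalibratedMatrix:
    """Residual responses plus the fitted nuisance-model coefficients."""

    residuals: pd.DataFrame
    model_record: dict = field(default_factory=dict)


@dataclass
class OutlierReport:
    cooks_d: pd.Series
    cutoff: float

    @property
    def flagged(self) -> pd.Series:
        return self.cooks_d > self.cutoff


def soil_pca(soil: pd.DataFrame, k: int = 3, standardize: bool = True) -> SoilPCs:
    """PCA of the soil property panel; returns the first ``k`` plot scores.

    Columns are centered, and unit-scaled when ``standardize`` (the
    default, since soil properties mix units). Score signs are fixed so the
    largest-loading property of each component is positive.
    """
    if soil.shape[1] < k:
        raise ValueError(f"need >= {k} properties, got {soil.shape[1]}")
    if soil.shape[0] < k + 1:
        raise ValueError(f"need >= {k + 1} plots for k={k}")
    x = soil.to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("soil table contains non-finite values")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = soil.columns[sd == 0].tolist()
            raise ValueError(f"constant soil propert(ies) cannot be standardized: {bad}")
        x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x - x.mean(axis=0))
    signs = np.sign(pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)])
    scores = scores * signs
    cols = [f"PC{i + 1}" for i in range(k)]
    return SoilPCs(
        scores=pd.DataFrame(scores, index=soil.index, columns=cols),
        explained_variance=pca.explained_variance_ratio_,
    )


def _poly2_design(coordinates: pd.DataFrame) -> np.ndarray:
    r = coordinates.iloc[:, 0].to_numpy(float)
    c = coordinates.iloc[:, 1].to_numpy(float)
    return np.column_stack([r, c, r**2, c**2, r * c])


def _lstsq_residuals(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient calibration design: rank {rank} < {x.shape[1]} columns"
        )
    return y - x @ coef, coef


def calibrate_response(
    values: pd.DataFrame,
    pcs: SoilPCs | None = None,
    coordinates: pd.DataFrame | None = None,
    spatial_model: str = "poly2",
    kernel_ranges: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    nugget: float = 0.1,
) -> CalibratedMatrix:
    """Regress out soil-PC and spatial structure; keep raw residuals.

    ``spatial_model``: ``poly2`` (degree-2 polynomial in row/col fixed
    effects, default), ``none``, or ``exp_kernel`` (generalized least
    squares under an exponential spatial correlation, range profiled over
    ``kernel_ranges`` by maximum Gaussian likelihood).
    """
    if spatial_model not in {"poly2", "none", "exp_kernel"}:
        raise ValueError(f"unknown spatial_model {spatial_model!r}")
    if isinstance(values, pd.Series):
        values = values.to_frame()
    n = len(values)
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if pcs is not None:
        if not pcs.scores.index.equals(values.index):
            raise ValueError("soil PC scores misaligned with response ids")
        parts.append(pcs.scores.to_numpy(float))
        names += list(pcs.scores.columns)
    if coordinates is not None and spatial_model == "poly2":
        if not coordinates.index.equals(values.index):
            raise ValueError("coordinates misaligned with response ids")
        parts.append(_poly2_design(coordinates))
        names += ["row", "col", "row2", "col2", "rowcol"]
    x = np.column_stack(parts)
    y = values.to_numpy(float)

    if spatial_model == "exp_kernel":
        if coordinates is None:
            raise ValueError("exp_kernel needs coordinates")
        resid, coefs, best = _gls_exp_kernel(x, y, coordinates, kernel_ranges, nugget)
        record = {"terms": names, "coefficients": coefs.T.tolist(), "kernel_range": best}
    else:
        resid, coefs = _lstsq_residuals(x, y)
        record = {"terms": names, "coefficients": coefs.T.tolist()}
    out = pd.DataFrame(resid, index=values.index, columns=values.columns)
    record["spatial_model"] = spatial_model
    record["responses"] = list(values.columns)
    return CalibratedMatrix(residuals=out, model_record=record)


def _gls_exp_kernel(x, y, coordinates, ranges, nugget):
    """Exponential-kernel spatial calibration.

    The range is profiled on a coarse grid by Gaussian likelihood; fixed
    effects are fit by GLS at the best range, and the spatial random
    field's best linear unbiased prediction is subtracted, so the returned
    residuals are spatially de-trended (universal-kriging residuals)."""
    r = coordinates.iloc[:, 0].to_numpy(float)
    c = coordinates.iloc[:, 1].to_numpy(float)
    d = np.hypot(r[:, None] - r[None, :], c[:, None] - c[None, :])
    n = len(r)
    best = None
    for rng_ in ranges:
        k_sp = (1 - nugget) * np.exp(-d / rng_)
        cov = k_sp + nugget * np.eye(n)
        l_ = np.linalg.cholesky(cov)
        xs = np.linalg.solve(l_, x)
        ys = np.linalg.solve(l_, y)
        coef, _, _, _ = np.linalg.lstsq(xs, ys, rcond=None)
        res_w = ys - xs @ coef
        sigma2 = (res_w**2).sum(axis=0) / n
        logdet = 2 * np.log(np.diag(l_)).sum()
        ll = (-0.5 * (n * np.log(sigma2) + logdet + n)).sum()
        if best is None or ll > best[0]:
            best = (ll, rng_, coef, k_sp, cov)
    _, rng_, coef, k_sp, cov = best
    marginal = y - x @ coef
    spatial_blup = k_sp @ np.linalg.solve(cov, marginal)
    return marginal - spatial_blup, coef, rng_


def adjust_genotype(values: pd.DataFrame, genotype_labels: pd.Series) -> CalibratedMatrix:
    """Residuals after removing per-genotype means (one-hot regression)."""
    if isinstance(values, pd.Series):
        values = values.to_frame()
    labels = genotype_labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("genotype labels missing for some observations")
    counts = labels.value_counts()
    singletons = counts.index[counts == 1].tolist()
    if singletons:
        warnings.warn(
            f"genotype(s) with a single observation (residual forced to 0): {singletons}"
        )
    means = values.groupby(labels).transform("mean")
    resid = values - means
    record = {
        "genotype_means": values.groupby(labels).mean().to_dict(),
        "responses": list(values.columns),
    }
    return CalibratedMatrix(residuals=resid, model_record=record)


def _interaction_design(design_terms: pd.DataFrame) -> pd.DataFrame:
    combo = design_terms.astype(str).agg(":".join, axis=1)
    return pd.get_dummies(combo, drop_first=False, dtype=float)


def cooks_outliers(
    response: pd.Series,
    design_terms: pd.DataFrame,
    cutoff: float | None = None,
) -> OutlierReport:
    """Cook's distance outlier flagging on the cell-mean (full interaction)
    linear model of the design factors; default cutoff 4/n."""
    import statsmodels.api as sm

    x = _interaction_design(design_terms.loc[response.index])
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    model = sm.OLS(response.to_numpy(float), x.to_numpy())
    fit = model.fit()
    d = fit.get_influence().cooks_distance[0]
    if not np.isfinite(d).all():
        raise np.linalg.LinAlgError("Cook's distance undefined (collinear design)")
    if cutoff is None:
        cutoff = 4.0 / n
    return OutlierReport(cooks_d=pd.Series(d, index=response.index), cutoff=float(cutoff))


def sequential_ss(y: np.ndarray, term_designs: list[tuple[str, np.ndarray]]) -> dict[str, float]:
    """Type-I (sequential) sums of squares via cumulative QR projections."""
    n = len(y)
    yc = y - y.mean()
    total = float(yc @ yc)
    x = np.ones((n, 1))
    ss = {}
    prev = 0.0
    for name, cols in term_designs:
        x = np.column_stack([x, cols])
        q, _ = np.linalg.qr(x)
        fitted = q @ (q.T @ yc)
        cur = float(fitted @ fitted)
        ss[name] = cur - prev
        prev = cur
    ss["residual"] = total - prev
    ss["total"] = total
    return ss


def variance_partition(
    response: pd.Series, factors: pd.DataFrame, interactions: bool = False
) -> pd.DataFrame:
    """Share of response variance explained by each design factor.

    Sequential sum of squares per term (factor order as given, optionally
    followed by all pairwise interactions) normalized by the total sum of
    squares; the residual completes the decomposition to 1.
    """
    y = response.to_numpy(float)
    factors = factors.loc[response.index]
    terms: list[tuple[str, np.ndarray]] = []
    for colname in factors.columns:
        d = pd.get_dummies(factors[colname].astype(str), drop_first=True, dtype=float)
        terms.append((colname, d.to_numpy()))
    if interactions:
        cols = list(factors.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                combo = factors[cols[i]].astype(str) + ":" + factors[cols[j]].astype(str)
                d = pd.get_dummies(combo, drop_first=True, dtype=float)
                terms.append((f"{cols[i]}:{cols[j]}", d.to_numpy()))
    ss = sequential_ss(y, terms)
    total = ss.pop("total")
    if total == 0:
        raise ValueError("response has zero variance")
    out = pd.DataFrame(
        {"term": list(ss.keys()), "ss": list(ss.values())}
    )
    out["proportion"] = out["ss"] / total
    return out
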