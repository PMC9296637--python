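"""Synthetic drought-trial experiments with planted ground truth.

Generates the four linked tables the analysis pipeline consumes — plot
layout, soil chemistry, OTU counts, plant phenotypes — with the statistical
structure the downstream stages assume:

* split-plot layout (replicate blocks x watering treatments, plus genotypes
  in field mode or SynCom arms in phenotyper mode);
* spatially autocorrelated soil properties driven by shared smooth latent
  fields over the plot grid;
* compositional, overdispersed, zero-inflated counts from a log-normal
  baseline community, with multiplicative treatment/compartment effects on
  designated OTUs;
* phenotypes assembled from genotype, drought, soil-PC, spatial-trend and
  hinge-shaped OTU-abundance contributions plus Gaussian noise.

Every planted parameter is recorded in :class:`SyntheticTruth`, the recovery
oracle for the pipeline's tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: the soil chemistry panel measured across the field
SOIL_PROPERTIES = (
    "ph", "cation_sum", "base_saturation", "soluble_salts", "organic_matter",
    "nitrate_n", "phosphorus", "potassium", "calcium", "magnesium",
    "sodium", "sulfur", "zinc", "iron", "manganese", "copper",
)

PHENOTYPER_PHENOTYPES = ("area", "fresh_weight")
FIELD_PHENOTYPES = ("height", "dry_weight")


@dataclass
class CausalOTU:
    """One planted abundance-threshold effect on a set of phenotypes.

    The slope can be given absolutely (``beta``, phenotype units per unit
    relative abundance) or relatively (``effect_sd``: the phenotype change
    accumulated between the threshold and the 99th-percentile abundance,
    in residual-noise standard deviations); the relative form is resolved
    against the realized abundance distribution when phenotypes are
    simulated, which keeps planted effects detectable regardless of how
    rare the OTU happens to be.
    """

    otu_id: str
    phenotypes: tuple[str, ...]
    beta: float | None = None        # post-threshold slope (per phenotype)
    sign: str = "-"                  # used when beta is resolved from effect_sd
    effect_sd: float = 4.0
    tau_quantile: float = 0.6        # threshold as a quantile of realized abundance
    tau: float | None = None         # resolved threshold on the abundance scale

    def __post_init__(self) -> None:
        if self.beta is not None:
            self.sign = "+" if self.beta > 0 else "-"


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic experiment."""

    causal_otus: list[CausalOTU] = field(default_factory=list)
    soil_effect_coefs: dict[str, list[float]] = field(default_factory=dict)
    spatial_params: dict[str, dict[str, float]] = field(default_factory=dict)
    treatment_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    otu_treatment_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    genotype_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float = 2.0          # NB size theta (var = mu + mu^2/theta)
    zero_inflation: float = 0.1      # per-cell structural-zero probability pi
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be > 0")

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["causal_otus"] = [CausalOTU(**c) for c in doc.get("causal_otus", [])]
        return cls(**doc)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def simulate_layout(
    n_blocks: int = 8,
    genotypes: Sequence[str] = ("BTx623",),
    watering: Sequence[str] = ("well_watered", "drought"),
    microbe_treatments: Sequence[str] | None = None,
    grid_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a split-plot trial layout.

    Each block occupies one horizontal band of the grid, split into
    contiguous main plots for the watering treatments (randomized side per
    block); genotype x SynCom subplots are randomized within each main plot.

    Returns a DataFrame indexed by ``plot_id`` with columns ``block``,
    ``row``, ``col``, ``watering``, ``genotype`` and (when SynCom arms are
    given) ``microbe_treatment``.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    arms = list(microbe_treatments) if microbe_treatments else [None]
    sub = [(g, m) for g in genotypes for m in arms]
    n_cols = len(sub)
    n_rows = n_blocks * len(watering)
    if grid_shape is not None:
        if grid_shape[0] < n_rows or grid_shape[1] < n_cols:
            raise ValueError(
                f"grid {grid_shape} too small for {n_rows} rows x {n_cols} cols"
            )
        n_rows, n_cols_grid = grid_shape
    rows = []
    plot = 0
    for b in range(1, n_blocks + 1):
        w_order = list(watering)
        rng.shuffle(w_order)
        for wi, w in enumerate(w_order):
            r = (b - 1) * len(watering) + wi
            order = rng.permutation(len(sub))
            for c, k in enumerate(order):
                g, m = sub[k]
                plot += 1
                rec = {
                    "plot_id": f"P{plot:04d}",
                    "block": b,
                    "row": r,
                    "col": c,
                    "watering": w,
                    "genotype": g,
                }
                if m is not None:
                    rec["microbe_treatment"] = m
                rows.append(rec)
    out = pd.DataFrame(rows).set_index("plot_id")
    return out


def expand_field_compartments(
    layout: pd.DataFrame,
    compartments: Sequence[str] = ("root", "rhizosphere", "soil"),
) -> pd.DataFrame:
    """One microbiome sample per (plot, compartment) for field mode."""
    frames = []
    for comp in compartments:
        f = layout.copy()
        f["compartment"] = comp
        f.index = [f"{p}_{comp}" for p in layout.index]
        f["plot_id"] = layout.index
        frames.append(f)
    out = pd.concat(frames)
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# soil
# ---------------------------------------------------------------------------

def _poly2(row: np.ndarray, col: np.ndarray, coefs: Mapping[str, float]) -> np.ndarray:
    return (
        coefs.get("const", 0.0)
        + coefs.get("row", 0.0) * row
        + coefs.get("col", 0.0) * col
        + coefs.get("row2", 0.0) * row**2
        + coefs.get("col2", 0.0) * col**2
        + coefs.get("rowcol", 0.0) * row * col
    )


def simulate_soil_field(
    layout: pd.DataFrame,
    properties: Sequence[str] = SOIL_PROPERTIES,
    gradient_params: Sequence[Mapping[str, float]] | None = None,
    noise_sd: float = 0.3,
    n_latent: int = 2,
    kernel: str | None = None,
    kernel_range: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate spatially structured soil chemistry on the plot grid.

    Each property is a loading on ``n_latent`` shared smooth latent fields
    (degree-2 polynomial trends by default, or an exponential-kernel
    Gaussian random field when ``kernel='exp'``) plus independent Gaussian
    noise, so properties are spatially autocorrelated and mutually
    correlated — the structure the soil-PCA calibration removes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(properties) < 2:
        raise ValueError("need >= 2 soil properties")
    rng = np.random.default_rng(seed)
    row = layout["row"].to_numpy(float)
    col = layout["col"].to_numpy(float)
    # scale coordinates to [0,1] so gradient magnitudes are grid-free
    rs = row / max(row.max(), 1.0)
    cs = col / max(col.max(), 1.0)
    n = len(layout)

    if gradient_params is not None:
        n_latent = len(gradient_params)
    latents = np.empty((n, n_latent))
    for k in range(n_latent):
        if kernel == "exp":
            d = np.hypot(row[:, None] - row[None, :], col[:, None] - col[None, :])
            cov = np.exp(-d / kernel_range)
            latents[:, k] = rng.multivariate_normal(np.zeros(n), cov)
        else:
            if gradient_params is not None:
                coefs = gradient_params[k]
            else:
                names = ("const", "row", "col", "row2", "col2", "rowcol")
                coefs = dict(zip(names, rng.normal(0, 1, size=6)))
            latents[:, k] = _poly2(rs, cs, coefs)

    loadings = rng.normal(0, 1, size=(n_latent, len(properties)))
    vals = latents @ loadings + rng.normal(0, noise_sd, size=(n, len(properties)))
    soil = pd.DataFrame(vals, index=layout.index, columns=list(properties))
    soil.index.name = "plot_id"
    return soil


# ---------------------------------------------------------------------------
# hinge response
# ---------------------------------------------------------------------------

def hinge_response(x, tau: float, beta: float):
    """Flat-then-linear response: 0 for x <= tau, beta*(x - tau) beyond.

    Continuous at the threshold; the elementary building block of the
    change-point association model.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x > tau, beta * (x - tau), 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    layout: pd.DataFrame,
    truth: SyntheticTruth,
    n_otus: int = 500,
    depth_range: tuple[int, int] = (20_000, 80_000),
    meanlog: float = 0.0,
    sdlog: float = 1.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a samples x OTUs count table.

    Baseline OTU abundances are log-normal (heavy-tailed rank-abundance
    curve). Per sample, OTUs designated in ``truth.otu_treatment_effects``
    receive multiplicative fold-changes keyed ``"column:level"`` (e.g.
    ``"watering:drought"``). Counts are Dirichlet-multinomial at the drawn
    depth (gamma weights with shape ``truth.dispersion``; ``theta = inf``
    degenerates to exact multinomial), then zero-inflated per cell with
    probability ``truth.zero_inflation``.

    Returns ``(counts, latent)`` where ``latent`` holds the per-sample
    latent relative abundances after treatment effects.
    """
    if not (0 <= truth.zero_inflation < 1):
        raise ValueError("zero_inflation must be in [0, 1)")
    if depth_range[0] <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    base = rng.lognormal(meanlog, sdlog, size=n_otus)
    # planted causal microbes are modeled as established colonizers: a
    # threshold association is only defined for taxa the survey detects,
    # so their baseline is floored at the community's 75th percentile
    planted = [c.otu_id for c in truth.causal_otus] + list(truth.otu_treatment_effects)
    if planted:
        floor = np.quantile(base, 0.75)
        for otu in planted:
            j = otu_ids.index(otu)
            base[j] = max(base[j], floor)

    logfold = np.zeros((len(layout), n_otus))
    col_of = {o: j for j, o in enumerate(otu_ids)}
    for otu, effects in truth.otu_treatment_effects.items():
        if otu not in col_of:
            raise ValueError(f"unknown causal OTU id {otu!r}")
        j = col_of[otu]
        for key, fold in effects.items():
            column, level = key.split(":")
            mask = (layout[column] == level).to_numpy()
            logfold[mask, j] += np.log(fold)

    props = base[None, :] * np.exp(logfold)
    props = props / props.sum(axis=1, keepdims=True)

    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=len(layout))
    theta = truth.dispersion
    counts = np.empty((len(layout), n_otus), dtype=np.int64)
    for i in range(len(layout)):
        p = props[i]
        if np.isfinite(theta):
            w = rng.gamma(theta, 1.0 / theta, size=n_otus)
            p = p * w
            p = p / p.sum()
        counts[i] = rng.multinomial(depths[i], p)
    if truth.zero_inflation > 0:
        drop = rng.random(counts.shape) < truth.zero_inflation
        counts[drop] = 0

    idx = layout.index.copy()
    counts_df = pd.DataFrame(counts, index=idx, columns=otu_ids)
    latent_df = pd.DataFrame(props, index=idx, columns=otu_ids)
    counts_df.index.name = latent_df.index.name = "sample_id"
    return counts_df, latent_df


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def resolve_effects(
    truth: SyntheticTruth, abundance: pd.DataFrame, noise_sd: float
) -> None:
    """Resolve relative causal parameters against realized abundances.

    Thresholds land at the stated quantile of each causal OTU's realized
    abundance (guaranteed inside the observed support); slopes given as
    ``effect_sd`` become absolute so the phenotype change over the
    post-threshold abundance range equals ``effect_sd * noise_sd``.
    """
    for c in truth.causal_otus:
        x = abundance[c.otu_id].to_numpy(float)
        if c.tau is None:
            c.tau = float(np.quantile(x, c.tau_quantile))
        if c.beta is None:
            span = float(np.quantile(x, 0.99) - c.tau)
            if span <= 0:
                span = float(max(x.max() - c.tau, np.finfo(float).eps))
            mag = c.effect_sd * max(noise_sd, np.finfo(float).eps) / span
            c.beta = mag if c.sign == "+" else -mag


def simulate_phenotypes(
    layout: pd.DataFrame,
    soil: pd.DataFrame | None,
    abundance: pd.DataFrame,
    truth: SyntheticTruth,
    phenotypes: Sequence[str] = PHENOTYPER_PHENOTYPES,
    noise_sd: float = 0.5,
    shared_noise_sd: float = 0.0,
    intercept: float = 10.0,
    n_soil_pcs: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble phenotypes from the planted contributions.

    ``phenotype = intercept + genotype + drought/microbe + soil-PC + spatial
    trend + sum of hinge responses of causal OTU abundances + noise``.
    ``shared_noise_sd`` adds a latent per-plant vigor term common to both
    phenotypes, inducing the within-plant correlation real paired size
    measurements show.
    """
    if not layout.index.equals(abundance.index):
        raise ValueError("layout and abundance sample ids are misaligned")
    if soil is not None and not layout.index.equals(soil.index):
        raise ValueError("layout and soil plot ids are misaligned")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n = len(layout)
    resolve_effects(truth, abundance, noise_sd)

    soil_pcs = None
    if soil is not None and truth.soil_effect_coefs:
        x = soil.to_numpy(float)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
        # principal axes of the soil panel (deterministic sign: max-|.| positive)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
        soil_pcs = (x @ vt.T * signs)[:, :n_soil_pcs]

    rs = layout["row"].to_numpy(float) / max(layout["row"].max(), 1)
    cs = layout["col"].to_numpy(float) / max(layout["col"].max(), 1)

    shared = rng.normal(0, shared_noise_sd, size=n) if shared_noise_sd > 0 else 0.0

    out = {}
    for ph in phenotypes:
        y = np.full(n, float(intercept))
        for col, eff in truth.treatment_effects.get(ph, {}).items():
            column, level = col.split(":")
            y += eff * (layout[column] == level).to_numpy(float)
        for geno, eff in truth.genotype_effects.get(ph, {}).items():
            y += eff * (layout["genotype"] == geno).to_numpy(float)
        if soil_pcs is not None and ph in truth.soil_effect_coefs:
            coefs = np.asarray(truth.soil_effect_coefs[ph], dtype=float)
            y += soil_pcs[:, : len(coefs)] @ coefs
        if ph in truth.spatial_params:
            y += _poly2(rs, cs, truth.spatial_params[ph])
        for c in truth.causal_otus:
            if ph in c.phenotypes:
                y += hinge_response(abundance[c.otu_id].to_numpy(), c.tau, c.beta)
        y += shared + rng.normal(0, noise_sd, size=n)
        out[ph] = y
    df = pd.DataFrame(out, index=layout.index)
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """Bundle of all tables of one simulated trial plus its ground truth."""

    layout: pd.DataFrame
    soil: pd.DataFrame | None
    counts: pd.DataFrame
    latent_abundance: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path, biom: bool = False) -> None:
        from . import _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_counts_tsv(self.counts, outdir / "counts.tsv")
        if biom:
            _io.write_biom_v1(self.counts, outdir / "counts.biom")
        self.layout.to_csv(outdir / "metadata.tsv", sep="\t")
        if self.soil is not None:
            self.soil.to_csv(outdir / "soil.tsv", sep="\t")
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
        self.truth.to_json(outdir / "truth.json")


def default_truth(
    mode: str = "phenotyper",
    n_causal: int = 10,
    n_otus: int = 500,
    effect_sd: float = 4.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Study-condition defaults for a planted-truth experiment.

    Half the causal OTUs get negative, half positive post-threshold slopes
    on both phenotypes of the mode; slope magnitudes are resolved so the
    phenotype change over the post-threshold abundance range is
    ``effect_sd`` residual-noise standard deviations (comfortably above
    the 3-sigma detectability floor).
    """
    phen = PHENOTYPER_PHENOTYPES if mode == "phenotyper" else FIELD_PHENOTYPES
    rng = np.random.default_rng(seed)
    causal_idx = rng.choice(np.arange(20, n_otus), size=n_causal, replace=False)
    causal = []
    for k, j in enumerate(sorted(causal_idx)):
        causal.append(
            CausalOTU(
                otu_id=f"OTU{j + 1:04d}",
                phenotypes=tuple(phen),
                sign="-" if k % 2 == 0 else "+",
                effect_sd=effect_sd,
                tau_quantile=0.5,
            )
        )
    treatment_effects = {ph: {"watering:drought": -2.0} for ph in phen}
    spatial = {ph: {"row": 1.0, "col": 0.5, "row2": -0.5} for ph in phen}
    soil_coefs = {ph: [0.8, -0.5, 0.3] for ph in phen} if mode == "field" else {}
    # a couple of drought-responsive OTUs for the differential-abundance stage
    otu_fx = {"OTU0005": {"watering:drought": 4.0}, "OTU0011": {"watering:drought": 0.25}}
    return SyntheticTruth(
        causal_otus=causal,
        soil_effect_coefs=soil_coefs,
        spatial_params=spatial,
        treatment_effects=treatment_effects,
        otu_treatment_effects=otu_fx,
        dispersion=2.0,
        zero_inflation=0.1,
        seed=seed,
    )


def simulate_experiment(
    mode: str = "phenotyper",
    n_blocks: int = 8,
    n_replicates: int = 6,
    genotypes: Sequence[str] | None = None,
    n_otus: int = 500,
    truth: SyntheticTruth | None = None,
    noise_sd: float = 0.5,
    shared_noise_sd: float = 0.3,
    depth_range: tuple[int, int] = (20_000, 80_000),
    seed: int = 0,
) -> SyntheticExperiment:
    """Simulate one complete experiment in ``phenotyper`` or ``field`` mode.

    Phenotyper mode: ``n_blocks`` greenhouse blocks x 2 watering x 4 SynCom
    arms (control/A/B/BV) x ``n_replicates`` replicate slots — the default
    8 x 6 gives 48 pots per (SynCom, watering) arm, the scale of a real
    high-throughput phenotyping run. Field mode: 8 blocks x 2 watering x
    genotypes, soil chemistry table included.
    """
    if mode not in {"phenotyper", "field"}:
        raise ValueError("mode must be 'phenotyper' or 'field'")
    if truth is None:
        truth = default_truth(mode=mode, n_otus=n_otus, seed=seed)
    truth.seed = seed
    if mode == "phenotyper":
        layout = simulate_layout(
            n_blocks=n_blocks,
            genotypes=[f"rep{r + 1}" for r in range(n_replicates)],
            microbe_treatments=("control", "A", "B", "BV"),
            seed=seed,
        )
        # replicate slots are not genotypes; drop the label to plain replicate
        layout = layout.rename(columns={"genotype": "replicate"})
        layout["genotype"] = "BTx623"
        soil = None
        phen = PHENOTYPER_PHENOTYPES
    else:
        genotypes = genotypes or [f"G{i + 1:02d}" for i in range(24)]
        layout = simulate_layout(n_blocks=n_blocks, genotypes=genotypes, seed=seed)
        soil = simulate_soil_field(layout, seed=seed + 1)
        phen = FIELD_PHENOTYPES
        if truth.genotype_effects == {}:
            rng = np.random.default_rng(seed + 2)
            truth.genotype_effects = {
                ph: {g: float(e) for g, e in zip(genotypes, rng.normal(0, 1, len(genotypes)))}
                for ph in phen
            }
    counts, latent = simulate_counts(
        layout, truth, n_otus=n_otus, depth_range=depth_range, seed=seed + 10
    )
    rel = counts.div(counts.sum(axis=1), axis=0)
    phenos = simulate_phenotypes(
        layout, soil, rel, truth,
        phenotypes=phen, noise_sd=noise_sd,
        shared_noise_sd=shared_noise_sd, seed=seed + 20,
    )
    return SyntheticExperiment(layout, soil, counts, rel, phenos, truth)


def synthetic_taxonomy(
    otu_ids: Sequence[str], seed: int = 0, protect: Sequence[str] = ()
) -> pd.DataFrame:
    """Invent a taxonomy table for simulated OTUs.

    A handful of phyla/genera drawn from the taxa the sorghum studies
    report, plus a small fraction flagged plastid or unknown so the QC
    removal step has work to do. OTUs in ``protect`` (typically the
    planted-truth OTUs, which must stay analyzable downstream) always get
    a real bacterial lineage.
    """
    rng = np.random.default_rng(seed)
    protect = set(protect)
    phyla = ["Proteobacteria", "Actinobacteria", "Bacteroidetes", "Firmicutes", "Acidobacteria"]
    genera = {
        "Proteobacteria": ["Variovorax", "Pseudomonas", "Noviherbaspirillum", "Pseudolabrys", "Nordella"],
        "Actinobacteria": ["Arthrobacter", "Marmoricola", "Streptomyces"],
        "Bacteroidetes": ["Flavobacterium", "Chitinophaga"],
        "Firmicutes": ["Paenibacillus", "Bacillus"],
        "Acidobacteria": ["Granulicella"],
    }
    rows = []
    for o in otu_ids:
        u = rng.random()
        if o in protect:
            u = 1.0
        if u < 0.02:
            rows.append({"otu_id": o, "kingdom": "Bacteria", "phylum": "", "genus": "", "flag": "unknown"})
        elif u < 0.04:
            rows.append({"otu_id": o, "kingdom": "Viridiplantae", "phylum": "Streptophyta", "genus": "", "flag": "plastid"})
        else:
            p = phyla[rng.integers(len(phyla))]
            g = genera[p][rng.integers(len(genera[p]))]
            rows.append({"otu_id": o, "kingdom": "Bacteria", "phylum": p, "genus": g, "flag": ""})
    return pd.DataFrame(rows).set_index("otu_id")
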