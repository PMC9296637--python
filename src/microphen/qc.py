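"""OTU-table quality control and normalization.

The filter chain, in the order it is applied:

1. drop samples with total counts below a depth cutoff (default 10,000);
2. rescale each sample proportionally to a reference depth (default: the
   deepest sample — 617,753 for the study's deposited table);
3. drop OTUs whose rescaled counts fall outside [min_count, max_count]
   (defaults 100 / 200,000): an OTU is removed when it is below the low
   bound in *every* sample, or above the high bound in *any* sample;
4. scale each sample to relative abundance (rows sum to 1);
5. drop OTUs flagged plastid/mitochondrial/unknown by their taxonomy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class EmptyResultError(ValueError):
    """A filter removed everything."""


def _check_counts(table: pd.DataFrame) -> None:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise EmptyResultError("count table is empty")
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def filter_samples_by_depth(table: pd.DataFrame, min_total: float = 10_000) -> pd.DataFrame:
    """Retain samples with total counts >= ``min_total`` (strict less-than
    removed), preserving sample order."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    _check_counts(table)
    keep = table.sum(axis=1) >= min_total
    if not keep.any():
        raise EmptyResultError(
            f"all {len(table)} samples fall below depth {min_total}"
        )
    return table.loc[keep]


def rescale_counts(table: pd.DataFrame, ref_depth: float | None = None) -> pd.DataFrame:
    """Multiply each sample by ``ref_depth / total``.

    ``ref_depth`` defaults to the largest sample total. Values are kept
    fractional — no rounding.
    """
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ZeroDivisionError(f"zero-total sample(s): {bad}")
    if ref_depth is None:
        ref_depth = float(totals.max())
    return table.mul(ref_depth / totals, axis=0)


def filter_otus_by_bounds(
    rescaled: pd.DataFrame,
    min_count: float = 100,
    max_count: float = 200_000,
    low_bound_scope: str = "all_samples",
) -> pd.Index:
    """OTU ids surviving the rescaled-count bounds.

    Low bound: with ``low_bound_scope='all_samples'`` (default) an OTU is
    removed only when its rescaled count is below ``min_count`` in every
    sample; with ``'any_sample'`` a single sub-threshold sample suffices.
    High bound: removed when above ``max_count`` in any sample.
    """
    if min_count > max_count:
        raise ValueError("min_count must be <= max_count")
    if low_bound_scope not in {"all_samples", "any_sample"}:
        raise ValueError("low_bound_scope must be 'all_samples' or 'any_sample'")
    if low_bound_scope == "all_samples":
        too_low = (rescaled < min_count).all(axis=0)
    else:
        too_low = (rescaled < min_count).any(axis=0)
    too_high = (rescaled > max_count).any(axis=0)
    keep = ~(too_low | too_high)
    return rescaled.columns[keep]


def proportional_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample division by the sample total; rows sum to 1."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ZeroDivisionError(f"zero-total sample(s): {bad}")
    return table.div(totals, axis=0)


def taxonomy_flags(taxonomy: pd.DataFrame) -> pd.Series:
    """Per-OTU flag in {unknown, plastid, mitochondrial, ''}.

    Uses an explicit ``flag`` column when present; otherwise derives flags
    from the lineage (chloroplast/plastid/mitochondria labels, plant
    kingdoms, or an empty/unknown phylum).
    """
    if "flag" in taxonomy.columns:
        return taxonomy["flag"].fillna("").astype(str)
    lineage = taxonomy.astype(str).agg(";".join, axis=1).str.lower()
    flags = pd.Series("", index=taxonomy.index, dtype=str)
    flags[lineage.str.contains("chloroplast|plastid|streptophyta|viridiplantae")] = "plastid"
    flags[lineage.str.contains("mitochondri")] = "mitochondrial"
    phylum = taxonomy.get("phylum", pd.Series("", index=taxonomy.index)).fillna("")
    unknown = (phylum.str.strip() == "") | phylum.str.lower().eq("unknown")
    flags[unknown & (flags == "")] = "unknown"
    return flags


def remove_taxa(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    drop_flags: Iterable[str] = ("plastid", "unknown"),
) -> pd.DataFrame:
    """Drop OTUs whose taxonomy flag is in ``drop_flags``.

    OTUs with no taxonomy row are treated as ``unknown``.
    """
    drop_flags = set(drop_flags)
    if not drop_flags:
        return table
    flags = taxonomy_flags(taxonomy)
    flags = flags.reindex(table.columns, fill_value="unknown")
    keep = ~flags.isin(drop_flags)
    return table.loc[:, table.columns[keep]]


def aggregate_rank(
    table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str = "phylum"
) -> pd.DataFrame:
    """Sum counts over OTUs sharing a rank label.

    Empty labels aggregate under ``unclassified_<parent>`` where the parent
    is the nearest non-empty higher rank. Per-sample totals are preserved
    exactly.
    """
    if rank not in TAXONOMY_RANKS or rank not in taxonomy.columns:
        raise ValueError(f"invalid rank {rank!r}")
    labels = taxonomy[rank].reindex(table.columns).fillna("").astype(str)
    empties = labels.str.strip() == ""
    if empties.any():
        higher = [r for r in TAXONOMY_RANKS[: TAXONOMY_RANKS.index(rank)] if r in taxonomy.columns]
        for otu in labels.index[empties]:
            parent = "unknown"
            for r in reversed(higher):
                v = str(taxonomy.at[otu, r]) if otu in taxonomy.index else ""
                if v.strip():
                    parent = v
                    break
            labels.at[otu] = f"unclassified_{parent}"
    return table.T.groupby(labels).sum().T


def qc_pipeline(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    min_depth: float = 10_000,
    ref_depth: float | None = None,
    min_count: float = 100,
    max_count: float = 200_000,
    drop_flags: Sequence[str] = ("plastid", "unknown"),
    low_bound_scope: str = "all_samples",
) -> tuple[pd.DataFrame, dict]:
    """Full chain: depth filter -> rescale -> OTU bounds -> taxon removal ->
    proportional scaling. Returns the relative-abundance table and a tally
    of what each stage removed."""
    tally: dict = {"n_samples_in": int(table.shape[0]), "n_otus_in": int(table.shape[1])}
    kept = filter_samples_by_depth(table, min_depth)
    tally["n_samples_depth_filtered"] = int(table.shape[0] - kept.shape[0])
    rescaled = rescale_counts(kept, ref_depth)
    surviving = filter_otus_by_bounds(
        rescaled, min_count, max_count, low_bound_scope=low_bound_scope
    )
    tally["n_otus_bounds_filtered"] = int(kept.shape[1] - len(surviving))
    counts = kept.loc[:, surviving]
    if taxonomy is not None:
        before = counts.shape[1]
        counts = remove_taxa(counts, taxonomy, drop_flags)
        tally["n_otus_taxa_removed"] = int(before - counts.shape[1])
    if counts.shape[1] == 0:
        raise EmptyResultError("no OTUs survive QC")
    rel = proportional_scale(counts)
    tally["n_samples_out"] = int(rel.shape[0])
    tally["n_otus_out"] = int(rel.shape[1])
    return rel, tally
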