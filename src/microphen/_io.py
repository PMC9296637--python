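"""Tabular I/O helpers.

All tables travel as pandas DataFrames. Count tables are oriented
samples x OTUs with the sample identifier in the first column of the TSV.
BIOM v1 ("JSON") tables are supported with a minimal sparse reader/writer.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samples x OTUs count table from TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_counts_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_table_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if index_col is not None:
        df.index = df.index.astype(str)
    return df


def write_table_tsv(table: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table.

    Accepts either one column per rank, or a single semicolon-delimited
    ``lineage`` column (``k__Bacteria;p__Actinobacteria;...`` or plain
    labels), which is split into the canonical ranks.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "lineage" in cols or "taxonomy" in cols:
        col = "lineage" if "lineage" in cols else "taxonomy"
        ranks = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
        split = df[col].fillna("").str.split(";", expand=True)
        split = split.iloc[:, : len(ranks)]
        split.columns = ranks[: split.shape[1]]
        for c in split.columns:
            split[c] = (
                split[c]
                .fillna("")
                .str.strip()
                .str.replace(r"^[a-z]__", "", regex=True)
            )
        out = split
        for extra in df.columns:
            if extra != col:
                out[extra] = df[extra]
        return out
    return df.fillna("")


# ---------------------------------------------------------------------------
# BIOM v1 (JSON) — minimal sparse OTU-table support
# ---------------------------------------------------------------------------

def read_biom_v1(path: str | Path) -> pd.DataFrame:
    """Read a BIOM v1 JSON OTU table into a samples x OTUs DataFrame."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    # BIOM stores observations (OTUs) as rows; we work samples x OTUs.
    return pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)


def write_biom_v1(table: pd.DataFrame, path: str | Path, table_id: str = "otu-table") -> None:
    """Write a samples x OTUs DataFrame as sparse BIOM v1 JSON."""
    dense = table.to_numpy().T  # observations x samples
    rows, cols = np.nonzero(dense)
    data = [[int(r), int(c), float(dense[r, c])] for r, c in zip(rows, cols)]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microphen",
        "date": datetime.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [int(dense.shape[0]), int(dense.shape[1])],
        "rows": [{"id": str(o), "metadata": None} for o in table.columns],
        "columns": [{"id": str(s), "metadata": None} for s in table.index],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: ``.biom``/``.json`` -> BIOM v1, else TSV."""
    p = Path(path)
    if p.suffix in {".biom", ".json"}:
        return read_biom_v1(p)
    return read_counts_tsv(p)
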