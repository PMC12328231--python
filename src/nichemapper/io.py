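"""File input/output for every table the pipeline consumes or emits.

Counts travel as TSV (genes in rows, header of sample IDs) or MatrixMarket
coordinate files with genes.tsv / cells.tsv sidecars; screen, ligand-receptor,
survival and dose-response tables are plain TSV with documented columns; gene
sets load from GMT. Numeric exports are fixed to six significant digits so
reruns diff byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts_tsv",
    "write_counts_mtx",
    "read_table",
    "read_gene_list",
    "read_gmt",
    "format_sig",
    "write_report_json",
]

# required columns per documented TSV schema
TABLE_SCHEMAS = {
    "screen": ("gene", "guide", "log2fc"),
    "lr": ("ligand", "receptor"),
    "survival": ("id", "time", "event", "expression"),
    "dose_response": ("dose", "fa"),
    "cell_meta": ("cell_id", "population", "stage"),
}


def _require_file(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    if p.stat().st_size == 0:
        raise ValueError(f"empty input file: {p}")
    return p


def read_counts(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a gene x sample (or cell x gene) integer count matrix.

    ``fmt="tsv"``: first column gene IDs, header = sample IDs.
    ``fmt="mtx"``: MatrixMarket coordinate file; row (genes.tsv) and column
    (cells.tsv) sidecars are looked up next to it. Duplicate IDs, ragged
    rows and non-integer values are rejected with the offending location.
    """
    p = _require_file(path)
    if fmt == "tsv":
        try:
            df = pd.read_csv(p, sep="\t", index_col=0)
        except pd.errors.ParserError as err:
            raise ValueError(f"{p}: malformed TSV ({err})") from err
        if df.shape[1] == 0:
            raise ValueError(f"{p}: no sample columns")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"{p}: duplicate gene ID {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[df.dtypes == object][0]
            raise ValueError(f"{p}: non-numeric values in column {bad!r}")
        if np.any(arr != np.floor(arr)):
            gi, si = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"{p}: non-integer count at gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r} (data line {gi + 2})"
            )
        if np.any(arr < 0):
            raise ValueError(f"{p}: negative counts")
        return df.astype(np.int64)
    if fmt == "mtx":
        genes_p = p.with_name("genes.tsv")
        cells_p = p.with_name("cells.tsv")
        _require_file(genes_p)
        _require_file(cells_p)
        genes = pd.read_csv(genes_p, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(cells_p, sep="\t", header=None)[0].tolist()
        try:
            mat = spio.mmread(p)
        except ValueError as err:
            raise ValueError(f"{p}: malformed MatrixMarket entry ({err})") from err
        mat = sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{p}: matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes x {len(cells)} cells)"
            )
        if len(set(genes)) != len(genes):
            raise ValueError(f"{genes_p}: duplicate gene IDs")
        dense = np.asarray(mat.todense())
        if np.any(dense != np.floor(dense)):
            raise ValueError(f"{p}: non-integer counts")
        return pd.DataFrame(
            dense.astype(np.int64), index=pd.Index(genes, name="gene"), columns=cells
        )
    raise ValueError(f"unknown counts format {fmt!r} (use 'tsv' or 'mtx')")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    """Write MatrixMarket + genes.tsv/cells.tsv sidecars next to ``path``."""
    p = Path(path)
    spio.mmwrite(p.with_suffix(".mtx"), sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        p.with_name("genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(counts.columns).to_csv(
        p.with_name("cells.tsv"), sep="\t", index=False, header=False
    )


def read_table(path, kind: str) -> pd.DataFrame:
    """Read one of the documented TSV schemas (see ``TABLE_SCHEMAS``)."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{p}: missing required column(s) {', '.join(missing)}")
    if kind == "survival":
        bad = set(df["event"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"{p}: event values must be 0/1, found {sorted(bad)}")
        if (df["time"] < 0).any():
            raise ValueError(f"{p}: negative survival times")
    return df


def read_gene_list(path) -> list:
    """One gene per line; '#' comments and blank lines ignored."""
    p = _require_file(path)
    out = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> genes..."""
    p = _require_file(path)
    sets = {}
    for i, line in enumerate(p.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{p}: line {i}: GMT needs name, description, genes")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def format_sig(x, digits: int = 6) -> float:
    """Round to ``digits`` significant digits for byte-stable exports."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _round_tree(obj, digits=6):
    if isinstance(obj, dict):
        return {k: _round_tree(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return format_sig(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report_json(report: dict, path) -> None:
    """Serialize a report dict with 6-significant-digit floats, sorted keys."""
    Path(path).write_text(
        json.dumps(_round_tree(report), indent=2, sort_keys=True) + "\n"
    )
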