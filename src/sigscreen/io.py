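"""Readers and writers for expression matrices, sample sheets, GMT gene
sets, signature tables and run configurations.

Supported matrix formats: dense TSV/CSV (genes as rows, header row of
sample IDs) and MatrixMarket coordinate files accompanied by
``.rownames`` / ``.colnames`` side files (one identifier per line).
All table outputs are UTF-8, tab-delimited, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from .datatypes import ExpressionDataset, GeneSetCollection, Signature, SnrTable


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(matrix_path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample matrix from TSV/CSV or MatrixMarket triplet."""
    path = Path(matrix_path)
    if path.suffix.lower() == ".mtx":
        mat = scipy.io.mmread(str(path)).toarray()
        rownames = Path(str(path) + ".rownames")
        colnames = Path(str(path) + ".colnames")
        if not rownames.exists() or not colnames.exists():
            # allow side files next to the .mtx stem as well
            rownames = path.with_suffix(".rownames")
            colnames = path.with_suffix(".colnames")
        genes = rownames.read_text().splitlines()
        samples = colnames.read_text().splitlines()
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match side files "
                f"({len(genes)} genes x {len(samples)} samples)"
            )
        return pd.DataFrame(mat, index=genes, columns=samples)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene identifiers in matrix file")
    return df


def read_expression(
    matrix_path: str | Path,
    samples_path: str | Path,
    scale: str,
    sep: str | None = None,
    uppercase_ids: bool = False,
) -> ExpressionDataset:
    """Read a matrix plus its sample sheet into a validated dataset.

    The sample sheet is a TSV/CSV whose first column holds sample IDs and
    which carries at least a ``Group`` column (``Batch`` optional).  Every
    matrix column must appear in the sheet.  Gene-ID matching elsewhere is
    exact by default; ``uppercase_ids`` folds IDs to upper case on read for
    deliberate cross-convention joins.
    """
    values = read_matrix(matrix_path, sep=sep)
    spath = Path(samples_path)
    ann = pd.read_csv(spath, sep=_infer_sep(spath, sep), index_col=0)
    ann.index = ann.index.astype(str)
    if uppercase_ids:
        values.index = values.index.str.upper()
        if values.index.duplicated().any():
            raise ValueError("uppercasing gene identifiers created duplicates")
    return ExpressionDataset(values=values, scale=scale, annotations=ann)


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path, samples_path: str | Path) -> None:
    dataset.values.to_csv(matrix_path, sep="\t")
    dataset.annotations.to_csv(samples_path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, member genes.

    Duplicate members within a set are dropped (first occurrence kept);
    duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        for g in members:
            if g:
                seen.setdefault(g)
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_signature(signature: Signature, path: str | Path, snr_table: SnrTable | None = None) -> None:
    """Write a signature as TSV ordered by ascending score.

    Columns: gene, rank_product, score, selected_by, snr (empty when no
    background dataset was supplied).
    """
    out = signature.table.copy()
    out.index.name = "gene"
    if "rank_product" not in out.columns:
        out["rank_product"] = np.nan
    if "selected_by" not in out.columns:
        out["selected_by"] = "rp"
    if snr_table is not None:
        out["snr"] = snr_table.table["snr"].reindex(out.index)
    else:
        out["snr"] = np.nan
    out = out.sort_values("score", kind="mergesort")
    out[["rank_product", "score", "selected_by", "snr"]].to_csv(path, sep="\t")


def read_signature(path: str | Path) -> Signature:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return Signature(table=df)


def write_snr_table(snr: SnrTable, path: str | Path) -> None:
    out = snr.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if Path(path).suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    return loaded or {}
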