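"""Readers and writers for the pipeline's plain-text file formats.

All formats are UTF-8 tab-separated text: expression matrices (genes x
samples, first column gene ids, first row sample header), detection
p-value matrices of identical shape, GMT gene-set files, two-column
sample->group tables, four-column gene annotation tables, and generic
result tables.  Readers validate eagerly and fail with coordinates; missing
values are a hard error (microarray summaries are complete), never imputed.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_detection_matrix",
    "read_gmt",
    "write_gmt",
    "read_sample_groups",
    "write_sample_groups",
    "read_annotations",
    "write_annotations",
    "write_results_table",
]


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        out[col] = converted
    return out


def read_expression_matrix(
    path: str | Path, scale: str = "log2", offset: float = 0.0
) -> ExpressionDataset:
    """Read a genes x samples expression TSV into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        Tab-separated text file; first row sample header, first column gene
        identifiers, numeric body.
    scale
        ``"log2"`` if the file already holds log2 values (the internal
        canonical scale), ``"linear"`` to apply ``log2(x + offset)``.
    offset
        Pseudo-value added before the log2 transform of linear input.
    """
    if scale not in ("log2", "linear"):
        raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")
    df = _read_matrix(path)
    ds = ExpressionDataset(df, provenance=[f"read_expression_matrix({Path(path).name}, scale={scale})"])
    if scale == "linear":
        from .preprocess import log2_transform

        ds = log2_transform(ds, offset=offset)
    return ds


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.values.to_csv(path, sep="\t", float_format="%.8g", index_label="gene")


def read_detection_matrix(path: str | Path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Attach a detection p-value matrix (same shape/labels as the expression matrix)."""
    dp = _read_matrix(path)
    from dataclasses import replace

    return replace(dataset, detection_p=dp.loc[dataset.values.index, dataset.values.columns]
                   if set(dp.index) >= set(dataset.values.index) and set(dp.columns) >= set(dataset.values.columns)
                   else dp)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...`` per line.

    Duplicate genes within a set are removed with a logged warning; a
    duplicate set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen: dict[str, None] = {}
            dropped = 0
            for g in genes:
                if g in seen:
                    dropped += 1
                else:
                    seen[g] = None
            if dropped:
                logger.warning("%s:%d: set %r contained %d duplicate gene(s); removed", path, lineno, name, dropped)
            sets[name] = tuple(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names:
            fields = [name, collection.description(name), *collection.members(name)]
            fh.write("\t".join(fields) + "\n")


def read_sample_groups(
    path: str | Path, dataset: ExpressionDataset, condition: str | None = None
) -> ExpressionDataset:
    """Attach a two-column ``sample TAB group`` table to a dataset.

    Row order in the file is irrelevant; every dataset sample must be
    labeled and every labeled sample must exist in the dataset.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample {dup!r} in group file")
    mapping = pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())
    out = dataset.with_groups(mapping, condition=condition)
    counts = out.groups.value_counts().to_dict()
    logger.info("attached groups: %s", counts)
    return out


def write_sample_groups(dataset: ExpressionDataset, path: str | Path) -> None:
    if dataset.groups is None:
        raise ValueError("dataset has no groups to write")
    dataset.groups.rename_axis("sample").rename("group").to_csv(
        path, sep="\t", header=False
    )


def read_annotations(path: str | Path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Attach a four-column annotation TSV: gene, symbol, chromosome, multi_mapped (0/1)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene", "symbol", "chromosome", "multi_mapped"],
        dtype={"gene": str, "symbol": str, "chromosome": str},
    )
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r} in annotation file")
    ann = df.set_index("gene")
    if not set(ann["multi_mapped"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: multi_mapped must be 0 or 1")
    from dataclasses import replace

    return replace(dataset, annotations=ann)


def write_annotations(dataset: ExpressionDataset, path: str | Path) -> None:
    if dataset.annotations is None:
        raise ValueError("dataset has no annotations to write")
    dataset.annotations.rename_axis("gene").to_csv(path, sep="\t", header=False)


def write_results_table(
    records: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str] = (),
    index: bool = True,
) -> None:
    """Write a result table as TSV with >= 6 significant digits and stable row order.

    ``header_lines`` are emitted first as ``#``-prefixed comment lines (used
    for provenance: config hash, seed, package version).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    if records.shape[0] == 0:
        raise ValueError("refusing to write an empty result table")
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", float_format="%.8g", index=index)
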