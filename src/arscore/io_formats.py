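"""Readers and writers for the file formats the pipeline touches.

Supported inputs: GMT gene-set collections (Broad dialect), expression
matrices as plain TSV (gene id column + sample header) or GCT 1.2, and
two-column sample-label TSVs. Outputs: activity matrices, generic tables,
and pathway networks as TSV edge lists or GraphML. No computation happens
here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .errors import FormatError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .correlation_network import PathwayNetwork

logger = logging.getLogger(__name__)

#: Tokens (case-insensitive) treated as missing values in expression input.
NA_TOKENS = frozenset({"", "na", "nan", "null"})

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_activity",
    "write_activity",
    "read_table",
    "write_table",
    "write_network",
]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB gene...``.

    Duplicate genes within a line are collapsed; duplicate set names are a
    format error; a line with fewer than three fields is a parse error that
    names the line number. Set order follows file line order.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = sets.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the highest mean."""
    if df.index.is_unique:
        return df
    means = df.mean(axis=1, skipna=True).to_numpy()
    order = np.argsort(-means, kind="stable")
    # first occurrence after sorting by descending mean wins
    ranked = df.iloc[order]
    kept = ranked[~ranked.index.duplicated(keep="first")]
    dropped = len(df) - len(kept)
    logger.info("collapsed %d duplicate gene rows (kept highest-mean row)", dropped)
    # restore the original first-seen gene order
    first_seen = df.index[~df.index.duplicated(keep="first")]
    return kept.loc[first_seen]


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert to float, mapping NA tokens to NaN and locating bad cells."""
    cleaned = df.copy()
    for col in cleaned.columns:
        series = cleaned[col]
        if series.dtype == object:
            stripped = series.astype(str).str.strip()
            is_na = stripped.str.lower().isin(NA_TOKENS)
            numeric = pd.to_numeric(stripped.mask(is_na), errors="coerce")
            bad = numeric.isna() & ~is_na
            if bad.any():
                gene = series.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(
                    f"{path}: non-numeric value {series[bad].iloc[0]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                )
            cleaned[col] = numeric
    return cleaned.astype(float)


def read_expression(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    ``format='tsv'``: first column gene id, header row of sample ids.
    ``format='gct'``: GCT 1.2 (version line ``#1.2``, dims line, Name and
    Description columns). NA tokens ("", NA, NaN, null; case-insensitive)
    become missing values; duplicate gene ids are collapsed by keeping the
    row with the highest mean.
    """
    if format not in {"tsv", "gct"}:
        raise ValueError(f"unknown expression format {format!r}")
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=object, keep_default_na=False)
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT dims line says {n_genes} x {n_samples} "
                f"but data block is {df.shape[0]} x {df.shape[1]}"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=object, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df = _coerce_numeric(df, path)
    return _collapse_duplicate_genes(df)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV of ``sample_id TAB group_label``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, label)")
    labels = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="label")
    labels.index.name = "sample_id"
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def write_activity(activity: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    """Write an activity matrix (pathways as rows) as TSV.

    Values are printed with 17 significant digits so a write/read round trip
    is lossless to beyond 12 significant digits.
    """
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        activity.to_csv(fh, sep="\t", index_label="pathway", float_format="%.17g")


def read_activity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "pathway"
    return df.astype(float)


def write_table(table: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    """Write a generic results table as TSV with a header row."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", float_format="%.17g")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_network(
    network: "PathwayNetwork",
    path: str | Path,
    format: str = "tsv",
    header: list[str] | None = None,
) -> None:
    """Write a pathway network as a TSV edge list or GraphML.

    Edge-list rows are ``pathway_a pathway_b rho sign`` with
    ``pathway_a < pathway_b`` lexicographically and rows sorted, so output
    is deterministic. An empty network yields a header-only file.
    """
    if format == "graphml":
        import networkx as nx

        graph = nx.Graph()
        for node, size in network.nodes.items():
            graph.add_node(node, size=int(size) if size is not None else 0)
        for a, b, rho, sign in network.edges:
            graph.add_edge(a, b, rho=float(rho), sign=sign)
        nx.write_graphml(graph, path)
        return
    if format != "tsv":
        raise ValueError(f"unknown network format {format!r}")
    rows = []
    for a, b, rho, sign in network.edges:
        a, b = sorted((a, b))
        rows.append((a, b, rho, sign))
    rows.sort()
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("pathway_a\tpathway_b\trho\tsign\n")
        for a, b, rho, sign in rows:
            fh.write(f"{a}\t{b}\t{rho!r}\t{sign}\n")
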