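"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
counts.tsv    first column ``gene``, remaining columns sample ids, integer cells
samples.tsv   columns ``sample_id``, ``group``
network.sif   ``source<TAB>interaction<TAB>target`` (2-column edge lists also accepted)
genesets.gmt  ``name<TAB>description<TAB>gene1<TAB>gene2...``
clinical.tsv  per-sample clinical parameters

All writers emit UTF-8 with ``\\n`` line endings and tab separators; readers
skip ``#`` comment lines (used by the pipeline to stamp a config hash).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, *, index: bool = False,
              header_comment: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally preceded by a ``#`` comment line."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment is not None:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(counts: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    """Counts are genes x samples; the gene index is written as a ``gene`` column."""
    out = counts.copy()
    out.index.name = "gene"
    write_tsv(out.reset_index(), path, header_comment=header_comment)


def read_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "gene"
    return df.astype(int)


def write_samples(groups: Mapping[str, str] | pd.Series, path, *,
                  header_comment: str | None = None) -> None:
    ser = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    df = pd.DataFrame({"sample_id": ser.index, "group": ser.values})
    write_tsv(df, path, header_comment=header_comment)


def read_samples(path) -> pd.Series:
    df = read_tsv(path, dtype=str)
    ser = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    ser.index.name = "sample_id"
    return ser


def write_sif(edges: Sequence[tuple[str, str]], path, *, interaction: str = "pp",
              header_comment: str | None = None) -> None:
    """SIF dialect: one ``source<TAB>interaction<TAB>target`` line per edge."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment is not None:
            fh.write(f"# {header_comment}\n")
        for u, v in edges:
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_sif(path) -> list[tuple[str, str]]:
    """Read SIF or bare 2-column edge lists; returns ordered (source, target) pairs."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 3:
                edges.append((parts[0], parts[2]))
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise ValueError(f"malformed network line: {line!r}")
    return edges


def write_gmt(sets: Mapping[str, Sequence[str]], path, *,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
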