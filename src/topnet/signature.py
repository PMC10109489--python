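"""Condition-characteristic gene signatures and sample clustering.

The characteristic signature of the primary contrast is its set of
TopNet-captured DEGs minus every gene captured by the control contrasts'
TopNets. Exclusion is by gene identity (directions are kept for reporting
but ignored for subtraction); each subtraction step is recorded in the
provenance so reported set sizes are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger(__name__)


@dataclass
class StudyDesign:
    """Named two-group comparisons, one primary and any number of controls."""

    comparisons: list[tuple[str, str, str]]  # (name, test group, reference group)
    primary: str
    controls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.comparisons]
        if len(set(names)) != len(names):
            raise ValueError("comparison names must be unique")
        if self.primary not in names:
            raise ValueError(f"primary comparison {self.primary!r} not defined")
        if self.primary in self.controls:
            raise ValueError("the primary comparison cannot be its own control")
        unknown = [c for c in self.controls if c not in names]
        if unknown:
            raise ValueError(f"unknown control comparisons: {unknown}")

    def groups_of(self, name: str) -> tuple[str, str]:
        for n, t, r in self.comparisons:
            if n == name:
                return t, r
        raise KeyError(name)


#: The four-comparison design of the emulated study: RHD vs ARF is primary,
#: each condition vs healthy controls is subtracted.
DEFAULT_DESIGN = StudyDesign(
    comparisons=[
        ("RHD_vs_ARF", "RHD", "ARF"),
        ("RHD_vs_HC", "RHD", "HC"),
        ("ARF_vs_HC", "ARF", "HC"),
        ("CHD_vs_HC", "CHD", "HC"),
    ],
    primary="RHD_vs_ARF",
    controls=["RHD_vs_HC", "ARF_vs_HC", "CHD_vs_HC"],
)


@dataclass
class SignatureSet:
    """Signature genes with their primary-contrast directions, plus provenance."""

    genes: dict[str, str]  # gene -> direction in the primary contrast
    provenance: list[dict] = field(default_factory=list)

    @property
    def up(self) -> list[str]:
        return sorted(g for g, d in self.genes.items() if d == "up")

    @property
    def down(self) -> list[str]:
        return sorted(g for g, d in self.genes.items() if d == "down")

    def __len__(self) -> int:
        return len(self.genes)


def characteristic_degs(
    primary_captured: Mapping[str, str],
    control_captured: Sequence[Mapping[str, str]],
    control_names: Sequence[str] | None = None,
) -> SignatureSet:
    """Subtract every control-captured gene from the primary captured set.

    Subtraction is by gene identity; each step's removed/remaining sizes go
    into the provenance. Monotone: enlarging any control set never enlarges
    the signature, and subtracting a set from itself leaves nothing.
    """
    names = list(control_names or [f"control_{i+1}" for i in range(len(control_captured))])
    current = dict(primary_captured)
    prov = [{"step": "primary", "size": len(current)}]
    for name, ctrl in zip(names, control_captured):
        removed = sorted(set(current) & set(ctrl))
        for g in removed:
            del current[g]
        prov.append({"step": f"minus {name}", "removed": len(removed),
                     "size": len(current)})
    return SignatureSet(genes=current, provenance=prov)


def common_degs(
    deg_set_a: Mapping[str, str],
    deg_set_b: Mapping[str, str],
) -> dict[str, str]:
    """Direction-concordant intersection of two DEG sets (up/up and down/down)."""
    return {
        g: d for g, d in deg_set_a.items()
        if deg_set_b.get(g) == d and d in ("up", "down")
    }


def direction_counts(degs: Mapping[str, str]) -> dict[str, int]:
    vals = list(degs.values())
    return {"up": vals.count("up"), "down": vals.count("down")}


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every row to mean 0, sd 1 (population sd); constant rows are dropped."""
    arr = matrix.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("dropping %d constant rows before clustering", int(constant.sum()))
    arr = (arr[~constant] - mu[~constant]) / sd[~constant]
    return pd.DataFrame(arr, index=matrix.index[~constant], columns=matrix.columns)


def cluster_samples(
    norm_counts: pd.DataFrame,
    gene_list: Sequence[str],
    *,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Hierarchically cluster samples on row-Z-scored expression of a gene list.

    Returns (leaf-order sample ids, scipy linkage matrix, z-scored matrix).
    Linkage is deterministic given the matrix; defaults are Euclidean
    distance with average linkage.
    """
    if norm_counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    missing = [g for g in gene_list if g not in norm_counts.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:5]}...")
    z = zscore_rows(norm_counts.loc[list(gene_list)])
    if z.empty:
        raise ValueError("no non-constant genes left to cluster on")
    lm = linkage(z.to_numpy().T, method=method, metric=metric)
    order = [z.columns[i] for i in leaves_list(lm)]
    return order, lm, z
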