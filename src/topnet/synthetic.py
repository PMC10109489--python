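"""Synthetic multi-group RNA-seq studies with planted ground truth.

Generates everything the pipeline consumes — a negative-binomial count
matrix over four groups (default sizes ARF 5, RHD 5, CHD 5, HC 2, mirroring
a small sequenced cohort), a directed scale-free interaction network whose
nodes are genes of the matrix, gene sets, a clinical table, and planted
truth (per-gene log2 fold changes and a connected perturbed module) — so
every downstream stage can be tested against known answers.

Count model
-----------
counts[g, j] ~ NB(mean = s_j * baseline_g * 2**beta_{g,k(j)}, dispersion alpha)
with Var = mu + alpha * mu**2 (alpha = 1/size in the size/prob convention).
Baselines are log-normal; s_j are per-sample library-size factors drawn
log-uniform in [0.7, 1.4] by default so normalization is non-trivial.
Sampling is gamma-Poisson, which is exact for this parameterization.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as tio
from .deg import CountMatrix
from .network import InteractionNetwork

DEFAULT_GROUP_SIZES = {"ARF": 5, "RHD": 5, "CHD": 5, "HC": 2}

#: Clinical generator conditions: (mean, sd) per group per parameter, and
#: clinical cohort sizes. These mirror the laboratory table of the study
#: population the pipeline emulates.
CLINICAL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CHD": {"neutrophil_pct": (48.48, 8.73), "lymphocyte_pct": (37.04, 7.51),
            "esr": (13.41, 11.11)},
    "RHD": {"neutrophil_pct": (58.75, 12.22), "lymphocyte_pct": (31.49, 11.53),
            "esr": (13.79, 9.89), "crp": (3.13, 2.31)},
    "ARF": {"neutrophil_pct": (59.68, 12.28), "lymphocyte_pct": (30.60, 11.01),
            "esr": (38.06, 24.75), "crp": (34.28, 31.54), "aso": (536.87, 199.28)},
}
CLINICAL_GROUP_SIZES = {"CHD": 30, "RHD": 30, "ARF": 17}


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    group: str
    log2fc: float


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``dispersion`` is the NB alpha with Var = mu + alpha * mu**2; scalar or
    per-gene vector. ``baseline_log_mean``/``baseline_log_sd`` are on the
    natural-log scale of the per-gene baseline mean.
    """

    n_genes: int = 1000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    dispersion: float | np.ndarray = 0.05
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    network_nodes: int = 300
    network_edges_per_node: int = 2
    planted_module_size: int = 20
    library_size_range: tuple[float, float] | None = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least one sample")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be strictly positive")
        if disp.ndim == 1 and disp.size != self.n_genes:
            raise ValueError("per-gene dispersion must have length n_genes")
        if self.n_genes < self.planted_module_size:
            raise ValueError("n_genes must be >= planted_module_size")
        if self.network_nodes < 2:
            raise ValueError("network needs at least 2 nodes")
        known = set(self.group_sizes)
        for eff in self.planted_effects:
            if eff.group not in known:
                raise ValueError(f"planted effect on unknown group {eff.group!r}")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i}" for g, n in self.group_sizes.items() for i in range(1, n + 1)]


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its planted truth."""

    counts: CountMatrix
    network: InteractionNetwork
    gene_sets: dict[str, list[str]]
    truth_de: pd.DataFrame  # columns gene, group, log2fc
    planted_module: list[str]
    clinical: pd.DataFrame
    config: SimulationConfig


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts for every (gene, sample) plus the planted-truth table.

    Deterministic in (config, seed); gamma-Poisson sampling realizes
    Var = mu + alpha * mu**2 exactly.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                                 size=config.n_genes))

    beta = {g: np.zeros(config.n_genes) for g in config.group_sizes}
    for eff in config.planted_effects:
        if eff.gene not in gene_pos:
            raise ValueError(f"planted effect on unknown gene {eff.gene!r}")
        beta[eff.group][gene_pos[eff.gene]] += eff.log2fc

    samples = config.sample_ids
    group_of = [g for g, n in config.group_sizes.items() for _ in range(n)]
    groups = pd.Series(group_of, index=samples, name="group")
    if config.library_size_range is not None:
        lo, hi = config.library_size_range
        size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    else:
        size_factors = np.ones(len(samples))

    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float),
                            (config.n_genes,)).copy()
    mat = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = baseline * 2.0 ** beta[groups[s]] * size_factors[j]
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        mat[:, j] = rng.poisson(lam)

    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame(
        [(e.gene, e.group, e.log2fc) for e in config.planted_effects],
        columns=["gene", "group", "log2fc"],
    )
    return CountMatrix(counts, groups), truth


def simulate_network(config: SimulationConfig) -> InteractionNetwork:
    """Directed scale-free network over the first ``network_nodes`` gene ids.

    Preferential-attachment topology (heavy-tailed degrees, as in curated
    interaction networks) with each edge oriented uniformly at random; the
    undirected skeleton is connected, so the digraph is weakly connected.
    """
    if config.network_nodes > config.n_genes:
        raise ValueError("network_nodes cannot exceed n_genes")
    rng = np.random.default_rng(config.seed + 1)
    m = min(config.network_edges_per_node, config.network_nodes - 1)
    ug = nx.barabasi_albert_graph(config.network_nodes, m,
                                  seed=int(rng.integers(2**31)))
    genes = config.gene_ids[: config.network_nodes]
    edges = []
    for a, b in sorted(ug.edges):
        u, v = (a, b) if rng.random() < 0.5 else (b, a)
        edges.append((genes[u], genes[v]))
    return InteractionNetwork.from_edges(edges)


def plant_perturbed_module(
    network: InteractionNetwork,
    size: int,
    log2fc: float,
    group: str,
    seed: int = 0,
    exclude: set[str] | None = None,
    degree_bias: str | None = None,
) -> tuple[list[str], list[PlantedEffect]]:
    """Pick a weakly-connected node set by seeded BFS and assign it a log2FC.

    ``exclude`` nodes are never entered, which keeps independently planted
    modules non-adjacent. ``degree_bias`` steers where the module lands:
    ``"low"`` starts from peripheral nodes and expands through low-degree
    neighbors (a module off the network's transit routes), ``"high"`` starts
    from hubs; ``None`` starts from a seeded random node.
    """
    exclude = exclude or set()
    candidates = [n for n in network.nodes if n not in exclude]
    if size > len(candidates):
        raise ValueError("requested module larger than the available network")
    rng = np.random.default_rng(seed)
    und = network.graph.to_undirected(as_view=True)
    deg = dict(und.degree())
    order = [str(n) for n in rng.permutation(candidates)]
    if degree_bias == "low":
        order.sort(key=lambda n: deg[n])
    elif degree_bias == "high":
        order.sort(key=lambda n: -deg[n])
    elif degree_bias is not None:
        raise ValueError("degree_bias must be None, 'low' or 'high'")
    nbr_key = (lambda v: (deg[v], v)) if degree_bias == "low" else None
    for start in order:
        seen = [start]
        seen_set = {start}
        queue = deque([start])
        while queue and len(seen) < size:
            u = queue.popleft()
            for v in sorted(und.neighbors(u), key=nbr_key):
                if v not in seen_set and v not in exclude:
                    seen.append(v)
                    seen_set.add(v)
                    queue.append(v)
                    if len(seen) == size:
                        break
        if len(seen) == size:
            effects = [PlantedEffect(g, group, log2fc) for g in seen]
            return seen, effects
    raise ValueError(f"no connected set of {size} nodes avoiding the excluded set")


def simulate_gene_sets(
    config: SimulationConfig,
    special: dict[str, list[str]] | None = None,
    n_random: int = 20,
    size_range: tuple[int, int] = (15, 50),
) -> dict[str, list[str]]:
    """A GMT-style collection: planted sets plus seeded random draws."""
    rng = np.random.default_rng(config.seed + 2)
    genes = np.array(config.gene_ids)
    sets: dict[str, list[str]] = {k: list(v) for k, v in (special or {}).items()}
    for i in range(1, n_random + 1):
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        members = sorted(rng.choice(genes, size=k, replace=False))
        sets[f"RANDOM_SET_{i:02d}"] = list(members)
    return sets


def simulate_clinical(
    seed: int = 0,
    group_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Clinical table (neutrophil %, lymphocyte %, ESR, CRP, ASO) per patient.

    Values are truncated normals with the group means/SDs of
    :data:`CLINICAL_PARAMS`; percentages are clipped to plausible ranges so
    the neutrophil-to-lymphocyte ratio is always defined.
    """
    rng = np.random.default_rng(seed + 3)
    sizes = group_sizes or dict(CLINICAL_GROUP_SIZES)
    rows = []
    for grp, n in sizes.items():
        params = CLINICAL_PARAMS.get(grp, CLINICAL_PARAMS["CHD"])
        for i in range(1, n + 1):
            row: dict[str, object] = {"sample_id": f"{grp}_clin_{i}", "group": grp}
            for name, (mean, sd) in params.items():
                val = rng.normal(mean, sd)
                if name.endswith("_pct"):
                    val = float(np.clip(val, 5.0, 95.0))
                else:
                    val = float(max(val, 0.0))
                row[name] = round(val, 3)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """The shipped end-to-end fixture.

    Plants a connected ``planted_module_size``-gene module with a net log2FC
    of 2 in the primary RHD-vs-ARF contrast, split +1 in RHD / -1 in ARF so
    neither disease group departs from healthy controls by more than 2-fold
    on those genes; plants two decoy modules in HC (log2FC -3 and +3) that
    dominate the control-comparison TopNets in both modes. Gene sets include
    the planted module, the decoys, and random sets.
    """
    if config is None:
        config = SimulationConfig(seed=0 if seed is None else seed)
    elif seed is not None:
        config = replace(config, seed=seed)

    network = simulate_network(config)
    decoy_size = config.planted_module_size  # decoys sized like the module
    # the module sits in the low-degree periphery, off the transit routes the
    # control-comparison shortest paths use; the decoys sit on the hubs those
    # paths must cross, so the control TopNets concentrate on them.
    module, eff_up = plant_perturbed_module(
        network, config.planted_module_size, 1.0, "RHD",
        seed=config.seed + 10, degree_bias="low")
    eff_dn = [PlantedEffect(g, "ARF", -1.0) for g in module]
    blocked = set(module) | {
        v for g in module for v in nx.all_neighbors(network.graph, g)
    }

    def _plant_decoy(log2fc: float, seed: int, extra: set[str]) -> tuple[list[str], list[PlantedEffect]]:
        # insulate the module's whole neighborhood when the graph allows it,
        # else fall back to excluding the module itself (small networks)
        try:
            return plant_perturbed_module(
                network, decoy_size, log2fc, "HC", seed=seed,
                exclude=blocked | extra, degree_bias="high")
        except ValueError:
            return plant_perturbed_module(
                network, decoy_size, log2fc, "HC", seed=seed,
                exclude=set(module) | extra, degree_bias="high")

    # decoy-decoy adjacency is harmless (both are control-planted), so only
    # the module stays insulated from them.
    decoy_up, eff_decoy_up = _plant_decoy(-3.0, config.seed + 11, set())
    decoy_dn, eff_decoy_dn = _plant_decoy(3.0, config.seed + 12, set(decoy_up))

    effects = list(config.planted_effects) + eff_up + eff_dn + eff_decoy_up + eff_decoy_dn
    config = replace(config, planted_effects=effects)

    counts, truth = simulate_counts(config)
    gene_sets = simulate_gene_sets(
        config,
        special={"PLANTED_MODULE": module, "DECOY_UP": decoy_up, "DECOY_DN": decoy_dn},
    )
    clinical = simulate_clinical(seed=config.seed)
    return SyntheticStudy(
        counts=counts,
        network=network,
        gene_sets=gene_sets,
        truth_de=truth,
        planted_module=module,
        clinical=clinical,
        config=config,
    )


def write_fixture(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write the whole study as plain-text files; round-trips exactly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / "counts.tsv",
        "samples": d / "samples.tsv",
        "network": d / "network.sif",
        "gene_sets": d / "genesets.gmt",
        "truth_de": d / "truth_de.tsv",
        "module": d / "module.txt",
        "clinical": d / "clinical.tsv",
    }
    tio.write_counts(study.counts.counts, paths["counts"])
    tio.write_samples(study.counts.groups, paths["samples"])
    tio.write_sif(study.network.edges, paths["network"])
    tio.write_gmt(study.gene_sets, paths["gene_sets"])
    tio.write_tsv(study.truth_de, paths["truth_de"])
    paths["module"].write_text("".join(f"{g}\n" for g in study.planted_module),
                               encoding="utf-8")
    tio.write_tsv(study.clinical, paths["clinical"])
    return paths


def read_fixture(directory) -> SyntheticStudy:
    """Read back a fixture written by :func:`write_fixture`."""
    d = Path(directory)
    counts = tio.read_counts(d / "counts.tsv")
    groups = tio.read_samples(d / "samples.tsv")
    return SyntheticStudy(
        counts=CountMatrix(counts, groups),
        network=InteractionNetwork.from_sif(d / "network.sif"),
        gene_sets=tio.read_gmt(d / "genesets.gmt"),
        truth_de=tio.read_tsv(d / "truth_de.tsv"),
        planted_module=(d / "module.txt").read_text(encoding="utf-8").split(),
        clinical=tio.read_tsv(d / "clinical.tsv"),
        config=SimulationConfig(),  # not serialized; carries defaults only
    )
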