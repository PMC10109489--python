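"""End-to-end orchestration: DE -> condition networks -> TopNets -> signature.

``analyze`` is the in-memory core; ``run_pipeline`` wraps it with file I/O,
input validation, provenance (a config hash stamped on every output) and
deterministic, byte-reproducible artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as tio
from .clinical import pairwise_tests, summarize_groups
from .deg import CountMatrix, call_degs, deg_table, estimate_size_factors, wald_test
from .enrichment import GeneSetCollection, fisher_enrichment
from .network import InteractionNetwork, TopNet, mine_topnet
from .signature import DEFAULT_DESIGN, SignatureSet, StudyDesign, characteristic_degs, cluster_samples

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    counts: str
    samples: str
    network: str
    gene_sets: str | None = None
    clinical: str | None = None
    design: StudyDesign = field(default_factory=lambda: DEFAULT_DESIGN)
    fold_threshold: float = 2.0
    alpha: float = 0.05
    use_adjusted: bool = False
    path_fraction: float | None = 0.005
    permutation_k: int | None = None  # if set, use permutation threshold instead
    permutation_alpha: float = 0.01
    undirected: bool = False
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    make_heatmap: bool = True
    seed: int = 0
    out_dir: str = "topnet_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        design_raw = raw.pop("design", None)
        cfg = cls(**raw)
        if design_raw is not None:
            cfg.design = StudyDesign(
                comparisons=[tuple(c) for c in design_raw["comparisons"]],
                primary=design_raw["primary"],
                controls=list(design_raw.get("controls", [])),
            )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = {
            "comparisons": [list(c) for c in self.design.comparisons],
            "primary": self.design.primary,
            "controls": list(self.design.controls),
        }
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(
    cm: CountMatrix,
    network: InteractionNetwork,
    gene_sets: Mapping[str, list[str]] | None,
    design: StudyDesign,
) -> ValidationReport:
    """Check id overlap between counts, network, gene sets and the design."""
    rep = ValidationReport()
    genes = set(cm.genes)
    net_nodes = set(network.graph.nodes)
    overlap = genes & net_nodes
    if not overlap:
        rep.fatal.append("no overlap between count-matrix genes and network nodes")
        return rep
    foreign = len(net_nodes - genes)
    if foreign:
        rep.warnings.append(
            f"{foreign}/{len(net_nodes)} network nodes lack expression data and will be dropped"
        )
    if gene_sets is not None:
        gmt_genes = set().union(*gene_sets.values()) if gene_sets else set()
        missing = len(gmt_genes - genes)
        if missing:
            rep.warnings.append(f"{missing} gene-set genes absent from the count matrix")
    groups = set(cm.groups)
    for name, test, ref in design.comparisons:
        for g in (test, ref):
            if g not in groups:
                rep.fatal.append(f"comparison {name}: group {g!r} not in sample metadata")
    return rep


@dataclass
class ComparisonResult:
    name: str
    de: pd.DataFrame  # called Wald table
    topnet: TopNet


@dataclass
class AnalysisResult:
    comparisons: dict[str, ComparisonResult]
    signature: SignatureSet
    norm_counts: pd.DataFrame
    leaf_order: list[str] | None = None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    clinical_summary: pd.DataFrame | None = None
    clinical_tests: pd.DataFrame | None = None


def analyze(
    cm: CountMatrix,
    network: InteractionNetwork,
    design: StudyDesign = DEFAULT_DESIGN,
    *,
    gene_sets: Mapping[str, list[str]] | None = None,
    clinical: pd.DataFrame | None = None,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    path_fraction: float | None = 0.005,
    path_threshold: float | None = None,
    undirected: bool = False,
    cluster_metric: str = "euclidean",
    cluster_method: str = "average",
) -> AnalysisResult:
    """Run every stage of the analysis in memory.

    Per comparison: Wald DE -> fold changes onto the network in active and
    repressed modes -> all-pairs shortest-path mining -> TopNet -> captured
    DEGs. Then the signature (primary captured minus all control captured),
    enrichment of each gene list, clustering on the signature, and clinical
    summaries if a table is given.
    """
    net = network.undirected() if undirected else network
    comparisons: dict[str, ComparisonResult] = {}
    for name, test, ref in design.comparisons:
        de = call_degs(
            wald_test(cm, test, ref),
            fold_threshold=fold_threshold, alpha=alpha, use_adjusted=use_adjusted,
        )
        fc = {g: 2.0 ** l for g, l in zip(de["gene"], de["log2fc"])}
        degs = {r.gene: r.direction for r in de.itertuples() if r.is_deg}
        logger.info("%s: %d DEGs (%d up, %d down)", name, len(degs),
                    sum(d == "up" for d in degs.values()),
                    sum(d == "down" for d in degs.values()))
        topnet = mine_topnet(
            net, fc, degs, comparison=name,
            fraction=path_fraction, threshold=path_threshold,
        )
        logger.info("%s TopNet: %d nodes, %d edges, %d captured DEGs", name,
                    len(topnet.nodes), len(topnet.edges), len(topnet.captured_degs))
        comparisons[name] = ComparisonResult(name=name, de=de, topnet=topnet)

    signature = characteristic_degs(
        comparisons[design.primary].topnet.captured_degs,
        [comparisons[c].topnet.captured_degs for c in design.controls],
        control_names=design.controls,
    )
    logger.info("signature: %d genes (%d up, %d down)", len(signature),
                len(signature.up), len(signature.down))

    sf = estimate_size_factors(cm.counts)
    norm = cm.counts / sf

    leaf_order = None
    if len(signature) >= 1 and cm.counts.shape[1] >= 2:
        try:
            leaf_order, _, _ = cluster_samples(
                norm, sorted(signature.genes),
                metric=cluster_metric, method=cluster_method,
            )
        except ValueError as exc:  # e.g. all signature rows constant
            logger.warning("clustering skipped: %s", exc)

    enrich: dict[str, pd.DataFrame] = {}
    if gene_sets:
        gmt_genes = set().union(*gene_sets.values())
        universe = set(cm.genes) & gmt_genes
        coll = GeneSetCollection(
            sets={t: set(g) for t, g in gene_sets.items()}
        ).restricted(universe)
        queries = {
            f"degs_{design.primary}": set(
                g for g, d in _deg_dirs(comparisons[design.primary].de).items()
            ),
            "topnet_active": comparisons[design.primary].topnet.active_nodes,
            "topnet_repressed": comparisons[design.primary].topnet.repressed_nodes,
            "signature": set(signature.genes),
        }
        for qname, qgenes in queries.items():
            enrich[qname] = fisher_enrichment(qgenes & universe, coll)

    clin_summary = clin_tests = None
    if clinical is not None:
        clin_summary = summarize_groups(clinical)
        clin_tests = pairwise_tests(clinical, parameter="nlr")

    return AnalysisResult(
        comparisons=comparisons,
        signature=signature,
        norm_counts=norm,
        leaf_order=leaf_order,
        enrichment=enrich,
        clinical_summary=clin_summary,
        clinical_tests=clin_tests,
    )


def _deg_dirs(de: pd.DataFrame) -> dict[str, str]:
    return {r.gene: r.direction for r in de.itertuples() if r.is_deg}


def _topnet_frames(t: TopNet) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for n in sorted(t.nodes):
        mode = ("common" if n in t.common_nodes
                else "active" if n in t.active_nodes else "repressed")
        rows.append({
            "node": n, "mode": mode,
            "is_deg": n in t.captured_degs,
            "direction": t.captured_degs.get(n, "none"),
        })
    edge_rows = [
        {"source": u, "target": v,
         "mode": ("common" if (u, v) in t.active_edges and (u, v) in t.repressed_edges
                  else "active" if (u, v) in t.active_edges else "repressed")}
        for u, v in sorted(t.edges)
    ]
    return pd.DataFrame(rows), pd.DataFrame(edge_rows)


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Load inputs, validate, analyze, and write the artifact bundle.

    Every TSV/JSON output carries the config hash; identical (config, seed)
    runs produce byte-identical files.
    """
    cm = CountMatrix(tio.read_counts(config.counts), tio.read_samples(config.samples))
    network = InteractionNetwork.from_sif(config.network)
    gene_sets = tio.read_gmt(config.gene_sets) if config.gene_sets else None
    clinical = tio.read_tsv(config.clinical) if config.clinical else None

    report = validate_inputs(cm, network, gene_sets, config.design)
    for w in report.warnings:
        logger.warning("validate: %s", w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.fatal))

    path_threshold = None
    if config.permutation_k:
        from .network import build_condition_network, permutation_threshold

        de = call_degs(wald_test(cm, *config.design.groups_of(config.design.primary)),
                       fold_threshold=config.fold_threshold, alpha=config.alpha)
        fc = {g: 2.0 ** l for g, l in zip(de["gene"], de["log2fc"])}
        cnet = build_condition_network(
            network.undirected() if config.undirected else network, fc, "active")
        path_threshold = permutation_threshold(
            cnet, k=config.permutation_k, alpha=config.permutation_alpha,
            seed=config.seed,
        )
        logger.info("permutation threshold: %.4g", path_threshold)

    result = analyze(
        cm, network, config.design,
        gene_sets=gene_sets, clinical=clinical,
        fold_threshold=config.fold_threshold, alpha=config.alpha,
        use_adjusted=config.use_adjusted,
        path_fraction=None if path_threshold is not None else config.path_fraction,
        path_threshold=path_threshold,
        undirected=config.undirected,
        cluster_metric=config.cluster_metric, cluster_method=config.cluster_method,
    )
    _write_bundle(result, config)
    return result


def _write_bundle(result: AnalysisResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash}"

    for name, comp in result.comparisons.items():
        tio.write_tsv(deg_table(comp.de), out / f"de_{name}.tsv", header_comment=tag)
        nodes, edges = _topnet_frames(comp.topnet)
        tio.write_tsv(nodes, out / f"topnet_{name}_nodes.tsv", header_comment=tag)
        tio.write_tsv(edges, out / f"topnet_{name}_edges.tsv", header_comment=tag)

    sig_rows = []
    primary_de = result.comparisons[config.design.primary].de.set_index("gene")
    for g in sorted(result.signature.genes):
        sig_rows.append({
            "gene": g,
            "direction": result.signature.genes[g],
            "log2fc": primary_de.loc[g, "log2fc"],
            "p": primary_de.loc[g, "p"],
        })
    tio.write_tsv(pd.DataFrame(sig_rows, columns=["gene", "direction", "log2fc", "p"]),
                  out / "signature.tsv", header_comment=tag)

    echoed = config.to_dict()
    echoed.pop("out_dir", None)  # a location, not an analysis parameter
    prov = {
        "config_hash": config.config_hash,
        "config": echoed,
        "signature_steps": result.signature.provenance,
        "topnet_sizes": {
            n: {"nodes": len(c.topnet.nodes), "edges": len(c.topnet.edges),
                "captured_degs": len(c.topnet.captured_degs)}
            for n, c in result.comparisons.items()
        },
    }
    (out / "provenance.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    for qname, df in result.enrichment.items():
        tio.write_tsv(df, out / f"enrichment_{qname}.tsv", header_comment=tag)

    if result.leaf_order is not None:
        (out / "leaf_order.txt").write_text(
            "".join(f"{s}\n" for s in result.leaf_order), encoding="utf-8")
        if config.make_heatmap and len(result.signature) >= 2:
            _write_heatmap(result, config, out / "heatmap.png")

    if result.clinical_summary is not None:
        tio.write_tsv(result.clinical_summary, out / "clinical_summary.tsv",
                      header_comment=tag)
        tio.write_tsv(result.clinical_tests, out / "pairwise_tests.tsv",
                      header_comment=tag)


def _write_heatmap(result: AnalysisResult, config: PipelineConfig, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .signature import zscore_rows

    z = zscore_rows(result.norm_counts.loc[sorted(result.signature.genes)])
    z = z[result.leaf_order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.08 * z.shape[0])))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("samples (dendrogram leaf order)")
    ax.set_ylabel(f"{z.shape[0]} signature genes (row Z-scores)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="row Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "topnet"})
    plt.close(fig)
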