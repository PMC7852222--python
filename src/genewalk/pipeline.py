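"""End-to-end orchestration: files in, ranked gene-GO relevance table out.

Stages (per the method's design): assemble the GWN; pool a null distribution
of neighbor similarities from nreps_null degree-matched randomized networks;
then nreps_graph times, embed the real GWN, score every connected gene-GO
annotation pair against the null and apply the dual (gene/global) BH
correction; finally aggregate repeats into means with confidence intervals.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import assembly
from .assembly import GO_ANNOTATION, OntologyTerm
from .embedding import TrainingConfig, train_embeddings
from .nullmodel import NullDistribution, PipelineConfig, build_null, p_values
from .stats import RESULT_COLUMNS, aggregate_repeats, dual_adjust
from .walks import sample_walks

logger = logging.getLogger(__name__)

#: Offset separating real-GWN repeat seeds from null-replicate seeds
#: (null replicate j uses seed + j).
_GRAPH_SEED_OFFSET = 100_000


def annotation_pairs(gwn: nx.Graph) -> list[tuple[str, str]]:
    """All connected gene-GO annotation pairs, sorted for determinism."""
    pairs = [
        (a, b) if gwn.nodes[a].get("kind") == "gene" else (b, a)
        for a, b, lab in gwn.edges(data="label")
        if lab == GO_ANNOTATION
    ]
    return sorted(pairs)


def score_gwn(
    gwn: nx.Graph,
    null: NullDistribution,
    training: TrainingConfig,
    L: int = 10,
    n_iteration: int = 100,
) -> pd.DataFrame:
    """One embedding repeat: similarities, empirical p-values, dual BH."""
    corpus = sample_walks(gwn, L=L, n_iteration=n_iteration, seed=training.seed)
    emb = train_embeddings(corpus, training)
    pairs = [p for p in annotation_pairs(gwn) if p[0] in emb and p[1] in emb]
    sims = emb.similarities(pairs)
    tab = pd.DataFrame(pairs, columns=["gene", "go_id"])
    tab["similarity"] = sims
    tab["p_value"] = p_values(sims, null)
    return dual_adjust(tab)


def run_gwn_pipeline(
    gwn: nx.Graph,
    ontology: dict[str, OntologyTerm],
    config: PipelineConfig | None = None,
    training: TrainingConfig | None = None,
    L: int = 10,
    n_iteration: int = 100,
) -> pd.DataFrame:
    """Run null building, repeated embedding and aggregation on an assembled GWN."""
    config = config or PipelineConfig()
    training = training or TrainingConfig()
    if gwn.number_of_edges() == 0:
        raise ValueError("assembled GWN has no edges")

    n_by_label: dict[str, int] = {}
    for _, _, lab in gwn.edges(data="label"):
        n_by_label[lab] = n_by_label.get(lab, 0) + 1
    logger.info(
        "GWN: %d nodes, %d edges (%s)", gwn.number_of_nodes(),
        gwn.number_of_edges(),
        ", ".join(f"{k}={v}" for k, v in sorted(n_by_label.items())),
    )

    null = build_null(gwn, config, training, L=L, n_iteration=n_iteration)
    logger.info("null distribution: %d similarity values from %d networks",
                len(null), null.n_source_networks)

    per_repeat = []
    for i in range(config.nreps_graph):
        tcfg = TrainingConfig(
            dim_rep=training.dim_rep, window=training.window,
            k_neg=training.k_neg, sample=training.sample,
            min_count=training.min_count, epochs=training.epochs,
            alpha=training.alpha, min_alpha=training.min_alpha,
            seed=config.seed + _GRAPH_SEED_OFFSET + i,
        )
        per_repeat.append(score_gwn(gwn, null, tcfg, L=L, n_iteration=n_iteration))

    agg = aggregate_repeats(per_repeat)

    agg["go_name"] = [ontology[g].name if g in ontology else "" for g in agg.go_id]
    agg["go_domain"] = [
        ontology[g].namespace if g in ontology else "" for g in agg.go_id
    ]
    agg["ncon_gene"] = [gwn.degree(g) for g in agg.gene]
    agg["ncon_go"] = [gwn.degree(g) for g in agg.go_id]
    agg = agg[RESULT_COLUMNS].sort_values(
        ["gene", "gene_padj", "go_id"], kind="mergesort"
    ).reset_index(drop=True)

    genes = [n for n, k in gwn.nodes(data="kind") if k == "gene"]
    with_go = {g for g in agg.gene}
    relevant = agg.loc[agg.gene_padj < config.fdr_alpha, "gene"].nunique()
    logger.info(
        "%d/%d genes have >=1 connected GO term; %d/%d have >=1 relevant term "
        "at gene_padj < %g",
        len(with_go), len(genes), relevant, len(genes), config.fdr_alpha,
    )
    return agg


def run_genewalk(
    genes_file,
    network_file,
    obo_file,
    gaf_file,
    network_format: str = "sif",
    config: PipelineConfig | None = None,
    training: TrainingConfig | None = None,
    include_unconnected: bool = True,
    L: int = 10,
    n_iteration: int = 100,
) -> pd.DataFrame:
    """File-level entry point: parse inputs, assemble, run, return the table."""
    genes = assembly.parse_gene_list(open(genes_file))
    if network_format == "sif":
        gene_edges = assembly.parse_sif(open(network_file))
    elif network_format == "edge_list":
        gene_edges = assembly.parse_edge_list(open(network_file))
    else:
        raise ValueError(f"unknown network format {network_format!r}")
    with open(obo_file) as fh:
        ontology = assembly.parse_obo(fh)
    with open(gaf_file) as fh:
        annotations = assembly.parse_gaf(fh)
    gwn = assembly.assemble_gwn(
        genes, gene_edges, annotations, ontology,
        include_unconnected=include_unconnected,
    )
    return run_gwn_pipeline(
        gwn, ontology, config=config, training=training, L=L,
        n_iteration=n_iteration,
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write the result table as CSV with 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6g")
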