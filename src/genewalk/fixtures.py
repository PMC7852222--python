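"""Self-contained synthetic inputs with planted, recoverable structure.

The generator emulates the four inputs of a real run — gene list, gene-gene
interaction network, GO-style ontology and GAF annotations — plus a ground
truth. Genes are partitioned into interaction modules (a planted-partition
graph: dense within modules, sparse between); each module is annotated to a
few dedicated *signal* leaf terms shared by all its members (relevant), and
genes occasionally receive a *decoy* annotation to another module's signal
leaf (not relevant). Recovering the signal annotations and rejecting the
decoys is exactly the discrimination the relevance-ranking method is
supposed to perform.

A structureless "null" variant (Erdos-Renyi gene layer, uniformly random
annotations, no relevant labels) supports type-I-error checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import AnnotationRecord, OntologyTerm

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class SyntheticConfig:
    """Planted-structure fixture parameters.

    Defaults: 4 modules of 15 genes, within-module edge probability 0.4
    versus 0.02 between modules, 2 signal leaf terms per module, a 0.3
    per-gene decoy annotation rate, and a depth-3 branching-3 ontology per
    namespace.
    """

    n_modules: int = 4
    genes_per_module: int = 15
    p_in: float = 0.4
    p_out: float = 0.02
    signal_terms_per_module: int = 2
    decoy_annotation_rate: float = 0.3
    ontology_depth: int = 3
    branching: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        for name in ("n_modules", "genes_per_module", "signal_terms_per_module",
                     "ontology_depth", "branching"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Fixture:
    """A complete synthetic input set plus its ground-truth labels."""

    genes: list[str]
    gene_edges: list[tuple[str, str]]
    annotations: list[AnnotationRecord]
    ontology: dict[str, OntologyTerm]
    truth: pd.DataFrame          # columns: gene, go_id, is_relevant
    modules: dict[str, int] = field(default_factory=dict)


def generate_ontology(
    depth: int, branching: int, id_offset: int = 1_000_000
) -> dict[str, OntologyTerm]:
    """A rooted is_a tree per GO namespace: branching^level terms at each level.

    Purely deterministic; term ids are sequential GO:-style accessions.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    terms: dict[str, OntologyTerm] = {}
    counter = id_offset
    for ns in _NAMESPACES:
        level_nodes: list[list[str]] = []
        for level in range(depth + 1):
            nodes = []
            for i in range(branching ** level):
                go_id = f"GO:{counter:07d}"
                counter += 1
                parent = (
                    frozenset({level_nodes[level - 1][i // branching]})
                    if level > 0 else frozenset()
                )
                terms[go_id] = OntologyTerm(
                    go_id=go_id,
                    name=f"synthetic {ns.replace('_', ' ')} L{level} term {i}",
                    namespace=ns,
                    parent_ids=parent,
                )
                nodes.append(go_id)
            level_nodes.append(nodes)
    return terms


def ontology_leaves(ontology: dict[str, OntologyTerm],
                    namespace: str | None = None) -> list[str]:
    """Terms with no children (sorted), optionally within one namespace."""
    parents = {p for t in ontology.values() for p in t.parent_ids}
    return sorted(
        t.go_id for t in ontology.values()
        if t.go_id not in parents
        and (namespace is None or t.namespace == namespace)
    )


def _bernoulli_edges(genes_a, genes_b, p, rng, within):
    edges = []
    if within:
        pairs = [(a, b) for i, a in enumerate(genes_a) for b in genes_a[i + 1:]]
    else:
        pairs = [(a, b) for a in genes_a for b in genes_b]
    if not pairs:
        return edges
    keep = rng.random(len(pairs)) < p
    return [pair for pair, k in zip(pairs, keep) if k]


def generate_fixture(config: SyntheticConfig) -> Fixture:
    """Generate the planted-module fixture; reproducible given config.seed."""
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config.ontology_depth, config.branching)
    leaves = ontology_leaves(ontology, "biological_process")
    n_signal = config.n_modules * config.signal_terms_per_module
    if n_signal > len(leaves):
        raise ValueError(
            f"{n_signal} signal terms requested but only {len(leaves)} leaves"
        )

    genes: list[str] = []
    modules: dict[str, int] = {}
    per_module: list[list[str]] = []
    for m in range(config.n_modules):
        block = [f"G{m:02d}N{i:02d}" for i in range(config.genes_per_module)]
        per_module.append(block)
        genes.extend(block)
        for g in block:
            modules[g] = m

    edges: list[tuple[str, str]] = []
    for m, block in enumerate(per_module):
        edges.extend(_bernoulli_edges(block, None, config.p_in, rng, within=True))
        for other in per_module[m + 1:]:
            edges.extend(
                _bernoulli_edges(block, other, config.p_out, rng, within=False)
            )

    # Allocate signal leaves so distinct modules draw from distinct parent
    # families: shared parents would couple modules two is_a steps above the
    # leaves and blur exactly the community signal being planted. Parents are
    # then shared across modules only at depth <= 1.
    families: dict[str, list[str]] = {}
    for leaf in leaves:
        parent = min(ontology[leaf].parent_ids) if ontology[leaf].parent_ids \
            else ""
        families.setdefault(parent, []).append(leaf)
    family_order = rng.permutation(sorted(families))
    signal_terms: list[list[str]] = [[] for _ in range(config.n_modules)]
    fi = 0
    for m in range(config.n_modules):
        while len(signal_terms[m]) < config.signal_terms_per_module:
            if fi >= len(family_order):
                raise ValueError(
                    f"{n_signal} signal terms requested but leaf parent "
                    "families are exhausted"
                )
            group = families[family_order[fi]]
            fi += 1
            take = min(
                config.signal_terms_per_module - len(signal_terms[m]), len(group)
            )
            idx = rng.choice(len(group), size=take, replace=False)
            signal_terms[m].extend(group[i] for i in sorted(idx))

    annotations: list[AnnotationRecord] = []
    truth_rows = []
    for m, block in enumerate(per_module):
        other_signals = [
            t for mm, ts in enumerate(signal_terms) if mm != m for t in ts
        ]
        for g in block:
            for t in signal_terms[m]:
                annotations.append(AnnotationRecord(g, t, "IDA"))
                truth_rows.append((g, t, True))
            if other_signals and rng.random() < config.decoy_annotation_rate:
                t = other_signals[rng.integers(len(other_signals))]
                annotations.append(AnnotationRecord(g, t, "IDA"))
                truth_rows.append((g, t, False))

    truth = pd.DataFrame(truth_rows, columns=["gene", "go_id", "is_relevant"])
    return Fixture(genes, edges, annotations, ontology, truth, modules)


def generate_null_fixture(
    n_genes: int = 60,
    p_edge: float = 0.1,
    annotations_per_gene: int = 2,
    ontology_depth: int = 3,
    branching: int = 3,
    seed: int = 0,
) -> Fixture:
    """Structureless fixture: Erdos-Renyi gene layer, uniform random leaf
    annotations, every truth label False. Used for type-I selectivity checks;
    the edge density matches the default planted fixture's gene layer."""
    rng = np.random.default_rng(seed)
    ontology = generate_ontology(ontology_depth, branching)
    leaves = ontology_leaves(ontology, "biological_process")
    genes = [f"G00N{i:02d}" for i in range(n_genes)]
    edges = _bernoulli_edges(genes, None, p_edge, rng, within=True)
    annotations = []
    truth_rows = []
    for g in genes:
        picks = rng.choice(len(leaves), size=annotations_per_gene, replace=False)
        for k in picks:
            annotations.append(AnnotationRecord(g, leaves[k], "IDA"))
            truth_rows.append((g, leaves[k], False))
    truth = pd.DataFrame(truth_rows, columns=["gene", "go_id", "is_relevant"])
    return Fixture(genes, edges, annotations, ontology, truth,
                   {g: 0 for g in genes})


def write_fixture_files(fixture: Fixture, directory) -> dict[str, Path]:
    """Write the fixture in the real input formats; round-trips exactly.

    Emits: gene list, two-column edge list, GAF 2.1 (evidence IDA, empty
    qualifier, DB "SYNTH", taxon:9606), minimal OBO, and the truth CSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": directory / "genes.txt",
        "network": directory / "network.txt",
        "gaf": directory / "annotations.gaf",
        "obo": directory / "ontology.obo",
        "truth": directory / "truth.csv",
    }
    paths["genes"].write_text("".join(f"{g}\n" for g in fixture.genes))
    paths["network"].write_text(
        "".join(f"{a}\t{b}\n" for a, b in fixture.gene_edges)
    )
    aspect = {"biological_process": "P", "molecular_function": "F",
              "cellular_component": "C"}
    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for i, rec in enumerate(fixture.annotations):
            asp = aspect[fixture.ontology[rec.go_id].namespace]
            fh.write(
                "\t".join([
                    "SYNTH", f"S{i:06d}", rec.symbol, "", rec.go_id,
                    "SYNTH:ref", rec.evidence_code, "", asp, "", "",
                    "protein", "taxon:9606", "20200101", "SYNTH", "", "",
                ]) + "\n"
            )
    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for go_id in sorted(fixture.ontology):
            term = fixture.ontology[go_id]
            fh.write(f"\n[Term]\nid: {term.go_id}\nname: {term.name}\n"
                     f"namespace: {term.namespace}\n")
            for p in sorted(term.parent_ids):
                fh.write(f"is_a: {p} ! {fixture.ontology[p].name}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
    fixture.truth.to_csv(paths["truth"], index=False)
    return paths
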