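"""Assembly of the GeneWalk network (GWN).

The GWN is an undirected *simple* graph joining three node/edge layers:

* context genes, connected by ``gene_gene`` edges taken from a user-supplied
  interaction network (SIF or two-column edge list), restricted to pairs of
  input genes;
* GO terms, connected among themselves by ``go_is_a`` edges from the ontology
  (is_a parent relations only);
* ``go_annotation`` edges joining a gene to each of its curated GO
  annotations that survive the evidence-code and NOT-qualifier filters.

Multiple lines of evidence for the same node pair are collapsed so that the
degree d(n) of a node counts *distinct* neighbors.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

#: GO evidence codes accepted by default: manually reviewed experimental
#: evidence (EXP family), high-throughput experimental evidence (HTP family)
#: and phylogenetically inferred evidence (IBA/IBD). Electronic annotations
#: (IEA) and other non-experimental codes are excluded.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD",
    }
)

GENE_GENE = "gene_gene"
GO_ANNOTATION = "go_annotation"
GO_IS_A = "go_is_a"


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class OntologyTerm:
    """One GO term: accession, label, namespace, is_a parents, obsolete flag."""

    go_id: str
    name: str
    namespace: str
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene -> GO term annotation with its evidence code and qualifiers."""

    symbol: str
    go_id: str
    evidence_code: str
    qualifiers: frozenset[str] = field(default_factory=frozenset)


def _as_stream(stream):
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_gene_list(stream) -> list[str]:
    """Read one gene symbol per line; '#' starts a comment; de-duplicated."""
    seen: dict[str, None] = {}
    for line in _as_stream(stream):
        sym = line.split("#", 1)[0].strip()
        if sym:
            seen.setdefault(sym, None)
    return list(seen)


def parse_edge_list(stream) -> list[tuple[str, str]]:
    """Parse a two-column whitespace-separated edge list.

    Each non-empty line is ``NodeA NodeB``. Duplicate lines are allowed;
    collapse happens at assembly.
    """
    edges = []
    for lineno, line in enumerate(_as_stream(stream), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 2:
            raise ParseError(
                f"edge list line {lineno}: expected 2 tokens, got {len(tokens)}"
            )
        edges.append((tokens[0], tokens[1]))
    return edges


def parse_sif(stream) -> list[tuple[str, str, str]]:
    """Parse simple interaction format: ``NodeA <relation_type> NodeB``.

    The relation type is kept as edge metadata only; it never affects the
    walk topology.
    """
    triples = []
    for lineno, line in enumerate(_as_stream(stream), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 3:
            raise ParseError(
                f"SIF line {lineno}: expected 3 tokens, got {len(tokens)}"
            )
        a, rel, b = tokens
        triples.append((a, rel, b))
    return triples


def parse_gaf(
    stream,
    allowed_evidence: frozenset[str] | set[str] | None = None,
    symbol_map: dict[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Parse GAF 2.1 annotations, keeping experimentally supported records.

    Records are kept only if their evidence code is in ``allowed_evidence``
    (default: the 13 experimental/phylogenetic codes) and their qualifier
    field does not contain ``NOT``. Gene identity is the DB Object Symbol
    column (case-sensitive); ``symbol_map`` optionally remaps DB Object IDs
    to symbols for users whose network namespace differs from the GAF's.

    Rows with fewer than 15 columns are skipped with a logged warning.
    """
    if allowed_evidence is None:
        allowed_evidence = EXPERIMENTAL_EVIDENCE_CODES
    stream = _as_stream(stream)
    good_lines = []
    for lineno, line in enumerate(stream, start=1):
        if line.startswith("!"):
            good_lines.append(line)
            continue
        if not line.strip():
            continue
        if len(line.rstrip("\n").split("\t")) < 15:
            logger.warning("GAF line %d has fewer than 15 columns; skipped", lineno)
            continue
        good_lines.append(line)
    records = []
    for rec in GOA.gafiterator(io.StringIO("".join(good_lines))):
        qualifiers = frozenset(q for q in rec["Qualifier"] if q)
        if "NOT" in qualifiers:
            continue
        if rec["Evidence"] not in allowed_evidence:
            continue
        symbol = rec["DB_Object_Symbol"]
        if symbol_map is not None:
            symbol = symbol_map.get(rec["DB_Object_ID"], symbol)
        records.append(
            AnnotationRecord(
                symbol=symbol,
                go_id=rec["GO_ID"],
                evidence_code=rec["Evidence"],
                qualifiers=qualifiers,
            )
        )
    return records


def parse_obo(stream) -> dict[str, OntologyTerm]:
    """Parse an OBO ontology into a mapping go_id -> OntologyTerm.

    Only ``is_a`` lines populate parents; other relationship types
    (part_of, regulates, ...) are ignored. Obsolete terms are retained here
    with ``obsolete=True`` and excluded later at assembly.
    """
    graph = obonet.read_obo(_as_stream(stream), ignore_obsolete=False)
    terms: dict[str, OntologyTerm] = {}
    for go_id, data in graph.nodes(data=True):
        terms[go_id] = OntologyTerm(
            go_id=go_id,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parent_ids=frozenset(data.get("is_a", ())),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    return terms


def assemble_gwn(
    genes: list[str],
    gene_edges,
    annotations: list[AnnotationRecord],
    ontology: dict[str, OntologyTerm],
    include_unconnected: bool = True,
) -> nx.Graph:
    """Assemble the GeneWalk network from parsed inputs.

    Parameters
    ----------
    genes
        Input gene symbols (the context). Must be non-empty.
    gene_edges
        Either ``(a, b)`` pairs (edge list) or ``(a, rel, b)`` triples (SIF).
        Only edges between two input genes become ``gene_gene`` edges; a SIF
        edge joining an input gene to a GO identifier present in the ontology
        is accepted as an extra ``go_annotation`` edge (user-injected
        gene-function links). All other edges are dropped.
    annotations
        Filtered GAF records; records for genes outside the input list or
        for GO ids missing from the ontology are skipped (the latter with a
        warning).
    ontology
        All ontology terms; every non-obsolete term becomes a node, with
        ``go_is_a`` edges to its non-obsolete parents.
    include_unconnected
        If True (default), every input gene is a node even with degree 0;
        if False, genes without at least one ``gene_gene`` edge are dropped.
    """
    if not genes:
        raise ValueError("empty input gene list")
    gene_set = set(genes)

    gwn = nx.Graph()

    # gene-gene layer, restricted to input-gene pairs; multi-edges collapse
    # automatically because nx.Graph holds at most one edge per pair
    extra_annotation_edges = []
    for edge in gene_edges:
        if len(edge) == 3:
            a, rel, b = edge
        else:
            (a, b), rel = edge, None
        if a == b:
            continue
        if a in gene_set and b in gene_set:
            gwn.add_edge(a, b, label=GENE_GENE, relation=rel)
        else:
            # SIF-injected gene->GO link (either endpoint order)
            if b in gene_set:
                a, b = b, a
            if a in gene_set and b in ontology and not ontology[b].obsolete:
                extra_annotation_edges.append((a, b))

    if include_unconnected:
        gwn.add_nodes_from(genes, kind="gene")
    for n in gwn.nodes:
        gwn.nodes[n]["kind"] = "gene"

    # ontology layer: all non-obsolete terms, is_a edges only
    for term in ontology.values():
        if term.obsolete:
            continue
        gwn.add_node(term.go_id, kind="go")
        for parent in term.parent_ids:
            p = ontology.get(parent)
            if p is not None and not p.obsolete:
                gwn.add_edge(term.go_id, parent, label=GO_IS_A)
                gwn.nodes[parent]["kind"] = "go"

    # annotation layer
    for rec in annotations:
        if rec.symbol not in gene_set or rec.symbol not in gwn:
            continue
        if "NOT" in rec.qualifiers:
            continue
        term = ontology.get(rec.go_id)
        if term is None:
            logger.warning(
                "annotation %s -> %s skipped: GO id not in ontology",
                rec.symbol, rec.go_id,
            )
            continue
        if term.obsolete:
            logger.warning(
                "annotation %s -> %s skipped: obsolete term", rec.symbol, rec.go_id
            )
            continue
        gwn.add_edge(rec.symbol, rec.go_id, label=GO_ANNOTATION)
    for gene, go_id in extra_annotation_edges:
        if gene in gwn:
            gwn.add_edge(gene, go_id, label=GO_ANNOTATION)

    return gwn


def go_level(go_id: str, ontology: dict[str, OntologyTerm]) -> int:
    """Level of a GO term: shortest is_a path length to its namespace root.

    The namespace root (a term with no non-obsolete parents) has level 0.
    """
    if go_id not in ontology:
        raise KeyError(f"unknown GO term {go_id}")
    if ontology[go_id].obsolete:
        raise ValueError(f"obsolete GO term {go_id}")
    # BFS upward over is_a; level = first depth at which a root is reached
    frontier = {go_id}
    seen = set(frontier)
    level = 0
    while frontier:
        nxt = set()
        for term_id in frontier:
            parents = {
                p for p in ontology[term_id].parent_ids
                if p in ontology and not ontology[p].obsolete
            }
            if not parents:
                return level
            nxt.update(parents - seen)
        seen.update(nxt)
        frontier = nxt
        level += 1
    raise ValueError(f"is_a cycle detected above {go_id}")


def write_gwn(gwn: nx.Graph, path) -> None:
    """Dump the GWN as a three-column edge list: NodeA NodeB label."""
    with open(path, "w") as fh:
        for a, b, data in sorted(gwn.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('label', '')}\n")
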