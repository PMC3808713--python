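"""Two-layer signed causal network model.

The networks handled here have two layers, in the style of curated
cause-and-effect biological network models encoded in BEL (Biological
Expression Language):

* a *functional backbone layer*: nodes representing biological activities
  (e.g., the transcriptional activity of a receptor), connected by signed
  directed causal edges ("A increases B" / "A decreases B");
* a *transcriptional evidence layer*: measured genes, each attached to one
  or more backbone nodes by a signed evidence edge stating how the backbone
  activity modulates the gene's expression.

Backbone activities are not directly measured; gene log2 fold changes act
as boundary conditions from which backbone values are inferred (see
:mod:`npa.core`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx
import pandas as pd

__all__ = [
    "TwoLayerNetwork",
    "ValidationReport",
    "NetworkFormatError",
    "ContradictionError",
    "parse_network",
    "validate_network",
    "read_network",
    "write_network",
    "network_to_json",
    "network_from_json",
]

#: BEL-style relation vocabulary accepted in edge lists, mapped to edge signs.
RELATION_SIGNS: Mapping[str, int] = {
    "increases": +1,
    "directlyIncreases": +1,
    "decreases": -1,
    "directlyDecreases": -1,
}

LAYERS = ("backbone", "evidence")

Edge = tuple[str, str, int]


class NetworkFormatError(ValueError):
    """Malformed network input (unknown token, self-loop, bad endpoint)."""


class ContradictionError(NetworkFormatError):
    """The same (source, target, layer) appears with conflicting signs."""


@dataclass(frozen=True)
class TwoLayerNetwork:
    """A signed directed backbone graph plus signed backbone-to-gene evidence.

    Node and edge containers are sorted tuples so that all downstream linear
    algebra sees a deterministic (lexicographic) ordering.

    Parameters
    ----------
    backbone_nodes, gene_nodes
        Node identifiers for the functional and transcriptional layers.
        Case-sensitive exact strings; the two sets must be disjoint.
    backbone_edges
        ``(source, target, sign)`` triples between backbone nodes.
    evidence_edges
        ``(backbone, gene, sign)`` triples; the source must be a backbone
        node and the target a gene. A gene regulated by several backbone
        nodes simply carries one evidence edge per regulator.
    """

    backbone_nodes: tuple[str, ...]
    gene_nodes: tuple[str, ...]
    backbone_edges: tuple[Edge, ...]
    evidence_edges: tuple[Edge, ...]
    name: str = "network"

    def __post_init__(self) -> None:
        bb = tuple(sorted(self.backbone_nodes))
        gg = tuple(sorted(self.gene_nodes))
        be = tuple(sorted(self.backbone_edges))
        ee = tuple(sorted(self.evidence_edges))
        object.__setattr__(self, "backbone_nodes", bb)
        object.__setattr__(self, "gene_nodes", gg)
        object.__setattr__(self, "backbone_edges", be)
        object.__setattr__(self, "evidence_edges", ee)

        bb_set, gg_set = set(bb), set(gg)
        if bb_set & gg_set:
            raise NetworkFormatError(
                f"nodes appear in both layers: {sorted(bb_set & gg_set)}"
            )
        seen: set[tuple[str, str, str]] = set()
        for src, tgt, sign in be:
            if sign not in (+1, -1):
                raise NetworkFormatError(f"backbone edge {src}->{tgt}: sign {sign!r}")
            if src == tgt:
                raise NetworkFormatError(f"self-loop on backbone node {src!r}")
            if src not in bb_set or tgt not in bb_set:
                raise NetworkFormatError(
                    f"backbone edge {src}->{tgt}: endpoint not a declared backbone node"
                )
            key = (src, tgt, "backbone")
            if key in seen:
                raise NetworkFormatError(f"duplicate backbone edge {src}->{tgt}")
            seen.add(key)
        for src, tgt, sign in ee:
            if sign not in (+1, -1):
                raise NetworkFormatError(f"evidence edge {src}->{tgt}: sign {sign!r}")
            if src not in bb_set:
                raise NetworkFormatError(
                    f"evidence edge {src}->{tgt}: source is not a backbone node"
                )
            if tgt not in gg_set:
                raise NetworkFormatError(
                    f"evidence edge {src}->{tgt}: target is not a gene node"
                )
            key = (src, tgt, "evidence")
            if key in seen:
                raise NetworkFormatError(f"duplicate evidence edge {src}->{tgt}")
            seen.add(key)

    # -- convenience -------------------------------------------------------

    @property
    def n_backbone(self) -> int:
        return len(self.backbone_nodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_nodes)

    def evidence_for_gene(self, gene: str) -> list[tuple[str, int]]:
        """Regulators of ``gene`` as ``(backbone node, sign)`` pairs."""
        return [(b, s) for (b, g, s) in self.evidence_edges if g == gene]

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame with columns source/relation/target/layer."""
        rows = [
            (s, "increases" if sign > 0 else "decreases", t, layer)
            for layer, edges in (
                ("backbone", self.backbone_edges),
                ("evidence", self.evidence_edges),
            )
            for (s, t, sign) in edges
        ]
        return pd.DataFrame(rows, columns=["source", "relation", "target", "layer"])


@dataclass
class ValidationReport:
    """Diagnosis of whether backbone values can be inferred from gene data.

    A backbone connected component is *identifiable* when at least one of
    its nodes carries an evidence edge to a gene in the network: boundary
    information then propagates along backbone edges to the whole component.
    Components without any evidence have no boundary data and the fitting
    linear system is singular for them.
    """

    is_valid: bool
    identifiable_components: list[tuple[str, ...]]
    unidentifiable_components: list[tuple[str, ...]]
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def parse_network(
    edge_records: Union[pd.DataFrame, Iterable[Mapping[str, str]]],
    name: str = "network",
) -> TwoLayerNetwork:
    """Build a :class:`TwoLayerNetwork` from a tabular edge list.

    Records must provide columns ``source``, ``relation``, ``target``,
    ``layer`` with ``relation`` in the four-token BEL vocabulary
    (increases / directlyIncreases / decreases / directlyDecreases) and
    ``layer`` in {backbone, evidence}. Anything else is an error, never a
    guess. Duplicate rows with a consistent sign are collapsed with a
    warning; conflicting signs for the same (source, target, layer) raise
    :class:`ContradictionError` because they would make the energy
    functional ill-posed.
    """
    if not isinstance(edge_records, pd.DataFrame):
        edge_records = pd.DataFrame(list(edge_records))
    required = ["source", "relation", "target", "layer"]
    missing = [c for c in required if c not in edge_records.columns]
    if missing:
        raise NetworkFormatError(f"edge list missing column(s) {missing}")

    edges: dict[tuple[str, str, str], int] = {}
    duplicates: list[str] = []
    for row_no, rec in enumerate(edge_records[required].itertuples(index=False)):
        src, relation, tgt, layer = (str(v).strip() for v in rec)
        if relation not in RELATION_SIGNS:
            raise NetworkFormatError(
                f"row {row_no}: unknown relation {relation!r} "
                f"(expected one of {sorted(RELATION_SIGNS)})"
            )
        if layer not in LAYERS:
            raise NetworkFormatError(
                f"row {row_no}: unknown layer {layer!r} (expected one of {LAYERS})"
            )
        if src == tgt:
            raise NetworkFormatError(f"row {row_no}: self-loop {src!r} -> {tgt!r}")
        sign = RELATION_SIGNS[relation]
        key = (src, tgt, layer)
        if key in edges:
            if edges[key] != sign:
                raise ContradictionError(
                    f"row {row_no}: {src} -> {tgt} ({layer}) appears with "
                    "conflicting signs"
                )
            duplicates.append(f"{src} -> {tgt} ({layer})")
        else:
            edges[key] = sign
    if duplicates:
        warnings.warn(
            f"collapsed {len(duplicates)} duplicate consistent edge(s): "
            + "; ".join(sorted(set(duplicates))),
            stacklevel=2,
        )

    backbone_edges = [
        (s, t, sign) for (s, t, layer), sign in edges.items() if layer == "backbone"
    ]
    evidence_edges = [
        (s, t, sign) for (s, t, layer), sign in edges.items() if layer == "evidence"
    ]
    backbone_nodes = {s for s, t, _ in backbone_edges} | {t for s, t, _ in backbone_edges}
    backbone_nodes |= {s for s, _, _ in evidence_edges}
    gene_nodes = {t for _, t, _ in evidence_edges}
    overlap = backbone_nodes & gene_nodes
    if overlap:
        raise NetworkFormatError(
            f"identifier(s) used both as backbone node and gene: {sorted(overlap)}"
        )
    return TwoLayerNetwork(
        backbone_nodes=tuple(backbone_nodes),
        gene_nodes=tuple(gene_nodes),
        backbone_edges=tuple(backbone_edges),
        evidence_edges=tuple(evidence_edges),
        name=name,
    )


def validate_network(net: TwoLayerNetwork) -> ValidationReport:
    """Check that every backbone component is reachable from gene evidence.

    Connectivity treats backbone edges as unordered. Diagnoses are returned,
    never raised.
    """
    graph = nx.Graph()
    graph.add_nodes_from(net.backbone_nodes)
    graph.add_edges_from((s, t) for s, t, _ in net.backbone_edges)

    gene_set = set(net.gene_nodes)
    evidenced = {b for b, g, _ in net.evidence_edges if g in gene_set}

    identifiable: list[tuple[str, ...]] = []
    unidentifiable: list[tuple[str, ...]] = []
    for comp in nx.connected_components(graph):
        comp_t = tuple(sorted(comp))
        (identifiable if comp & evidenced else unidentifiable).append(comp_t)
    identifiable.sort()
    unidentifiable.sort()

    errors: list[str] = []
    warns: list[str] = []
    for comp in unidentifiable:
        errors.append(
            f"backbone component {comp} has no evidence edge; its values are "
            "not identifiable from gene data"
        )
    orphans = gene_set - {g for _, g, _ in net.evidence_edges}
    if orphans:
        warns.append(f"gene(s) without evidence edges: {sorted(orphans)}")
    return ValidationReport(
        is_valid=not errors and not unidentifiable,
        identifiable_components=identifiable,
        unidentifiable_components=unidentifiable,
        warnings=warns,
        errors=errors,
    )


# -- I/O -------------------------------------------------------------------


def read_network(path: Union[str, Path], name: str | None = None) -> TwoLayerNetwork:
    """Read a network from a TSV edge list (``#`` comment lines ignored)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return parse_network(df, name=name or path.stem)


def write_network(net: TwoLayerNetwork, path: Union[str, Path]) -> None:
    """Write the network as a sorted TSV edge list (round-trips via read)."""
    net.to_frame().to_csv(path, sep="\t", index=False)


def network_to_json(net: TwoLayerNetwork) -> str:
    return json.dumps(
        {
            "name": net.name,
            "backbone_nodes": list(net.backbone_nodes),
            "gene_nodes": list(net.gene_nodes),
            "backbone_edges": [list(e) for e in net.backbone_edges],
            "evidence_edges": [list(e) for e in net.evidence_edges],
        },
        indent=2,
    )


def network_from_json(text: str) -> TwoLayerNetwork:
    obj = json.loads(text)
    return TwoLayerNetwork(
        backbone_nodes=tuple(obj["backbone_nodes"]),
        gene_nodes=tuple(obj["gene_nodes"]),
        backbone_edges=tuple((s, t, int(x)) for s, t, x in obj["backbone_edges"]),
        evidence_edges=tuple((s, t, int(x)) for s, t, x in obj["evidence_edges"]),
        name=obj.get("name", "network"),
    )
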