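"""Aggregate fingerprint results into interaction-network graph data.

Three graph builders are provided: a ligand interaction network (ligand
atoms vs protein residues, frequency-thresholded), a residue interaction
network with display filters (segment, sequence separation, interaction
type, isolated nodes), and a two-state comparison annotating edges as
only-A / only-B / both.  Graphs are NetworkX MultiGraphs exportable to
GraphML and JSON node-link data; no rendering is done here.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .chem_model import ResidueId, Structure
from .errors import FilterError
from .fingerprint import FingerprintResult

__all__ = [
    "lig_network",
    "residue_network",
    "compare_states",
    "write_graphml",
    "write_json",
]


def _residue_node(rid: ResidueId) -> str:
    return str(rid)


def lig_network(result: FingerprintResult, threshold: float = 0.3) -> nx.MultiGraph:
    """Ligand interaction network.

    One edge per (ligand residue, protein residue, interaction) group whose
    frequency is >= ``threshold``; the ligand endpoint is the most frequent
    ligand atom for that group (ties broken by lowest atom index) and the
    edge weight is the group frequency.
    """
    if not (0.0 <= threshold <= 1.0):
        raise FilterError(f"threshold must be in [0, 1], got {threshold}")
    freqs = result.frequencies()

    # Per-group ligand-atom occurrence counts (one count per frame per atom).
    atom_counts: dict[tuple, dict] = {}
    for (frame, lig, prot, name), dr in result.entries.items():
        if not dr.present:
            continue
        counts = atom_counts.setdefault((lig, prot, name), {})
        for atom in set(dr.ligand_atoms):
            counts[atom] = counts.get(atom, 0) + 1

    graph = nx.MultiGraph()
    for (lig, prot, name), freq in freqs.items():
        if freq < threshold:
            continue
        counts = atom_counts[(lig, prot, name)]
        best_atom = min(counts, key=lambda a: (-counts[a], a))
        lig_node = f"{lig}:atom{best_atom}"
        prot_node = _residue_node(prot)
        graph.add_node(lig_node, kind="ligand_atom", atom_index=int(best_atom),
                       residue=str(lig))
        graph.add_node(prot_node, kind="residue", name=prot.name,
                       number=prot.number, chain=prot.chain)
        graph.add_edge(lig_node, prot_node, key=name, interaction=name,
                       weight=float(freq))
    _record_degrees(graph)
    return graph


def residue_network(
    result: FingerprintResult,
    *,
    min_frequency: float = 0.0,
    segment_map: dict | None = None,
    drop_same_segment: bool = False,
    min_residue_gap: int = 0,
    exclude_interactions=(),
    drop_isolated: bool = True,
    drop_covalent: str | None = None,
    structure: Structure | None = None,
) -> nx.MultiGraph:
    """Residue interaction network with display filters.

    Filters (all optional, independent, and commuting):

    * ``drop_same_segment`` — remove edges whose endpoints carry the same
      segment label in ``segment_map``; residues missing from the map raise
      :class:`FilterError`.
    * ``min_residue_gap`` — remove same-chain edges with residue-number
      difference strictly below the gap (the published display rule is
      ``min_residue_gap=3``: pairs less than 3 apart are hidden).
    * ``exclude_interactions`` — remove edges of the named interaction types.
    * ``drop_covalent`` — ``"adjacent"`` removes same-chain edges between
      consecutive residue numbers; ``"bonded"`` removes edges between
      residues sharing a parent bond (requires ``structure``).
    * ``drop_isolated`` — prune nodes left without edges.
    """
    if drop_same_segment and segment_map is None:
        raise FilterError("drop_same_segment requires a segment_map")
    if drop_covalent not in (None, "adjacent", "bonded"):
        raise FilterError(f"unknown drop_covalent mode {drop_covalent!r}")
    if drop_covalent == "bonded" and structure is None:
        raise FilterError("drop_covalent='bonded' requires a structure")

    bonded_pairs: set = set()
    if drop_covalent == "bonded":
        res_of = {}
        for frag in structure.residues:
            for p in frag.parent_indices:
                res_of[p] = frag.residue_id
        for i, j in structure.bond_pairs():
            if res_of[i] != res_of[j]:
                bonded_pairs.add(frozenset((res_of[i], res_of[j])))

    exclude = set(exclude_interactions)

    def segment_of(rid: ResidueId):
        key = str(rid)
        if key in segment_map:
            return segment_map[key]
        if rid in segment_map:
            return segment_map[rid]
        raise FilterError(f"residue {key} missing from segment map")

    graph = nx.MultiGraph()
    for (lig, prot, name), freq in result.frequencies().items():
        if freq < min_frequency:
            continue
        if name in exclude:
            continue
        if drop_same_segment and segment_of(lig) == segment_of(prot):
            continue
        if (
            min_residue_gap > 0
            and lig.chain == prot.chain
            and abs(lig.number - prot.number) < min_residue_gap
        ):
            continue
        if drop_covalent == "adjacent" and (
            lig.chain == prot.chain and abs(lig.number - prot.number) == 1
        ):
            continue
        if drop_covalent == "bonded" and frozenset((lig, prot)) in bonded_pairs:
            continue
        for rid in (lig, prot):
            attrs = {"kind": "residue", "name": rid.name, "number": rid.number,
                     "chain": rid.chain}
            if segment_map is not None:
                try:
                    attrs["segment"] = str(segment_of(rid))
                except FilterError:
                    pass
            graph.add_node(_residue_node(rid), **attrs)
        graph.add_edge(
            _residue_node(lig), _residue_node(prot), key=name,
            interaction=name, weight=float(freq),
            intra=bool(lig.chain == prot.chain),
        )

    if drop_isolated:
        graph.remove_nodes_from([n for n, d in graph.degree() if d == 0])
    _record_degrees(graph)
    return graph


def _record_degrees(graph: nx.MultiGraph) -> None:
    for node, degree in graph.degree():
        graph.nodes[node]["degree"] = int(degree)


def _edge_set(graph: nx.MultiGraph) -> dict:
    edges = {}
    for u, v, key, data in graph.edges(keys=True, data=True):
        ident = (tuple(sorted((u, v))), data.get("interaction", key))
        edges[ident] = data
    return edges


def compare_states(graph_a: nx.MultiGraph, graph_b: nx.MultiGraph) -> nx.MultiGraph:
    """Union graph with each edge labelled 'only-A', 'only-B' or 'both'."""
    edges_a = _edge_set(graph_a)
    edges_b = _edge_set(graph_b)
    out = nx.MultiGraph()
    for g in (graph_a, graph_b):
        for node, attrs in g.nodes(data=True):
            out.add_node(node, **attrs)
    for ident in sorted(set(edges_a) | set(edges_b)):
        (u, v), interaction = ident
        in_a, in_b = ident in edges_a, ident in edges_b
        state = "both" if (in_a and in_b) else ("only-A" if in_a else "only-B")
        attrs = {"interaction": interaction, "state": state}
        if in_a:
            attrs["weight_a"] = edges_a[ident].get("weight", 1.0)
        if in_b:
            attrs["weight_b"] = edges_b[ident].get("weight", 1.0)
        out.add_edge(u, v, key=interaction, **attrs)
    _record_degrees(out)
    return out


def write_graphml(graph: nx.MultiGraph, path) -> None:
    nx.write_graphml(graph, str(path))


def write_json(graph: nx.MultiGraph, path) -> None:
    data = nx.node_link_data(graph, edges="edges")
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
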