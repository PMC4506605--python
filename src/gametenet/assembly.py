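"""Derived-network construction: compartment overlap, membrane subnetwork, union.

The study's network algebra has three steps.  First, the sperm and egg
compartment networks are intersected on their shared proteins; the overlap
network keeps every interaction from *either* compartment whose endpoints
are both shared (edge union restricted to shared nodes — the only reading
under which the overlap can carry more edges than the smaller input, which
the study's reported counts require).  Second, the overlap is restricted to
membrane candidates (signal peptide and/or transmembrane domain).  Third,
the two high-confidence networks derived from the membrane network are
merged by plain node/edge union.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx

from .model import Network, ProteinRecord, ValidationError, annotation_index

__all__ = ["overlap_network", "membrane_subnetwork", "union_networks"]


def overlap_network(net_a: Network, net_b: Network) -> Network:
    """Intersect two compartment networks on their shared proteins.

    Nodes: intersection of the two node sets.  Edges: union of both edge
    sets restricted to pairs with both endpoints shared.  Disjoint node sets
    yield an empty network.
    """
    shared = set(net_a.nodes) & set(net_b.nodes)
    g = nx.Graph()
    g.add_nodes_from(shared)
    for net in (net_a, net_b):
        for a, b in net.edges:
            if a in shared and b in shared:
                g.add_edge(a, b)
    return g


def membrane_subnetwork(net: Network, annotations: Sequence[ProteinRecord]) -> Network:
    """Induced subgraph on membrane candidates.

    A node is kept iff its annotation has a signal peptide and/or a
    transmembrane domain.  Every network node must be annotated; a missing
    annotation raises :class:`ValidationError` naming the node, because
    silently dropping unannotated proteins would change target lists
    invisibly.
    """
    idx = annotation_index(annotations)
    missing = sorted(n for n in net.nodes if n not in idx)
    if missing:
        raise ValidationError(
            f"nodes missing from annotation table: {', '.join(missing)}"
        )
    keep = {n for n in net.nodes if idx[n].is_membrane}
    return nx.Graph(net.subgraph(keep))


def union_networks(net_a: Network, net_b: Network) -> Network:
    """Node union and edge union of two networks, deduplicated."""
    g = nx.Graph()
    g.add_nodes_from(net_a.nodes)
    g.add_nodes_from(net_b.nodes)
    g.add_edges_from(net_a.edges)
    g.add_edges_from(net_b.edges)
    return g
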