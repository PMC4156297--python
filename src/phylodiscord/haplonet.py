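"""Statistical-parsimony (TCS-style) haplotype networks.

Sequences are collapsed to haplotypes, and haplotypes are joined by
single-mutation edges under a fixed connection limit: at step lengths
j = 1, 2, ..., limit, components whose minimum inter-component distance is
j are connected, inserting j-1 inferred (unsampled) intermediate nodes on
each new path.  All equally short alternative connections at the same j
are retained, producing the reticulations (loops) characteristic of
statistical-parsimony networks.  Components that cannot be joined within
the limit stay disconnected.

Distances are mismatch counts with gaps treated as missing by default
(``gap_policy="missing"``); a 5th-state option scores gap vs base as a
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import Alignment

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "build_parsimony_network",
    "network_summary",
]


@dataclass
class Haplotype:
    """A collapsed sequence class: representative + member labels."""

    id: str
    sequence: str
    members: list[str]
    taxa: dict[str, int] = field(default_factory=dict)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """Sampled + inferred haplotype nodes joined by single-step edges.

    The graph is a :class:`networkx.Graph`; node attributes: ``sampled``
    (bool), ``frequency`` (0 for inferred), ``members``, ``taxa``.
    """

    graph: nx.Graph
    haplotypes: list[Haplotype]
    limit: int

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["sampled"]]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["sampled"]]

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def write_dot(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("graph haplotypes {\n")
            for n, d in self.graph.nodes(data=True):
                shape = "circle" if d["sampled"] else "point"
                fh.write(f'  "{n}" [shape={shape}, label="{n} ({d["frequency"]})"];\n')
            for u, v in self.graph.edges():
                fh.write(f'  "{u}" -- "{v}";\n')
            fh.write("}\n")

    def write_graphml(self, path: str) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n,
                sampled=bool(d["sampled"]),
                frequency=int(d["frequency"]),
                members=",".join(d.get("members", [])),
            )
        g.add_edges_from(self.graph.edges())
        nx.write_graphml(g, path)

    def write_node_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsampled\tfrequency\tmembers\ttaxa\n")
            for n, d in self.graph.nodes(data=True):
                taxa = ";".join(f"{t}:{c}" for t, c in sorted(d.get("taxa", {}).items()))
                fh.write(
                    f"{n}\t{int(d['sampled'])}\t{d['frequency']}\t"
                    f"{','.join(d.get('members', []))}\t{taxa}\n"
                )


def collapse_haplotypes(
    aln: Alignment, missing_policy: str = "exact"
) -> list[Haplotype]:
    """Group identical sequences into haplotypes with frequencies.

    Equivalence follows :func:`phylodiscord.alignment.merge_identical`;
    the representative is the first member in input order and node ids
    ``H1, H2, ...`` follow input order (deterministic).
    """
    from .alignment import merge_identical

    merged, mapping = merge_identical(aln, missing_policy=missing_policy)
    haps = []
    for k, rep in enumerate(merged.labels, 1):
        members = mapping[rep]
        taxa: dict[str, int] = {}
        for lab in members:
            t = aln.info(lab).taxon
            taxa[t] = taxa.get(t, 0) + 1
        haps.append(
            Haplotype(id=f"H{k}", sequence=merged.sequence(rep), members=members, taxa=taxa)
        )
    return haps


def _hap_distances(haps: list[Haplotype], gap_policy: str) -> np.ndarray:
    """Pairwise mismatch counts between haplotype sequences."""
    from . import iupac

    M = np.vstack([iupac.encode(h.sequence) for h in haps])
    n = len(haps)
    D = np.zeros((n, n), dtype=int)
    present = M != 0
    for i in range(n):
        for j in range(i + 1, n):
            if gap_policy == "missing":
                comp = present[i] & present[j]
                d = int((comp & ((M[i] & M[j]) == 0)).sum())
            elif gap_policy == "fifth-state":
                both_gap = ~present[i] & ~present[j]
                d = int((~both_gap & (((M[i] & M[j]) == 0) | (present[i] != present[j]))).sum())
            else:
                raise ValueError(f"unknown gap_policy {gap_policy!r}")
            D[i, j] = D[j, i] = d
    return D


def build_parsimony_network(
    haplotypes: list[Haplotype], limit: int = 30, gap_policy: str = "missing"
) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network under a step limit."""
    if not haplotypes:
        raise ValueError("no haplotypes")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(
            h.id, sampled=True, frequency=h.frequency, members=list(h.members), taxa=h.taxa
        )
    D = _hap_distances(haplotypes, gap_policy)
    ids = [h.id for h in haplotypes]
    n_inferred = 0

    def add_path(u: str, v: str, steps: int) -> None:
        nonlocal n_inferred
        prev = u
        for _ in range(steps - 1):
            n_inferred += 1
            mid = f"I{n_inferred}"
            g.add_node(mid, sampled=False, frequency=0, members=[], taxa={})
            g.add_edge(prev, mid)
            prev = mid
        g.add_edge(prev, v)

    for j in range(1, limit + 1):
        # component membership before this round; all qualifying pairs at
        # distance j are connected (equal-length alternatives retained)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        pairs = []
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                if D[a, b] == j and comp_of[ids[a]] != comp_of[ids[b]]:
                    pairs.append((a, b))
        for a, b in pairs:
            add_path(ids[a], ids[b], j)
    return HaplotypeNetwork(graph=g, haplotypes=haplotypes, limit=limit)


def network_summary(net: HaplotypeNetwork) -> dict:
    """Node/component counts and the inter-haplotype path-length spectrum."""
    g = net.graph
    sampled = net.sampled_nodes
    lengths: dict[int, int] = {}
    for i, u in enumerate(sampled):
        dist = nx.single_source_shortest_path_length(g, u)
        for v in sampled[i + 1:]:
            if v in dist:
                lengths[dist[v]] = lengths.get(dist[v], 0) + 1
    return {
        "n_sampled": len(sampled),
        "n_inferred": len(net.inferred_nodes),
        "n_edges": g.number_of_edges(),
        "n_components": nx.number_connected_components(g),
        "total_frequency": sum(g.nodes[n]["frequency"] for n in sampled),
        "path_length_counts": dict(sorted(lengths.items())),
    }
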