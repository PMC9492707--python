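"""Molecular connectivity graphs: construction, fragmentation, derivation.

A molecule is a simple undirected graph with per-atom element symbols and
formal charges and per-bond orders.  Fragmentation for bond-dissociation
studies cuts either every bridge (non-cyclic) bond — each cut giving an
unordered pair of fragments — or a ring bond, giving a single ring-opened
product.  Resulting fragmentations are deduplicated by a canonical
iterative-neighborhood-refinement (Weisfeiler-Lehman) hash over
(element, formal charge, degree) labels; the exhaustive VF2 isomorphism
route exists in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

# single-bond covalent radii (angstrom), common main-group + battery-relevant
# elements; used only for distance-based bond perception from bare geometry
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Li": 1.28, "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Al": 1.21,
    "Zn": 1.22,
}

#: perception margin: atoms bond when closer than 1.2x the radius sum
PERCEPTION_SCALE = 1.2


@dataclass
class MolGraph:
    """Simple molecular graph; nodes carry element and formal charge."""

    graph: nx.Graph

    # -- construction ------------------------------------------------------

    @classmethod
    def from_bonds(
        cls,
        elements: Sequence[str],
        bonds: Sequence[Tuple[int, int]] | Sequence[Tuple[int, int, float]],
        formal_charges: Optional[Sequence[int]] = None,
    ) -> "MolGraph":
        """Build from an explicit bond list; bond tuples may carry an order."""
        g = nx.Graph()
        charges = formal_charges or [0] * len(elements)
        if len(charges) != len(elements):
            raise ValueError("formal_charges length must match elements")
        for i, (el, q) in enumerate(zip(elements, charges)):
            g.add_node(i, element=el, formal_charge=int(q))
        for bond in bonds:
            i, j = int(bond[0]), int(bond[1])
            order = float(bond[2]) if len(bond) > 2 else 1.0
            if i == j or not (0 <= i < len(elements)) or not (0 <= j < len(elements)):
                raise ValueError(f"invalid bond ({i}, {j})")
            g.add_edge(i, j, order=order)
        return cls(g)

    @classmethod
    def from_xyz(
        cls,
        elements: Sequence[str],
        coords: np.ndarray,
        scale: float = PERCEPTION_SCALE,
    ) -> "MolGraph":
        """Perceive single bonds from geometry via covalent radii * scale.

        Explicit bond lists always take precedence over perception; use this
        only when no connectivity is available.
        """
        coords = np.asarray(coords, dtype=float)
        n = len(elements)
        g = nx.Graph()
        for i, el in enumerate(elements):
            if el not in COVALENT_RADII:
                raise ValueError(f"no covalent radius for element {el!r}")
            g.add_node(i, element=el, formal_charge=0)
        for i in range(n):
            for j in range(i + 1, n):
                rmax = scale * (COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]])
                if np.linalg.norm(coords[i] - coords[j]) <= rmax:
                    g.add_edge(i, j, order=1.0)
        return cls(g)

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    @property
    def elements(self) -> List[str]:
        return [self.graph.nodes[i]["element"] for i in sorted(self.graph.nodes)]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def formula(self) -> str:
        from collections import Counter

        counts = Counter(self.elements)
        return "".join(
            f"{el}{counts[el] if counts[el] > 1 else ''}" for el in sorted(counts)
        )

    # -- canonical hashing -------------------------------------------------

    def canonical_hash(self) -> str:
        """Weisfeiler-Lehman hash over (element, formal charge, degree)."""
        g = self.graph.copy()
        for i in g.nodes:
            d = g.nodes[i]
            g.nodes[i]["wl"] = f"{d['element']}|{d['formal_charge']}|{g.degree[i]}"
        return nx.weisfeiler_lehman_graph_hash(g, node_attr="wl", iterations=4)

    def is_isomorphic(self, other: "MolGraph") -> bool:
        """Exact VF2 isomorphism respecting element and formal charge."""
        nm = nx.algorithms.isomorphism.categorical_node_match(
            ["element", "formal_charge"], ["", 0]
        )
        return nx.is_isomorphic(self.graph, other.graph, node_match=nm)

    def subgraph(self, nodes: Sequence[int]) -> "MolGraph":
        sub = self.graph.subgraph(nodes).copy()
        return MolGraph(nx.convert_node_labels_to_integers(sub, ordering="sorted"))


@dataclass
class Fragmentation:
    """One unique way of cutting a molecule for a dissociation calculation."""

    bond: Tuple[int, int]
    fragments: Tuple[MolGraph, ...]  # two for a bridge cut, one for ring-open
    mode: str  # "non-cyclic" | "ring-open"
    key: str = field(init=False)
    equivalent_bonds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        hashes = sorted(f.canonical_hash() for f in self.fragments)
        self.key = f"{self.mode}:" + "+".join(hashes)


def enumerate_fragments(
    g: MolGraph,
    mode: str = "non-cyclic",
    bonds: Optional[Sequence[Tuple[int, int]]] = None,
) -> List[Fragmentation]:
    """Enumerate unique single-bond fragmentations of a connected molecule.

    ``non-cyclic`` mode cuts every bridge bond (or the explicit `bonds`
    subset), producing fragment pairs; ``ring-open`` mode cuts every
    non-bridge (ring) bond, each producing one connected product.
    Symmetry-equivalent cuts collapse to a single entry whose
    ``equivalent_bonds`` lists the redundant bonds.
    """
    if mode not in ("non-cyclic", "ring-open"):
        raise ValueError(f"unknown fragmentation mode {mode!r}")
    if not g.is_connected():
        raise ValueError("fragmentation requires a connected molecular graph")
    bridges = set(frozenset(e) for e in nx.bridges(g.graph))
    if bonds is not None:
        for i, j in bonds:
            if not g.graph.has_edge(i, j):
                raise ValueError(f"bond ({i}, {j}) not present in graph")
        edges = [tuple(b) for b in bonds]
    elif mode == "non-cyclic":
        edges = [e for e in g.graph.edges if frozenset(e) in bridges]
    else:
        edges = [e for e in g.graph.edges if frozenset(e) not in bridges]

    out: Dict[str, Fragmentation] = {}
    for i, j in edges:
        h = g.graph.copy()
        h.remove_edge(i, j)
        comps = [sorted(cc) for cc in nx.connected_components(h)]
        if mode == "non-cyclic":
            if len(comps) != 2:
                # an explicitly requested ring bond leaves one component
                frags = (MolGraph(nx.convert_node_labels_to_integers(h, ordering="sorted")),)
                frag_mode = "ring-open"
            else:
                frags = tuple(
                    MolGraph(
                        nx.convert_node_labels_to_integers(
                            h.subgraph(cc).copy(), ordering="sorted"
                        )
                    )
                    for cc in comps
                )
                frag_mode = "non-cyclic"
        else:
            if len(comps) != 1:
                continue  # not a ring bond
            frags = (MolGraph(nx.convert_node_labels_to_integers(h, ordering="sorted")),)
            frag_mode = "ring-open"
        frag = Fragmentation(bond=(i, j), fragments=frags, mode=frag_mode)
        if frag.key in out:
            out[frag.key].equivalent_bonds.append((i, j))
        else:
            out[frag.key] = frag
    return list(out.values())


def derive_molecule(
    g1: MolGraph, site1: int, g2: MolGraph, site2: int, order: float = 1.0
) -> MolGraph:
    """Connect two molecules by one new bond between `site1` and `site2`.

    The second graph's indices are offset by ``g1.n_atoms``.  A single bond
    is formed by default; double/triple bonds via `order`.  The operation
    composes: apply it repeatedly to attach several groups.
    """
    if not (0 <= site1 < g1.n_atoms):
        raise ValueError(f"site1={site1} out of range for {g1.n_atoms}-atom graph")
    if not (0 <= site2 < g2.n_atoms):
        raise ValueError(f"site2={site2} out of range for {g2.n_atoms}-atom graph")
    a = nx.convert_node_labels_to_integers(g1.graph, ordering="sorted")
    b = nx.convert_node_labels_to_integers(
        g2.graph, first_label=g1.n_atoms, ordering="sorted"
    )
    merged = nx.union(a, b)
    merged.add_edge(site1, g1.n_atoms + site2, order=float(order))
    return MolGraph(merged)
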