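"""Shared fixtures: small hand-built networks and term collections."""

from __future__ import annotations

import pytest

from assocnet import Edge, Network, Node, Term, TermCollection


@pytest.fixture
def two_triangles() -> Network:
    """Two disjoint triangles with uniform score 0.9."""
    nodes = [Node(f"N{i}", canonical_name=f"gene{i}") for i in range(6)]
    pairs = [("N0", "N1"), ("N1", "N2"), ("N0", "N2"),
             ("N3", "N4"), ("N4", "N5"), ("N3", "N5")]
    return Network(nodes, [Edge(u, v, {"experiments": 0.9}, 0.9) for u, v in pairs])


@pytest.fixture
def chain_network() -> Network:
    """A--B--C chain with scores 0.9, 0.9."""
    return Network(
        ["A", "B", "C"],
        [Edge("A", "B", {}, 0.9), Edge("B", "C", {}, 0.9)],
    )


@pytest.fixture
def small_collection() -> TermCollection:
    genes = [f"G{i}" for i in range(20)]
    return TermCollection(
        [
            Term("T1", "GO Biological Process", "alpha process", frozenset(genes[:5])),
            Term("T2", "GO Biological Process", "beta process", frozenset(genes[3:8])),
            Term("T3", "Pathways", "gamma pathway", frozenset(genes[10:14])),
            Term("T4", "GO Biological Process", "delta process", frozenset(genes)),
        ]
    )
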