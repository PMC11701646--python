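"""Scored association networks.

A network is a set of proteins (nodes) plus scored edges in one of three
modes:

``functional``
    undirected associations between proteins contributing to a common
    function; each edge carries per-channel evidence subscores and a
    combined confidence in [0, 1].
``physical``
    undirected subset restricted to binding / co-complex evidence; same
    edge representation as functional.
``regulatory``
    directed, typed and optionally signed edges ("who regulates whom"),
    with one confidence per direction.

Confidence scores estimate the probability that the postulated association
is real given the evidence.  Evidence arrives through seven independent
channels (genomic neighborhood, gene fusion, phylogenetic co-occurrence,
co-expression, experiments, curated databases, text mining); the combined
score integrates the channel subscores under an independence assumption
after removing a configurable prior (the baseline probability that a
random pair is associated).

The physical and regulatory networks are by construction subsets of the
functional network: every specific edge must also appear in the functional
network with an equal-or-higher confidence.  :func:`check_mode_consistency`
verifies that containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import InvalidInputError, InvalidParameterError

#: The seven evidence channels, in canonical order.
CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)

_CHANNEL_SET = frozenset(CHANNELS)


@dataclass(frozen=True)
class Node:
    """A protein/gene. Identifiers are opaque strings, never parsed."""

    id: str
    canonical_name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("node id must be a non-empty string")
        if not self.canonical_name:
            object.__setattr__(self, "canonical_name", self.id)


class ActionType(str, Enum):
    """Closed taxonomy of regulatory interaction types.

    ``REGULATION`` has the two signed subtypes ``POSITIVE_REGULATION`` and
    ``NEGATIVE_REGULATION``; catalysis of post-translational modifications
    has six subtypes. Serialized with underscores (e.g.
    ``catalysis_of_phosphorylation``).
    """

    REGULATION = "regulation"
    POSITIVE_REGULATION = "positive_regulation"
    NEGATIVE_REGULATION = "negative_regulation"
    REGULATION_OF_GENE_EXPRESSION = "regulation_of_gene_expression"
    REGULATION_OF_DEGRADATION = "regulation_of_degradation"
    CATALYSIS_OF_PTM = "catalysis_of_post_translational_modifications"
    CATALYSIS_OF_SMALL_PROTEIN_CONJUGATION = "catalysis_of_small_protein_conjugation"
    CATALYSIS_OF_SMALL_PROTEIN_REMOVAL = "catalysis_of_small_protein_removal"
    CATALYSIS_OF_PHOSPHORYLATION = "catalysis_of_phosphorylation"
    CATALYSIS_OF_DEPHOSPHORYLATION = "catalysis_of_dephosphorylation"
    CATALYSIS_OF_SMALL_MOLECULE_CONJUGATION = "catalysis_of_small_molecule_conjugation"
    CATALYSIS_OF_SMALL_MOLECULE_REMOVAL = "catalysis_of_small_molecule_removal"


#: Action types that may carry a positive/negative sign.
SIGNABLE_ACTION_TYPES = frozenset(
    {ActionType.POSITIVE_REGULATION, ActionType.NEGATIVE_REGULATION}
)


def _check_score(value: float, what: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise InvalidInputError(f"{what} must be in [0, 1], got {value!r}")
    return value


def validate_channels(channels: Mapping[str, float]) -> dict[str, float]:
    """Validate a channel-score mapping; unknown channels are rejected."""
    out: dict[str, float] = {}
    for name, score in channels.items():
        if name not in _CHANNEL_SET:
            raise InvalidInputError(f"unknown evidence channel {name!r}")
        out[name] = _check_score(score, f"channel {name!r} score")
    return out


@dataclass
class Edge:
    """Undirected scored edge (functional or physical mode).

    The node pair is stored in sorted order; an absent channel means
    subscore 0.
    """

    u: str
    v: str
    channels: dict[str, float] = field(default_factory=dict)
    combined: float = 0.0

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise InvalidInputError(f"self-edge on {self.u!r} is not allowed")
        if self.v < self.u:
            self.u, self.v = self.v, self.u
        self.channels = validate_channels(self.channels)
        self.combined = _check_score(self.combined, "combined score")

    @property
    def key(self) -> tuple[str, str]:
        return (self.u, self.v)


@dataclass
class RegulatoryEdge:
    """Directed, typed, optionally signed edge with per-direction confidence.

    ``confidence_forward`` scores source→target; ``confidence_reverse`` is 0
    for unidirectional relations.  A sign is only allowed on the signable
    action types (positive/negative regulation).
    """

    source: str
    target: str
    action_type: ActionType = ActionType.REGULATION
    sign: str = "unspecified"
    confidence_forward: float = 0.0
    confidence_reverse: float = 0.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InvalidInputError(f"self-edge on {self.source!r} is not allowed")
        self.action_type = ActionType(self.action_type)
        if self.sign not in ("positive", "negative", "unspecified"):
            raise InvalidInputError(f"invalid sign {self.sign!r}")
        if self.sign != "unspecified" and self.action_type not in SIGNABLE_ACTION_TYPES:
            raise InvalidInputError(
                f"action type {self.action_type.value!r} cannot carry sign {self.sign!r}"
            )
        self.confidence_forward = _check_score(self.confidence_forward, "confidence_forward")
        self.confidence_reverse = _check_score(self.confidence_reverse, "confidence_reverse")
        if self.confidence_forward == 0.0 and self.confidence_reverse == 0.0:
            raise InvalidInputError(
                f"regulatory edge {self.source}->{self.target} has no positive confidence"
            )

    @property
    def key(self) -> tuple[str, str, ActionType]:
        return (self.source, self.target, self.action_type)

    @property
    def confidence(self) -> float:
        """Best confidence over the two directions."""
        return max(self.confidence_forward, self.confidence_reverse)


MODES = ("functional", "physical", "regulatory")


class Network:
    """Node set plus scored edges with a mode tag.

    Invariants enforced at construction: all edge endpoints are in the node
    set, no self-edges, and at most one edge per unordered pair (regulatory:
    per ordered pair and action type).
    """

    def __init__(
        self,
        nodes: Iterable[Node | str],
        edges: Iterable[Edge | RegulatoryEdge] = (),
        mode: str = "functional",
    ) -> None:
        if mode not in MODES:
            raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")
        self.mode = mode
        self.nodes: dict[str, Node] = {}
        for node in nodes:
            if isinstance(node, str):
                node = Node(node)
            if node.id in self.nodes:
                raise InvalidInputError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.edges: list[Edge | RegulatoryEdge] = []
        self._by_key: dict[tuple, Edge | RegulatoryEdge] = {}
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: Edge | RegulatoryEdge) -> None:
        if self.mode == "regulatory":
            if not isinstance(edge, RegulatoryEdge):
                raise InvalidInputError("regulatory networks hold RegulatoryEdge objects")
            endpoints = (edge.source, edge.target)
        else:
            if not isinstance(edge, Edge):
                raise InvalidInputError(f"{self.mode} networks hold undirected Edge objects")
            endpoints = (edge.u, edge.v)
        for nid in endpoints:
            if nid not in self.nodes:
                raise InvalidInputError(f"edge endpoint {nid!r} is not in the node set")
        if edge.key in self._by_key:
            raise InvalidInputError(f"duplicate edge {edge.key!r}")
        self._by_key[edge.key] = edge
        self.edges.append(edge)

    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def names(self) -> dict[str, str]:
        """Map node id → canonical display name."""
        return {nid: n.canonical_name for nid, n in self.nodes.items()}

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Network mode={self.mode!r} nodes={len(self.nodes)} edges={len(self.edges)}>"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.nodes == other.nodes
            and self._by_key == other._by_key
        )


def combine_channel_scores(
    scores: Mapping[str, float],
    enabled: Iterable[str] | None = None,
    prior: float = 0.0,
) -> float:
    """Probabilistically combine channel subscores into one confidence.

    Each enabled channel score first has the prior removed,
    ``s' = max(0, (s - prior) / (1 - prior))``; the prior-free evidence is
    combined as a noisy-OR, ``c = 1 - prod(1 - s')``, assuming channel
    independence; finally the prior is restored:
    ``combined = c * (1 - prior) + prior``.

    The result lies in ``[prior, 1]``, is invariant under channel ordering
    and monotone non-decreasing in every channel score.  Evidence at or
    below the prior contributes nothing (clamps to the prior).

    Parameters
    ----------
    scores
        Mapping channel name → subscore in [0, 1]; absent channels count 0.
    enabled
        Channels to include (default: all seven).
    prior
        Baseline association probability, in ``[0, 1)``.
    """
    prior = float(prior)
    if not (0.0 <= prior < 1.0):
        raise InvalidParameterError(f"prior must be in [0, 1), got {prior!r}")
    if enabled is None:
        enabled_t: tuple[str, ...] = CHANNELS
    else:
        enabled_t = tuple(enabled)
        for name in enabled_t:
            if name not in _CHANNEL_SET:
                raise InvalidParameterError(f"unknown channel {name!r} in enabled set")
    residual = 1.0
    for name in enabled_t:
        s = _check_score(scores.get(name, 0.0), f"channel {name!r} score")
        s_prime = max(0.0, (s - prior) / (1.0 - prior))
        residual *= 1.0 - s_prime
    return (1.0 - residual) * (1.0 - prior) + prior


def recompute_combined(
    network: Network,
    enabled: Iterable[str],
    prior: float = 0.0,
) -> Network:
    """Recompute combined scores from a subset of enabled channels.

    Edges with no enabled evidence above the prior (recomputed score equal
    to the prior) are dropped; all nodes are retained.
    """
    enabled_t = tuple(enabled)
    if not enabled_t:
        raise InvalidParameterError("enabled channel set must be non-empty")
    if network.mode == "regulatory":
        raise InvalidInputError("recompute_combined applies to channel-scored networks")
    new_edges = []
    for edge in network.edges:
        assert isinstance(edge, Edge)
        combined = combine_channel_scores(edge.channels, enabled_t, prior)
        if combined <= prior:
            continue  # no enabled evidence remains
        kept = {ch: s for ch, s in edge.channels.items() if ch in enabled_t}
        new_edges.append(Edge(edge.u, edge.v, kept, combined))
    return Network(network.nodes.values(), new_edges, network.mode)


def filter_by_confidence(network: Network, cutoff: float) -> Network:
    """Keep exactly the edges with confidence >= cutoff; nodes are retained."""
    cutoff = float(cutoff)
    if not (0.0 <= cutoff <= 1.0):
        raise InvalidParameterError(f"cutoff must be in [0, 1], got {cutoff!r}")

    def conf(edge: Edge | RegulatoryEdge) -> float:
        return edge.confidence if isinstance(edge, RegulatoryEdge) else edge.combined

    kept = [replace(e) if isinstance(e, RegulatoryEdge) else Edge(e.u, e.v, dict(e.channels), e.combined)
            for e in network.edges if conf(e) >= cutoff]
    return Network(network.nodes.values(), kept, network.mode)


class ModeViolation(NamedTuple):
    """One pair breaking functional-containment of a specific network."""

    pair: tuple[str, str]
    specific_confidence: float
    functional_confidence: float | None  # None: pair absent from functional


def check_mode_consistency(
    specific: Network, functional: Network, tol: float = 1e-12
) -> list[ModeViolation]:
    """Verify that a physical/regulatory network is contained in its functional parent.

    Every pair in the specific network (either direction for regulatory
    edges) must be present in the functional network with an equal-or-higher
    combined score.  Returns the list of violating pairs; an empty list
    means the two networks are consistent.
    """
    if specific.mode not in ("physical", "regulatory"):
        raise InvalidInputError(
            f"specific network must be physical or regulatory, got {specific.mode!r}"
        )
    if functional.mode != "functional":
        raise InvalidInputError(
            f"parent network must be functional, got {functional.mode!r}"
        )
    parent: dict[tuple[str, str], float] = {}
    for edge in functional.edges:
        assert isinstance(edge, Edge)
        parent[edge.key] = edge.combined

    violations: list[ModeViolation] = []
    for edge in specific.edges:
        if isinstance(edge, RegulatoryEdge):
            pair = tuple(sorted((edge.source, edge.target)))
            conf = edge.confidence
        else:
            pair = edge.key
            conf = edge.combined
        func = parent.get(pair)  # type: ignore[arg-type]
        if func is None:
            violations.append(ModeViolation(pair, conf, None))  # type: ignore[arg-type]
        elif func + tol < conf:
            violations.append(ModeViolation(pair, conf, func))  # type: ignore[arg-type]
    return violations
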