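"""Seeded generators for every input the toolkit consumes.

These generators produce planted-module networks, term collections with a
small-term-heavy noise component, contaminated query sets and separable
gold standards — each with its ground truth returned alongside, so
downstream recovery can be measured.  All randomness flows from a single
seed through named substreams, making every fixture a pure function of its
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy.stats import beta as beta_dist

from .calibrate import GoldStandard, ScoredPrediction
from .enrich import Term, TermCollection
from .errors import InvalidInputError, InvalidParameterError
from .network import (
    CHANNELS,
    ActionType,
    Edge,
    Network,
    Node,
    combine_channel_scores,
)

# substream tags: one per generator, so fixtures drawn from one seed are
# mutually independent
_STREAMS = {"network": 1, "terms": 2, "query": 3, "gold": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a small planted-module benchmark: three modules of 15
    proteins, dense high-confidence edges inside modules (p_in = 0.6,
    scores drawn around 0.8) and sparse weaker edges between them
    (p_out = 0.05).  Score entries may be a constant float or a Beta
    (a, b) shape pair.  The gold standard draws positive raw scores from
    Beta(5, 2) and negative from Beta(2, 5) — overlapping but separable, a
    realistic benchmark difficulty.
    """

    seed: int = 0
    module_sizes: tuple[int, ...] = (15, 15, 15)
    p_in: float = 0.6
    p_out: float = 0.05
    score_in: float | tuple[float, float] = (8.0, 2.0)
    score_out: float | tuple[float, float] = (2.0, 8.0)
    # term collection
    n_noise_terms: int = 200
    noise_size_geom_p: float = 0.5
    noise_size_max: int = 30
    # query
    contamination: float = 0.2
    # gold standard / calibration benchmark
    n_gold_positives: int = 1000
    gold_negative_per_positive: float = 9.0
    beta_pos: tuple[float, float] = (5.0, 2.0)
    beta_neg: tuple[float, float] = (2.0, 5.0)
    gold_category: str = "regulation"

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.contamination):
            if not (0.0 <= p <= 1.0):
                raise InvalidParameterError(f"probability {p} outside [0, 1]")
        if any(s < 1 for s in self.module_sizes):
            raise InvalidParameterError("module sizes must be >= 1")


def _draw_score(spec: float | tuple[float, float], rng: np.random.Generator) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    a, b = spec
    # keep scores strictly inside (0, 1) so -ln transforms stay finite
    return float(np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-9))


def _decompose_channels(
    combined: float, rng: np.random.Generator
) -> tuple[dict[str, float], float]:
    """Split a target combined score across two random channels.

    Solves the zero-prior noisy-OR backwards: with mixing fraction u,
    s1 = 1 - (1-c)^u and s2 = 1 - (1-c)^(1-u) recombine to c exactly (up
    to float rounding).  The returned combined score is recomputed from the
    channels so stored and recomputed scores agree bit-for-bit.
    """
    ch = rng.choice(len(CHANNELS), size=2, replace=False)
    u = rng.uniform(0.2, 0.8)
    rest = 1.0 - combined
    channels = {
        CHANNELS[ch[0]]: 1.0 - rest**u,
        CHANNELS[ch[1]]: 1.0 - rest ** (1.0 - u),
    }
    return channels, combine_channel_scores(channels)


def planted_partition_network(config: SynthConfig) -> tuple[Network, dict[str, int]]:
    """Planted-partition network plus the true module label of every node.

    Within-module pairs are linked with probability ``p_in`` (scores from
    ``score_in``), between-module pairs with ``p_out`` (scores from
    ``score_out``).  Channel subscores are decomposed from the drawn
    combined score so channel recombination reproduces it exactly.
    """
    rng = _rng(config.seed, "network")
    labels: dict[str, int] = {}
    nodes: list[Node] = []
    for module, size in enumerate(config.module_sizes):
        for j in range(len(nodes), len(nodes) + size):
            nid = f"P{j:04d}"
            nodes.append(Node(nid, canonical_name=f"gene{j}", species="synthetic"))
            labels[nid] = module
    ids = [n.id for n in nodes]
    edges: list[Edge] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same = labels[ids[i]] == labels[ids[j]]
            p = config.p_in if same else config.p_out
            if rng.random() >= p:
                continue
            target = _draw_score(config.score_in if same else config.score_out, rng)
            channels, combined = _decompose_channels(target, rng)
            edges.append(Edge(ids[i], ids[j], channels, combined))
    return Network(nodes, edges, mode="functional"), labels


def synth_term_collection(
    universe: Iterable[str],
    planted_sets: Mapping[str, Iterable[str]],
    config: SynthConfig,
) -> tuple[TermCollection, list[str]]:
    """Term collection with planted terms plus small-term-heavy noise.

    ``planted_sets`` maps a description to its member genes; each becomes a
    term in the "GO Biological Process" category.  Noise terms draw their
    sizes from a geometric distribution (floor 1, rich in single-gene
    terms, which exercises the viability filter) and their members
    uniformly from the universe.  Returns the collection and the planted
    term ids.
    """
    universe = sorted(set(universe))
    if not universe:
        raise InvalidInputError("universe must be non-empty")
    rng = _rng(config.seed, "terms")
    terms: list[Term] = []
    planted_ids: list[str] = []
    for idx, (description, members) in enumerate(planted_sets.items()):
        members = frozenset(members)
        if not members <= set(universe):
            raise InvalidInputError(f"planted set {description!r} leaves the universe")
        tid = f"PLANTED:{idx:04d}"
        planted_ids.append(tid)
        terms.append(Term(tid, "GO Biological Process", description, members))
    for j in range(config.n_noise_terms):
        size = int(min(rng.geometric(config.noise_size_geom_p),
                       config.noise_size_max, len(universe)))
        members = rng.choice(len(universe), size=size, replace=False)
        terms.append(
            Term(
                f"NOISE:{j:05d}",
                "GO Biological Process",
                f"noise set {j}",
                frozenset(universe[i] for i in members),
            )
        )
    return TermCollection(terms), planted_ids


def synth_query_set(
    collection: TermCollection,
    planted_term_id: str,
    contamination: float,
    seed: int,
    universe: Iterable[str] | None = None,
) -> frozenset[str]:
    """Query built from a planted term with a contamination fraction.

    A fraction (1 − c) of the query (rounded to nearest) is drawn from the
    planted term's members, the remainder uniformly from the rest of the
    universe; the query size equals the planted term's size.
    """
    if planted_term_id not in collection.terms:
        raise InvalidInputError(f"unknown planted term {planted_term_id!r}")
    if not (0.0 <= contamination <= 1.0):
        raise InvalidParameterError("contamination must be in [0, 1]")
    rng = _rng(seed, "query")
    members = sorted(collection.terms[planted_term_id].members)
    pool = sorted(set(universe) if universe is not None else collection.universe)
    outside = sorted(set(pool) - set(members))
    size = len(members)
    k_in = int(round((1.0 - contamination) * size))
    k_out = min(size - k_in, len(outside))
    chosen = set(
        members[i] for i in rng.choice(len(members), size=k_in, replace=False)
    )
    if k_out:
        chosen |= {outside[i] for i in rng.choice(len(outside), size=k_out, replace=False)}
    return frozenset(chosen)


def synth_regulatory_gold(
    universe: Iterable[str],
    config: SynthConfig,
) -> tuple[GoldStandard, list[ScoredPrediction], Callable[[np.ndarray], np.ndarray]]:
    """Gold standard + scored predictions + the analytic posterior.

    Positive pairs get raw scores from Beta(beta_pos), sampled non-positive
    pairs from Beta(beta_neg).  The returned closure computes the exact
    mixture posterior P(positive | raw) implied by those densities and the
    positive fraction, for calibration-recovery checks.  Action types are
    assigned uniformly over the taxonomy; signs follow the signed subtypes.
    """
    universe = sorted(set(universe))
    n_genes = len(universe)
    if n_genes < 2:
        raise InvalidInputError("universe must contain at least two genes")
    rng = _rng(config.seed, "gold")
    n_pos = config.n_gold_positives
    n_neg = int(round(config.gold_negative_per_positive * n_pos))
    total_pairs = n_genes * (n_genes - 1)
    if n_pos + n_neg > total_pairs:
        raise InvalidParameterError(
            f"universe of {n_genes} genes has only {total_pairs} ordered pairs; "
            f"cannot draw {n_pos + n_neg}"
        )
    # sample distinct ordered non-self pairs by index
    idx = rng.choice(total_pairs, size=n_pos + n_neg, replace=False)
    pairs = []
    for flat in idx:
        a, b = divmod(int(flat), n_genes - 1)
        if b >= a:
            b += 1
        pairs.append((universe[a], universe[b]))
    positives = frozenset(pairs[:n_pos])
    gold = GoldStandard(config.gold_category, positives, frozenset(universe))

    action_types = list(ActionType)
    predictions: list[ScoredPrediction] = []
    raw_pos = rng.beta(*config.beta_pos, size=n_pos)
    raw_neg = rng.beta(*config.beta_neg, size=n_neg)
    for pair, raw in zip(pairs, np.concatenate([raw_pos, raw_neg])):
        action = action_types[int(rng.integers(len(action_types)))]
        sign = {
            ActionType.POSITIVE_REGULATION: "positive",
            ActionType.NEGATIVE_REGULATION: "negative",
        }.get(action, "unspecified")
        predictions.append(
            ScoredPrediction(pair[0], pair[1], float(raw), "unknown", action, sign)
        )

    pi = n_pos / (n_pos + n_neg)
    a1, b1 = config.beta_pos
    a2, b2 = config.beta_neg

    def posterior(raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        f_pos = beta_dist.pdf(raw, a1, b1)
        f_neg = beta_dist.pdf(raw, a2, b2)
        num = pi * f_pos
        den = num + (1.0 - pi) * f_neg
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, pi)
        return out

    return gold, predictions, posterior
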