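"""Overrepresentation analysis with a power-aware term-viability filter.

Given a query gene set, a background (gene universe) and a collection of
annotated gene sets ("terms", organized into "categories" such as Gene
Ontology Biological Process), each term is tested for overrepresentation
with the one-sided hypergeometric tail, and p-values are corrected within
each category by the Benjamini–Hochberg (BH) step-up procedure.

The distinguishing feature is the *viability filter*: before testing, terms
whose best-case p-value (complete overlap with the query) cannot reach the
significance level are excluded, and crucially they do not count toward the
multiple-testing correction.  Ontology-style collections contain many more
tiny terms than large ones; removing the hopeless ones increases power for
every tested term without ever excluding a term that could have been
rejected — a term excluded under the default bound satisfies
``p_min(m) > alpha``, and since a BH-adjusted q-value is never below its
raw p-value, such a term can never be BH-significant at ``alpha``.

Result rows carry, per term:

* ``pvalue`` and ``fdr`` (within-category BH);
* ``strength`` — log10(observed / expected) fold enrichment;
* ``signal`` — weighted harmonic mean of the observed/expected ratio and
  −log10(FDR), the default ranking key (balances effect size against
  statistical confidence);
* redundancy ``kept`` flags (greedy Jaccard filter in p-value order) and
  similarity ``group`` labels (average-linkage Jaccard clustering).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .errors import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class Term:
    """One annotated gene set within a category."""

    id: str
    category: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidInputError(f"term {self.id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


class TermCollection:
    """A set of terms, unique by id, grouped into categories."""

    def __init__(self, terms: Iterable[Term]):
        self.terms: dict[str, Term] = {}
        for term in terms:
            if term.id in self.terms:
                raise InvalidInputError(f"duplicate term id {term.id!r}")
            self.terms[term.id] = term

    @property
    def universe(self) -> frozenset[str]:
        """Union of all term members."""
        out: set[str] = set()
        for term in self.terms.values():
            out |= term.members
        return frozenset(out)

    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for term in self.terms.values():
            seen.setdefault(term.category, None)
        return list(seen)

    def by_category(self) -> dict[str, list[Term]]:
        out: dict[str, list[Term]] = {}
        for term in self.terms.values():
            out.setdefault(term.category, []).append(term)
        return out

    def merged(self, other: "TermCollection") -> "TermCollection":
        return TermCollection(list(self.terms.values()) + list(other.terms.values()))

    def __iter__(self):
        return iter(self.terms.values())

    def __len__(self) -> int:
        return len(self.terms)


class ViabilityBound(Enum):
    """Threshold against which the best-case p-value is compared.

    ``ALPHA`` (default) uses the loosest possible BH rejection level and is
    guaranteed never to exclude a rejectable term.  ``ALPHA_OVER_T`` uses the
    Bonferroni-style ``alpha / T`` bound (T = term count in the category);
    stricter, excludes more terms, but may drop a term that the step-up
    procedure would have rejected.
    """

    ALPHA = "alpha"
    ALPHA_OVER_T = "alpha_over_t"


@dataclass
class EnrichmentOptions:
    """Tunable settings for :func:`run_enrichment`."""

    alpha: float = 0.05
    viability_filter: bool = True
    viability_bound: ViabilityBound = ViabilityBound.ALPHA
    jaccard_cutoff: float | None = None
    group_cutoff: float | None = None
    w_ratio: float = 1.0
    w_fdr: float = 1.0
    fdr_floor: float = 1e-15


@dataclass
class EnrichmentQuery:
    """Query gene set, optional background, and analysis options."""

    query: frozenset[str]
    background: frozenset[str] | None = None
    options: EnrichmentOptions = field(default_factory=EnrichmentOptions)

    def __post_init__(self) -> None:
        self.query = frozenset(self.query)
        if self.background is not None:
            self.background = frozenset(self.background)
        if not (0.0 < self.options.alpha < 1.0):
            raise InvalidParameterError("alpha must lie in (0, 1)")


@dataclass
class EnrichmentRow:
    """Per-term test result."""

    term: Term
    observed: int
    expected: float
    term_size_effective: int
    pvalue: float
    fdr: float
    strength: float
    signal: float
    members_effective: frozenset[str]
    group: str | None = None
    kept: bool = True

    @property
    def ratio(self) -> float:
        return self.observed / self.expected if self.expected > 0 else 0.0


def hypergeometric_tail(k: int, n: int, m: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    N genes in the background, m of which belong to the term; n are drawn
    (the query); k is the observed overlap.
    """
    if not (0 <= k <= min(n, m) and 0 <= n <= N and 0 <= m <= N):
        raise InvalidInputError(
            f"inconsistent counts k={k}, n={n}, m={m}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def min_achievable_pvalue(m: int, n: int, N: int) -> float:
    """Best-case (complete-overlap) p-value for a term of size m."""
    if not (1 <= m <= N) or not (1 <= n <= N):
        raise InvalidInputError(f"need 1 <= m, n <= N; got m={m}, n={n}, N={N}")
    return hypergeometric_tail(min(m, n), n, m, N)


def _viable_size_mask(n: int, N: int, threshold: float) -> np.ndarray:
    """Boolean mask over term sizes 0..N: True where p_min(m) <= threshold."""
    m = np.arange(N + 1)
    k_best = np.minimum(m, n)
    with np.errstate(divide="ignore"):
        p_min = hypergeom.sf(k_best - 1, N, m, n)
    mask = p_min <= threshold
    mask[0] = False
    return mask


def viable_term_size_range(
    n: int,
    N: int,
    alpha: float,
    collection: Mapping[str, int] | None = None,
    bound: ViabilityBound = ViabilityBound.ALPHA,
) -> tuple[int | None, int | None, list[str]]:
    """Smallest and largest term sizes with any statistical potential.

    A term of effective size ``m`` is viable iff its best-case p-value
    ``p_min(m) = P(X >= min(m, n))`` does not exceed the significance
    threshold (the most lenient BH rejection level under the default
    bound).  Returns ``(m_lo, m_hi, excluded_ids)`` where ``excluded_ids``
    lists the non-viable entries of ``collection`` (a mapping term id →
    effective size).  ``(None, None, ...)`` when no size is viable.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if n < 1:
        raise InvalidInputError("query size n must be >= 1")
    threshold = alpha
    if bound is ViabilityBound.ALPHA_OVER_T and collection:
        threshold = alpha / max(len(collection), 1)
    mask = _viable_size_mask(n, N, threshold)
    viable = np.flatnonzero(mask)
    m_lo = int(viable[0]) if viable.size else None
    m_hi = int(viable[-1]) if viable.size else None
    excluded: list[str] = []
    if collection is not None:
        for tid, size in collection.items():
            if size < 1 or size > N or not mask[size]:
                excluded.append(tid)
    return m_lo, m_hi, excluded


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values, input order preserved.

    ``q_i = min over j with p_(j) >= p_(i) of p_(j) * T / j``, clamped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    T = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * T / np.arange(1, T + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(T)
    q[order] = q_sorted
    return q


def signal(
    ratio: float,
    fdr: float,
    w_ratio: float = 1.0,
    w_fdr: float = 1.0,
    fdr_floor: float = 1e-15,
) -> float:
    """Weighted harmonic mean of the enrichment ratio and −log10(FDR).

    Returns 0 when either component carries no evidence (ratio <= 0 or
    FDR >= 1).  The FDR is floored at ``fdr_floor`` so vanishing q-values
    do not dominate the mean.
    """
    if w_ratio < 0 or w_fdr < 0 or w_ratio + w_fdr <= 0:
        raise InvalidParameterError("signal weights must be non-negative with positive sum")
    if ratio <= 0:
        return 0.0
    b = -math.log10(max(fdr, fdr_floor))
    if w_fdr == 0:
        return float(ratio)
    if b <= 0:
        return 0.0
    if w_ratio == 0:
        return b
    return (w_ratio + w_fdr) / (w_ratio / ratio + w_fdr / b)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B| for two non-empty gene sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise InvalidInputError("Jaccard similarity needs non-empty sets")
    return len(sa & sb) / len(sa | sb)


def _p_order_key(row: EnrichmentRow) -> tuple:
    # ties broken by larger effective size, then lexicographic id
    return (row.pvalue, -row.term_size_effective, row.term.id)


def redundancy_filter(
    rows: list[EnrichmentRow], jaccard_cutoff: float
) -> list[EnrichmentRow]:
    """Greedy Jaccard redundancy filter within one category.

    Rows are visited in ascending p-value order (ties: larger term first,
    then id); a row is kept iff its similarity to every already-kept row is
    at most the cutoff.  Sets are compared after background intersection.
    Mutates and returns ``rows`` with updated ``kept`` flags.
    """
    if not (0.0 <= jaccard_cutoff <= 1.0):
        raise InvalidParameterError("jaccard_cutoff must be in [0, 1]")
    kept: list[EnrichmentRow] = []
    for row in sorted(rows, key=_p_order_key):
        if not row.members_effective:
            row.kept = False
            continue
        row.kept = all(
            jaccard(row.members_effective, other.members_effective) <= jaccard_cutoff
            for other in kept
        )
        if row.kept:
            kept.append(row)
    return rows


def group_terms(
    rows: list[EnrichmentRow], group_cutoff: float
) -> dict[str, list[EnrichmentRow]]:
    """Average-linkage Jaccard grouping of one category's rows.

    Clusters are merged while the average similarity of the merge is at
    least ``group_cutoff`` (equivalently: average-linkage distance
    1 − Jaccard at most 1 − cutoff).  Returns group label → rows, with
    groups ordered by the maximum signal of their terms (descending) and
    rows within a group by individual signal; ``row.group`` is set to the
    label.  Labels are ``g1``, ``g2``, ... in that order.
    """
    if not (0.0 <= group_cutoff <= 1.0):
        raise InvalidParameterError("group_cutoff must be in [0, 1]")
    rows = [r for r in rows]
    if not rows:
        return {}
    if len(rows) == 1:
        labels = np.array([1])
    else:
        sets = [r.members_effective for r in rows]
        dist = np.zeros((len(rows), len(rows)))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                sim = jaccard(sets[i], sets[j]) if sets[i] and sets[j] else 0.0
                dist[i, j] = dist[j, i] = 1.0 - sim
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=1.0 - group_cutoff, criterion="distance")
    clusters: dict[int, list[EnrichmentRow]] = {}
    for row, lab in zip(rows, labels):
        clusters.setdefault(int(lab), []).append(row)
    ordered = sorted(
        clusters.values(),
        key=lambda grp: (-max(r.signal for r in grp), min(r.term.id for r in grp)),
    )
    out: dict[str, list[EnrichmentRow]] = {}
    for idx, grp in enumerate(ordered, start=1):
        label = f"g{idx}"
        grp.sort(key=lambda r: (-r.signal, r.pvalue, r.term.id))
        for row in grp:
            row.group = label
        out[label] = grp
    return out


def run_enrichment(
    query: EnrichmentQuery | Iterable[str],
    collection: TermCollection,
    background: Iterable[str] | None = None,
    options: EnrichmentOptions | None = None,
) -> list[EnrichmentRow]:
    """Full overrepresentation pipeline.

    Per category: intersect term members with the background, drop
    non-viable terms (they do not count toward the correction), test the
    rest with the hypergeometric tail, BH-correct within the category, and
    compute strength and signal.  Redundancy filtering and similarity
    grouping run when the corresponding cutoffs are set in the options.
    Rows are returned sorted by signal descending (group order when
    grouping is on).

    An effectively empty query yields an empty list with a warning rather
    than an exception.
    """
    if not isinstance(query, EnrichmentQuery):
        query = EnrichmentQuery(
            frozenset(query),
            frozenset(background) if background is not None else None,
            options or EnrichmentOptions(),
        )
    opts = query.options
    bg = query.background if query.background is not None else collection.universe
    bg = frozenset(bg)
    q = query.query & bg
    if not q or not bg:
        warnings.warn("query is empty after background intersection; no tests run")
        return []
    N, n = len(bg), len(q)

    all_rows: list[EnrichmentRow] = []
    for category, terms in collection.by_category().items():
        eff = {t.id: t.members & bg for t in terms}
        sizes = {tid: len(mem) for tid, mem in eff.items() if len(mem) >= 1}
        if opts.viability_filter:
            _, _, excluded = viable_term_size_range(
                n, N, opts.alpha, sizes, opts.viability_bound
            )
            tested = [t for t in terms if t.id in sizes and t.id not in set(excluded)]
        else:
            tested = [t for t in terms if t.id in sizes]
        if not tested:
            continue
        pvals = []
        for term in tested:
            k = len(q & eff[term.id])
            pvals.append(hypergeometric_tail(k, n, sizes[term.id], N))
        qvals = benjamini_hochberg(pvals)
        for term, p, fdr in zip(tested, pvals, qvals):
            m = sizes[term.id]
            k = len(q & eff[term.id])
            expected = n * m / N
            ratio = k / expected
            strength = math.log10(ratio) if k > 0 else float("nan")
            sig = signal(ratio, float(fdr), opts.w_ratio, opts.w_fdr, opts.fdr_floor)
            all_rows.append(
                EnrichmentRow(
                    term=term,
                    observed=k,
                    expected=expected,
                    term_size_effective=m,
                    pvalue=float(p),
                    fdr=float(fdr),
                    strength=strength,
                    signal=sig,
                    members_effective=frozenset(eff[term.id]),
                )
            )

    by_cat: dict[str, list[EnrichmentRow]] = {}
    for row in all_rows:
        by_cat.setdefault(row.term.category, []).append(row)
    if opts.jaccard_cutoff is not None:
        for rows in by_cat.values():
            redundancy_filter(rows, opts.jaccard_cutoff)
    if opts.group_cutoff is not None:
        groups: list[tuple[float, str, list[EnrichmentRow]]] = []
        for rows in by_cat.values():
            grouped = group_terms([r for r in rows if r.kept], opts.group_cutoff)
            for label, grp in grouped.items():
                groups.append((max(r.signal for r in grp), label, grp))
        groups.sort(key=lambda item: (-item[0], item[1]))
        ordered: list[EnrichmentRow] = []
        for idx, (_, _, grp) in enumerate(groups, start=1):
            label = f"g{idx}"
            for row in grp:
                row.group = label
            ordered.extend(grp)
        ordered.extend(
            sorted(
                (r for r in all_rows if not r.kept),
                key=lambda r: (-r.signal, r.pvalue, r.term.id),
            )
        )
        return ordered
    return sorted(all_rows, key=lambda r: (-r.signal, r.pvalue, r.term.id))


@dataclass(frozen=True)
class PlotRecord:
    """One dot of the enrichment dot plot."""

    term_id: str
    description: str
    category: str
    x_signal: float
    fdr: float
    size_observed: int
    y_rank: int
    group: str | None


def dotplot_table(rows: Sequence[EnrichmentRow]) -> list[PlotRecord]:
    """Plot records for the kept rows, in display (y-rank) order.

    x = signal, color key = FDR, dot size key = observed count; the y-rank
    follows the incoming row order, which is the grouping order when
    grouping was applied.
    """
    records = []
    rank = 0
    for row in rows:
        if not row.kept:
            continue
        records.append(
            PlotRecord(
                term_id=row.term.id,
                description=row.term.description,
                category=row.term.category,
                x_signal=row.signal,
                fdr=row.fdr,
                size_observed=row.observed,
                y_rank=rank,
                group=row.group,
            )
        )
        rank += 1
    return records


ENRICHMENT_COLUMNS = (
    "category",
    "term_id",
    "description",
    "observed",
    "expected",
    "term_size_effective",
    "pvalue",
    "fdr",
    "strength",
    "signal",
    "group",
    "kept",
)


def enrichment_table(rows: Sequence[EnrichmentRow]):
    """Rows as a pandas DataFrame with the standard output columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "category": r.term.category,
                "term_id": r.term.id,
                "description": r.term.description,
                "observed": r.observed,
                "expected": r.expected,
                "term_size_effective": r.term_size_effective,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "strength": r.strength,
                "signal": r.signal,
                "group": r.group if r.group is not None else "",
                "kept": r.kept,
            }
            for r in rows
        ],
        columns=list(ENRICHMENT_COLUMNS),
    )
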