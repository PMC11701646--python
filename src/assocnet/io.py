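"""Reading and writing the text formats the package consumes.

Formats handled here:

* links tables — whitespace-separated text with one header row, one edge per
  row, per-channel subscores and a combined score.  Scores come in two
  dialects: the unit scale (floats in [0, 1]) and the "millipoint" scale
  (integers 0–1000); ``score_scale="auto"`` infers millipoint iff any score
  value exceeds 1.
* regulatory tables — TSV with columns
  (source, target, action_type, sign, confidence_forward, confidence_reverse).
* gene-set collections — GMT (term id, description, members...) with the
  category supplied per file, or long-form TSV (term_id, category,
  description, gene).
* plain gene lists (one id per line) and calibration-curve TSVs.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .calibrate import CalibrationCurve
from .enrich import Term, TermCollection
from .errors import InvalidInputError, InvalidParameterError, ParseError
from .network import CHANNELS, ActionType, Edge, Network, Node, RegulatoryEdge

# Column-name aliases accepted in links-table headers.  The historical
# download dialect spells co-occurrence as "cooccurence" and uses
# "experimental" / "combined_score"; both spellings are accepted.
_HEADER_ALIASES = {
    "neighborhood": "neighborhood",
    "fusion": "fusion",
    "cooccurence": "cooccurrence",
    "cooccurrence": "cooccurrence",
    "coexpression": "coexpression",
    "experimental": "experiments",
    "experiments": "experiments",
    "database": "database",
    "textmining": "textmining",
    "combined_score": "combined",
    "combined": "combined",
}

#: Header written by :func:`write_links_table` (download dialect).
LINKS_HEADER = (
    "protein1 protein2 neighborhood fusion cooccurence coexpression "
    "experimental database textmining combined_score"
)

REGULATORY_COLUMNS = (
    "source",
    "target",
    "action_type",
    "sign",
    "confidence_forward",
    "confidence_reverse",
)


def _scale_scores(df: pd.DataFrame, cols: list[str], score_scale: str, path: str) -> None:
    if score_scale not in ("auto", "unit", "millipoint"):
        raise InvalidParameterError(f"unknown score_scale {score_scale!r}")
    if not cols:
        return
    values = df[cols].to_numpy(dtype=float)
    if score_scale == "auto":
        score_scale = "millipoint" if (values > 1).any() else "unit"
    if score_scale == "millipoint":
        values = values / 1000.0
    if (values < 0).any() or (values > 1).any():
        raise InvalidInputError(f"{path}: score outside [0, 1] after scaling")
    df[cols] = values


def read_links_table(path: str | Path, score_scale: str = "auto") -> Network:
    """Read a whitespace-separated links table into a functional-mode network.

    The header must name the two node columns ``protein1``/``protein2``;
    remaining columns are channel subscores and/or the combined score.
    Duplicate pairs with identical scores are collapsed; conflicting
    duplicates raise :class:`ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: missing header row") from None
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "protein1" or cols[1] != "protein2":
        raise ParseError(
            f"{path}: header must start with 'protein1 protein2', got {cols[:2]}"
        )
    score_cols: list[str] = []
    mapped: dict[str, str] = {}
    for col in cols[2:]:
        if col not in _HEADER_ALIASES:
            raise ParseError(f"{path}: unrecognized column {col!r}")
        mapped[col] = _HEADER_ALIASES[col]
        score_cols.append(col)
    _scale_scores(df, score_cols, score_scale, str(path))

    nodes: dict[str, Node] = {}
    seen: dict[tuple[str, str], Edge] = {}
    for row in df.itertuples(index=False):
        u, v = str(row[0]), str(row[1])
        channels: dict[str, float] = {}
        combined = None
        for i, col in enumerate(score_cols, start=2):
            value = float(row[i])
            name = mapped[col]
            if name == "combined":
                combined = value
            elif value > 0:
                channels[name] = value
        if combined is None:
            from .network import combine_channel_scores

            combined = combine_channel_scores(channels)
        try:
            edge = Edge(u, v, channels, combined)
        except InvalidInputError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        prev = seen.get(edge.key)
        if prev is not None:
            if prev.channels != edge.channels or prev.combined != edge.combined:
                raise ParseError(
                    f"{path}: duplicate pair {edge.u}--{edge.v} with conflicting scores"
                )
            continue
        seen[edge.key] = edge
        for nid in (u, v):
            nodes.setdefault(nid, Node(nid))
    return Network(nodes.values(), seen.values(), mode="functional")


def _fmt_unit(x: float) -> str:
    return repr(float(x))


def write_links_table(
    network: Network, path: str | Path, score_scale: str = "unit"
) -> None:
    """Write a channel-scored network in the links-table dialect.

    ``unit`` writes full-precision floats (lossless round-trip);
    ``millipoint`` writes integers 0–1000 (scores quantized to 1/1000).
    """
    if score_scale not in ("unit", "millipoint"):
        raise InvalidParameterError(f"score_scale must be unit or millipoint")
    if network.mode == "regulatory":
        raise InvalidInputError("use write_regulatory_table for regulatory networks")

    def fmt(x: float) -> str:
        if score_scale == "millipoint":
            return str(int(round(x * 1000)))
        return _fmt_unit(x)

    path = Path(path)
    with path.open("w") as fh:
        fh.write(LINKS_HEADER + "\n")
        for edge in network.edges:
            assert isinstance(edge, Edge)
            scores = [edge.channels.get(ch, 0.0) for ch in CHANNELS] + [edge.combined]
            fh.write(" ".join([edge.u, edge.v, *(fmt(s) for s in scores)]) + "\n")


def read_regulatory_table(path: str | Path) -> Network:
    """Read a six-column TSV of directed regulatory edges."""
    path = Path(path)
    nodes: dict[str, Node] = {}
    edges: list[RegulatoryEdge] = []
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != REGULATORY_COLUMNS:
            raise ParseError(
                f"{path}: expected header {REGULATORY_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(row)}")
            src, tgt, action, sign, fwd, rev = row
            try:
                edge = RegulatoryEdge(
                    src, tgt, ActionType(action), sign, float(fwd), float(rev)
                )
            except (ValueError, InvalidInputError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            edges.append(edge)
            for nid in (src, tgt):
                nodes.setdefault(nid, Node(nid))
    return Network(nodes.values(), edges, mode="regulatory")


def write_regulatory_table(network: Network, path: str | Path) -> None:
    if network.mode != "regulatory":
        raise InvalidInputError("write_regulatory_table requires a regulatory network")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(REGULATORY_COLUMNS) + "\n")
        for edge in network.edges:
            assert isinstance(edge, RegulatoryEdge)
            fh.write(
                "\t".join(
                    [
                        edge.source,
                        edge.target,
                        edge.action_type.value,
                        edge.sign,
                        _fmt_unit(edge.confidence_forward),
                        _fmt_unit(edge.confidence_reverse),
                    ]
                )
                + "\n"
            )


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene id per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gmt(path: str | Path, category: str) -> TermCollection:
    """Read a GMT file (term id TAB description TAB member...), one category."""
    terms = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT rows need id, description, members")
        terms.append(Term(parts[0], category, parts[1], frozenset(parts[2:])))
    return TermCollection(terms)


def write_gmt(collection: TermCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in collection:
            fh.write("\t".join([term.id, term.description, *sorted(term.members)]) + "\n")


def read_term_table(path: str | Path) -> TermCollection:
    """Read a long-form TSV (term_id, category, description, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["term_id", "category", "description", "gene"]
    if list(df.columns) != required:
        raise ParseError(f"{path}: expected columns {required}, got {list(df.columns)}")
    terms = []
    for (tid, cat, desc), grp in df.groupby(
        ["term_id", "category", "description"], sort=False
    ):
        terms.append(Term(str(tid), str(cat), str(desc), frozenset(grp["gene"])))
    return TermCollection(terms)


def read_calibration_curve(path: str | Path) -> CalibrationCurve:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["raw_knot", "confidence"]:
        raise ParseError(f"{path}: expected columns raw_knot, confidence")
    return CalibrationCurve(df["raw_knot"].to_numpy(float), df["confidence"].to_numpy(float))


def write_calibration_curve(curve: CalibrationCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("raw_knot\tconfidence\n")
        for knot, value in zip(curve.knots, curve.values):
            fh.write(f"{_fmt_unit(knot)}\t{_fmt_unit(value)}\n")
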