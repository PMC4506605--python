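"""Domain types and I/O for two-compartment protein-interaction evidence.

The study this package supports collects candidate protein-protein
interactions (PPIs) for two gamete compartments (sperm and egg), each
candidate carrying per-evidence-channel confidence scores, a MINT-inspired
(MI) confidence score for physical evidence, a publication count and
physical/conservation flags.  This module defines the record types for
proteins and evidence, the undirected simple-graph network representation
(a :class:`networkx.Graph`), and tab-separated readers/writers for all of
them.

Conventions
-----------
* Accessions are opaque strings; no identifier mapping is attempted.
  Annotation tables carry both accession and gene symbol, and reports print
  gene symbols.
* Evidence pairs are canonicalized (lexicographically sorted); the unordered
  pair identifies the record.  Self-interactions are rejected at parse time
  because every downstream metric assumes a simple graph.
* Duplicate pairs are merged conservatively: per-channel maximum score,
  maximum MI score and publication count, logical OR of flags.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GameteNetError",
    "FormatError",
    "ValidationError",
    "ProteinRecord",
    "EvidenceRecord",
    "read_annotations",
    "read_evidence",
    "build_network",
    "new_network",
    "validate_network",
    "networks_equal",
    "write_network",
    "read_network",
]

COMPARTMENTS = ("sperm", "egg")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}
_NA_TOKENS = {"", "na"}


class GameteNetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GameteNetError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(GameteNetError):
    """Input content violates a domain invariant."""


def _parse_bool(token: str, *, context: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValidationError(f"{context}: cannot parse boolean value {token!r}")


# ---------------------------------------------------------------------------
# Protein annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its membrane annotations and compartment membership.

    Parameters
    ----------
    accession
        Opaque identifier (UniProt-style); unique within one table.
    gene_symbol
        Human-readable symbol used in reports and drug lookups.
    has_signal_peptide, has_transmembrane
        Sequence-feature flags; a protein with either is treated as a
        membrane candidate (the study's proxy for gamete-surface candidacy).
    compartments
        Subset of {"sperm", "egg"}; non-empty for any protein in a network.
    """

    accession: str
    gene_symbol: str
    has_signal_peptide: bool = False
    has_transmembrane: bool = False
    compartments: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        bad = set(self.compartments) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(
                f"protein {self.accession}: unknown compartments {sorted(bad)}"
            )

    @property
    def is_membrane(self) -> bool:
        """Signal sequence and/or transmembrane domain present."""
        return self.has_signal_peptide or self.has_transmembrane


_ANNOTATION_COLUMNS = (
    "accession",
    "gene_symbol",
    "signal_peptide",
    "transmembrane",
    "compartments",
)


def read_annotations(path: str | Path) -> list[ProteinRecord]:
    """Read a protein annotation TSV into a list of :class:`ProteinRecord`.

    Expected columns: ``accession``, ``gene_symbol``, ``signal_peptide``,
    ``transmembrane``, ``compartments`` (semicolon-separated).  Boolean
    columns accept 0/1/true/false/yes/no case-insensitively.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        On duplicate accessions or unparseable cells.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _ANNOTATION_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            acc = (row["accession"] or "").strip()
            if not acc:
                raise ValidationError(f"{path}:{lineno}: empty accession")
            if acc in seen:
                raise ValidationError(f"{path}: duplicate accession {acc!r}")
            seen.add(acc)
            comps = frozenset(
                c.strip() for c in (row["compartments"] or "").split(";") if c.strip()
            )
            records.append(
                ProteinRecord(
                    accession=acc,
                    gene_symbol=(row["gene_symbol"] or "").strip(),
                    has_signal_peptide=_parse_bool(
                        row["signal_peptide"], context=f"{path}:{lineno}"
                    ),
                    has_transmembrane=_parse_bool(
                        row["transmembrane"], context=f"{path}:{lineno}"
                    ),
                    compartments=comps,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Interaction evidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceRecord:
    """One candidate interaction with its confidence evidence.

    ``channel_scores`` are the per-evidence-channel probabilities fed to the
    noisy-OR score combiner; ``mi_score`` is the MINT-inspired confidence
    value for the physical-evidence route.  ``combined_score`` is never
    trusted from input files: it is (re)computed by the filtering stage so
    that filtering is reproducible from the channel scores alone.
    """

    protein_a: str
    protein_b: str
    channel_scores: tuple[float, ...] = ()
    combined_score: float | None = None
    mi_score: float = 0.0
    n_publications: int = 0
    is_physical: bool = False
    n_conserved_species: int = 0

    def __post_init__(self) -> None:
        a, b = self.protein_a, self.protein_b
        if not a or not b:
            raise ValidationError("evidence record with empty protein identifier")
        if a == b:
            raise ValidationError(f"self-interaction {a!r}-{b!r} is not allowed")
        if a > b:  # canonical order: lexicographically sorted pair
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)
        for s in self.channel_scores:
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"channel score {s} outside [0, 1] for pair "
                    f"({self.protein_a}, {self.protein_b})"
                )
        if not 0.0 <= self.mi_score <= 1.0:
            raise ValidationError(
                f"mi_score {self.mi_score} outside [0, 1] for pair "
                f"({self.protein_a}, {self.protein_b})"
            )
        if self.n_publications < 0 or self.n_conserved_species < 0:
            raise ValidationError("publication / conservation counts must be >= 0")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


_EVIDENCE_REQUIRED = (
    "protein_a",
    "protein_b",
    "mi_score",
    "n_publications",
    "is_physical",
    "n_conserved_species",
)
_CHANNEL_PREFIX = "score_"


def _parse_float(token: str, lo: float, hi: float, context: str) -> float | None:
    t = token.strip()
    if t.lower() in _NA_TOKENS:
        return None
    try:
        v = float(t)
    except ValueError as exc:
        raise ValidationError(f"{context}: cannot parse number {token!r}") from exc
    if not lo <= v <= hi:
        raise ValidationError(f"{context}: value {v} outside [{lo}, {hi}]")
    return v


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Read an interaction-evidence TSV, canonicalize and merge duplicates.

    Expected columns: ``protein_a``, ``protein_b``, any number of channel
    columns named ``score_<channel>``, then ``mi_score``, ``n_publications``,
    ``is_physical``, ``n_conserved_species``.  Unset numeric cells may be
    empty or ``NA`` (an unset channel score means that channel reported no
    evidence for the pair; unset MI/publication cells default to zero).

    Records for the same unordered pair are merged: per-channel maximum
    score, maximum MI score, maximum publication and conservation counts,
    logical OR of the physical flag.  The result is sorted by pair and is
    therefore independent of row order in the file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _EVIDENCE_REQUIRED:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        channel_cols = [c for c in header if c.startswith(_CHANNEL_PREFIX)]

        # per-pair accumulators
        chans: dict[tuple[str, str], dict[str, float]] = {}
        rest: dict[tuple[str, str], dict] = {}
        for lineno, row in enumerate(reader, start=2):
            ctx = f"{path}:{lineno}"
            a = (row["protein_a"] or "").strip()
            b = (row["protein_b"] or "").strip()
            if not a or not b:
                raise ValidationError(f"{ctx}: empty protein identifier")
            if a == b:
                raise ValidationError(f"{ctx}: self-interaction {a!r}")
            pair = (a, b) if a < b else (b, a)
            row_ch: dict[str, float] = {}
            for col in channel_cols:
                v = _parse_float(row.get(col) or "", 0.0, 1.0, f"{ctx} ({col})")
                if v is not None:
                    row_ch[col] = v
            mi = _parse_float(row["mi_score"] or "", 0.0, 1.0, f"{ctx} (mi_score)")
            pubs_f = _parse_float(
                row["n_publications"] or "", 0.0, float("inf"), f"{ctx} (n_publications)"
            )
            cons_f = _parse_float(
                row["n_conserved_species"] or "",
                0.0,
                float("inf"),
                f"{ctx} (n_conserved_species)",
            )
            phys = _parse_bool(row["is_physical"] or "0", context=ctx)
            cur_ch = chans.setdefault(pair, {})
            for col, v in row_ch.items():
                cur_ch[col] = max(cur_ch.get(col, 0.0), v)
            cur = rest.setdefault(
                pair,
                {"mi": 0.0, "pubs": 0, "phys": False, "cons": 0},
            )
            cur["mi"] = max(cur["mi"], mi or 0.0)
            cur["pubs"] = max(cur["pubs"], int(pubs_f or 0))
            cur["phys"] = cur["phys"] or phys
            cur["cons"] = max(cur["cons"], int(cons_f or 0))

    records = []
    for pair in sorted(rest):
        cur = rest[pair]
        scores = tuple(chans[pair][c] for c in channel_cols if c in chans[pair])
        records.append(
            EvidenceRecord(
                protein_a=pair[0],
                protein_b=pair[1],
                channel_scores=scores,
                mi_score=cur["mi"],
                n_publications=cur["pubs"],
                is_physical=cur["phys"],
                n_conserved_species=cur["cons"],
            )
        )
    return records


def write_evidence(records: Sequence[EvidenceRecord], path: str | Path,
                   n_channels: int | None = None) -> None:
    """Write evidence records to the TSV layout read by :func:`read_evidence`."""
    if n_channels is None:
        n_channels = max((len(r.channel_scores) for r in records), default=0)
    channel_cols = [f"{_CHANNEL_PREFIX}ch{i + 1}" for i in range(n_channels)]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein_a", "protein_b", *channel_cols, *_EVIDENCE_REQUIRED[2:]]
        )
        for r in records:
            cells = [f"{s:.6f}" for s in r.channel_scores]
            cells += [""] * (n_channels - len(cells))
            writer.writerow(
                [
                    r.protein_a,
                    r.protein_b,
                    *cells,
                    f"{r.mi_score:.6f}",
                    r.n_publications,
                    int(r.is_physical),
                    r.n_conserved_species,
                ]
            )


def write_annotations(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write protein annotations to the TSV layout read by :func:`read_annotations`."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.accession,
                    r.gene_symbol,
                    int(r.has_signal_peptide),
                    int(r.has_transmembrane),
                    ";".join(sorted(r.compartments)),
                ]
            )


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

#: Networks are undirected simple graphs of protein identifiers.  Isolated
#: nodes are permitted (degree 0).  networkx.Graph already guarantees
#: undirectedness and edge uniqueness; self-loops are rejected here.
Network = nx.Graph


def new_network(nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()) -> Network:
    """Build a validated network from node and edge iterables."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        if a == b:
            raise ValidationError(f"self-loop on {a!r} is not allowed")
        g.add_edge(a, b)
    return g


def validate_network(net: Network) -> None:
    """Raise :class:`ValidationError` if *net* violates the simple-graph invariants."""
    if net.is_directed():
        raise ValidationError("network must be undirected")
    loops = list(nx.nodes_with_selfloops(net))
    if loops:
        raise ValidationError(f"network contains self-loops on {sorted(loops)}")


def networks_equal(a: Network, b: Network) -> bool:
    """True when two networks have identical node and edge sets."""
    return set(a.nodes) == set(b.nodes) and {
        frozenset(e) for e in a.edges
    } == {frozenset(e) for e in b.edges}


def build_network(records: Sequence[EvidenceRecord]) -> Network:
    """Assemble the network spanned by a list of evidence records.

    Nodes are every accession appearing in any record; edges are the distinct
    canonical pairs.  An empty record list yields an empty network.
    """
    return new_network(
        nodes=(p for r in records for p in r.pair),
        edges=(r.pair for r in records),
    )


_SIF_RELATION = "pp"
_FORMATS = ("sif", "edge-tsv")


def write_network(net: Network, path: str | Path, fmt: str = "sif") -> None:
    """Write a network as SIF or two-column edge TSV.

    The SIF dialect is ``node<TAB>pp<TAB>node``, one line per edge, plus one
    bare line per isolated node.  The edge TSV has a ``protein_a``/
    ``protein_b`` header; an isolated node is written as a row with an empty
    second column so that round-tripping reproduces the network exactly.
    Output is sorted for determinism.
    """
    if fmt not in _FORMATS:
        raise GameteNetError(f"unknown network format {fmt!r}; expected one of {_FORMATS}")
    validate_network(net)
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with Path(path).open("w", newline="") as fh:
        if fmt == "sif":
            for a, b in edges:
                fh.write(f"{a}\t{_SIF_RELATION}\t{b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        else:
            fh.write("protein_a\tprotein_b\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
            for n in isolated:
                fh.write(f"{n}\t\n")


def read_network(path: str | Path, fmt: str = "sif") -> Network:
    """Read a network written by :func:`write_network`."""
    if fmt not in _FORMATS:
        raise GameteNetError(f"unknown network format {fmt!r}; expected one of {_FORMATS}")
    g = nx.Graph()
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if fmt == "edge-tsv":
        if not lines:
            raise FormatError(f"{path}: missing edge-tsv header")
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1 if fmt == "sif" else 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if fmt == "sif":
            if len(parts) == 1:
                g.add_node(parts[0])
                continue
            if len(parts) != 3 or parts[1] != _SIF_RELATION:
                raise FormatError(f"{path}:{lineno}: malformed SIF line {line!r}")
            a, b = parts[0], parts[2]
        else:
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b = parts
            if not b:
                g.add_node(a)
                continue
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
        g.add_edge(a, b)
    return g


def annotation_index(records: Sequence[ProteinRecord]) -> Mapping[str, ProteinRecord]:
    """Index annotations by accession (helper used across the pipeline)."""
    return {r.accession: r for r in records}
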