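"""Domain types shared by every rfamkit module.

Coordinates are 1-based and inclusive throughout, matching how Rfam reports
hit positions; conversion to Python's 0-based half-open slices happens only
at internal slicing boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import (
    EmptySequenceError,
    IllegalResidueError,
    ValidationError,
)

#: Canonical RNA residues plus the IUPAC nucleotide ambiguity codes. Ambiguity
#: codes are accepted and forwarded unchanged; the Rfam service tolerates them.
RNA_ALPHABET = frozenset("ACGU")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
_LEGAL = RNA_ALPHABET | IUPAC_AMBIGUITY

ACCESSION_RE = re.compile(r"^RF\d{5}$")

#: Maximum query length accepted by the Rfam sequence-search endpoint.
SEARCH_WINDOW_LIMIT = 10_000


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence (uppercase, T already converted to U)."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError()
        for i, ch in enumerate(self.residues, start=1):
            if ch not in _LEGAL:
                raise IllegalResidueError(i, ch)

    def __len__(self) -> int:
        return len(self.residues)


def normalize_sequence(raw: str, identifier: str = "query") -> RnaSequence:
    """Normalize a raw nucleotide string into an :class:`RnaSequence`.

    Whitespace is stripped, the string is upper-cased and DNA thymine is
    replaced by uracil. Residues outside {A,C,G,U} plus the IUPAC ambiguity
    codes raise :class:`IllegalResidueError` with the 1-based offending
    position. Idempotent: normalizing an already-normalized sequence is a
    no-op.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise EmptySequenceError()
    return RnaSequence(identifier=identifier, residues=cleaned)


def validate_accession(token: str) -> str:
    """Classify ``token`` as ``"accession"`` (RFxxxxx) or ``"id"``.

    Every retrieval operation accepts either an Rfam family accession or a
    family ID mnemonic; this only classifies, it never rejects — unknown IDs
    fail later at lookup time.
    """
    if not token or not token.strip():
        raise ValidationError("family accession or ID must be non-empty")
    return "accession" if ACCESSION_RE.match(token.strip()) else "id"


@dataclass(frozen=True)
class SequenceFragment:
    """A window of a long query sequence, with its position in the parent."""

    parent_id: str
    parent_start: int  # 1-based inclusive
    parent_end: int  # 1-based inclusive
    residues: str

    def __post_init__(self) -> None:
        if self.parent_start < 1 or self.parent_end < self.parent_start:
            raise ValidationError(
                f"bad fragment coordinates ({self.parent_start}, {self.parent_end})"
            )
        if self.parent_end - self.parent_start + 1 != len(self.residues):
            raise ValidationError(
                "fragment residues length does not match its coordinates"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class RfamHit:
    """One covariance-model homology hit on a query sequence.

    ``query_start``/``query_end`` are 1-based inclusive positions on the
    original (parent) query, normalized so start <= end; a hit the server
    reported with start > end is stored with ``strand == Strand.MINUS``.
    The e-value is the quantity clan competition ranks on (lower is better);
    ``bit_score`` breaks e-value ties.
    """

    rfam_accession: str
    rfam_id: str
    query_start: int
    query_end: int
    strand: Strand = Strand.PLUS
    bit_score: float = 0.0
    e_value: float = 1.0
    alignment_block: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not ACCESSION_RE.match(self.rfam_accession):
            raise ValidationError(
                f"bad Rfam accession {self.rfam_accession!r} (expected RF + 5 digits)"
            )
        if self.query_start < 1 or self.query_end < self.query_start:
            raise ValidationError(
                f"hit coordinates must satisfy 1 <= start <= end, got "
                f"({self.query_start}, {self.query_end})"
            )
        if self.e_value <= 0:
            raise ValidationError(f"e-value must be positive, got {self.e_value}")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


def make_hit(
    accession: str,
    family_id: str,
    start: int,
    end: int,
    *,
    bit_score: float = 0.0,
    e_value: float = 1.0,
    strand: Optional[Strand] = None,
    alignment_block: Optional[str] = None,
) -> RfamHit:
    """Build a hit, normalizing a server-reported minus-strand hit.

    The Rfam service reports reverse-strand hits with start > end; those are
    normalized here to start <= end with ``strand == MINUS`` so that all
    downstream overlap arithmetic is uniform.
    """
    if strand is None:
        strand = Strand.PLUS if start <= end else Strand.MINUS
    if start > end:
        start, end = end, start
    return RfamHit(
        rfam_accession=accession,
        rfam_id=family_id,
        query_start=start,
        query_end=end,
        strand=strand,
        bit_score=bit_score,
        e_value=e_value,
        alignment_block=alignment_block,
    )


class ClanAssignment:
    """Family accession -> clan identifier map used by clan competition.

    Families absent from the map belong to no clan and never compete.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._mapping: dict[str, str] = dict(mapping or {})

    def clan_of(self, accession: str) -> Optional[str]:
        return self._mapping.get(accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ClanAssignment) and self._mapping == other._mapping

    def __repr__(self) -> str:
        return f"ClanAssignment({len(self._mapping)} families)"


@dataclass(frozen=True)
class SearchOptions:
    """Options of the long-sequence search pipeline.

    ``window`` is the per-fragment length limit imposed by the service
    (10,000 nt); ``fragments_overlap`` is the number of positions shared by
    consecutive fragments so that hits near a boundary are seen whole by at
    least one fragment. ``clan_overlap_threshold`` is the minimum overlap,
    as a fraction of the shorter hit, for two same-clan hits to compete
    (default 0.5, i.e. 50% of the length of the shortest hit).
    """

    fragments_overlap: int = 3000
    clan_competition_filter: bool = False
    clan_overlap_threshold: float = 0.5
    window: int = SEARCH_WINDOW_LIMIT

    def __post_init__(self) -> None:
        if self.fragments_overlap < 0:
            raise ValidationError("fragments_overlap must be non-negative")
        if self.fragments_overlap >= self.window:
            raise ValidationError("fragments_overlap must be smaller than the window")
        if not (0 < self.clan_overlap_threshold <= 1):
            raise ValidationError("clan_overlap_threshold must be in (0, 1]")
        if self.window < 1:
            raise ValidationError("window must be positive")


@dataclass(frozen=True)
class FamilySummary:
    """Brief description of one Rfam family."""

    accession: str
    id: str
    description: str = ""
    number_of_sequences: int = 0
    metadata: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.accession or not self.id:
            raise ValidationError("family summary requires accession and id")


@dataclass(frozen=True)
class ConsensusStructure:
    """Paired (consensus sequence, structure string) record.

    ``notation`` is ``"DB"`` (extended dot-bracket) or ``"WUSS"``. The
    sequence may carry Rfam's case/ambiguity markup; the only structural
    requirements are equal lengths and balanced bracket families.
    """

    sequence: str
    structure: str
    notation: str = "DB"

    def __post_init__(self) -> None:
        if self.notation not in ("DB", "WUSS"):
            raise ValidationError(f"unknown structure notation {self.notation!r}")
        if len(self.sequence) != len(self.structure):
            raise ValidationError(
                "consensus sequence and structure must have equal lengths "
                f"({len(self.sequence)} vs {len(self.structure)})"
            )
        # Balance is enforced via the pairing map; import here to avoid a cycle.
        from .formats import pairing_map

        pairing_map(self.structure)


@dataclass
class SeedAlignment:
    """A gapped multiple alignment with Stockholm-style annotations.

    ``rows`` is an ordered list of (name, gapped sequence); ``column_annotations``
    holds per-column lines such as the consensus structure (GC lines);
    ``row_annotations`` holds per-row per-column lines (GR lines);
    ``file_annotations`` holds file-level key -> list-of-values (GF lines).
    """

    rows: list[tuple[str, str]] = field(default_factory=list)
    column_annotations: dict[str, str] = field(default_factory=dict)
    row_annotations: dict[str, dict[str, str]] = field(default_factory=dict)
    file_annotations: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        names = [n for n, _ in self.rows]
        if len(set(names)) != len(names):
            raise ValidationError("alignment row names must be unique")
        lengths = {len(s) for _, s in self.rows}
        lengths |= {len(v) for v in self.column_annotations.values()}
        for per_row in self.row_annotations.values():
            lengths |= {len(v) for v in per_row.values()}
        if len(lengths) > 1:
            raise ValidationError(f"ragged alignment: column counts {sorted(lengths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeedAlignment):
            return NotImplemented
        return (
            self.rows == other.rows
            and self.column_annotations == other.column_annotations
            and self.row_annotations == other.row_annotations
            and self.file_annotations == other.file_annotations
        )


@dataclass(frozen=True)
class SequenceRegion:
    """One genomic region annotated as a member of a family."""

    genbank_accession: str
    region_start: int
    region_end: int
    description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.region_start < 1 or self.region_end < 1:
            raise ValidationError("region coordinates must be positive")


@dataclass(frozen=True)
class PdbCorrespondence:
    """Mapping between PDB structure residues and covariance-model positions."""

    pdb_id: str
    chain: str
    pdb_residue_start: int
    pdb_residue_end: int
    cm_position_start: int
    cm_position_end: int

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise ValidationError(f"PDB id must be 4 characters, got {self.pdb_id!r}")


def hits_sorted(hits: Sequence[RfamHit]) -> list[RfamHit]:
    """Hits in canonical query-coordinate order."""
    return sorted(hits, key=lambda h: (h.query_start, h.query_end, h.rfam_accession))
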