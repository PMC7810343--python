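"""Long-sequence search orchestration.

The Rfam sequence-search endpoint accepts queries of at most 10,000 nt. To
search a sequence of any length, the query is split into overlapping
fragments, each fragment is searched independently, fragment-local hit
coordinates are mapped back onto the parent sequence, and hits found twice
inside an overlap region are collapsed. Clan competition is then applied
optionally. The overlap (3,000 nt by default here, matching typical use on
a viral genome) should exceed the longest expected hit so that any motif
straddling a fragment boundary is seen whole by at least one fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .clanfilter import clan_competition
from .errors import (
    BadOverlapError,
    CoordinateOutOfRangeError,
    FamilyNotFoundError,
    FragmentSearchFailedError,
    NotFoundError,
    ReplayMissError,
    ServiceError,
)
from .model import (
    ClanAssignment,
    RfamHit,
    RnaSequence,
    SearchOptions,
    SequenceFragment,
    Strand,
    hits_sorted,
    make_hit,
    normalize_sequence,
)
from .transport import Transport


@dataclass(frozen=True)
class FragmentPlan:
    """Fragmentation of a parent sequence of length L into search windows.

    Fragments are 1-based inclusive (start, end) intervals that cover
    [1, L] with no gaps; consecutive fragments share exactly ``overlap``
    positions; starts increase by ``window - overlap``; the final fragment
    ends exactly at L.
    """

    window: int
    overlap: int
    fragments: tuple[tuple[int, int], ...]


def plan_fragments(sequence_length: int, window: int = 10_000, overlap: int = 3000) -> FragmentPlan:
    """Plan overlapping fragments for a sequence of ``sequence_length`` nt.

    A sequence no longer than the window yields the single fragment
    (1, L). Otherwise fragment starts form the arithmetic progression 1,
    1 + (window - overlap), 1 + 2(window - overlap), ... and each fragment
    spans ``window`` positions except the last, which ends at L.
    """
    if sequence_length < 1:
        raise CoordinateOutOfRangeError("sequence length must be >= 1")
    if overlap < 0 or overlap >= window:
        raise BadOverlapError(overlap, window)
    if sequence_length <= window:
        return FragmentPlan(window=window, overlap=overlap, fragments=((1, sequence_length),))
    step = window - overlap
    fragments: list[tuple[int, int]] = []
    start = 1
    while True:
        end = start + window - 1
        if end >= sequence_length:
            fragments.append((start, sequence_length))
            break
        fragments.append((start, end))
        start += step
    return FragmentPlan(window=window, overlap=overlap, fragments=tuple(fragments))


def cut_fragments(seq: RnaSequence, plan: FragmentPlan) -> list[SequenceFragment]:
    """Materialize a plan into residue-carrying fragments of ``seq``."""
    return [
        SequenceFragment(
            parent_id=seq.identifier,
            parent_start=start,
            parent_end=end,
            residues=seq.residues[start - 1 : end],
        )
        for start, end in plan.fragments
    ]


def map_hit_to_parent(local_hit: RfamHit, fragment: SequenceFragment) -> RfamHit:
    """Translate fragment-local hit coordinates onto the parent sequence.

    parent position = fragment.parent_start + local position - 1; strand,
    scores and the alignment block are unchanged.
    """
    if local_hit.query_start < 1 or local_hit.query_end > len(fragment):
        raise CoordinateOutOfRangeError(
            f"local hit ({local_hit.query_start}, {local_hit.query_end}) outside "
            f"fragment of length {len(fragment)}"
        )
    offset = fragment.parent_start - 1
    return RfamHit(
        rfam_accession=local_hit.rfam_accession,
        rfam_id=local_hit.rfam_id,
        query_start=local_hit.query_start + offset,
        query_end=local_hit.query_end + offset,
        strand=local_hit.strand,
        bit_score=local_hit.bit_score,
        e_value=local_hit.e_value,
        alignment_block=local_hit.alignment_block,
    )


def deduplicate_hits(hits: Sequence[RfamHit]) -> list[RfamHit]:
    """Collapse hits reported identically by two overlapping fragments.

    At most one hit survives per (accession, start, end, strand) key — the
    one with the lowest e-value. Output is sorted by query coordinates;
    the operation is idempotent and insensitive to input order. Hits with
    shifted boundaries are deliberately NOT merged here: boundary-truncated
    near-duplicates are a clan-competition concern, not a dedup one.
    """
    best: dict[tuple, RfamHit] = {}
    for hit in hits:
        key = (hit.rfam_accession, hit.query_start, hit.query_end, hit.strand)
        prev = best.get(key)
        if prev is None or (hit.e_value, -hit.bit_score) < (prev.e_value, -prev.bit_score):
            best[key] = hit
    return hits_sorted(best.values())


def parse_hit_payload(payload: dict) -> list[RfamHit]:
    """Parse a completed search-job payload into fragment-local hits.

    Accepts both the flat shape used by the replay fixtures
    (``{"hits": [{accession, id, start, end, ...}]}``) and the Rfam web
    service's nested shape (``{"hits": {family_id: [{...}]}}``). Hits the
    server reports with start > end come out normalized with strand = minus.
    """
    raw = payload.get("hits", [])
    records: list[dict] = []
    if isinstance(raw, dict):
        for family_id, rows in raw.items():
            for row in rows:
                row = dict(row)
                row.setdefault("id", family_id)
                records.append(row)
    else:
        records = [dict(r) for r in raw]
    hits = []
    for row in records:
        strand = row.get("strand")
        hits.append(
            make_hit(
                accession=row.get("accession") or row.get("acc"),
                family_id=row.get("id", ""),
                start=int(row.get("start")),
                end=int(row.get("end")),
                bit_score=float(row.get("bit_score", row.get("score", 0.0))),
                e_value=float(row.get("e_value", row.get("E", 1.0))),
                strand=Strand(strand) if strand else None,
                alignment_block=row.get("alignment"),
            )
        )
    return hits


def sequence_search(
    seq: RnaSequence,
    options: Optional[SearchOptions] = None,
    clans: Optional[ClanAssignment] = None,
    *,
    transport: Transport,
) -> list[RfamHit]:
    """Identify non-coding RNA families in a sequence of unlimited length.

    Splits the query per :func:`plan_fragments`, runs one search job per
    fragment, maps hits back to parent coordinates, deduplicates, and — when
    ``options.clan_competition_filter`` is set — applies clan competition.
    Any fragment failure aborts the whole search with
    :class:`FragmentSearchFailedError`: a partial hit list would be a silent
    false negative.
    """
    options = options or SearchOptions()
    plan = plan_fragments(len(seq), window=options.window, overlap=options.fragments_overlap)
    all_hits: list[RfamHit] = []
    for fragment in cut_fragments(seq, plan):
        try:
            payload = transport.run_search(fragment)
        except (ServiceError, NotFoundError) as exc:
            raise FragmentSearchFailedError(
                (fragment.parent_start, fragment.parent_end), exc
            ) from exc
        for local in parse_hit_payload(payload):
            all_hits.append(map_hit_to_parent(local, fragment))
    hits = deduplicate_hits(all_hits)
    if options.clan_competition_filter:
        hits = clan_competition(
            hits, clans or ClanAssignment(), threshold=options.clan_overlap_threshold
        )
    return hits


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

HITS_TSV_COLUMNS = (
    "rfam_accession",
    "rfam_id",
    "query_start",
    "query_end",
    "strand",
    "bit_score",
    "e_value",
)


def write_hits_tsv(hits: Sequence[RfamHit]) -> str:
    """Tab-delimited hit table with a header row."""
    lines = ["\t".join(HITS_TSV_COLUMNS)]
    for h in hits:
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    h.rfam_accession,
                    h.rfam_id,
                    h.query_start,
                    h.query_end,
                    h.strand.value,
                    f"{h.bit_score:g}",
                    f"{h.e_value:g}",
                )
            )
        )
    return "\n".join(lines) + "\n"


def read_fasta_sequence(path: str | Path) -> RnaSequence:
    """Read the first record of a FASTA file as a normalized RNA sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return normalize_sequence(str(record.seq), identifier=record.id)
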