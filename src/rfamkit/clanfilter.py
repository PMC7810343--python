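"""Clan-competition filtering of overlapping homology hits.

Rfam groups evolutionarily related or structurally similar families into
clans; hits from same-clan families on (nearly) the same region of a query
are redundant annotations. Clan competition keeps, within each group of
overlapping same-clan hits, only the best hit and discards the rest.

Two hits compete when (i) their families map to the same clan, (ii) they lie
on the same strand, and (iii) they overlap by at least a threshold fraction
of the length of the *shorter* hit (default 0.5). Ranking is by ascending
e-value, with descending bit score breaking e-value ties and the family
accession as the final lexicographic tie-break, making the order total and
the result independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import ClanAssignment, RfamHit, hits_sorted


@dataclass(frozen=True)
class OverlapReport:
    """Overlap between two coordinate-normalized hits."""

    hit_a: RfamHit
    hit_b: RfamHit
    overlap_nt: int
    fraction_of_shortest: float


def overlap_fraction(a: RfamHit, b: RfamHit) -> OverlapReport:
    """Overlap length and its fraction of the shorter hit.

    Symmetric in its arguments; a hit contained in (or identical to) the
    other yields fraction 1.0; disjoint hits yield 0.0.
    """
    overlap = max(0, min(a.query_end, b.query_end) - max(a.query_start, b.query_start) + 1)
    fraction = overlap / min(a.length, b.length)
    return OverlapReport(hit_a=a, hit_b=b, overlap_nt=overlap, fraction_of_shortest=fraction)


def rank_key(hit: RfamHit) -> tuple:
    """Total competition order: best hit first.

    E-value primary, bit score secondary (covers e-value ties), then the
    family accession and coordinates so the order — and therefore the
    filter's result — never depends on input order.
    """
    return (
        hit.e_value,
        -hit.bit_score,
        hit.rfam_accession,
        hit.query_start,
        hit.query_end,
        hit.strand.value,
    )


def clan_competition(
    hits: Sequence[RfamHit],
    clans: ClanAssignment,
    threshold: float = 0.5,
) -> list[RfamHit]:
    """Pairwise clan competition: of two competing hits, only the better is kept.

    A hit is discarded exactly when some strictly better-ranked hit of the
    same clan and strand overlaps it by at least ``threshold`` of the
    shorter of the two. The comparison runs over every such pair in the
    input, so whether a hit survives depends only on the hits that outrank
    it, never on removal order — which makes the filter idempotent,
    insensitive to input permutation, and monotone in the threshold
    (raising it never discards more). Hits whose family belongs to no clan
    are always kept. Output preserves query-coordinate sort order.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("clan overlap threshold must be in (0, 1]")
    ranked = sorted(hits, key=rank_key)
    kept: list[RfamHit] = []
    for i, hit in enumerate(ranked):
        clan = clans.clan_of(hit.rfam_accession)
        if clan is None:
            kept.append(hit)
            continue
        beaten = any(
            clans.clan_of(better.rfam_accession) == clan
            and better.strand == hit.strand
            and rank_key(better) < rank_key(hit)
            and overlap_fraction(hit, better).fraction_of_shortest >= threshold
            for better in ranked[:i]
        )
        if not beaten:
            kept.append(hit)
    return hits_sorted(kept)


# ---------------------------------------------------------------------------
# Clan snapshot table
# ---------------------------------------------------------------------------


def parse_clan_table(text: str) -> ClanAssignment:
    """Parse a two-column TSV (family_accession, clan_accession).

    Lines starting with ``#`` are comments. A family listed twice with
    different clans is an error (each family belongs to at most one clan).
    """
    mapping: dict[str, str] = {}
    for no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"clan table line {no}: expected 2 tab-separated columns")
        family, clan = parts[0].strip(), parts[1].strip()
        if family in mapping and mapping[family] != clan:
            raise ValidationError(
                f"clan table line {no}: family {family} assigned to two clans"
            )
        mapping[family] = clan
    return ClanAssignment(mapping)


def write_clan_table(clans: ClanAssignment) -> str:
    lines = ["# family_accession\tclan_accession"]
    for family, clan in sorted(clans.items()):
        lines.append(f"{family}\t{clan}")
    return "\n".join(lines) + "\n"


def load_clan_snapshot(path: str | Path | None = None) -> ClanAssignment:
    """Load the bundled clan snapshot, or a user-provided table."""
    if path is not None:
        return parse_clan_table(Path(path).read_text())
    from importlib.resources import files

    return parse_clan_table(
        files("rfamkit.data").joinpath("clan_snapshot.tsv").read_text()
    )
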