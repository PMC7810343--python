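"""Clan-competition filtering: overlap arithmetic, greedy semantics, oracle."""

import itertools
import random

import pytest

from conftest import random_clans, random_hits
from rfamkit.clanfilter import (
    clan_competition,
    overlap_fraction,
    parse_clan_table,
    rank_key,
    write_clan_table,
)
from rfamkit.errors import ValidationError
from rfamkit.model import ClanAssignment, Strand, make_hit


def hit(acc, fam, start, end, e=1e-10, score=50.0, strand=None):
    return make_hit(acc, fam, start, end, e_value=e, bit_score=score, strand=strand)


# ---------------------------------------------------------------------------
# overlap_fraction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, overlap_nt, fraction",
    [
        ((2, 300), (2, 300), 299, 1.0),  # identical intervals
        ((29_537, 29_871), (29_604, 29_663), 60, 1.0),  # containment: 3'-UTR vs pseudoknot
        ((1, 100), (200, 300), 0, 0.0),  # disjoint
        ((1, 100), (51, 250), 50, 0.5),  # half the shorter hit
    ],
)
def test_overlap_fraction_cases(a, b, overlap_nt, fraction):
    ha, hb = hit("RF00001", "a", *a), hit("RF00002", "b", *b)
    report = overlap_fraction(ha, hb)
    assert report.overlap_nt == overlap_nt
    assert report.fraction_of_shortest == pytest.approx(fraction)
    # symmetry
    swapped = overlap_fraction(hb, ha)
    assert swapped.overlap_nt == report.overlap_nt
    assert swapped.fraction_of_shortest == report.fraction_of_shortest


# ---------------------------------------------------------------------------
# clan_competition semantics
# ---------------------------------------------------------------------------


def test_disjoint_same_clan_hits_both_kept():
    clans = ClanAssignment({"RF00001": "CL1", "RF00002": "CL1"})
    hits = [hit("RF00001", "a", 1, 100), hit("RF00002", "b", 200, 300)]
    assert clan_competition(hits, clans) == sorted(hits, key=lambda h: h.query_start)


def test_full_overlap_different_clans_both_kept():
    clans = ClanAssignment({"RF00001": "CL1", "RF00002": "CL2"})
    hits = [hit("RF00001", "a", 1, 100), hit("RF00002", "b", 1, 100)]
    assert len(clan_competition(hits, clans)) == 2


def test_unclanned_hits_never_compete():
    clans = ClanAssignment({"RF00001": "CL1"})
    hits = [hit("RF00001", "a", 1, 100, e=1e-20), hit("RF00002", "b", 1, 100, e=1e-3)]
    assert len(clan_competition(hits, clans)) == 2


def test_worst_evalue_hit_is_removed():
    clans = ClanAssignment({"RF00001": "CL1", "RF00002": "CL1"})
    best = hit("RF00001", "a", 1, 100, e=1e-20)
    worst = hit("RF00002", "b", 10, 110, e=1e-5)
    assert clan_competition([worst, best], clans) == [best]


def test_bit_score_breaks_evalue_ties():
    clans = ClanAssignment({"RF00001": "CL1", "RF00002": "CL1"})
    lo = hit("RF00002", "b", 1, 100, e=1e-10, score=40.0)
    hi = hit("RF00001", "a", 1, 100, e=1e-10, score=90.0)
    assert clan_competition([lo, hi], clans) == [hi]


def test_opposite_strand_hits_never_compete():
    clans = ClanAssignment({"RF00001": "CL1", "RF00002": "CL1"})
    plus = hit("RF00001", "a", 1, 100, strand=Strand.PLUS)
    minus = hit("RF00002", "b", 1, 100, strand=Strand.MINUS)
    assert len(clan_competition([plus, minus], clans)) == 2


def test_threshold_bounds_validated():
    with pytest.raises(ValidationError):
        clan_competition([], ClanAssignment(), threshold=0.0)
    with pytest.raises(ValidationError):
        clan_competition([], ClanAssignment(), threshold=1.1)


def test_case_study_groupings_reduce_seven_hits_to_three(case_study):
    kept = clan_competition(case_study.hits, case_study.clans, threshold=0.5)
    assert [h.rfam_id for h in kept] == ["Sarbecovirus-5UTR", "Corona_FSE", "Sarbecovirus-3UTR"]
    # all competing overlaps are containments/identities, so even the most
    # permissive threshold removes the same hits
    assert clan_competition(case_study.hits, case_study.clans, threshold=1.0) == kept


# ---------------------------------------------------------------------------
# Properties against an independent subset-enumeration oracle
# ---------------------------------------------------------------------------


def oracle_clan_competition(hits, clans, threshold):
    """Subset-enumeration oracle for pairwise clan competition.

    The result is the unique subset S such that (i) every member of S has no
    strictly better-ranked conflicting hit anywhere in the input, and (ii)
    every non-member has at least one — where 'conflict' means same clan,
    same strand, and overlap >= threshold of the shorter hit. Found here by
    brute force over all subsets, independently of the implementation's
    rank-ordered sweep.
    """

    def conflict(a, b):
        return (
            clans.clan_of(a.rfam_accession) is not None
            and clans.clan_of(a.rfam_accession) == clans.clan_of(b.rfam_accession)
            and a.strand == b.strand
            and overlap_fraction(a, b).fraction_of_shortest >= threshold
        )

    for r in range(len(hits), -1, -1):
        for subset in itertools.combinations(hits, r):
            kept = set(subset)
            valid = all(
                (
                    not any(rank_key(g) < rank_key(h) and conflict(h, g) for g in hits)
                )
                == (h in kept)
                for h in hits
            )
            if valid:
                return sorted(kept, key=lambda h: (h.query_start, h.query_end, h.rfam_accession))
    raise AssertionError("oracle found no valid subset")  # pragma: no cover


def random_instance(rng):
    hits = random_hits(rng, rng.randint(0, 8), span=200)
    # distinct accessions so the rank order is total
    hits = [
        make_hit(
            f"RF{i:05d}",
            h.rfam_id,
            h.query_start,
            h.query_end,
            bit_score=h.bit_score,
            e_value=h.e_value,
            strand=h.strand,
        )
        for i, h in enumerate(hits)
    ]
    clans = ClanAssignment(random_clans(rng, hits))
    threshold = rng.choice([0.25, 0.5, 0.75, 1.0])
    return hits, clans, threshold


def test_matches_bruteforce_oracle_on_random_instances():
    rng = random.Random(20_260_928)
    for _ in range(1000):
        hits, clans, threshold = random_instance(rng)
        assert clan_competition(hits, clans, threshold) == oracle_clan_competition(
            hits, clans, threshold
        )


def test_idempotence_permutation_invariance_and_retained_set_properties():
    rng = random.Random(424_242)
    for _ in range(300):
        hits, clans, threshold = random_instance(rng)
        kept = clan_competition(hits, clans, threshold)
        assert set(kept) <= set(hits)
        assert clan_competition(kept, clans, threshold) == kept  # idempotent
        shuffled = hits[:]
        rng.shuffle(shuffled)
        assert clan_competition(shuffled, clans, threshold) == kept
        # no two retained same-clan same-strand hits overlap >= threshold
        for a, b in itertools.combinations(kept, 2):
            same_clan = (
                clans.clan_of(a.rfam_accession) is not None
                and clans.clan_of(a.rfam_accession) == clans.clan_of(b.rfam_accession)
            )
            if same_clan and a.strand == b.strand:
                assert overlap_fraction(a, b).fraction_of_shortest < threshold


def test_threshold_monotonicity():
    """Raising the threshold only makes the filter more permissive."""
    rng = random.Random(77)
    for _ in range(200):
        hits, clans, _ = random_instance(rng)
        kept_low = clan_competition(hits, clans, threshold=0.3)
        kept_high = clan_competition(hits, clans, threshold=0.8)
        assert set(kept_low) <= set(kept_high)


# ---------------------------------------------------------------------------
# Clan table I/O
# ---------------------------------------------------------------------------


def test_clan_table_round_trip_and_comments():
    text = "# comment\nRF00001\tCL00001\nRF00002\tCL00001\n"
    clans = parse_clan_table(text)
    assert clans.clan_of("RF00001") == "CL00001"
    assert clans.clan_of("RF09999") is None
    assert parse_clan_table(write_clan_table(clans)) == clans


def test_clan_table_rejects_conflicting_assignment():
    with pytest.raises(ValidationError):
        parse_clan_table("RF00001\tCL00001\nRF00001\tCL00002\n")


def test_bundled_snapshot_covers_fixture_families():
    from rfamkit.clanfilter import load_clan_snapshot
    from rfamkit.fixtures import CASE_STUDY_HITS

    clans = load_clan_snapshot()
    for acc, _, _, _, clan in CASE_STUDY_HITS:
        assert clans.clan_of(acc) == clan
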