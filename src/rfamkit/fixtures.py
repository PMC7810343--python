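"""Deterministic synthetic data and replay-store generation.

Everything needed to exercise the full toolkit offline is generated here:

* :func:`generate_world` — a synthetic genome with literal family motifs
  planted at known positions, plus a replay store whose per-fragment search
  responses report exactly the motif occurrences each fragment contains
  (an exact-match stand-in for the server-side covariance-model scan).
  Ground truth is recorded, so precision/recall of the search pipeline can
  be measured exactly.
* :func:`build_case_study` — a replayable reconstruction of a whole-genome
  annotation run on a 29,903-nt betacoronavirus genome: seven non-coding
  RNA hits (paired 5'-UTR families, the frameshifting element, paired
  3'-UTR families with their nested pseudoknot and s2m motifs), the clan
  groupings that make clan competition collapse them to three, and family
  data (summary, consensus structure, seed alignment, tree, covariance
  model, SVG, regions, PDB mapping) for the families involved. The genome
  and all family payloads are synthetic; the hit coordinates, family IDs
  and clan structure are the real annotation layout of such a genome.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .model import ClanAssignment, RfamHit, RnaSequence, make_hit
from .search import cut_fragments, plan_fragments
from .transport import EndpointRequest, ReplayStore, TransportResponse

_RNA = "ACGU"


# ---------------------------------------------------------------------------
# Replay-store recording helpers
# ---------------------------------------------------------------------------


def _record_json(store: ReplayStore, request: EndpointRequest, payload, status: int = 200) -> None:
    store.record(
        request,
        TransportResponse(
            status=status,
            content_kind="json",
            body=json.dumps(payload).encode(),
        ),
    )


def record_fragment_search(
    store: ReplayStore,
    fragment,
    hits: Sequence[dict],
    *,
    pending_polls: int = 0,
) -> str:
    """Record a submit + poll pair for one fragment's search job.

    ``hits`` are fragment-local hit dicts (accession, id, start, end,
    bit_score, e_value). ``pending_polls`` prepends that many recorded
    pending responses before the completed one, emulating the asynchronous
    pending -> done transition of the live service.
    """
    submit = EndpointRequest(kind="search_submit", params={"sequence": fragment.residues})
    job_id = "job-" + submit.canonical_key()
    _record_json(store, submit, {"job_id": job_id})
    done = {"status": "done", "hits": list(hits)}
    poll = EndpointRequest(kind="search_poll", params={"job_id": job_id})
    if pending_polls > 0:
        body = {"responses": [{"status": "pending"}] * pending_polls + [done]}
    else:
        body = done
    _record_json(store, poll, body)
    return job_id


def record_family_lookup(store: ReplayStore, accession: str, family_id: str) -> None:
    payload = {"accession": accession, "id": family_id}
    _record_json(store, EndpointRequest(kind="id_lookup", accession_or_id=accession), payload)
    _record_json(store, EndpointRequest(kind="id_lookup", accession_or_id=family_id), payload)


# ---------------------------------------------------------------------------
# Synthetic worlds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticFamily:
    """A made-up RNA family recognized by literal motif matching."""

    accession: str
    id: str
    motif: str
    clan: Optional[str] = None
    summary: str = ""
    e_value: float = 1e-10
    bit_score: float = 50.0

    def __post_init__(self) -> None:
        assert len(self.motif) >= 20, "family motifs must be >= 20 nt"


@dataclass
class World:
    """A synthetic genome with planted motifs and exact ground truth."""

    seed: int
    families: list[SyntheticFamily]
    genome: RnaSequence
    truth: list[RfamHit] = field(default_factory=list)


def _random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_RNA) for _ in range(length))


def _scan_occurrences(genome: str, motif: str) -> list[tuple[int, int]]:
    """All 1-based inclusive occurrences of ``motif`` in ``genome``."""
    out = []
    start = genome.find(motif)
    while start != -1:
        out.append((start + 1, start + len(motif)))
        start = genome.find(motif, start + 1)
    return out


def generate_world(
    seed: int,
    n_families: int = 3,
    genome_length: int = 25_000,
    motif_length: tuple[int, int] = (24, 40),
    window: int = 10_000,
    overlap: int = 3000,
    span_boundary: bool = False,
    duplicate_family: bool = False,
) -> World:
    """Generate a reproducible synthetic world.

    Each family gets a random motif (24-40 nt by default, comfortably above
    the 20-nt floor) planted at a random non-overlapping genome position.
    With ``span_boundary`` the first motif is planted across the first
    fragment boundary, inside the overlap zone, so only the second fragment
    sees it whole. With ``duplicate_family`` the first family is planted a
    second time. Ground truth is re-derived by scanning the final genome, so
    it is exact even in the (vanishingly unlikely) event of an accidental
    motif occurrence in the random background.
    """
    assert n_families >= 1
    rng = random.Random(seed)
    families = [
        SyntheticFamily(
            accession=f"RF9{i:04d}",
            id=f"synfam-{seed}-{i}",
            motif=_random_rna(rng, rng.randint(*motif_length)),
            clan=f"CL9{i % 2:04d}" if rng.random() < 0.5 else None,
            summary=f"Synthetic RNA family {i} of world {seed}.",
            e_value=10 ** rng.uniform(-40, -6),
            bit_score=round(rng.uniform(30, 200), 1),
        )
        for i in range(n_families)
    ]

    genome = list(_random_rna(rng, genome_length))
    occupied: list[tuple[int, int]] = []

    def plant(motif: str, pos0: int) -> None:
        genome[pos0 : pos0 + len(motif)] = motif
        occupied.append((pos0, pos0 + len(motif) - 1))

    def free_position(length: int, lo: int = 0, hi: Optional[int] = None) -> int:
        hi = genome_length - length if hi is None else min(hi, genome_length - length)
        for _ in range(1000):
            pos0 = rng.randint(lo, hi)
            if all(pos0 + length - 1 < s or pos0 > e for s, e in occupied):
                return pos0
        raise RuntimeError("could not place motif")  # pragma: no cover

    for i, fam in enumerate(families):
        if span_boundary and i == 0 and genome_length > window:
            # straddle the first boundary: start before position `window`,
            # end after it, inside the overlap so fragment 2 contains it whole
            pos0 = window - rng.randint(1, min(len(fam.motif) - 1, overlap - 1))
            plant(fam.motif, pos0)
        else:
            plant(fam.motif, free_position(len(fam.motif)))
    if duplicate_family:
        plant(families[0].motif, free_position(len(families[0].motif)))

    genome_str = "".join(genome)
    truth = []
    for fam in families:
        for start, end in _scan_occurrences(genome_str, fam.motif):
            truth.append(
                make_hit(
                    fam.accession,
                    fam.id,
                    start,
                    end,
                    bit_score=fam.bit_score,
                    e_value=fam.e_value,
                )
            )
    truth.sort(key=lambda h: (h.query_start, h.query_end, h.rfam_accession))
    return World(
        seed=seed,
        families=families,
        genome=RnaSequence(identifier=f"synthetic-world-{seed}", residues=genome_str),
        truth=truth,
    )


def write_world_store(
    world: World,
    directory: str | Path,
    window: int = 10_000,
    overlap: int = 3000,
) -> ReplayStore:
    """Record per-fragment search responses consistent with exact motif matching.

    For every fragment of the standard plan, the recorded response lists the
    motif occurrences *fully contained* in that fragment, in fragment-local
    coordinates — the offline stand-in for the server-side scan.
    """
    store = ReplayStore(directory)
    plan = plan_fragments(len(world.genome), window=window, overlap=overlap)
    by_acc = {f.accession: f for f in world.families}
    for fragment in cut_fragments(world.genome, plan):
        local_hits = []
        for hit in world.truth:
            if hit.query_start >= fragment.parent_start and hit.query_end <= fragment.parent_end:
                fam = by_acc[hit.rfam_accession]
                local_hits.append(
                    {
                        "accession": hit.rfam_accession,
                        "id": hit.rfam_id,
                        "start": hit.query_start - fragment.parent_start + 1,
                        "end": hit.query_end - fragment.parent_start + 1,
                        "bit_score": fam.bit_score,
                        "e_value": fam.e_value,
                    }
                )
        record_fragment_search(store, fragment, local_hits)
    return store


def world_clans(world: World) -> ClanAssignment:
    return ClanAssignment({f.accession: f.clan for f in world.families if f.clan})


# ---------------------------------------------------------------------------
# Case study: whole-genome annotation of a 29,903-nt betacoronavirus genome
# ---------------------------------------------------------------------------

#: (accession, family id, start, end, clan) for the seven non-coding RNA
#: elements of the case-study genome. Coordinates are 1-based inclusive on
#: the 29,903-nt genome. The two 5'-UTR families share one clan, the two
#: 3'-UTR families plus the nested pseudoknot (Corona_pk3) and s2m motifs
#: share another, and the frameshifting element belongs to no clan.
CASE_STUDY_HITS: tuple[tuple[str, str, int, int, Optional[str]], ...] = (
    ("RF03117", "bCoV-5UTR", 2, 300, "CL00116"),
    ("RF03120", "Sarbecovirus-5UTR", 2, 300, "CL00116"),
    ("RF00507", "Corona_FSE", 13470, 13551, None),
    ("RF03121", "bCoV-3UTR", 29519, 29871, "CL00117"),
    ("RF03125", "Sarbecovirus-3UTR", 29537, 29871, "CL00117"),
    ("RF00165", "Corona_pk3", 29604, 29663, "CL00117"),
    ("RF00164", "s2m", 29728, 29770, "CL00117"),
)

#: Family IDs of the hits that survive clan competition at threshold 0.5:
#: the Sarbecovirus-specific UTR variants outrank their generic counterparts,
#: and the pseudoknot/s2m motifs are nested inside the 3'-UTR hit.
CASE_STUDY_SURVIVORS = ("Sarbecovirus-5UTR", "Corona_FSE", "Sarbecovirus-3UTR")

CASE_STUDY_GENOME_LENGTH = 29_903
CASE_STUDY_WINDOW = 10_000
CASE_STUDY_OVERLAP = 3000

_CASE_STUDY_SEED = 20_903

_FAMILY_DESCRIPTIONS = {
    "RF03117": "Betacoronavirus 5' untranslated region (150-200 nt).",
    "RF03120": "Sarbecovirus 5' untranslated region, specific of SARS betacoronaviruses.",
    "RF00507": "Coronavirus frameshifting stimulation element stem loop.",
    "RF03121": "Betacoronavirus 3' untranslated region (300-500 nt).",
    "RF03125": "Sarbecovirus 3' untranslated region, specific of SARS betacoronaviruses.",
    "RF00165": "Coronavirus 3' UTR pseudoknot of approximately 55 nt.",
    "RF00164": "Coronavirus stem-loop II-like motif (s2m).",
    "RF00005": "Transfer RNA (tRNA).",
}


def _case_study_evalues(rng: random.Random) -> dict[str, tuple[float, float]]:
    """Draw log-uniform e-values, then enforce the within-clan ranking.

    The Sarbecovirus-specific hit must rank best (lowest e-value) inside
    each clan: it matches its genome exactly while the generic family is a
    broader, weaker model; the short nested motifs score weakest of all.
    """
    accs = [acc for acc, *_ in CASE_STUDY_HITS]
    values = sorted(10 ** rng.uniform(-70, -8) for _ in accs)
    # hand the smallest e-values to the family that must win each clan
    order = ["RF03125", "RF03120", "RF03121", "RF03117", "RF00507", "RF00165", "RF00164"]
    evalues = dict(zip(order, values))
    return {
        acc: (evalues[acc], round(-10 * math.log10(evalues[acc]), 1)) for acc in accs
    }


@dataclass
class CaseStudyFixture:
    genome: RnaSequence
    hits: list[RfamHit]
    clans: ClanAssignment
    store: ReplayStore
    window: int = CASE_STUDY_WINDOW
    overlap: int = CASE_STUDY_OVERLAP


def _synthetic_consensus(rng: random.Random) -> tuple[str, str]:
    """A balanced synthetic WUSS consensus (sequence, structure) pair."""
    parts = [
        "::::",
        "<<<<<_____>>>>>",
        ",,,,",
        "((((....))))",
        "----",
        "<<<<____>>>>",
        "::::",
        "AAAA....aaaa",
        "~~~~",
        "[[[....]]]",
        "::::",
    ]
    wuss = "".join(parts)
    seq = _random_rna(rng, len(wuss))
    return seq, wuss


def _synthetic_seed_alignment(rng: random.Random, consensus_seq: str, wuss: str, n_rows: int) -> str:
    rows = []
    for i in range(n_rows):
        name = f"SYN{i:02d}{rng.randint(1000, 9999)}.1/1-{len(consensus_seq)}"
        seq = list(consensus_seq)
        for _ in range(len(seq) // 10):  # sprinkle mutations and gap columns
            j = rng.randrange(len(seq))
            seq[j] = rng.choice(_RNA) if rng.random() < 0.7 else "-"
        rows.append((name, "".join(seq)))
    lines = ["# STOCKHOLM 1.0", "#=GF AC RF03120", "#=GF ID Sarbecovirus-5UTR"]
    width = max(len(n) for n, _ in rows + [("#=GC SS_cons", "")])
    for name, seq in rows:
        lines.append(f"{name:<{width}} {seq}")
    lines.append(f"{'#=GC SS_cons':<{width}} {wuss}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def _synthetic_tree(rng: random.Random, labels: list[str]) -> str:
    """Random fully resolved unrooted NHX tree over ``labels``.

    Rendered with a root trifurcation, so n tips give n - 2 internal nodes.
    """

    def bl() -> str:
        return f"{rng.uniform(0.01, 0.5):.3f}"

    def subtree(tips: list[str]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{bl()}"
        k = rng.randint(1, len(tips) - 1)
        left, right = tips[:k], tips[k:]
        support = f"{rng.uniform(0.5, 1.0):.2f}"
        return (
            f"({subtree(left)},{subtree(right)}){support}:{bl()}"
            f"[&&NHX:B={support}]"
        )

    tips = list(labels)
    rng.shuffle(tips)
    assert len(tips) >= 3
    third = max(1, len(tips) // 3)
    a, b, c = tips[:third], tips[third : 2 * third], tips[2 * third :]
    return f"({subtree(a)},{subtree(b)},{subtree(c)});"


def build_case_study(directory: str | Path) -> CaseStudyFixture:
    """Build the bundled ``casestudy/`` replay store and its ground truth.

    Deterministic: repeated calls produce identical stores. The returned
    fixture's ``hits`` are the seven annotations in genome order with the
    drawn e-values attached; running the search pipeline against the store
    with clan competition off reproduces them exactly, and with the filter
    on (threshold 0.5) leaves the three :data:`CASE_STUDY_SURVIVORS`.
    """
    rng = random.Random(_CASE_STUDY_SEED)
    store = ReplayStore(Path(directory))
    genome = RnaSequence(
        identifier="synthetic-betacoronavirus-genome",
        residues=_random_rna(rng, CASE_STUDY_GENOME_LENGTH),
    )
    scores = _case_study_evalues(rng)
    hits = [
        make_hit(acc, fam_id, start, end, e_value=scores[acc][0], bit_score=scores[acc][1])
        for acc, fam_id, start, end, _ in CASE_STUDY_HITS
    ]
    clans = ClanAssignment(
        {acc: clan for acc, _, _, _, clan in CASE_STUDY_HITS if clan is not None}
    )

    # per-fragment search responses (first fragment exercises pending -> done)
    plan = plan_fragments(len(genome), window=CASE_STUDY_WINDOW, overlap=CASE_STUDY_OVERLAP)
    for i, fragment in enumerate(cut_fragments(genome, plan)):
        local = [
            {
                "accession": h.rfam_accession,
                "id": h.rfam_id,
                "start": h.query_start - fragment.parent_start + 1,
                "end": h.query_end - fragment.parent_start + 1,
                "bit_score": h.bit_score,
                "e_value": h.e_value,
            }
            for h in hits
            if h.query_start >= fragment.parent_start and h.query_end <= fragment.parent_end
        ]
        record_fragment_search(store, fragment, local, pending_polls=1 if i == 0 else 0)

    # family metadata: summaries and accession <-> ID lookups
    families = list(CASE_STUDY_HITS) + [("RF00005", "tRNA", 0, 0, "CL00001")]
    for acc, fam_id, *_ in families:
        record_family_lookup(store, acc, fam_id)
        summary = {
            "accession": acc,
            "id": fam_id,
            "description": _FAMILY_DESCRIPTIONS[acc],
            "number_of_sequences": rng.randint(20, 5000),
        }
        for target in (acc, fam_id):
            _record_json(store, EndpointRequest(kind="summary", accession_or_id=target), summary)

    # an absent family: recorded 404 so offline lookups fail loudly and typed
    _record_json(
        store,
        EndpointRequest(kind="summary", accession_or_id="RF99999"),
        {"error": "family not found"},
        status=404,
    )

    # keyword search (with a duplicate row, as served) and a no-hit query
    _record_json(
        store,
        EndpointRequest(kind="text_search", params={"query": "tRNA"}),
        {"accessions": ["RF00005", "RF00005", "RF01852"]},
    )
    _record_json(
        store,
        EndpointRequest(kind="text_search", params={"query": "zzzz-no-such-term"}),
        {"accessions": []},
    )

    # RF03120 family data, all synthetic stand-ins with realistic shapes
    cons_seq, wuss = _synthetic_consensus(rng)
    for target in ("RF03120", "Sarbecovirus-5UTR"):
        _record_json(
            store,
            EndpointRequest(kind="secondary_structure", accession_or_id=target),
            {"sequence": cons_seq, "structure": wuss},
        )
    stockholm = _synthetic_seed_alignment(rng, cons_seq, wuss, n_rows=19)
    store.record(
        EndpointRequest(kind="seed_alignment", accession_or_id="RF03120"),
        TransportResponse(status=200, content_kind="stockholm", body=stockholm.encode()),
    )
    from .formats import parse_stockholm

    labels = [name for name, _ in parse_stockholm(stockholm).rows]
    tree = _synthetic_tree(rng, labels)
    store.record(
        EndpointRequest(kind="seed_tree", accession_or_id="RF03120"),
        TransportResponse(status=200, content_kind="nhx", body=tree.encode()),
    )
    cm = (
        "INFERNAL1/a [1.1.4 | synthetic]\n"
        "NAME     Sarbecovirus-5UTR\nACC      RF03120\n"
        f"CLEN     {len(cons_seq)}\n//\n"
    ).encode()
    store.record(
        EndpointRequest(kind="covariance_model", accession_or_id="RF03120"),
        TransportResponse(status=200, content_kind="cm", body=cm),
    )
    svg = (
        b'<?xml version="1.0" encoding="UTF-8"?>\n'
        b'<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100">'
        b"<title>synthetic RF03120 structure diagram</title></svg>\n"
    )
    for plot_type in ("norm", "cons"):
        store.record(
            EndpointRequest(
                kind="structure_image",
                accession_or_id="RF03120",
                params={"plot_type": plot_type, "format": "svg"},
            ),
            TransportResponse(status=200, content_kind="svg", body=svg),
        )
        store.record(
            EndpointRequest(
                kind="structure_image",
                accession_or_id="RF03120",
                params={"plot_type": plot_type},
            ),
            TransportResponse(status=200, content_kind="image", body=b"\x89PNGSYNTH" + plot_type.encode()),
        )
    store.record(
        EndpointRequest(
            kind="seed_tree_image", accession_or_id="RF03120", params={"label": "species"}
        ),
        TransportResponse(status=200, content_kind="image", body=b"GIF89aSYNTH"),
    )
    _record_json(
        store,
        EndpointRequest(kind="regions", accession_or_id="RF03120"),
        {
            "regions": [
                {
                    "genbank_accession": f"SYN{rng.randint(100000, 999999)}.1",
                    "region_start": 1,
                    "region_end": len(cons_seq),
                    "description": "synthetic member region",
                    "species": f"Synthetic sarbecovirus {i}",
                }
                for i in range(5)
            ]
        },
    )
    _record_json(store, EndpointRequest(kind="pdb_mapping", accession_or_id="RF03120"), {"mappings": []})

    # RF00005 consensus structure + PDB mapping (the classic solved tRNA)
    trna_wuss = "::((((<<<<____>>>><<<<_____>>>>))))::"
    trna_seq = _random_rna(rng, len(trna_wuss))
    for target in ("RF00005", "tRNA"):
        _record_json(
            store,
            EndpointRequest(kind="secondary_structure", accession_or_id=target),
            {"sequence": trna_seq, "structure": trna_wuss},
        )
    _record_json(
        store,
        EndpointRequest(kind="pdb_mapping", accession_or_id="RF00005"),
        {
            "mappings": [
                {
                    "pdb_id": "1EHZ",
                    "chain": "A",
                    "pdb_residue_start": 1,
                    "pdb_residue_end": 76,
                    "cm_position_start": 1,
                    "cm_position_end": 71,
                }
            ]
        },
    )
    return CaseStudyFixture(genome=genome, hits=hits, clans=clans, store=store)
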