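import random

import pytest

from rfamkit.client import RfamClient
from rfamkit.fixtures import build_case_study
from rfamkit.model import SeedAlignment, make_hit


@pytest.fixture(scope="session")
def case_study(tmp_path_factory):
    """The replayable whole-genome annotation fixture (built once)."""
    directory = tmp_path_factory.mktemp("casestudy")
    return build_case_study(directory)


@pytest.fixture()
def case_client(case_study):
    return RfamClient.for_replay(case_study.store.directory, clans=case_study.clans)


# ---------------------------------------------------------------------------
# Random-instance generators shared by property tests
# ---------------------------------------------------------------------------


def random_hits(rng: random.Random, n: int, span: int = 500) -> list:
    """Random coordinate-normalized hits over a small coordinate span."""
    hits = []
    for i in range(n):
        start = rng.randint(1, span)
        end = start + rng.randint(0, 80)
        hits.append(
            make_hit(
                f"RF{rng.randint(0, 99999):05d}",
                f"fam{i}",
                start,
                end,
                bit_score=round(rng.uniform(10, 100), 1),
                e_value=10 ** rng.uniform(-30, 0),
            )
        )
    return hits


def random_clans(rng: random.Random, hits, n_clans: int = 3):
    """Assign each hit's family to a random clan, or to none."""
    mapping = {}
    for h in hits:
        if rng.random() < 0.75:
            mapping[h.rfam_accession] = f"CL{rng.randint(1, n_clans):05d}"
    return mapping


def random_wuss(rng: random.Random, max_len: int = 120) -> str:
    """A random balanced WUSS-style structure string.

    Mixes the four bracket families, pseudoknot letter pairs and the WUSS
    unpaired symbol classes; built recursively so balance holds by
    construction.
    """
    families = [("<", ">"), ("(", ")"), ("[", "]"), ("{", "}"), ("A", "a"), ("B", "b")]
    unpaired = ":,_-~."

    def build(budget: int) -> str:
        if budget <= 0:
            return ""
        roll = rng.random()
        if roll < 0.35 and budget >= 2:
            o, c = rng.choice(families)
            inner = build(budget - 2)
            return o + inner + c
        if roll < 0.6 and budget >= 2:
            k = rng.randint(1, budget // 2)
            return build(k) + build(budget - k)
        n = rng.randint(1, min(4, budget))
        return "".join(rng.choice(unpaired) for _ in range(n))

    return build(rng.randint(1, max_len)) or "."


ALN_NAME_CHARS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_./-"


def random_alignment(rng: random.Random) -> SeedAlignment:
    """A random SeedAlignment with rows, GF/GS/GC/GR annotations and gaps."""
    n_rows = rng.randint(1, 20)
    width = rng.randint(1, 200)
    names = []
    while len(names) < n_rows:
        name = "".join(rng.choice(ALN_NAME_CHARS) for _ in range(rng.randint(1, 12)))
        if name not in names and not name.startswith("#"):
            names.append(name)

    def row() -> str:
        return "".join(
            rng.choice("ACGU-.") if rng.random() < 0.5 else rng.choice("ACGU")
            for _ in range(width)
        )

    aln = SeedAlignment(rows=[(name, row()) for name in names])
    if rng.random() < 0.8:
        aln.column_annotations["SS_cons"] = "".join(
            rng.choice("<>().:,_-~") for _ in range(width)
        )
    if rng.random() < 0.4:
        aln.column_annotations["RF"] = "".join(rng.choice("ACGUx.") for _ in range(width))
    if rng.random() < 0.5:
        aln.file_annotations["ID"] = ["random-family"]
        aln.file_annotations["CC"] = ["first comment", "second comment"]
    if rng.random() < 0.3:
        aln.file_annotations[f"GS {names[0]} AC"] = ["SYN000001.1"]
    if rng.random() < 0.4:
        target = rng.choice(names)
        aln.row_annotations[target] = {
            "PP": "".join(rng.choice("0123456789*.") for _ in range(width))
        }
    return aln
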