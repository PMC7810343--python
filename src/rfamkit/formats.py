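"""Readers, writers and converters for the formats the toolkit touches.

Stockholm 1.0 / Pfam-dialect alignments, gapped and ungapped FASTA, two-line
consensus-structure files in extended dot-bracket (DB) or WUSS notation,
Newick/NHX trees (via dendropy), tab-delimited exports, and opaque
pass-through of Infernal covariance models and SVG images.

The Stockholm reader/writer is lossless on the :class:`~rfamkit.model.SeedAlignment`
data model: every GF/GS/GC/GR annotation line survives a round trip verbatim,
which generic alignment readers that map annotation keys do not guarantee.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import dendropy

from .errors import (
    MalformedNewickError,
    MalformedStockholmError,
    NotACovarianceModelError,
    NotAnSvgError,
    RaggedAlignmentError,
    UnbalancedStructureError,
)
from .model import ConsensusStructure, PdbCorrespondence, SeedAlignment, SequenceRegion


class StructureNotation(str, Enum):
    DB = "DB"
    WUSS = "WUSS"


class AlignmentFormat(str, Enum):
    STOCKHOLM = "stockholm"
    PFAM = "pfam"
    FASTA = "fasta"
    FASTAU = "fastau"


class PlotType(str, Enum):
    """Secondary-structure diagram flavours offered by the Rfam service."""

    NORM = "norm"  # plain diagram
    CONS = "cons"  # sequence conservation
    FCBP = "fcbp"  # basepair conservation
    COV = "cov"  # covariation
    ENT = "ent"  # relative entropy
    MAXCM = "maxcm"  # maximum covariance-model parse
    RSCAPE = "rscape"  # R-scape analysis of the seed alignment
    RSCAPE_CYK = "rscape-cyk"  # structure predicted by R-scape


class TreeLabelType(str, Enum):
    SPECIES = "species"
    ACC = "acc"


# ---------------------------------------------------------------------------
# Secondary-structure strings
# ---------------------------------------------------------------------------

#: Opening bracket -> closing bracket for the nested families kept distinct in
#: extended dot-bracket notation.
_BRACKET_PAIRS = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSING = {v: k for k, v in _BRACKET_PAIRS.items()}

#: WUSS symbols that denote an unpaired position (loop/bulge/insert classes).
WUSS_UNPAIRED = set(":,_-~.")


def pairing_map(structure: str) -> dict[int, int]:
    """Base-pair map of a structure string (1-based positions, both directions).

    Handles the four bracket families and pseudoknot letter pairs (``A``/``a``
    .. ``Z``/``z``), each matched with its own stack. Any other character is
    treated as unpaired. Raises :class:`UnbalancedStructureError` on a close
    without an open or a leftover open, reporting the family and 1-based
    position.
    """
    stacks: dict[str, list[int]] = {}
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(structure, start=1):
        if ch in _BRACKET_PAIRS:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSING:
            opener = _CLOSING[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise UnbalancedStructureError(opener + ch, pos)
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
        elif ch.isalpha():
            if ch.isupper():
                stacks.setdefault(ch, []).append(pos)
            else:
                stack = stacks.get(ch.upper(), [])
                if not stack:
                    raise UnbalancedStructureError(ch.upper() + ch, pos)
                i = stack.pop()
                pairs[i] = pos
                pairs[pos] = i
    for opener, stack in stacks.items():
        if stack:
            fam = opener + _BRACKET_PAIRS.get(opener, opener.lower())
            raise UnbalancedStructureError(fam, stack[-1])
    return pairs


def wuss_to_dotbracket(ss: str) -> str:
    """Convert a WUSS structure string to extended dot-bracket notation.

    Bracket families ``<>``, ``()``, ``[]``, ``{}`` and pseudoknot letter
    pairs are preserved as distinct families; every WUSS unpaired symbol
    (``:``, ``,``, ``_``, ``-``, ``~``, ``.``) becomes ``.``. Length and the
    base-pair set are preserved exactly.
    """
    pairing_map(ss)  # raises on unbalanced input
    out = []
    for ch in ss:
        if ch in _BRACKET_PAIRS or ch in _CLOSING or ch.isalpha():
            out.append(ch)
        else:
            out.append(".")
    return "".join(out)


def write_consensus_file(cs: ConsensusStructure) -> str:
    """Two-line record: consensus sequence, then structure string.

    The layout is the extended dot-bracket file understood by helix-plotting
    tools; :func:`parse_consensus_file` inverts it losslessly.
    """
    return f"{cs.sequence}\n{cs.structure}\n"


def parse_consensus_file(text: str, notation: str = "DB") -> ConsensusStructure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 2:
        raise MalformedStockholmError(1, "consensus file must have exactly two lines")
    return ConsensusStructure(sequence=lines[0], structure=lines[1], notation=notation)


# ---------------------------------------------------------------------------
# Stockholm alignments
# ---------------------------------------------------------------------------

_STOCKHOLM_HEADER = "# STOCKHOLM 1.0"


def parse_stockholm(text: str) -> SeedAlignment:
    """Parse a Stockholm 1.0 record into a :class:`SeedAlignment`.

    Interleaved (multi-block) records are supported: repeated occurrences of
    a row or annotation name across blocks are concatenated in order. GS
    lines are kept in ``file_annotations`` under ``"GS <name> <key>"`` so
    nothing is dropped.
    """
    lines = text.splitlines()
    if not lines or lines[0].strip() != _STOCKHOLM_HEADER:
        raise MalformedStockholmError(1, f"missing {_STOCKHOLM_HEADER!r} header")

    aln = SeedAlignment()
    row_index: dict[str, int] = {}
    for no, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip()
        if not line:
            continue
        if line == "//":
            break
        if line.startswith("#=GF"):
            parts = line.split(None, 2)
            if len(parts) < 2:
                raise MalformedStockholmError(no, "bad GF line")
            key = parts[1]
            value = parts[2] if len(parts) == 3 else ""
            aln.file_annotations.setdefault(key, []).append(value)
        elif line.startswith("#=GS"):
            parts = line.split(None, 3)
            if len(parts) < 3:
                raise MalformedStockholmError(no, "bad GS line")
            key = f"GS {parts[1]} {parts[2]}"
            value = parts[3] if len(parts) == 4 else ""
            aln.file_annotations.setdefault(key, []).append(value)
        elif line.startswith("#=GC"):
            parts = line.split()
            if len(parts) != 3:
                raise MalformedStockholmError(no, "bad GC line")
            aln.column_annotations[parts[1]] = (
                aln.column_annotations.get(parts[1], "") + parts[2]
            )
        elif line.startswith("#=GR"):
            parts = line.split()
            if len(parts) != 4:
                raise MalformedStockholmError(no, "bad GR line")
            per_row = aln.row_annotations.setdefault(parts[1], {})
            per_row[parts[2]] = per_row.get(parts[2], "") + parts[3]
        elif line.startswith("#"):
            continue  # other comments are not part of the data model
        else:
            parts = line.split()
            if len(parts) != 2:
                raise MalformedStockholmError(no, "expected '<name> <sequence>'")
            name, seq = parts
            if name in row_index:
                i = row_index[name]
                aln.rows[i] = (name, aln.rows[i][1] + seq)
            else:
                row_index[name] = len(aln.rows)
                aln.rows.append((name, seq))

    widths = {len(s) for _, s in aln.rows}
    widths |= {len(v) for v in aln.column_annotations.values()}
    for per_row in aln.row_annotations.values():
        widths |= {len(v) for v in per_row.values()}
    if len(widths) > 1:
        raise RaggedAlignmentError(
            f"rows/annotations have differing lengths: {sorted(widths)}"
        )
    return aln


def _stockholm_body(aln: SeedAlignment) -> list[str]:
    out = [_STOCKHOLM_HEADER]
    for key, values in aln.file_annotations.items():
        for value in values:
            if key.startswith("GS "):
                out.append(f"#=GS {key[3:]} {value}".rstrip())
            else:
                out.append(f"#=GF {key} {value}".rstrip())
    name_width = max(
        [len(n) for n, _ in aln.rows]
        + [len(f"#=GC {k}") for k in aln.column_annotations]
        + [len(f"#=GR {n} {k}") for n, per in aln.row_annotations.items() for k in per]
        + [0]
    )
    for name, seq in aln.rows:
        out.append(f"{name:<{name_width}} {seq}")
        for key, value in aln.row_annotations.get(name, {}).items():
            tag = f"#=GR {name} {key}"
            out.append(f"{tag:<{name_width}} {value}")
    for key, value in aln.column_annotations.items():
        tag = f"#=GC {key}"
        out.append(f"{tag:<{name_width}} {value}")
    out.append("//")
    return out


GAP_CHARS = frozenset("-.")


def write_alignment(aln: SeedAlignment, fmt: AlignmentFormat | str) -> str:
    """Serialize an alignment.

    ``stockholm``: single-block Stockholm 1.0, round-trippable by
    :func:`parse_stockholm`. ``pfam``: the same single-block dialect, with the
    ``SS_cons`` consensus-structure line rewritten in dot-bracket notation
    when it converts cleanly (the "alternative secondary structure notation").
    ``fasta``: gapped rows verbatim. ``fastau``: rows with every gap
    character (``-`` and ``.``) removed.
    """
    fmt = AlignmentFormat(fmt)
    aln.validate()
    if fmt is AlignmentFormat.STOCKHOLM:
        return "\n".join(_stockholm_body(aln)) + "\n"
    if fmt is AlignmentFormat.PFAM:
        clone = SeedAlignment(
            rows=list(aln.rows),
            column_annotations=dict(aln.column_annotations),
            row_annotations={n: dict(p) for n, p in aln.row_annotations.items()},
            file_annotations={k: list(v) for k, v in aln.file_annotations.items()},
        )
        ss = clone.column_annotations.get("SS_cons")
        if ss is not None:
            try:
                clone.column_annotations["SS_cons"] = wuss_to_dotbracket(ss)
            except UnbalancedStructureError:
                pass  # keep the original annotation rather than invent pairs
        return "\n".join(_stockholm_body(clone)) + "\n"
    records = []
    for name, seq in aln.rows:
        if fmt is AlignmentFormat.FASTAU:
            seq = "".join(ch for ch in seq if ch not in GAP_CHARS)
        records.append(f">{name}\n{seq}")
    return "\n".join(records) + "\n"


# ---------------------------------------------------------------------------
# Newick / NHX trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSummary:
    """Shape summary of a parsed Newick/NHX tree."""

    tip_count: int
    internal_node_count: int
    tip_labels: tuple[str, ...] = ()
    has_branch_lengths: bool = False
    nhx_comments: tuple[str, ...] = field(default=(), compare=False)


def parse_nhx(text: str) -> TreeSummary:
    """Parse one Newick/NHX statement and summarize its shape.

    NHX comment blocks (``[&&NHX:...]``) are preserved opaquely in
    ``nhx_comments``. The root counts as an internal node iff it has at
    least two children, so a fully resolved unrooted tree with n tips
    reports n - 2 internal nodes and a strictly bifurcating rooted tree
    reports n - 1.
    """
    if not text.strip().endswith(";"):
        raise MalformedNewickError("statement must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,  # keep NHX blocks opaque
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise MalformedNewickError(str(exc)) from exc

    tips = [leaf for leaf in tree.leaf_node_iter()]
    internal = 0
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if node is tree.seed_node:
            if n_children >= 2:
                internal += 1
        elif n_children >= 1:
            internal += 1
    labels = tuple(
        (leaf.taxon.label if leaf.taxon is not None else (leaf.label or ""))
        for leaf in tips
    )
    has_bl = any(
        node.edge.length is not None
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    )
    comments: list[str] = []
    for node in tree.preorder_node_iter():
        comments.extend(str(c) for c in node.comments)
    return TreeSummary(
        tip_count=len(tips),
        internal_node_count=internal,
        tip_labels=labels,
        has_branch_lengths=has_bl,
        nhx_comments=tuple(comments),
    )


# ---------------------------------------------------------------------------
# Tab-delimited exports
# ---------------------------------------------------------------------------


def _escape(fieldval: object) -> str:
    return (
        str(fieldval)
        .replace("\\", "\\\\")
        .replace("\t", "\\t")
        .replace("\n", "\\n")
    )


def _unescape(fieldval: str) -> str:
    out = []
    it = iter(fieldval)
    for ch in it:
        if ch == "\\":
            nxt = next(it, "")
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, nxt))
        else:
            out.append(ch)
    return "".join(out)


REGIONS_COLUMNS = ("genbank_accession", "region_start", "region_end", "description", "species")
PDB_COLUMNS = (
    "pdb_id",
    "chain",
    "pdb_residue_start",
    "pdb_residue_end",
    "cm_position_start",
    "cm_position_end",
)


def write_regions_tsv(regions: Sequence[SequenceRegion]) -> str:
    lines = ["\t".join(REGIONS_COLUMNS)]
    for r in regions:
        lines.append(
            "\t".join(
                _escape(v)
                for v in (
                    r.genbank_accession,
                    r.region_start,
                    r.region_end,
                    r.description,
                    r.species,
                )
            )
        )
    return "\n".join(lines) + "\n"


def parse_regions_tsv(text: str) -> list[SequenceRegion]:
    lines = [ln for ln in text.splitlines() if ln]
    out = []
    for ln in lines[1:]:
        acc, start, end, desc, species = (_unescape(f) for f in ln.split("\t"))
        out.append(
            SequenceRegion(
                genbank_accession=acc,
                region_start=int(start),
                region_end=int(end),
                description=desc,
                species=species,
            )
        )
    return out


def write_pdb_tsv(rows: Sequence[PdbCorrespondence]) -> str:
    lines = ["\t".join(PDB_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                _escape(v)
                for v in (
                    r.pdb_id,
                    r.chain,
                    r.pdb_residue_start,
                    r.pdb_residue_end,
                    r.cm_position_start,
                    r.cm_position_end,
                )
            )
        )
    return "\n".join(lines) + "\n"


def parse_pdb_tsv(text: str) -> list[PdbCorrespondence]:
    lines = [ln for ln in text.splitlines() if ln]
    out = []
    for ln in lines[1:]:
        pdb_id, chain, ps, pe, cs, ce = (_unescape(f) for f in ln.split("\t"))
        out.append(
            PdbCorrespondence(
                pdb_id=pdb_id,
                chain=chain,
                pdb_residue_start=int(ps),
                pdb_residue_end=int(pe),
                cm_position_start=int(cs),
                cm_position_end=int(ce),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Opaque pass-throughs
# ---------------------------------------------------------------------------

_SVG_ROOT_RE = re.compile(rb"<svg[\s>]", re.IGNORECASE)


def passthrough_cm(payload: bytes) -> bytes:
    """Validate and return Infernal covariance-model bytes unchanged."""
    if not payload.lstrip().startswith(b"INFERNAL"):
        raise NotACovarianceModelError()
    return payload


def passthrough_svg(payload: bytes) -> bytes:
    """Validate and return SVG/XML bytes unchanged."""
    if not _SVG_ROOT_RE.search(payload):
        raise NotAnSvgError()
    return payload
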