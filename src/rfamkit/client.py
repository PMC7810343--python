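"""High-level Rfam client: one method per service capability.

Wraps a :class:`~rfamkit.transport.Transport` and converts raw payloads
into the domain types of :mod:`rfamkit.model` using :mod:`rfamkit.formats`.
Every method accepts either a family accession (RFxxxxx) or a family ID
mnemonic (e.g. ``tRNA``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from . import formats
from .clanfilter import load_clan_snapshot
from .formats import (
    AlignmentFormat,
    PlotType,
    StructureNotation,
    TreeLabelType,
)
from .model import (
    ClanAssignment,
    ConsensusStructure,
    FamilySummary,
    PdbCorrespondence,
    RfamHit,
    RnaSequence,
    SearchOptions,
    SeedAlignment,
    SequenceRegion,
    validate_accession,
)
from .search import sequence_search
from .transport import EndpointRequest, Transport


class RfamClient:
    def __init__(self, transport: Transport, clans: Optional[ClanAssignment] = None) -> None:
        self.transport = transport
        self.clans = clans if clans is not None else load_clan_snapshot()

    @classmethod
    def for_replay(cls, directory: str | Path, clans: Optional[ClanAssignment] = None) -> "RfamClient":
        return cls(Transport.for_replay(directory), clans=clans)

    # -- searches ------------------------------------------------------

    def text_search(self, query: str) -> list[str]:
        """Accessions of families whose ID, summary or description match."""
        return self.transport.text_search(query)

    def sequence_search(
        self, seq: RnaSequence, options: Optional[SearchOptions] = None
    ) -> list[RfamHit]:
        """Non-coding RNA hits in a query of unlimited length."""
        return sequence_search(seq, options, self.clans, transport=self.transport)

    # -- lookups -------------------------------------------------------

    def accession_to_id(self, accession: str) -> str:
        validate_accession(accession)
        return self.transport.lookup_id(accession)[1]

    def id_to_accession(self, family_id: str) -> str:
        validate_accession(family_id)
        return self.transport.lookup_id(family_id)[0]

    # -- family data ---------------------------------------------------

    def summary(self, family: str) -> FamilySummary:
        payload = self.transport.fetch_json(
            EndpointRequest(kind="summary", accession_or_id=family)
        )
        known = {"accession", "id", "description", "number_of_sequences"}
        return FamilySummary(
            accession=str(payload["accession"]),
            id=str(payload["id"]),
            description=str(payload.get("description", "")),
            number_of_sequences=int(payload.get("number_of_sequences", 0)),
            metadata={k: str(v) for k, v in payload.items() if k not in known},
        )

    def consensus_structure(
        self, family: str, notation: StructureNotation | str = StructureNotation.DB
    ) -> ConsensusStructure:
        """Consensus sequence and secondary structure of a family.

        The service stores the structure in WUSS notation; the default
        ``DB`` output converts it to extended dot-bracket, preserving
        bracket families and pseudoknot letters.
        """
        notation = StructureNotation(notation)
        payload = self.transport.fetch_json(
            EndpointRequest(kind="secondary_structure", accession_or_id=family)
        )
        sequence = str(payload["sequence"])
        structure = str(payload["structure"])  # WUSS as served
        if notation is StructureNotation.DB:
            structure = formats.wuss_to_dotbracket(structure)
        return ConsensusStructure(sequence=sequence, structure=structure, notation=notation.value)

    def structure_image(self, family: str, plot_type: PlotType | str = PlotType.NORM) -> bytes:
        """Raster/vector structure diagram as opaque bytes."""
        plot_type = PlotType(plot_type)
        return self.transport.fetch(
            EndpointRequest(
                kind="structure_image",
                accession_or_id=family,
                params={"plot_type": plot_type.value},
            )
        ).body

    def structure_svg(self, family: str, plot_type: PlotType | str = PlotType.NORM) -> bytes:
        """Structure diagram as SVG/XML bytes (validated, byte-preserved)."""
        plot_type = PlotType(plot_type)
        body = self.transport.fetch(
            EndpointRequest(
                kind="structure_image",
                accession_or_id=family,
                params={"plot_type": plot_type.value, "format": "svg"},
            )
        ).body
        return formats.passthrough_svg(body)

    def seed_alignment(self, family: str) -> SeedAlignment:
        """The curated seed alignment the family's covariance model is built from."""
        body = self.transport.fetch(
            EndpointRequest(kind="seed_alignment", accession_or_id=family)
        ).body
        return formats.parse_stockholm(body.decode())

    def seed_alignment_text(self, family: str, fmt: AlignmentFormat | str) -> str:
        return formats.write_alignment(self.seed_alignment(family), AlignmentFormat(fmt))

    def seed_tree(self, family: str) -> str:
        """Phylogenetic tree of the seed alignment, as NHX text."""
        body = self.transport.fetch(
            EndpointRequest(kind="seed_tree", accession_or_id=family)
        ).body
        return body.decode()

    def seed_tree_image(self, family: str, label: TreeLabelType | str = TreeLabelType.SPECIES) -> bytes:
        label = TreeLabelType(label)
        return self.transport.fetch(
            EndpointRequest(
                kind="seed_tree_image",
                accession_or_id=family,
                params={"label": label.value},
            )
        ).body

    def covariance_model(self, family: str) -> bytes:
        """Infernal covariance model, validated and byte-preserved."""
        body = self.transport.fetch(
            EndpointRequest(kind="covariance_model", accession_or_id=family)
        ).body
        return formats.passthrough_cm(body)

    def regions(self, family: str) -> list[SequenceRegion]:
        """All sequence regions annotated as members of the family."""
        payload = self.transport.fetch_json(
            EndpointRequest(kind="regions", accession_or_id=family)
        )
        rows = payload["regions"] if isinstance(payload, dict) else payload
        return [
            SequenceRegion(
                genbank_accession=str(r["genbank_accession"]),
                region_start=int(r["region_start"]),
                region_end=int(r["region_end"]),
                description=str(r.get("description", "")),
                species=str(r.get("species", "")),
            )
            for r in rows
        ]

    def pdb_mapping(self, family: str) -> list[PdbCorrespondence]:
        """PDB entries with solved 3D structures of family members."""
        payload = self.transport.fetch_json(
            EndpointRequest(kind="pdb_mapping", accession_or_id=family)
        )
        rows = payload["mappings"] if isinstance(payload, dict) else payload
        return [
            PdbCorrespondence(
                pdb_id=str(r["pdb_id"]),
                chain=str(r["chain"]),
                pdb_residue_start=int(r["pdb_residue_start"]),
                pdb_residue_end=int(r["pdb_residue_end"]),
                cm_position_start=int(r["cm_position_start"]),
                cm_position_end=int(r["cm_position_end"]),
            )
            for r in rows
        ]
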