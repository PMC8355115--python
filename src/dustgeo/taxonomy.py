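"""Species assignment of OTUs against a local barcode reference.

Assignment mirrors a 100%-identity barcode lookup: an OTU is assigned every
reference species whose deposited barcode contains the full OTU sequence with
zero mismatches (either strand).  Minibarcodes are short, so one OTU often
matches several congeneric species; all matches are retained.  Names are then
normalized to plain binomials (infraspecific ranks stripped, placeholder taxa
such as "uncultured plant" dropped), optionally passed through a user-supplied
synonym table to harmonize nomenclature with the occurrence store, and finally
de-duplicated so each species is represented at most once per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .otu_tables import Marker, OtuRecord, SampleTable

log = logging.getLogger(__name__)

#: lowercase tokens that mark a non-species placeholder name
_PLACEHOLDER_TOKENS = {
    "uncultured",
    "unidentified",
    "environmental",
    "unclassified",
    "sp",
    "sp.",
    "aff.",
    "cf.",
}


@dataclass(frozen=True)
class ReferenceRecord:
    """One barcode reference entry (a local stand-in for a Genbank record)."""

    accession: str
    species_name: str
    marker: Marker
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.accession} has empty sequence")
        if len(self.species_name.split()) < 2:
            raise ValueError(
                f"reference {self.accession} species name {self.species_name!r} is not binomial"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class SpeciesAssignment:
    """Set of species names matched to one OTU at 100% identity."""

    otu_id: str
    species: set[str] = field(default_factory=set)

    @property
    def assigned(self) -> bool:
        return bool(self.species)


def normalize_name(raw: str) -> str | None:
    """Trim a raw taxon name to a normalized binomial, or None to drop it.

    "Pinus strobus var. chiapensis" -> "Pinus strobus"; placeholder taxa
    ("uncultured plant", "Quercus sp.") return None.  Idempotent.
    """
    tokens = str(raw).replace("_", " ").split()
    if len(tokens) < 2:
        return None
    genus, epithet = tokens[0], tokens[1]
    if genus.lower() in _PLACEHOLDER_TOKENS or epithet.lower() in _PLACEHOLDER_TOKENS:
        return None
    if not (genus.isalpha() and epithet.isalpha()):
        return None
    return f"{genus.capitalize()} {epithet.lower()}"


def apply_synonym_map(name: str, synonyms: dict[str, str]) -> str:
    """Map a binomial through a synonym table (single hop, never chained)."""
    return synonyms.get(name, name)


def assign_species(
    otu: OtuRecord,
    reference: list[ReferenceRecord],
    synonyms: dict[str, str] | None = None,
) -> SpeciesAssignment:
    """Match one OTU against the reference at 100% identity.

    A reference record matches when its sequence contains the full OTU
    sequence (or its reverse complement — deposited strand is not guaranteed)
    with zero mismatches.  All matching species are kept; an empty set flags
    the OTU as unassigned and it is excluded from mapping.
    """
    if not reference:
        log.warning("empty reference; OTU %s left unassigned", otu.otu_id)
        return SpeciesAssignment(otu.otu_id, set())
    query = otu.sequence
    query_rc = str(Seq(query).reverse_complement())
    species: set[str] = set()
    for ref in reference:
        if ref.marker is not otu.marker:
            continue
        if query in ref.sequence or query_rc in ref.sequence:
            name = normalize_name(ref.species_name)
            if name is None:
                continue
            if synonyms is not None:
                name = apply_synonym_map(name, synonyms)
            species.add(name)
    return SpeciesAssignment(otu.otu_id, species)


def dedupe_species(
    assignments: list[SpeciesAssignment], table: SampleTable
) -> list[SpeciesAssignment]:
    """Ensure each species is represented by at most one OTU per sample.

    OTUs are processed in descending total-read order (ties by otu_id); a
    species claimed by an earlier OTU is removed from later OTUs' sets, and
    OTUs whose set empties are dropped from mapping.
    """
    reads = {r.otu_id: r.total_reads for r in table.records}
    ordered = sorted(assignments, key=lambda a: (-reads.get(a.otu_id, 0), a.otu_id))
    claimed: set[str] = set()
    out: list[SpeciesAssignment] = []
    for a in ordered:
        remaining = a.species - claimed
        if not remaining:
            if a.species:
                log.debug("OTU %s dropped: all its species already claimed", a.otu_id)
            continue
        claimed |= remaining
        out.append(SpeciesAssignment(a.otu_id, remaining))
    return out


def read_reference_fasta(path) -> list[ReferenceRecord]:
    """Read a barcode reference FASTA with headers ``accession|marker|Genus epithet``."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        parts = header.split("|")
        if len(parts) < 3:
            raise ValueError(f"bad reference header {header!r}; expected accession|marker|name")
        accession, marker_raw, name = parts[0], parts[1], "|".join(parts[2:])
        records.append(
            ReferenceRecord(accession.strip(), name.strip(), Marker.parse(marker_raw), str(rec.seq))
        )
    return records


def read_synonym_csv(path) -> dict[str, str]:
    """Read a 2-column CSV mapping raw binomial -> accepted binomial."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: synonym map needs 2 columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
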