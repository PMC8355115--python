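"""Per-sample OTU tables and stringency filtering.

An OTU table is the product of upstream read processing (demultiplexing,
merging, 99% de-novo clustering): one row per OTU with the read count observed
in each of the sequencing replicates (three by default) for one minibarcode
marker.  This module parses those tables, attaches representative sequences,
and applies the high-stringency culling rules used before taxonomic
assignment:

* total reads across replicates of at least ``min_total_reads`` (default 3);
* presence (>= 1 read) in at least ``min_replicates_present`` of the
  replicates (default 3 of 3);
* relative abundance — OTU reads over the sample's pre-filter read total —
  strictly above ``min_rel_abundance`` (default 1e-4).

OTUs found in negative controls (clean-slide swab, PCR blank) are removed by
exact sequence identity, and the tables from the two markers of one sample are
combined for downstream analysis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, SampleMismatchError

log = logging.getLogger(__name__)

DEFAULT_N_REPLICATES = 3


class Marker(enum.Enum):
    """Plant minibarcode marker of an OTU."""

    ITS2 = "ITS2"
    RBCL3A = "rbcL-3A"

    @classmethod
    def parse(cls, raw: str) -> "Marker":
        token = str(raw).strip()
        for m in cls:
            if token == m.value or token.upper() == m.name:
                return m
        raise ValueError(f"unknown marker {raw!r}")


@dataclass(frozen=True)
class OtuRecord:
    """One OTU: per-replicate read counts, marker, representative sequence."""

    otu_id: str
    marker: Marker
    reads: tuple[int, ...]
    sequence: str = ""

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.reads):
            raise ValueError(f"negative read count in OTU {self.otu_id}")
        seq = self.sequence.upper()
        if seq and set(seq) - set("ACGTN"):
            raise ValueError(f"non-DNA characters in sequence of OTU {self.otu_id}")
        object.__setattr__(self, "sequence", seq)

    @property
    def total_reads(self) -> int:
        return int(sum(self.reads))

    @property
    def n_replicates_present(self) -> int:
        return sum(1 for r in self.reads if r > 0)


@dataclass
class SampleTable:
    """All OTU records of one sample (one marker, or both after combining).

    ``prefilter_total_reads`` records the read total against which relative
    abundance is measured; it is set when :func:`filter_otus` first runs so
    that repeated filtering is idempotent.
    """

    sample_id: str
    records: list[OtuRecord] = field(default_factory=list)
    prefilter_total_reads: int | None = None
    rejected_rows: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.marker, r.otu_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ParseError(
                f"duplicate (marker, otu_id) in sample {self.sample_id!r}"
            )

    @property
    def total_reads(self) -> int:
        return sum(r.total_reads for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FilterConfig:
    """Stringency thresholds for OTU culling."""

    min_total_reads: int = 3
    min_replicates_present: int = 3
    min_rel_abundance: float = 1e-4

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0 or self.min_replicates_present <= 0:
            raise ValueError("count thresholds must be strictly positive")
        if self.min_rel_abundance <= 0:
            raise ValueError("min_rel_abundance must be strictly positive")


def read_otu_table(
    path,
    fasta_path,
    sample_id: str | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> SampleTable:
    """Parse a TSV/CSV OTU table and attach representative sequences.

    The table needs columns ``otu_id``, ``marker`` and ``rep1..repN``; the
    FASTA must contain a record for every otu_id.  Rows whose marker is not a
    supported minibarcode (e.g. trnL) are rejected — reported on
    ``SampleTable.rejected_rows`` and in the log — rather than failing the
    whole table.
    """
    import pathlib

    path = pathlib.Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    rep_cols = [f"rep{i}" for i in range(1, n_replicates + 1)]
    missing = {"otu_id", "marker", *rep_cols} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    records: list[OtuRecord] = []
    rejected: list[dict] = []
    seen: set[tuple[Marker, str]] = set()
    for row in df.itertuples(index=False):
        otu_id = str(row.otu_id)
        try:
            marker = Marker.parse(row.marker)
        except ValueError:
            rejected.append({"otu_id": otu_id, "marker": str(row.marker), "reason": "unknown marker"})
            log.warning("%s: rejected OTU %s with unsupported marker %r", path, otu_id, row.marker)
            continue
        if (marker, otu_id) in seen:
            raise ParseError(f"{path}: duplicate otu_id {otu_id!r} for marker {marker.value}")
        seen.add((marker, otu_id))
        if otu_id not in sequences:
            raise ParseError(f"{fasta_path}: no FASTA record for otu_id {otu_id!r}")
        reads = tuple(int(getattr(row, c)) for c in rep_cols)
        records.append(OtuRecord(otu_id, marker, reads, sequences[otu_id]))

    sid = sample_id if sample_id is not None else path.stem
    table = SampleTable(sample_id=sid, records=records)
    table.rejected_rows = rejected
    return table


def filter_otus(table: SampleTable, cfg: FilterConfig = FilterConfig()) -> SampleTable:
    """Apply the stringency filter; keeps an OTU iff all three rules pass.

    Relative abundance is measured against the sample's pre-filter read total
    (replicates pooled); the original total is carried on the returned table
    so the operation is idempotent.
    """
    denom = table.prefilter_total_reads
    if denom is None:
        denom = table.total_reads
    if denom == 0:
        log.warning("sample %s has zero total reads; filter returns empty table", table.sample_id)
        return SampleTable(table.sample_id, [], prefilter_total_reads=0)

    kept = [
        r
        for r in table.records
        if r.total_reads >= cfg.min_total_reads
        and r.n_replicates_present >= cfg.min_replicates_present
        and r.total_reads / denom > cfg.min_rel_abundance
    ]
    for r in table.records:
        if r not in kept:
            log.debug("sample %s: culled OTU %s (reads=%s)", table.sample_id, r.otu_id, r.reads)
    return SampleTable(table.sample_id, kept, prefilter_total_reads=denom)


def subtract_controls(table: SampleTable, controls: list[SampleTable]) -> SampleTable:
    """Remove OTUs whose representative sequence occurs in any control.

    Controls are clustered independently of the sample, so matching is by
    exact sequence identity, not otu_id.  An empty control list is identity.
    """
    contaminant_seqs = {r.sequence for c in controls for r in c.records if r.sequence}
    kept = [r for r in table.records if r.sequence not in contaminant_seqs]
    n_removed = len(table.records) - len(kept)
    if n_removed:
        log.info("sample %s: removed %d control-matched OTUs", table.sample_id, n_removed)
    return SampleTable(table.sample_id, kept, prefilter_total_reads=table.prefilter_total_reads)


def combine_markers(tables: list[SampleTable]) -> SampleTable:
    """Concatenate the per-marker tables of one sample into a single table."""
    if not tables:
        raise ValueError("no tables to combine")
    sample_ids = {t.sample_id for t in tables}
    if len(sample_ids) != 1:
        raise SampleMismatchError(f"cannot combine tables from samples {sorted(sample_ids)}")
    records = [r for t in tables for r in t.records]
    denoms = [t.prefilter_total_reads for t in tables]
    denom = sum(denoms) if all(d is not None for d in denoms) else None
    return SampleTable(tables[0].sample_id, records, prefilter_total_reads=denom)


def write_otu_table(table: SampleTable, path, fasta_path=None) -> None:
    """Write a SampleTable back to TSV (and optionally its sequences to FASTA)."""
    n_rep = len(table.records[0].reads) if table.records else DEFAULT_N_REPLICATES
    rows = [
        {
            "otu_id": r.otu_id,
            "marker": r.marker.value,
            **{f"rep{i + 1}": r.reads[i] for i in range(n_rep)},
        }
        for r in table.records
    ]
    cols = ["otu_id", "marker"] + [f"rep{i}" for i in range(1, n_rep + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for r in table.records:
                fh.write(f">{r.otu_id}\n{r.sequence}\n")
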