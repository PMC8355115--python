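"""Local store of georeferenced species occurrence records.

A Darwin-Core-style CSV (scientificName, TSN, decimalLatitude,
decimalLongitude, flags) stands in for a live biodiversity repository such as
BISON.  Ingest applies per-record quality control — provider QC flags,
coordinate range checks and the (0, 0) placeholder — and the store answers
species queries first by taxonomic serial number (TSN) and then by binomial,
capped at 100,000 records per query with a seeded uniform subsample when a
species exceeds the cap.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError

log = logging.getLogger(__name__)

DEFAULT_QUERY_CAP = 100_000


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lat: float
    lon: float
    tsn: int | None = None
    flagged: bool = False


@dataclass
class IngestReport:
    total: int = 0
    accepted: int = 0
    rejected: int = 0


def qc_filter(rec: dict) -> OccurrenceRecord | None:
    """QC one raw record; None means reject.

    Rejects provider-flagged records, coordinates outside valid ranges or
    missing, and the (0, 0) null-island placeholder.
    """
    flagged = bool(rec.get("flagged", False))
    if flagged:
        return None
    try:
        lat = float(rec["lat"])
        lon = float(rec["lon"])
    except (KeyError, TypeError, ValueError):
        return None
    if not (np.isfinite(lat) and np.isfinite(lon)):
        return None
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        return None
    if lat == 0.0 and lon == 0.0:
        return None
    tsn = rec.get("tsn")
    tsn = int(tsn) if tsn is not None and not pd.isna(tsn) else None
    return OccurrenceRecord(str(rec["species"]), lat, lon, tsn=tsn, flagged=False)


class OccurrenceStore:
    """QC-clean occurrence records indexed by TSN and by binomial."""

    def __init__(self, records: list[OccurrenceRecord], query_cap: int = DEFAULT_QUERY_CAP):
        self.records = list(records)
        self.query_cap = int(query_cap)
        self._by_name: dict[str, list[int]] = {}
        self._by_tsn: dict[int, list[int]] = {}
        for i, r in enumerate(self.records):
            self._by_name.setdefault(r.species, []).append(i)
            if r.tsn is not None:
                self._by_tsn.setdefault(r.tsn, []).append(i)

    def __len__(self) -> int:
        return len(self.records)

    def tsn_of(self, species: str) -> int | None:
        """TSN associated with a binomial, if any record carries one."""
        for i in self._by_name.get(species, []):
            if self.records[i].tsn is not None:
                return self.records[i].tsn
        return None

    def query(
        self, species: str, tsn: int | None = None, seed: int = 0
    ) -> list[OccurrenceRecord]:
        """All records for a species: TSN lookup first, then binomial.

        When the match count exceeds the per-query cap, a uniform random
        subsample of exactly the cap size is drawn with the given seed
        (original record order preserved).  An empty list is a valid outcome.
        """
        idx: list[int] = []
        if tsn is not None and tsn in self._by_tsn:
            idx = self._by_tsn[tsn]
        else:
            idx = self._by_name.get(species, [])
        if len(idx) > self.query_cap:
            rng = np.random.default_rng(seed)
            chosen = rng.choice(len(idx), size=self.query_cap, replace=False)
            idx = [idx[i] for i in np.sort(chosen)]
        return [self.records[i] for i in idx]

    def query_coords(self, species: str, tsn: int | None = None, seed: int = 0) -> np.ndarray:
        """(n, 2) array of (lon, lat) for a species query."""
        recs = self.query(species, tsn=tsn, seed=seed)
        if not recs:
            return np.empty((0, 2))
        return np.array([(r.lon, r.lat) for r in recs])


def species_query_seed(base_seed: int, species: str) -> int:
    """Stable per-species seed so query subsampling is order-independent."""
    return (int(base_seed) ^ zlib.crc32(species.encode())) & 0x7FFFFFFF


def ingest(path, query_cap: int = DEFAULT_QUERY_CAP) -> tuple[OccurrenceStore, IngestReport]:
    """Build a store from a Darwin-Core-style occurrence CSV.

    Required columns: scientificName, decimalLatitude, decimalLongitude;
    optional: TSN, flags (any truthy / nonzero value marks the record bad).
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read occurrence CSV {path}: {exc}") from exc
    required = {"scientificName", "decimalLatitude", "decimalLongitude"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing occurrence columns {sorted(missing)}")

    report = IngestReport(total=len(df))
    records: list[OccurrenceRecord] = []
    has_tsn = "TSN" in df.columns
    has_flags = "flags" in df.columns
    for row in df.itertuples(index=False):
        raw = {
            "species": getattr(row, "scientificName"),
            "lat": getattr(row, "decimalLatitude"),
            "lon": getattr(row, "decimalLongitude"),
            "tsn": getattr(row, "TSN") if has_tsn else None,
            "flagged": bool(getattr(row, "flags")) if has_flags and not pd.isna(getattr(row, "flags")) else False,
        }
        rec = qc_filter(raw)
        if rec is None:
            report.rejected += 1
        else:
            report.accepted += 1
            records.append(rec)
    log.info("%s: ingested %d/%d occurrence records", path, report.accepted, report.total)
    return OccurrenceStore(records, query_cap=query_cap), report
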