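import numpy as np
import pytest

from dustgeo.geogrid import GridSpec
from dustgeo.occurrences import OccurrenceRecord, OccurrenceStore
from dustgeo.otu_tables import Marker, OtuRecord, SampleTable


@pytest.fixture
def small_grid() -> GridSpec:
    """A 5x4 grid of 250-km cells for fast surface tests."""
    return GridSpec(cell_km=250.0, width_km=1250.0, height_km=1000.0)


@pytest.fixture
def toy_table() -> SampleTable:
    """Five-OTU table with a 10,000-read total whose survivor set is known.

    Hand-enumerated against the stringency rules (>=3 reads, 3-of-3
    replicates, relative abundance > 1e-4): A, C, D, E survive; B fails the
    replicate-presence rule.
    """
    recs = [
        OtuRecord("A", Marker.ITS2, (1, 1, 1), "ACGT"),
        OtuRecord("B", Marker.ITS2, (1, 1, 0), "ACGA"),
        OtuRecord("C", Marker.ITS2, (3000, 3000, 3000), "ACGC"),
        OtuRecord("D", Marker.RBCL3A, (300, 300, 300), "ACGG"),
        OtuRecord("E", Marker.RBCL3A, (30, 32, 33), "ACTT"),
    ]
    table = SampleTable("toy", recs)
    assert table.total_reads == 10_000
    return table


def make_store(records_by_species: dict[str, list[tuple[float, float]]],
               tsn: dict[str, int] | None = None,
               query_cap: int = 100_000) -> OccurrenceStore:
    """Build an in-memory store from {species: [(lon, lat), ...]}."""
    tsn = tsn or {}
    recs = [
        OccurrenceRecord(name, lat=lat, lon=lon, tsn=tsn.get(name))
        for name, coords in records_by_species.items()
        for lon, lat in coords
    ]
    return OccurrenceStore(recs, query_cap=query_cap)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_927)
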