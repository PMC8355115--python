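"""Synthetic species ranges, occurrence stores, references, and OTU tables.

The generator emulates everything the pipeline consumes so every stage is
testable without live sequence or biodiversity databases:

* a **species pool** of localized species — isotropic Gaussian ranges whose
  centres cluster around the configured collection sites — plus a fraction of
  cosmopolitan species whose records are uniform over the analysis extent;
* an **occurrence store** sampled from those ranges, with a configurable
  fraction of QC-flagged records;
* a **barcode reference** with one unique random minibarcode sequence per
  species and marker;
* per-sample **OTU tables** whose species composition is drawn in proportion
  to each species' range density at the truth site (local flora dominates
  settled airborne eDNA), with seasonal scaling of OTU counts, negative-
  binomial read counts per replicate, and injected low-quality and
  control-contaminant OTUs so the stringency filters have work to do.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geogrid import GridSpec, project, unproject
from .attribution import haversine
from .otu_tables import Marker, OtuRecord, SampleTable
from .taxonomy import ReferenceRecord

#: the four louvered-shelter collection sites (lon, lat)
STUDY_SITES: dict[str, tuple[float, float]] = {
    "MA": (-71.23, 42.44),
    "FL": (-85.66, 30.17),
    "NM": (-106.89, 34.06),
    "SC": (-81.63, 33.78),
}

_SEQ_LEN = {Marker.ITS2: 350, Marker.RBCL3A: 250}


@dataclass(frozen=True)
class SyntheticSpecies:
    """One simulated plant species and its range model."""

    name: str
    range_center: tuple[float, float]  # (lon, lat); ignored when cosmopolitan
    range_sigma_km: float
    n_records: int
    cosmopolitan: bool
    tsn: int | None
    sequences: dict[Marker, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated scenario.

    Defaults describe a spring-like sample: ~30 OTUs drawn by range density
    at the truth site from a pool of 120 species (20% cosmopolitan, the rest
    localized around the four study sites), 300 median occurrence records per
    species (log-normal), negative-binomial reads averaging 200 per
    replicate.  ``season_factor`` scales the OTU count (winter ~0.2);
    ``sample_frac_cosmopolitan`` forces a cosmopolitan share of the drawn
    OTUs instead of pure density weighting (the winter preset uses 0.5).
    """

    seed: int
    n_species: int = 120
    frac_cosmopolitan: float = 0.2
    records_lognorm_mu: float = math.log(300.0)
    records_lognorm_sigma: float = 0.7
    cosmopolitan_records_factor: float = 10.0
    range_sigma_km: float = 150.0
    site_spread_km: float = 120.0
    sites: tuple[tuple[float, float], ...] = tuple(STUDY_SITES.values())
    truth_site: tuple[float, float] = STUDY_SITES["MA"]
    n_otus_per_sample: int = 30
    read_mean: float = 200.0
    read_dispersion: float = 2.0
    season_factor: float = 1.0
    sample_frac_cosmopolitan: float | None = None
    transport_frac: float = 0.0
    n_low_quality_otus: int = 3
    contamination_rate: float = 0.1
    flag_rate: float = 0.05
    grid: GridSpec = GridSpec()

    def __post_init__(self) -> None:
        if self.n_species <= 0 or self.n_otus_per_sample <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.frac_cosmopolitan <= 1:
            raise ValueError("frac_cosmopolitan must be in [0, 1]")


def spring_scenario(seed: int, truth_site: tuple[float, float] = STUDY_SITES["MA"]) -> ScenarioConfig:
    """High-diversity conditions: many localized OTUs, full season factor."""
    return ScenarioConfig(seed=seed, truth_site=truth_site)


def winter_scenario(seed: int, truth_site: tuple[float, float] = STUDY_SITES["MA"]) -> ScenarioConfig:
    """Low-diversity conditions: few OTUs, half of them cosmopolitan.

    Winter-dormant local flora sheds little eDNA, so the localized OTUs that
    do appear are drawn with a large transported-material fraction: their
    source species need not grow near the collection site.
    """
    return ScenarioConfig(
        seed=seed,
        truth_site=truth_site,
        season_factor=0.2,
        sample_frac_cosmopolitan=0.5,
        transport_frac=0.7,
    )


def _base26(i: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = letters[i % 26]
    i //= 26
    while i:
        out = letters[i % 26] + out
        i //= 26
    return out


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def gen_species_pool(cfg: ScenarioConfig) -> list[SyntheticSpecies]:
    """Deterministically generate the scenario's species pool.

    The first ``round(n_species * frac_cosmopolitan)`` species are
    cosmopolitan; localized species centres cycle through the configured
    sites with Gaussian jitter of ``site_spread_km``.  Barcode sequences are
    unique across species within a marker (rejection sampling).
    """
    rng = np.random.default_rng(cfg.seed)
    n_cosmo = int(round(cfg.n_species * cfg.frac_cosmopolitan))
    pool: list[SyntheticSpecies] = []
    seen_seqs: dict[Marker, set[str]] = {m: set() for m in Marker}
    for i in range(cfg.n_species):
        cosmopolitan = i < n_cosmo
        if cosmopolitan:
            center = (0.0, 0.0)
            sigma = 0.0
        else:
            site = cfg.sites[(i - n_cosmo) % len(cfg.sites)]
            dx, dy = rng.normal(0.0, cfg.site_spread_km, size=2)
            lat = site[1] + dy / 111.19
            lon = site[0] + dx / (111.19 * math.cos(math.radians(site[1])))
            center = (lon, lat)
            sigma = cfg.range_sigma_km * rng.uniform(0.6, 1.5)
        n_records = int(round(float(rng.lognormal(cfg.records_lognorm_mu, cfg.records_lognorm_sigma))))
        n_records = max(1, n_records)
        if cosmopolitan:
            n_records = int(round(n_records * cfg.cosmopolitan_records_factor))
        sequences: dict[Marker, str] = {}
        for marker in Marker:
            seq = _random_dna(rng, _SEQ_LEN[marker])
            while seq in seen_seqs[marker]:
                seq = _random_dna(rng, _SEQ_LEN[marker])
            seen_seqs[marker].add(seq)
            sequences[marker] = seq
        tag = _base26(i)
        # ~98% of records carry a TSN in the emulated provider
        tsn = 1000 + i if rng.random() < 0.98 else None
        pool.append(
            SyntheticSpecies(
                name=f"Genus{tag} species{tag}",
                range_center=center,
                range_sigma_km=sigma,
                n_records=n_records,
                cosmopolitan=cosmopolitan,
                tsn=tsn,
                sequences=sequences,
            )
        )
    return pool


def _sample_species_coords(
    sp: SyntheticSpecies, n: int, cfg: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n, 2) lon/lat occurrence coordinates from a species' range model."""
    spec = cfg.grid
    if sp.cosmopolitan:
        x = rng.uniform(spec.x0, spec.x0 + spec.width_km, size=n)
        y = rng.uniform(spec.y0, spec.y0 + spec.height_km, size=n)
    else:
        cx, cy = project(sp.range_center[0], sp.range_center[1], spec)
        x = rng.normal(cx, max(sp.range_sigma_km, 1e-9), size=n)
        y = rng.normal(cy, max(sp.range_sigma_km, 1e-9), size=n)
    lon, lat = unproject(x, y, spec)
    return np.column_stack([np.atleast_1d(lon), np.atleast_1d(lat)])


def gen_occurrence_dataframe(pool: list[SyntheticSpecies], cfg: ScenarioConfig) -> pd.DataFrame:
    """Darwin-Core-style occurrence table for the whole pool.

    A ``flag_rate`` fraction of records is marked with a provider QC flag so
    ingest-time filtering is exercised.
    """
    rng = np.random.default_rng((cfg.seed + 0x0CC) & 0x7FFFFFFF)
    frames = []
    for sp in pool:
        coords = _sample_species_coords(sp, sp.n_records, cfg, rng)
        flags = (rng.random(sp.n_records) < cfg.flag_rate).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "scientificName": sp.name,
                    "TSN": sp.tsn if sp.tsn is not None else pd.NA,
                    "decimalLatitude": np.round(coords[:, 1], 6),
                    "decimalLongitude": np.round(coords[:, 0], 6),
                    "flags": flags,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["scientificName", "TSN", "decimalLatitude", "decimalLongitude", "flags"]
        )
    return pd.concat(frames, ignore_index=True)


def gen_occurrence_store(pool: list[SyntheticSpecies], cfg: ScenarioConfig, path):
    """Write the occurrence CSV and ingest it back through the standard path."""
    from .occurrences import ingest

    gen_occurrence_dataframe(pool, cfg).to_csv(path, index=False)
    return ingest(path)


def gen_reference(pool: list[SyntheticSpecies]) -> list[ReferenceRecord]:
    """Barcode reference covering every pool species at both markers."""
    out = []
    for i, sp in enumerate(pool):
        for marker in Marker:
            out.append(
                ReferenceRecord(
                    accession=f"SYN{i:04d}{marker.name[0]}",
                    species_name=sp.name,
                    marker=marker,
                    sequence=sp.sequences[marker],
                )
            )
    return out


def write_reference_fasta(reference: list[ReferenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reference:
            fh.write(f">{r.accession}|{r.marker.value}|{r.species_name}\n{r.sequence}\n")


def _truth_density_weights(pool: list[SyntheticSpecies], cfg: ScenarioConfig) -> np.ndarray:
    """Unnormalized probability that each species sheds eDNA at the truth site."""
    spec = cfg.grid
    extent_area = spec.width_km * spec.height_km
    w = np.empty(len(pool))
    for i, sp in enumerate(pool):
        if sp.cosmopolitan:
            w[i] = 1.0 / extent_area
        else:
            d = haversine(sp.range_center, cfg.truth_site)
            s2 = max(sp.range_sigma_km, 1.0) ** 2
            w[i] = math.exp(-(d * d) / (2.0 * s2)) / (2.0 * math.pi * s2)
    return w


def _nb_reads(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> tuple[int, ...]:
    """Negative-binomial replicate read counts (gamma-Poisson mixture)."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return tuple(int(v) for v in rng.poisson(lam))


def gen_sample(
    pool: list[SyntheticSpecies],
    cfg: ScenarioConfig,
    sample_id: str,
    seed: int,
    n_replicates: int = 3,
) -> tuple[dict[Marker, SampleTable], dict[Marker, SampleTable]]:
    """One unfiltered per-marker sample plus matching control tables.

    Species are drawn without replacement, weighted by range density at the
    truth site (or with a forced cosmopolitan share when
    ``sample_frac_cosmopolitan`` is set).  Each drawn species becomes one OTU
    on one marker (alternating).  Below-threshold OTUs and control
    contaminants are injected; the returned control tables share those
    contaminant sequences so :func:`~dustgeo.otu_tables.subtract_controls`
    removes them.
    """
    rng = np.random.default_rng(seed)
    n_target = max(1, int(round(cfg.n_otus_per_sample * cfg.season_factor)))
    weights = _truth_density_weights(pool, cfg)
    if cfg.transport_frac > 0:
        # long-range transported material: flatten toward a uniform draw
        w = weights / weights.sum()
        weights = (1.0 - cfg.transport_frac) * w + cfg.transport_frac / len(pool)

    cosmo_idx = [i for i, sp in enumerate(pool) if sp.cosmopolitan]
    local_idx = [i for i, sp in enumerate(pool) if not sp.cosmopolitan]
    if cfg.sample_frac_cosmopolitan is not None and cosmo_idx:
        n_cosmo = min(len(cosmo_idx), int(round(n_target * cfg.sample_frac_cosmopolitan)))
        n_local = min(len(local_idx), n_target - n_cosmo)
        chosen = list(rng.choice(cosmo_idx, size=n_cosmo, replace=False))
        wl = weights[local_idx]
        chosen += [
            local_idx[j]
            for j in rng.choice(len(local_idx), size=n_local, replace=False, p=wl / wl.sum())
        ]
    else:
        n_draw = min(n_target, len(pool))
        chosen = list(rng.choice(len(pool), size=n_draw, replace=False, p=weights / weights.sum()))

    records: dict[Marker, list[OtuRecord]] = {m: [] for m in Marker}
    markers = list(Marker)
    for k, i in enumerate(sorted(chosen)):
        marker = markers[k % len(markers)]
        reads = _nb_reads(rng, cfg.read_mean, cfg.read_dispersion, n_replicates)
        if sum(reads) < 3 or min(reads) == 0:  # real OTUs must survive the filter
            reads = tuple(max(1, r) for r in reads)
        records[marker].append(
            OtuRecord(f"otu{k:04d}", marker, reads, pool[i].sequences[marker])
        )

    # low-quality injections: fail the read-count / replicate-presence rules
    junk_patterns = [(1, 0, 0), (1, 1, 0), (2, 0, 0)]
    for j in range(cfg.n_low_quality_otus):
        marker = markers[j % len(markers)]
        reads = tuple(junk_patterns[j % len(junk_patterns)][:n_replicates])
        records[marker].append(
            OtuRecord(f"junk{j:03d}", marker, reads, _random_dna(rng, _SEQ_LEN[marker]))
        )

    # contaminants: present at healthy read counts but shared with controls
    control_records: dict[Marker, list[OtuRecord]] = {m: [] for m in Marker}
    n_contam = int(round(cfg.contamination_rate * n_target))
    for j in range(n_contam):
        marker = markers[j % len(markers)]
        seq = _random_dna(rng, _SEQ_LEN[marker])
        reads = _nb_reads(rng, cfg.read_mean, cfg.read_dispersion, n_replicates)
        reads = tuple(max(1, r) for r in reads)
        records[marker].append(OtuRecord(f"cont{j:03d}", marker, reads, seq))
        control_records[marker].append(
            OtuRecord(f"ctrl{j:03d}", marker, tuple([2] * n_replicates), seq)
        )

    tables = {
        m: SampleTable(sample_id=sample_id, records=recs) for m, recs in records.items()
    }
    controls = {
        m: SampleTable(sample_id=f"{sample_id}-control", records=recs)
        for m, recs in control_records.items()
    }
    return tables, controls
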