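"""End-to-end orchestration: tables -> taxonomy -> grid -> attribution.

One call, :func:`attribute_sample`, runs the whole chain for a sample whose
per-marker OTU tables are already parsed: stringency filtering, control
subtraction, marker combination, species assignment and de-duplication,
per-OTU gridded distributions, the overlay surface, and the mixture-model
metrics.  :func:`simulate_cohort` drives the same chain over synthetic
scenarios, writing and re-reading every standard file format on the way so
the real I/O path is exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .attribution import (
    AttributionResult,
    Thresholds,
    attribute_surface,
    unattributable,
)
from .errors import NoMappedOtusError
from .geogrid import GridSpec, GridSurface, otu_distribution, overlay
from .occurrences import OccurrenceStore
from .otu_tables import (
    FilterConfig,
    SampleTable,
    combine_markers,
    filter_otus,
    subtract_controls,
)
from .taxonomy import ReferenceRecord, SpeciesAssignment, assign_species, dedupe_species

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the attribution pipeline in one place.

    Defaults are the published operating point: 3-read / 3-of-3-replicate /
    1e-4 stringency, 100% identity assignment, >= 2 occurrences per cell,
    250-km grid, 90% TP and 600 km AT5PE cutoffs, 20-OTU reporting stratum.
    """

    filter: FilterConfig = FilterConfig()
    grid: GridSpec = GridSpec()
    thresholds: Thresholds = Thresholds()
    gmm_k_max: int = 10
    gmm_n_rep: int = 100
    peak_mode: str = "density"
    min_cell_occurrences: int = 2
    seed: int = 0


def prepare_tables(
    tables: list[SampleTable],
    controls: list[SampleTable],
    cfg: FilterConfig = FilterConfig(),
) -> SampleTable:
    """Filter each marker table, subtract controls, combine markers."""
    filtered = [subtract_controls(filter_otus(t, cfg), controls) for t in tables]
    return combine_markers(filtered)


def assign_sample(
    table: SampleTable,
    reference: list[ReferenceRecord],
    synonyms: dict[str, str] | None = None,
) -> list[SpeciesAssignment]:
    """Species assignment for every OTU, then per-sample species dedupe."""
    assignments = [
        a
        for r in table.records
        if (a := assign_species(r, reference, synonyms)).assigned
    ]
    return dedupe_species(assignments, table)


def map_sample(
    assignments: list[SpeciesAssignment],
    store: OccurrenceStore,
    spec: GridSpec,
    seed: int = 0,
    min_cell_occurrences: int = 2,
) -> GridSurface:
    """Gridded distribution per OTU, overlaid into the sample surface."""
    distributions = [
        otu_distribution(
            a.otu_id, a.species, store, spec, seed=seed, min_cell_occurrences=min_cell_occurrences
        )
        for a in assignments
    ]
    return overlay(distributions, spec)


def attribute_sample(
    tables: list[SampleTable],
    controls: list[SampleTable],
    reference: list[ReferenceRecord],
    store: OccurrenceStore,
    truth: tuple[float, float],
    cfg: PipelineConfig = PipelineConfig(),
    sample_id: str | None = None,
    site: str = "",
    synonyms: dict[str, str] | None = None,
) -> tuple[AttributionResult, GridSurface | None]:
    """Full attribution of one sample; never raises on an empty sample.

    Samples that lose every OTU to filtering, assignment or mapping come back
    as an explicit negative result with a reason, so cohort summaries keep
    them in denominators.
    """
    sid = sample_id if sample_id is not None else tables[0].sample_id
    combined = prepare_tables(tables, controls, cfg.filter)
    if not combined.records:
        return unattributable(sid, site, reason="no OTUs after filtering"), None
    assignments = assign_sample(combined, reference, synonyms)
    if not assignments:
        return unattributable(sid, site, reason="no species-level assignments"), None
    try:
        surface = map_sample(
            assignments, store, cfg.grid, seed=cfg.seed, min_cell_occurrences=cfg.min_cell_occurrences
        )
    except NoMappedOtusError:
        return unattributable(sid, site, reason="no mapped OTUs"), None
    result = attribute_surface(
        surface,
        truth,
        sample_id=sid,
        site=site,
        thresholds=cfg.thresholds,
        seed=cfg.seed,
        k_max=cfg.gmm_k_max,
        n_rep=cfg.gmm_n_rep,
        peak_mode=cfg.peak_mode,
    )
    return result, surface


def simulate_cohort(
    scenario,
    n_samples: int,
    workdir,
    site: str = "",
    pipeline_cfg: PipelineConfig | None = None,
) -> list[AttributionResult]:
    """Generate a scenario and attribute ``n_samples`` simulated samples.

    All intermediate artifacts (occurrence CSV, reference FASTA, per-sample
    OTU TSV + FASTA) are written under ``workdir`` and read back through the
    standard parsers, so simulated runs exercise the same I/O path as real
    data.  Deterministic in the scenario seed.
    """
    from . import synthetic
    from .otu_tables import read_otu_table, write_otu_table
    from .taxonomy import read_reference_fasta
    from .synthetic import gen_occurrence_store, gen_reference, gen_species_pool, write_reference_fasta

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if pipeline_cfg is None:
        pipeline_cfg = PipelineConfig(grid=scenario.grid, seed=scenario.seed)

    pool = gen_species_pool(scenario)
    store, _ = gen_occurrence_store(pool, scenario, workdir / "occurrences.csv")
    write_reference_fasta(gen_reference(pool), workdir / "reference.fasta")
    reference = read_reference_fasta(workdir / "reference.fasta")

    results = []
    for i in range(n_samples):
        sid = f"{site or 'sim'}-{i:03d}"
        tables_by_marker, controls_by_marker = synthetic.gen_sample(
            pool, scenario, sid, seed=(scenario.seed * 1000 + i) & 0x7FFFFFFF
        )
        tables = []
        for marker, t in tables_by_marker.items():
            tsv = workdir / f"{sid}.{marker.name}.tsv"
            fasta = workdir / f"{sid}.{marker.name}.fasta"
            write_otu_table(t, tsv, fasta)
            tables.append(read_otu_table(tsv, fasta, sample_id=sid))
        controls = list(controls_by_marker.values())
        result, _ = attribute_sample(
            tables, controls, reference, store, scenario.truth_site,
            cfg=pipeline_cfg, sample_id=sid, site=site,
        )
        results.append(result)
    return results


def seasonal_recovery_study(
    seed: int,
    workdir,
    n_spring: int = 20,
    n_winter: int = 12,
) -> dict[str, list[AttributionResult]]:
    """Attribute simulated spring-like and winter-like cohorts.

    Spring-like samples carry ~30 OTUs dominated by species localized near
    the truth site; winter-like samples carry ~6 OTUs, half cosmopolitan,
    with a large transported-material fraction.  Returns the per-season
    result lists; deterministic in ``seed``.
    """
    from .synthetic import spring_scenario, winter_scenario

    workdir = Path(workdir)
    spring = simulate_cohort(
        spring_scenario(seed=seed & 0x3FFFFFFF), n_spring, workdir / "spring", site="spring"
    )
    winter = simulate_cohort(
        winter_scenario(seed=(seed + 1) & 0x3FFFFFFF), n_winter, workdir / "winter", site="winter"
    )
    return {"spring": spring, "winter": winter}
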