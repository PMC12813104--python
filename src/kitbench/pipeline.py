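"""End-to-end benchmark analysis: filter, measure, rank.

The pipeline mirrors the study's downstream workflow on processed tables:

1. quantify per-sample chloroplast fractions on the raw table;
2. call kit-reagent contaminants from the kitome controls and quantify
   per-sample contamination levels (still on the raw table);
3. remove contaminant and chloroplast OTUs to obtain the filtered table;
4. compute community metrics on the filtered table (Shannon per sample,
   per-species Bray–Curtis + PCoA + PERMANOVA across kits, reproducibility
   per kit x species, OTU sharing across kits per species);
5. derive the nine ranking criteria and aggregate them into per-species
   Total and Quality rank tables.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decontam, metrics, ranking
from .tables import (
    KitProfile,
    OtuTable,
    SampleRecord,
    TaxonomyTable,
    ValidationError,
    validate_dataset,
)

logger = logging.getLogger("kitbench")


@dataclasses.dataclass
class SpeciesMetrics:
    distances: metrics.DistanceMatrix | None
    pcoa_coordinates: pd.DataFrame | None
    permanova: metrics.PermanovaResult | None
    reproducibility: dict[str, float]  # kit -> rate
    sharing: metrics.SharingResult


@dataclasses.dataclass
class BenchmarkResult:
    """Everything the pipeline computed, from contamination to kit ranks."""

    contamination: decontam.ContaminationReport
    filtered_table: OtuTable
    shannon: pd.Series  # per sample (NaN where a sample lost all reads)
    species_metrics: dict[str, SpeciesMetrics]
    criteria: dict[str, list[ranking.CriterionValues]]
    rank_tables: dict[str, ranking.RankTable]

    def metrics_dict(self) -> dict:
        """JSON-serialisable summary of the metric layer."""
        out: dict = {
            "shannon": {
                k: (None if isinstance(v, float) and math.isnan(v) else float(v))
                for k, v in self.shannon.items()
            },
            "species": {},
        }
        for species, sm in self.species_metrics.items():
            out["species"][species] = {
                "permanova": (
                    None
                    if sm.permanova is None
                    else dataclasses.asdict(sm.permanova)
                ),
                "reproducibility": sm.reproducibility,
                "sharing": {
                    "counts": sm.sharing.counts,
                    "universal_fraction": sm.sharing.universal_fraction,
                    "unique_fraction": sm.sharing.unique_fraction,
                    "other_fraction": sm.sharing.other_fraction,
                },
            }
        return out


def _species_and_kits(records: Sequence[SampleRecord]) -> tuple[list[str], list[str]]:
    species = list(dict.fromkeys(r.species for r in records if not r.is_control))
    kits = list(dict.fromkeys(r.kit for r in records))
    return species, kits


def derive_criteria(
    species: str,
    records: Sequence[SampleRecord],
    contamination: pd.Series,
    chloroplast: pd.Series,
    shannon: pd.Series,
    reproducibility: Mapping[str, float],
    kit_profiles: Sequence[KitProfile],
) -> list[ranking.CriterionValues]:
    """Build the nine-criterion panel for one species."""
    profile_by_kit = {p.kit: p for p in kit_profiles}
    rows = [r for r in records if r.species == species and not r.is_control]
    kits = list(dict.fromkeys(r.kit for r in rows))
    missing = [k for k in kits if k not in profile_by_kit]
    if missing:
        raise ValidationError(f"kits without profiles: {missing!r}")

    def per_kit(getter) -> dict[str, list]:
        values: dict[str, list] = {kit: [] for kit in kits}
        for record in rows:
            values[record.kit].append(getter(record))
        return values

    yields = {
        kit: [
            ranking.yield_per_gram(r.dna_conc, r.input_mass)
            for r in rows
            if r.kit == kit
        ]
        for kit in kits
    }
    din_values: dict[str, list | None] = {}
    for kit, entries in per_kit(lambda r: r.din).items():
        measured = [v for v in entries if v is not None]
        din_values[kit] = measured if measured else None
    dilution = {kit: next(r.dilution_factor for r in rows if r.kit == kit) for kit in kits}
    contamination_values = {
        kit: [float(contamination[r.sample_id]) for r in rows if r.kit == kit]
        for kit in kits
    }
    chloroplast_values = {
        kit: [float(chloroplast[r.sample_id]) for r in rows if r.kit == kit]
        for kit in kits
    }
    shannon_values = {
        kit: [
            float(shannon[r.sample_id])
            for r in rows
            if r.kit == kit and not math.isnan(float(shannon[r.sample_id]))
        ]
        or None
        for kit in kits
    }
    return [
        ranking.CriterionValues("dna_yield", yields, higher_is_better=True),
        ranking.CriterionValues("din", din_values, higher_is_better=True),
        ranking.CriterionValues("dilution", dilution, higher_is_better=False),
        ranking.CriterionValues(
            "kit_contamination", contamination_values, higher_is_better=False
        ),
        ranking.CriterionValues("chloroplast", chloroplast_values, higher_is_better=False),
        ranking.CriterionValues("shannon", shannon_values, higher_is_better=True),
        ranking.CriterionValues(
            "reproducibility", {k: float(reproducibility[k]) for k in kits},
            higher_is_better=True,
        ),
        ranking.CriterionValues(
            "simplicity", {k: float(profile_by_kit[k].simplicity) for k in kits},
            higher_is_better=False,
        ),
        ranking.CriterionValues(
            "cost", {k: float(profile_by_kit[k].cost_per_sample) for k in kits},
            higher_is_better=False,
        ),
    ]


def run_benchmark(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    records: Sequence[SampleRecord],
    kit_profiles: Sequence[KitProfile],
    n_permutations: int = 999,
    seed: int = 0,
    contaminant_threshold: float = decontam.DEFAULT_THRESHOLD,
    pooled_controls: bool = False,
) -> BenchmarkResult:
    """Run the full downstream analysis on one dataset."""
    validate_dataset(table, taxonomy, records)
    by_id = {r.sample_id: r for r in records}
    species_list, _ = _species_and_kits(
        [by_id[s] for s in table.sample_ids]
    )

    # contamination layer (raw table)
    _, chloroplast_fraction = decontam.remove_chloroplast(table, taxonomy)
    calls = decontam.call_contaminants(
        table,
        records,
        threshold=contaminant_threshold,
        n_permutations=n_permutations,
        seed=seed,
        pooled=pooled_controls,
    )
    contamination = decontam.contamination_level(table, calls.contaminant_otu_ids)
    report = decontam.ContaminationReport(
        calls=calls,
        per_sample_contamination=contamination,
        per_sample_chloroplast=chloroplast_fraction,
        mc_ratios=decontam.mc_ratio_table(table, records),
    )

    # filtered table: drop called contaminants, then chloroplast OTUs
    filtered = table.drop_otus(calls.contaminant_otu_ids)
    filtered, _ = decontam.remove_chloroplast(filtered, taxonomy)

    shannon = pd.Series(np.nan, index=filtered.frame.index, name="shannon")
    for sample_id in filtered.sample_ids:
        counts = filtered.frame.loc[sample_id]
        if counts.sum() > 0:
            shannon[sample_id] = metrics.shannon(counts.to_numpy())
        elif not by_id[sample_id].is_control:
            # kitome controls losing all reads after filtering is by design
            logger.warning("sample %s has no reads after filtering", sample_id)

    species_metrics: dict[str, SpeciesMetrics] = {}
    criteria: dict[str, list[ranking.CriterionValues]] = {}
    rank_tables: dict[str, ranking.RankTable] = {}
    for species in species_list:
        sample_ids = [
            s
            for s in filtered.sample_ids
            if by_id[s].species == species and filtered.frame.loc[s].sum() > 0
        ]
        kit_labels = [by_id[s].kit for s in sample_ids]
        distances = pcoa_coords = permanova_result = None
        if len(sample_ids) >= 2:
            distances = metrics.bray_curtis(filtered.select_samples(sample_ids))
            if len(sample_ids) >= 3:
                pcoa_coords, _ = metrics.pcoa(
                    distances, k=min(2, len(sample_ids) - 1)
                )
            label_counts = pd.Series(kit_labels).value_counts()
            if len(label_counts) >= 2 and label_counts.min() >= 2:
                permanova_result = metrics.permanova(
                    distances, kit_labels, n_permutations=n_permutations, seed=seed
                )
        reproducibility: dict[str, float] = {}
        species_records = [
            r for r in records if r.species == species and not r.is_control
        ]
        for kit in dict.fromkeys(r.kit for r in species_records):
            replicate_ids = [r.sample_id for r in species_records if r.kit == kit]
            if len(replicate_ids) >= 2:
                reproducibility[kit] = metrics.reproducibility_rate(
                    filtered, replicate_ids
                )
            else:
                reproducibility[kit] = 1.0
        sharing = metrics.otu_sharing(filtered, records, species)
        species_metrics[species] = SpeciesMetrics(
            distances=distances,
            pcoa_coordinates=pcoa_coords,
            permanova=permanova_result,
            reproducibility=reproducibility,
            sharing=sharing,
        )
        panel = derive_criteria(
            species,
            records,
            contamination,
            chloroplast_fraction,
            shannon,
            reproducibility,
            kit_profiles,
        )
        criteria[species] = panel
        rank_tables[species] = ranking.aggregate_ranks(panel, species=species)

    return BenchmarkResult(
        contamination=report,
        filtered_table=filtered,
        shannon=shannon,
        species_metrics=species_metrics,
        criteria=criteria,
        rank_tables=rank_tables,
    )
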