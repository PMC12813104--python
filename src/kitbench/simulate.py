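"""Synthetic OTU-table benchmark with planted kit effects.

The generator emulates the processed-table level of a DNA-extraction-kit
comparison for algae-associated microbiomes:

* one log-normal base community per algal species, with a species-specific
  fraction of reads assigned to chloroplast OTUs (host-plastid 16S
  amplification);
* per-kit systematic capture bias (log-normal per-OTU multipliers shared by
  all replicates of a kit) plus per-replicate random OTU dropout;
* kit-reagent ("kitome") contaminant OTUs mixed in at a mass fraction
  ``load / (load + template)``, so the contaminant share of reads rises as
  template DNA mass falls;
* one no-input kitome control per kit, drawn from the contaminant profile
  only;
* multinomial read sampling at a fixed depth;
* a QC table (concentration = template mass / 60 uL elution with
  multiplicative log-normal noise, input mass, DIN, absorbance ratios, PCR
  dilution factor) consistent with the kit parameters.

Every planted effect is recorded in a :class:`TruthBundle` so downstream
filtering and ranking can be validated against ground truth. A single seed
drives the whole dataset; the RNG is split hierarchically by
(species, kit, replicate), so adding a kit or species does not perturb the
draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .tables import (
    CHLOROPLAST_ORDER,
    CONTROL_SPECIES,
    KitProfile,
    OtuTable,
    SampleRecord,
    TaxonomyTable,
    write_kit_profiles,
    write_metadata,
    write_otu_table,
    write_qc,
    write_taxonomy,
)

ELUTION_VOLUME_UL = 60.0
QC_CONC_NOISE_SD = 0.1  # log-scale sd of the concentration measurement

# Marine-flavoured orders used for community lineages.
_COMMUNITY_ORDERS = (
    "Flavobacteriales",
    "Rhodobacterales",
    "Alteromonadales",
    "Caulobacterales",
    "Verrucomicrobiales",
    "Granulosicoccales",
    "Thiotrichales",
    "Cellvibrionales",
)
_COMMUNITY_LINEAGE = {
    "Flavobacteriales": ("Bacteria", "Bacteroidota", "Bacteroidia"),
    "Rhodobacterales": ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
    "Alteromonadales": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    "Caulobacterales": ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
    "Verrucomicrobiales": ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae"),
    "Granulosicoccales": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    "Thiotrichales": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    "Cellvibrionales": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
}

# Reagent contaminants carry distinct, recognisable genus labels so that
# taxonomy-based checks against the truth remain possible.
_CONTAMINANT_GENERA = (
    ("Staphylococcus-like", "Bacillota", "Bacilli", "Staphylococcales"),
    ("Streptococcus-like", "Bacillota", "Bacilli", "Lactobacillales"),
    ("Cutibacterium-like", "Actinobacteriota", "Actinobacteria", "Propionibacteriales"),
    ("Corynebacterium-like", "Actinobacteriota", "Actinobacteria", "Mycobacteriales"),
    ("Micrococcus-like", "Actinobacteriota", "Actinobacteria", "Micrococcales"),
    ("Escherichia-like", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales"),
    ("Pseudomonas-like", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales"),
    ("Ralstonia-like", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales"),
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    """Base-community parameters for one algal species."""

    name: str
    n_otus: int = 60
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.0
    chloroplast_fraction: float = 0.1
    n_chloroplast_otus: int = 3

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError(f"species {self.name!r}: n_otus must be >= 1")
        if not 0 <= self.chloroplast_fraction < 1:
            raise ValueError(
                f"species {self.name!r}: chloroplast_fraction must be in [0, 1)"
            )
        if self.n_chloroplast_otus < 0 or self.n_chloroplast_otus > self.n_otus:
            raise ValueError(
                f"species {self.name!r}: n_chloroplast_otus must be in 0..n_otus"
            )
        if self.chloroplast_fraction > 0 and self.n_chloroplast_otus == 0:
            raise ValueError(
                f"species {self.name!r}: chloroplast_fraction > 0 needs chloroplast OTUs"
            )


@dataclasses.dataclass(frozen=True)
class KitSpec:
    """Planted behaviour of one DNA-extraction kit.

    ``capture_bias_sd`` is the log-scale spread of the per-OTU capture
    multipliers (systematic, shared by replicates); ``dropout_rate`` is the
    per-replicate probability that an OTU is missed entirely.
    ``contaminant_load_ng`` and ``mean_template_ng`` set the kitome mixing
    fraction load/(load+template); ``kitome_read_factor`` scales the read
    depth of the kit's no-input control relative to real samples.
    """

    name: str
    capture_bias_sd: float = 0.5
    dropout_rate: float = 0.05
    contaminant_load_ng: float = 0.5
    mean_template_ng: float = 20.0
    dilution_factor: int | str = 1
    simplicity: int = 1
    cost_per_sample: float = 10.0
    kitome_read_factor: float = 0.5
    din_mean: float | None = 3.0
    a260_280_mean: float = 1.85
    a260_230_mean: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"kit {self.name!r}: dropout_rate must be in [0, 1)")
        if self.capture_bias_sd < 0:
            raise ValueError(f"kit {self.name!r}: capture_bias_sd must be >= 0")
        if self.contaminant_load_ng < 0:
            raise ValueError(f"kit {self.name!r}: contaminant_load_ng must be >= 0")
        if self.mean_template_ng < 0:
            raise ValueError(f"kit {self.name!r}: mean_template_ng must be >= 0")
        if self.simplicity not in {1, 2, 3, 4, 5}:
            raise ValueError(f"kit {self.name!r}: simplicity must be in 1..5")
        if self.kitome_read_factor < 0:
            raise ValueError(f"kit {self.name!r}: kitome_read_factor must be >= 0")

    @property
    def profile(self) -> KitProfile:
        return KitProfile(
            kit=self.name,
            simplicity=self.simplicity,
            cost_per_sample=self.cost_per_sample,
        )


@dataclasses.dataclass
class TruthBundle:
    """Ground truth for every planted effect in a benchmark dataset."""

    contaminant_otu_ids: frozenset[str]
    chloroplast_otu_ids: frozenset[str]
    base_proportions: dict[str, pd.Series]
    per_kit_bias: dict[str, dict[str, pd.Series]]
    mixing_fraction: dict[str, float]

    def __post_init__(self) -> None:
        if self.contaminant_otu_ids & self.chloroplast_otu_ids:
            raise ValueError("contaminant and chloroplast OTU sets must be disjoint")

    def to_json(self, path) -> None:
        payload = {
            "contaminant_otu_ids": sorted(self.contaminant_otu_ids),
            "chloroplast_otu_ids": sorted(self.chloroplast_otu_ids),
            "base_proportions": {
                sp: series.to_dict() for sp, series in self.base_proportions.items()
            },
            "per_kit_bias": {
                sp: {kit: series.to_dict() for kit, series in kits.items()}
                for sp, kits in self.per_kit_bias.items()
            },
            "mixing_fraction": self.mixing_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            contaminant_otu_ids=frozenset(payload["contaminant_otu_ids"]),
            chloroplast_otu_ids=frozenset(payload["chloroplast_otu_ids"]),
            base_proportions={
                sp: pd.Series(d) for sp, d in payload["base_proportions"].items()
            },
            per_kit_bias={
                sp: {kit: pd.Series(d) for kit, d in kits.items()}
                for sp, kits in payload["per_kit_bias"].items()
            },
            mixing_fraction=dict(payload["mixing_fraction"]),
        )


@dataclasses.dataclass
class DatasetBundle:
    """A complete synthetic benchmark: tables, metadata and ground truth."""

    otu_table: OtuTable
    taxonomy: TaxonomyTable
    metadata: list[SampleRecord]
    kit_profiles: list[KitProfile]
    truth: TruthBundle

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_otu_table(self.otu_table, outdir / "otu_table.tsv")
        write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        write_metadata(self.metadata, outdir / "metadata.csv")
        write_qc(self.metadata, outdir / "qc.csv")
        write_kit_profiles(self.kit_profiles, outdir / "kits.csv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

def _child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG keyed by (seed, *keys).

    String keys are hashed with CRC32, so streams depend only on the names
    involved, not on list positions.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode("utf8")))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _lognormal_proportions(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    raw = np.exp(rng.normal(mean, sd, size=n))
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_base_profile(
    spec: SpeciesSpec, seed: int
) -> tuple[pd.Series, TaxonomyTable]:
    """Draw a base community for one species.

    Returns proportions (summing to 1) over the species' OTUs and a matching
    taxonomy table. Exactly ``n_chloroplast_otus`` carry the order label
    ``Chloroplast`` and jointly receive ``chloroplast_fraction`` of the
    community mass; bacterial OTUs split the remainder log-normally.
    """
    if spec.n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    rng = _child_rng(seed, "base", spec.name)
    n_bact = spec.n_otus - spec.n_chloroplast_otus

    bact_ids = [f"{spec.name}_OTU{i:03d}" for i in range(n_bact)]
    chloro_ids = [f"{spec.name}_CHLORO{i:02d}" for i in range(spec.n_chloroplast_otus)]

    parts: list[np.ndarray] = []
    if n_bact:
        parts.append(
            _lognormal_proportions(rng, n_bact, spec.abundance_log_mean, spec.abundance_log_sd)
            * (1.0 - spec.chloroplast_fraction)
        )
    if spec.n_chloroplast_otus:
        parts.append(
            _lognormal_proportions(rng, spec.n_chloroplast_otus, 0.0, spec.abundance_log_sd)
            * spec.chloroplast_fraction
        )
    proportions = pd.Series(np.concatenate(parts), index=bact_ids + chloro_ids)
    proportions /= proportions.sum()

    lineages: dict[str, tuple[str, ...]] = {}
    orders = rng.choice(len(_COMMUNITY_ORDERS), size=n_bact)
    for i, otu in enumerate(bact_ids):
        order = _COMMUNITY_ORDERS[orders[i]]
        domain, phylum, klass = _COMMUNITY_LINEAGE[order]
        lineages[otu] = (domain, phylum, klass, order, f"{order[:-4]}aceae", f"{order[:4]}_g{i}")
    for otu in chloro_ids:
        lineages[otu] = ("Bacteria", "Cyanobacteria", "Cyanobacteriia", CHLOROPLAST_ORDER, "", "")
    return proportions, TaxonomyTable.from_records(lineages)


def apply_kit_bias(
    proportions: pd.Series,
    kit: KitSpec,
    seed: int,
    multipliers: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Apply per-OTU capture multipliers and random dropout, renormalised.

    ``multipliers`` may be supplied to reuse a kit's systematic bias across
    replicates while dropout stays replicate-specific; when omitted, fresh
    log-normal multipliers with spread ``capture_bias_sd`` are drawn.
    """
    total = float(np.asarray(proportions).sum())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1, got {total!r}")
    rng = _child_rng(seed, "bias", kit.name)
    if multipliers is None:
        multipliers = pd.Series(
            np.exp(rng.normal(0.0, kit.capture_bias_sd, size=len(proportions))),
            index=proportions.index,
        )
    biased = proportions * multipliers
    if kit.dropout_rate > 0:
        keep = rng.random(len(biased)) >= kit.dropout_rate
        dropped = biased.where(keep, 0.0)
        if dropped.sum() > 0:  # all-dropped draw would destroy the sample
            biased = dropped
    return biased / biased.sum(), multipliers


def mixing_fraction(kit: KitSpec) -> float:
    """Contaminant mass fraction load/(load+template) planted for a kit."""
    denominator = kit.contaminant_load_ng + kit.mean_template_ng
    if denominator == 0:
        raise ValueError(
            f"kit {kit.name!r}: contaminant load and template mass are both zero"
        )
    return kit.contaminant_load_ng / denominator


def spike_contaminants(
    proportions: pd.Series,
    kit: KitSpec,
    contaminant_profile: pd.Series,
) -> pd.Series:
    """Mix reagent contaminants into a community.

    The contaminant mass fraction is the closed-form
    ``load / (load + template)``, monotone decreasing in template mass.
    """
    if len(contaminant_profile) and not np.isclose(contaminant_profile.sum(), 1.0, atol=1e-8):
        raise ValueError("contaminant profile must sum to 1")
    w = mixing_fraction(kit)
    if len(contaminant_profile) == 0:
        return proportions.copy()
    mixed = pd.concat([(1.0 - w) * proportions, w * contaminant_profile])
    if mixed.index.duplicated().any():
        raise ValueError("community and contaminant OTU IDs overlap")
    return mixed


def sample_counts(proportions: pd.Series | np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial read sampling: counts sum to ``depth``."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=np.int64)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1, got {total!r}")
    if depth == 0:
        return np.zeros(p.size, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x636E7473]))
    return rng.multinomial(depth, p / total)


def generate_contaminant_profile(
    n_otus: int, seed: int, abundance_log_sd: float = 1.0
) -> tuple[pd.Series, TaxonomyTable]:
    """Log-normal kit-reagent contaminant community with distinct labels."""
    rng = _child_rng(seed, "contaminants")
    ids = [f"CONTAM_OTU{i:03d}" for i in range(n_otus)]
    proportions = pd.Series(
        _lognormal_proportions(rng, n_otus, 0.0, abundance_log_sd) if n_otus else [],
        index=ids,
        dtype=float,
    )
    lineages = {}
    for i, otu in enumerate(ids):
        genus, phylum, klass, order = _CONTAMINANT_GENERA[i % len(_CONTAMINANT_GENERA)]
        lineages[otu] = ("Bacteria", phylum, klass, order, f"{order[:-4]}aceae", genus)
    frame = pd.DataFrame.from_dict(lineages, orient="index")
    if len(frame):
        taxonomy = TaxonomyTable.from_records(lineages)
    else:
        taxonomy = TaxonomyTable(
            pd.DataFrame(columns=["domain", "phylum", "class", "order", "family", "genus"])
        )
    return proportions, taxonomy


def generate_benchmark_dataset(
    species: Sequence[SpeciesSpec],
    kits: Sequence[KitSpec],
    n_replicates: int = 3,
    depth: int = 50_000,
    seed: int = 0,
    n_contaminant_otus: int = 30,
) -> DatasetBundle:
    """Generate the full study design: species x kits x replicates + kitomes.

    One no-input kitome control per kit is drawn from the contaminant
    profile only, at ``depth * kitome_read_factor`` reads.
    """
    if not species:
        raise ValueError("species list must not be empty")
    if not kits:
        raise ValueError("kit list must not be empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    contaminant_profile, contaminant_tax = generate_contaminant_profile(
        n_contaminant_otus, seed
    )

    tax_frames = [contaminant_tax.frame]
    base_proportions: dict[str, pd.Series] = {}
    per_kit_bias: dict[str, dict[str, pd.Series]] = {}
    chloroplast_ids: set[str] = set()
    count_rows: dict[str, pd.Series] = {}
    records: list[SampleRecord] = []

    for sp in species:
        base, taxonomy = generate_base_profile(sp, seed)
        base_proportions[sp.name] = base
        tax_frames.append(taxonomy.frame)
        chloroplast_ids |= {
            otu
            for otu, order in taxonomy.rank("order").items()
            if order == CHLOROPLAST_ORDER
        }
        per_kit_bias[sp.name] = {}
        for kit in kits:
            bias_rng = _child_rng(seed, "kitbias", sp.name, kit.name)
            multipliers = pd.Series(
                np.exp(bias_rng.normal(0.0, kit.capture_bias_sd, size=len(base))),
                index=base.index,
            )
            per_kit_bias[sp.name][kit.name] = multipliers
            for rep in range(1, n_replicates + 1):
                rep_rng = _child_rng(seed, "rep", sp.name, kit.name, rep)
                biased, _ = apply_kit_bias(
                    base, kit, seed=int(rep_rng.integers(2**31)), multipliers=multipliers
                )
                mixed = spike_contaminants(biased, kit, contaminant_profile)
                counts = sample_counts(mixed, depth, seed=int(rep_rng.integers(2**31)))
                sample_id = f"{sp.name}_{kit.name}_r{rep}"
                count_rows[sample_id] = pd.Series(counts, index=mixed.index)

                qc_rng = _child_rng(seed, "qc", sp.name, kit.name, rep)
                conc = (
                    kit.mean_template_ng
                    / ELUTION_VOLUME_UL
                    * float(np.exp(qc_rng.normal(0.0, QC_CONC_NOISE_SD)))
                )
                din = None
                if kit.din_mean is not None:
                    din = float(np.clip(kit.din_mean + qc_rng.normal(0.0, 0.2), 1.0, 10.0))
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        species=sp.name,
                        kit=kit.name,
                        replicate=rep,
                        is_control=False,
                        dna_conc=conc,
                        input_mass=float(qc_rng.uniform(1.5, 5.0)),
                        din=din,
                        a260_280=float(kit.a260_280_mean + qc_rng.normal(0.0, 0.05)),
                        a260_230=float(kit.a260_230_mean + qc_rng.normal(0.0, 0.1)),
                        dilution_factor=kit.dilution_factor,
                    )
                )

    for kit in kits:
        kitome_rng = _child_rng(seed, "kitome", kit.name)
        kitome_depth = int(round(depth * kit.kitome_read_factor))
        if len(contaminant_profile):
            counts = sample_counts(
                contaminant_profile, kitome_depth, seed=int(kitome_rng.integers(2**31))
            )
        else:
            counts = np.zeros(0, dtype=np.int64)
        sample_id = f"kitome_{kit.name}"
        count_rows[sample_id] = pd.Series(counts, index=contaminant_profile.index)
        records.append(
            SampleRecord(
                sample_id=sample_id,
                species=CONTROL_SPECIES,
                kit=kit.name,
                replicate=1,
                is_control=True,
                dna_conc=max(kit.contaminant_load_ng / ELUTION_VOLUME_UL, 0.0),
                input_mass=None,
                din=None,
                a260_280=None,
                a260_230=None,
                dilution_factor=kit.dilution_factor,
            )
        )

    taxonomy = TaxonomyTable(pd.concat(tax_frames))
    all_otus = list(taxonomy.frame.index)
    matrix = pd.DataFrame(
        0, index=list(count_rows), columns=all_otus, dtype=np.int64
    )
    for sample_id, row in count_rows.items():
        matrix.loc[sample_id, row.index] = row.to_numpy()
    truth = TruthBundle(
        contaminant_otu_ids=frozenset(contaminant_profile.index),
        chloroplast_otu_ids=frozenset(chloroplast_ids),
        base_proportions=base_proportions,
        per_kit_bias=per_kit_bias,
        mixing_fraction={kit.name: mixing_fraction(kit) for kit in kits},
    )
    return DatasetBundle(
        otu_table=OtuTable(matrix),
        taxonomy=taxonomy,
        metadata=records,
        kit_profiles=[kit.profile for kit in kits],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# the default stated world
# ---------------------------------------------------------------------------

def default_species() -> list[SpeciesSpec]:
    """Three macroalgae with species-specific chloroplast loads.

    The red alga carries the heaviest plastid signal (~40% of reads); the
    brown and green algae sit in the 5–10% band.
    """
    return [
        SpeciesSpec("P_stenogona", n_otus=60, chloroplast_fraction=0.40, n_chloroplast_otus=4),
        SpeciesSpec("S_japonica", n_otus=60, chloroplast_fraction=0.10, n_chloroplast_otus=3),
        SpeciesSpec("U_lactuca", n_otus=60, chloroplast_fraction=0.075, n_chloroplast_otus=3),
    ]


def default_kits() -> list[KitSpec]:
    """Six commercial kits with qualitative behaviour taken from the study:

    yield ordering B&T/MonNEB/PowSoi high and QiaSto near zero; kitome read
    yields comparable to samples for B&T/PowFec/Thermo (M/C near 1) and low
    for QiaSto/PowSoi/MonNEB (M/C > 1); DIN unmeasurable for QiaSto; kits
    requiring PCR dilution (B&T, MonNEB); simplicity and cost per sample
    from the kit comparison table.
    """
    return [
        KitSpec("PowSoi", capture_bias_sd=0.6, dropout_rate=0.05,
                contaminant_load_ng=0.15, mean_template_ng=30.0, dilution_factor=1,
                simplicity=1, cost_per_sample=9.80, kitome_read_factor=0.30,
                din_mean=3.2),
        KitSpec("PowFec", capture_bias_sd=0.6, dropout_rate=0.08,
                contaminant_load_ng=1.2, mean_template_ng=20.0, dilution_factor=1,
                simplicity=1, cost_per_sample=9.66, kitome_read_factor=0.85,
                din_mean=3.0),
        KitSpec("QiaSto", capture_bias_sd=0.8, dropout_rate=0.10,
                contaminant_load_ng=0.08, mean_template_ng=1.5, dilution_factor=1,
                simplicity=1, cost_per_sample=7.68, kitome_read_factor=0.10,
                din_mean=None),
        KitSpec("B_T", capture_bias_sd=0.5, dropout_rate=0.05,
                contaminant_load_ng=1.5, mean_template_ng=40.0, dilution_factor=10,
                simplicity=2, cost_per_sample=4.48, kitome_read_factor=0.90,
                din_mean=3.5),
        KitSpec("Thermo", capture_bias_sd=0.5, dropout_rate=0.06,
                contaminant_load_ng=0.8, mean_template_ng=10.0, dilution_factor=1,
                simplicity=1, cost_per_sample=3.90, kitome_read_factor=0.80,
                din_mean=2.8),
        KitSpec("MonNEB", capture_bias_sd=0.4, dropout_rate=0.04,
                contaminant_load_ng=0.2, mean_template_ng=35.0, dilution_factor=10,
                simplicity=2, cost_per_sample=10.78, kitome_read_factor=0.35,
                din_mean=4.5),
    ]


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_TOP_LEVEL_KEYS = {"species", "kits", "n_replicates", "depth", "n_contaminant_otus"}


def load_simulation_config(path) -> dict:
    """Read a simulation config; returns generate_benchmark_dataset kwargs.

    Schema: optional ``species`` / ``kits`` lists (dataclass field names)
    plus scalar ``n_replicates``, ``depth``, ``n_contaminant_otus``.
    Unknown keys raise.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(payload) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)!r}")
    kwargs: dict = {}
    kwargs["species"] = (
        [SpeciesSpec(**entry) for entry in payload["species"]]
        if "species" in payload
        else default_species()
    )
    kwargs["kits"] = (
        [KitSpec(**entry) for entry in payload["kits"]]
        if "kits" in payload
        else default_kits()
    )
    for key in ("n_replicates", "depth", "n_contaminant_otus"):
        if key in payload:
            kwargs[key] = int(payload[key])
    return kwargs
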