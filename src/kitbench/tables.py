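"""Tabular containers and strict readers/writers for the kit benchmark.

File dialects
-------------
* OTU table: tab-separated, classic QIIME orientation — rows are OTUs,
  columns are samples, first column header ``#OTU ID``. In memory the
  orientation is samples x OTUs, which keeps per-sample operations natural.
* Taxonomy: tab-separated, one row per OTU with the six fixed ranks
  domain, phylum, class, order, family, genus. Missing ranks are stored as
  empty strings and never dropped.
* Metadata / QC: comma-separated. Sample design (species, kit, replicate,
  control flag) and QC measurements (DNA concentration, input mass, DIN,
  absorbance ratios, PCR dilution factor) may live in one CSV or be split
  into a metadata CSV plus a QC CSV joined on ``sample_id``.
* Kit profiles: comma-separated ``kit,simplicity,cost_per_sample``.
* Rank report: long tab-separated ``species,criterion,kit,rank``.

All parsers validate rather than coerce: malformed numerics, duplicate
identifiers and samples missing from the metadata raise
:class:`ValidationError` naming the offending row and column. Unknown
columns in input files are tolerated and ignored.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kitbench")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
CHLOROPLAST_ORDER = "Chloroplast"

#: Reserved species label for no-input (kitome) negative controls.
CONTROL_SPECIES = "control"

#: Fluorometer detection limit; concentrations below it are floored (ng/uL).
DNA_CONC_FLOOR = 0.1

DILUTION_FAILED = "failed"
VALID_DILUTIONS = (1, 10, 100)

METADATA_COLUMNS = ("sample_id", "species", "kit", "replicate", "is_control")
QC_COLUMNS = (
    "sample_id",
    "dna_conc",
    "input_mass",
    "din",
    "a260_280",
    "a260_230",
    "dilution_factor",
)


class ValidationError(ValueError):
    """Raised when an input table violates its documented schema."""


# ---------------------------------------------------------------------------
# numeric parsing helpers
# ---------------------------------------------------------------------------

def _parse_float(value, row: str, column: str, *, allow_missing: bool = True):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValidationError(f"missing value at row {row!r}, column {column!r}")
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        if allow_missing:
            return None
        raise ValidationError(f"missing value at row {row!r}, column {column!r}")
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(
            f"malformed numeric {text!r} at row {row!r}, column {column!r}"
        ) from exc


def _parse_int(value, row: str, column: str) -> int:
    number = _parse_float(value, row, column, allow_missing=False)
    if number != int(number):
        raise ValidationError(
            f"expected integer, got {value!r} at row {row!r}, column {column!r}"
        )
    return int(number)


def _parse_bool(value, row: str, column: str) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(
        f"malformed boolean {value!r} at row {row!r}, column {column!r}"
    )


def parse_dilution(value, row: str = "?", column: str = "dilution_factor"):
    """Parse a PCR dilution factor: 1, 10, 100 or the literal ``failed``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    if text.lower() == DILUTION_FAILED:
        return DILUTION_FAILED
    try:
        factor = int(float(text))
    except ValueError as exc:
        raise ValidationError(
            f"unknown dilution factor {value!r} at row {row!r}, column {column!r}"
        ) from exc
    if factor not in VALID_DILUTIONS:
        raise ValidationError(
            f"unknown dilution factor {value!r} at row {row!r}, column {column!r}"
        )
    return factor


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for label in labels:
        if label in seen:
            raise ValidationError(f"duplicate {what} {label!r}")
        seen.add(label)


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

class OtuTable:
    """Non-negative integer count matrix, samples x OTUs, with labels."""

    def __init__(self, frame: pd.DataFrame):
        _check_unique(list(frame.index), "sample ID")
        _check_unique(list(frame.columns), "OTU ID")
        values = frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            float_values = values.astype(float)
            if not np.all(np.mod(float_values, 1) == 0):
                bad = np.argwhere(np.mod(float_values, 1) != 0)[0]
                raise ValidationError(
                    "non-integer count at row "
                    f"{frame.index[bad[0]]!r}, column {frame.columns[bad[1]]!r}"
                )
            frame = frame.astype(np.int64)
            values = frame.to_numpy()
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                "negative count at row "
                f"{frame.index[bad[0]]!r}, column {frame.columns[bad[1]]!r}"
            )
        self.frame = frame.astype(np.int64) if values.size else frame
        self.frame.index.name = "sample_id"
        self.frame.columns.name = "otu_id"

    @classmethod
    def from_counts(
        cls,
        counts,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
    ) -> "OtuTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(sample_ids), columns=list(otu_ids)))

    # -- basic accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_otus(self) -> int:
        return self.frame.shape[1]

    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.frame.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples stay at zero."""
        totals = self.totals().to_numpy(dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.frame.div(safe, axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"unknown sample IDs {missing!r}")
        return OtuTable(self.frame.loc[list(sample_ids)].copy())

    def drop_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        drop = [o for o in otu_ids]
        missing = [o for o in drop if o not in self.frame.columns]
        if missing:
            raise ValidationError(f"unknown OTU IDs {missing!r}")
        return OtuTable(self.frame.drop(columns=drop).copy())

    def presence(self, min_count: int = 1) -> pd.DataFrame:
        return self.frame >= min_count

    def equals(self, other: "OtuTable") -> bool:
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


def read_otu_table(path) -> OtuTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    _check_unique(list(frame.index), "OTU ID")
    _check_unique(list(frame.columns), "sample ID")
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=np.int64)
    for column in frame.columns:
        for otu, raw in frame[column].items():
            value = _parse_float(raw, str(otu), str(column), allow_missing=False)
            if value != int(value):
                raise ValidationError(
                    f"non-integer count {raw!r} at row {otu!r}, column {column!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"negative count {raw!r} at row {otu!r}, column {column!r}"
                )
            numeric.loc[otu, column] = int(value)
    return OtuTable(numeric.T)


def write_otu_table(table: OtuTable, path) -> None:
    on_disk = table.frame.T
    on_disk.index.name = "#OTU ID"
    on_disk.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

class TaxonomyTable:
    """Per-OTU ranked lineage; the order rank drives chloroplast filtering."""

    def __init__(self, frame: pd.DataFrame):
        missing = [r for r in TAXONOMY_RANKS if r not in frame.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing ranks {missing!r}")
        _check_unique(list(frame.index), "OTU ID")
        self.frame = frame.loc[:, list(TAXONOMY_RANKS)].fillna("").astype(str)
        self.frame.index.name = "otu_id"

    @classmethod
    def from_records(cls, lineages: Mapping[str, Sequence[str]]) -> "TaxonomyTable":
        frame = pd.DataFrame.from_dict(dict(lineages), orient="index", columns=list(TAXONOMY_RANKS))
        return cls(frame)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame.index)

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValidationError(f"unknown taxonomy rank {rank!r}")
        return self.frame[rank]

    def subset(self, otu_ids: Sequence[str]) -> "TaxonomyTable":
        missing = [o for o in otu_ids if o not in self.frame.index]
        if missing:
            raise ValidationError(f"OTUs without taxonomy rows: {missing!r}")
        return TaxonomyTable(self.frame.loc[list(otu_ids)].copy())

    def equals(self, other: "TaxonomyTable") -> bool:
        return self.frame.equals(other.frame)


def read_taxonomy(path) -> TaxonomyTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    frame.index = frame.index.astype(str)
    return TaxonomyTable(frame)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata + QC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleRecord:
    """One sequencing sample: design factors plus extraction QC metrics.

    ``dna_conc`` is floored at :data:`DNA_CONC_FLOOR` (the fluorometer
    detection limit) on construction, mirroring how sub-detection
    concentrations are recorded in practice.
    """

    sample_id: str
    species: str
    kit: str
    replicate: int
    is_control: bool = False
    dna_conc: float | None = None
    input_mass: float | None = None
    din: float | None = None
    a260_280: float | None = None
    a260_230: float | None = None
    dilution_factor: int | str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be >= 1 for sample {self.sample_id!r}"
            )
        if self.is_control and self.species != CONTROL_SPECIES:
            raise ValidationError(
                f"control sample {self.sample_id!r} must use the reserved species "
                f"label {CONTROL_SPECIES!r}, got {self.species!r}"
            )
        if self.dna_conc is not None and self.dna_conc < DNA_CONC_FLOOR:
            self.dna_conc = DNA_CONC_FLOOR
        self.dilution_factor = parse_dilution(
            self.dilution_factor, self.sample_id, "dilution_factor"
        )


def read_metadata(path, qc_path=None) -> list[SampleRecord]:
    """Read sample metadata (optionally joined with a separate QC CSV).

    Concentrations below the 0.1 ng/uL detection floor are stored as 0.1
    with a logged warning.
    """
    meta = pd.read_csv(path, dtype=str)
    for column in METADATA_COLUMNS:
        if column not in meta.columns:
            raise ValidationError(f"metadata file missing column {column!r}")
    _check_unique(list(meta["sample_id"]), "sample ID")
    if qc_path is not None:
        qc = pd.read_csv(qc_path, dtype=str)
        if "sample_id" not in qc.columns:
            raise ValidationError("QC file missing column 'sample_id'")
        _check_unique(list(qc["sample_id"]), "sample ID")
        meta = meta.merge(qc, on="sample_id", how="left")

    records: list[SampleRecord] = []
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])

        def qc_value(column: str, *, row=row, sid=sid):
            if column not in row.index:
                return None
            return _parse_float(row[column], sid, column)

        conc = qc_value("dna_conc")
        if conc is not None and conc < DNA_CONC_FLOOR:
            logger.warning(
                "sample %s: dna_conc %.4g below detection floor, set to %.1f ng/uL",
                sid,
                conc,
                DNA_CONC_FLOOR,
            )
        records.append(
            SampleRecord(
                sample_id=sid,
                species=str(row["species"]),
                kit=str(row["kit"]),
                replicate=_parse_int(row["replicate"], sid, "replicate"),
                is_control=_parse_bool(row["is_control"], sid, "is_control"),
                dna_conc=conc,
                input_mass=qc_value("input_mass"),
                din=qc_value("din"),
                a260_280=qc_value("a260_280"),
                a260_230=qc_value("a260_230"),
                dilution_factor=row.get("dilution_factor"),
            )
        )
    return records


def _records_frame(records: Sequence[SampleRecord], columns: Sequence[str]) -> pd.DataFrame:
    rows = []
    for record in records:
        data = dataclasses.asdict(record)
        rows.append({c: data[c] for c in columns})
    frame = pd.DataFrame(rows, columns=list(columns))
    return frame


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    _records_frame(records, METADATA_COLUMNS).to_csv(path, index=False)


def write_qc(records: Sequence[SampleRecord], path) -> None:
    _records_frame(records, QC_COLUMNS).to_csv(path, index=False)


def records_by_id(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


def validate_dataset(
    table: OtuTable,
    taxonomy: TaxonomyTable | None,
    records: Sequence[SampleRecord],
) -> None:
    """Cross-table consistency: IDs in the OTU table must be resolvable."""
    known = {r.sample_id for r in records}
    missing_samples = [s for s in table.sample_ids if s not in known]
    if missing_samples:
        raise ValidationError(
            f"samples missing from metadata: {missing_samples!r}"
        )
    if taxonomy is not None:
        missing_otus = [o for o in table.otu_ids if o not in taxonomy.frame.index]
        if missing_otus:
            raise ValidationError(f"OTUs without taxonomy rows: {missing_otus!r}")


# ---------------------------------------------------------------------------
# kit profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class KitProfile:
    """Ranking inputs that are properties of the kit itself."""

    kit: str
    simplicity: int
    cost_per_sample: float

    def __post_init__(self) -> None:
        if self.simplicity not in {1, 2, 3, 4, 5}:
            raise ValidationError(
                f"kit {self.kit!r}: simplicity must be in 1..5, got {self.simplicity!r}"
            )
        if self.cost_per_sample <= 0:
            raise ValidationError(
                f"kit {self.kit!r}: cost_per_sample must be positive"
            )


def read_kit_profiles(path) -> list[KitProfile]:
    frame = pd.read_csv(path, dtype=str)
    for column in ("kit", "simplicity", "cost_per_sample"):
        if column not in frame.columns:
            raise ValidationError(f"kit profile file missing column {column!r}")
    _check_unique(list(frame["kit"]), "kit")
    profiles = []
    for _, row in frame.iterrows():
        kit = str(row["kit"])
        profiles.append(
            KitProfile(
                kit=kit,
                simplicity=_parse_int(row["simplicity"], kit, "simplicity"),
                cost_per_sample=_parse_float(
                    row["cost_per_sample"], kit, "cost_per_sample", allow_missing=False
                ),
            )
        )
    return profiles


def write_kit_profiles(profiles: Sequence[KitProfile], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rank report
# ---------------------------------------------------------------------------

def write_rank_report(rank_tables, path) -> None:
    """Write per-species rank tables as a long TSV.

    Besides the per-criterion ranks, four pseudo-criteria are written:
    ``total`` / ``quality`` (the summed ranks) and ``total_position`` /
    ``quality_position`` (the sorted, tie-aware positions).
    """
    rows = []
    for table in rank_tables:
        for criterion in table.per_criterion_ranks.index:
            for kit in table.per_criterion_ranks.columns:
                rows.append(
                    (table.species, criterion, kit, int(table.per_criterion_ranks.loc[criterion, kit]))
                )
        for kit in table.totals.index:
            rows.append((table.species, "total", kit, int(table.totals[kit])))
            rows.append((table.species, "quality", kit, int(table.quality[kit])))
            rows.append((table.species, "total_position", kit, int(table.total_positions[kit])))
            rows.append((table.species, "quality_position", kit, int(table.quality_positions[kit])))
    frame = pd.DataFrame(rows, columns=["species", "criterion", "kit", "rank"])
    frame.to_csv(path, sep="\t", index=False)


def read_rank_report(path):
    """Inverse of :func:`write_rank_report`; returns a list of RankTable."""
    from .ranking import RankTable

    frame = pd.read_csv(path, sep="\t", dtype={"species": str, "criterion": str, "kit": str})
    for column in ("species", "criterion", "kit", "rank"):
        if column not in frame.columns:
            raise ValidationError(f"rank report missing column {column!r}")
    special = {"total", "quality", "total_position", "quality_position"}
    tables = []
    for species, chunk in frame.groupby("species", sort=False):
        pivot = chunk[~chunk["criterion"].isin(special)].pivot(
            index="criterion", columns="kit", values="rank"
        )
        # preserve original criterion order within the file
        order = list(dict.fromkeys(chunk.loc[~chunk["criterion"].isin(special), "criterion"]))
        kit_order = list(dict.fromkeys(chunk["kit"]))
        pivot = pivot.loc[order, kit_order].astype(int)
        pivot.index.name = None
        pivot.columns.name = None

        def series(name: str, *, chunk=chunk, kit_order=kit_order) -> pd.Series:
            sub = chunk[chunk["criterion"] == name].set_index("kit")["rank"]
            return sub.loc[kit_order].rename(None).astype(int)

        tables.append(
            RankTable(
                species=str(species),
                per_criterion_ranks=pivot,
                totals=series("total"),
                quality=series("quality"),
                total_positions=series("total_position"),
                quality_positions=series("quality_position"),
            )
        )
    return tables
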