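"""QC-criterion derivation and the four kit-ranking rules with aggregation.

Ranking rules
-------------
* mean-value ranking — rank 1 to the kit with the best (highest or lowest)
  mean; used for DNA yield, DIN, Shannon, chloroplast content, simplicity
  and cost.
* contamination ranking — every kit whose contamination stays below a 1%
  threshold in *all* replicates shares rank 1; the remaining kits are
  ranked by ascending mean contamination starting right after the
  qualifying block.
* reproducibility ranking — the range between the best and worst
  reproducibility is split into six equal bins (per species); kits in the
  highest bin get rank 1, the next bin rank 2, and so on, with empty bins
  still consuming a rank number.
* dilution ranking — PCR dilution factors rank ascending (less dilution is
  better) with ``failed`` amplification ordered strictly worst.

Ties always use the minimum-rank convention with skipping (1, 1, 3), so
integer ranks can be summed. The Total rank sums all criteria; the Quality
rank excludes the simplicity and cost-per-sample criteria.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import DILUTION_FAILED, VALID_DILUTIONS, ValidationError

#: The default criterion panel for kit comparison.
CRITERIA = (
    "dna_yield",
    "din",
    "dilution",
    "kit_contamination",
    "chloroplast",
    "shannon",
    "reproducibility",
    "simplicity",
    "cost",
)

#: Criteria excluded from the Quality rank.
NON_QUALITY_CRITERIA = ("simplicity", "cost")

DEFAULT_CONTAMINATION_THRESHOLD = 0.01
DEFAULT_REPRODUCIBILITY_BINS = 6


# ---------------------------------------------------------------------------
# QC derivations
# ---------------------------------------------------------------------------

def yield_per_gram(
    conc: float, input_mass: float, elution_volume: float = 60.0
) -> float:
    """DNA yield in ng per gram of input: conc x elution volume / mass.

    The concentration is floored at the 0.1 ng/uL detection limit before
    the computation.
    """
    if input_mass is None or input_mass <= 0:
        raise ValidationError("input_mass must be positive")
    if conc is None or conc < 0:
        raise ValidationError("conc must be >= 0")
    return max(conc, 0.1) * elution_volume / input_mass


@dataclasses.dataclass(frozen=True)
class PurityFlags:
    pure: bool
    a260_280_ok: bool
    a260_230_ok: bool


def purity_flags(a260_280: float, a260_230: float) -> PurityFlags:
    """Purity windows: 260/280 in [1.7, 2.0] and 260/230 in [2.0, 2.2].

    Both bounds inclusive; a sample is pure iff both ratios are in window.
    """
    if a260_280 is None or a260_280 <= 0 or a260_230 is None or a260_230 <= 0:
        raise ValidationError("absorbance ratios must be positive")
    ok_280 = 1.7 <= a260_280 <= 2.0
    ok_230 = 2.0 <= a260_230 <= 2.2
    return PurityFlags(pure=ok_280 and ok_230, a260_280_ok=ok_280, a260_230_ok=ok_230)


# ---------------------------------------------------------------------------
# ranking rules
# ---------------------------------------------------------------------------

def _min_ranks(keys: Sequence[float]) -> np.ndarray:
    """Minimum-rank-with-skip ranking of keys, ascending (smaller = better)."""
    return rankdata(np.asarray(keys, dtype=float), method="min").astype(int)


def _as_value_list(value) -> list[float]:
    if isinstance(value, (int, float, np.integer, np.floating)):
        return [float(value)]
    return [float(v) for v in value]


def rank_by_mean(
    values: Mapping[str, Sequence[float] | float], higher_is_better: bool
) -> dict[str, int]:
    """Rank kits by their mean value; rank 1 is the best mean."""
    if not values:
        raise ValidationError("rank_by_mean requires at least one kit")
    kits = list(values)
    means = []
    for kit in kits:
        entries = _as_value_list(values[kit])
        if not entries:
            raise ValidationError(f"kit {kit!r} has an empty value list")
        means.append(float(np.mean(entries)))
    keys = [-m for m in means] if higher_is_better else means
    return dict(zip(kits, (int(r) for r in _min_ranks(keys))))


def rank_contamination(
    values: Mapping[str, Sequence[float]],
    threshold: float = DEFAULT_CONTAMINATION_THRESHOLD,
) -> dict[str, int]:
    """Contamination rule: sub-threshold-in-all-replicates kits share rank 1.

    Non-qualifying kits are ranked by ascending mean contamination,
    starting at rank (number of qualifying kits + 1), min-rank ties.
    """
    if not values:
        raise ValidationError("rank_contamination requires at least one kit")
    qualifying: list[str] = []
    rest: list[str] = []
    for kit, replicates in values.items():
        replicate_values = _as_value_list(replicates)
        if not replicate_values:
            raise ValidationError(f"kit {kit!r} is missing replicate values")
        (qualifying if all(v < threshold for v in replicate_values) else rest).append(kit)
    ranks = {kit: 1 for kit in qualifying}
    if rest:
        means = [float(np.mean(_as_value_list(values[kit]))) for kit in rest]
        offset = len(qualifying)
        for kit, r in zip(rest, _min_ranks(means)):
            ranks[kit] = offset + int(r)
    return {kit: ranks[kit] for kit in values}


def rank_reproducibility(
    values: Mapping[str, float], n_bins: int = DEFAULT_REPRODUCIBILITY_BINS
) -> dict[str, int]:
    """Equal-width binning of the observed range into ``n_bins`` ranks.

    Bins are half-open from below except the top bin, which is closed; the
    highest-value bin maps to rank 1 and empty bins still consume a rank.
    A degenerate (zero-width) range puts every kit at rank 1.
    """
    if not values:
        raise ValidationError("rank_reproducibility requires at least one kit")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    kits = list(values)
    v = np.array([float(values[kit]) for kit in kits])
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return {kit: 1 for kit in kits}
    width = (vmax - vmin) / n_bins
    idx = np.minimum(((v - vmin) // width).astype(int), n_bins - 1)
    return {kit: int(n_bins - i) for kit, i in zip(kits, idx)}


def rank_dilution(values: Mapping[str, int | str]) -> dict[str, int]:
    """Ascending by dilution factor; ``failed`` amplification ranks last."""
    if not values:
        raise ValidationError("rank_dilution requires at least one kit")
    kits = list(values)
    keys = []
    for kit in kits:
        factor = values[kit]
        if isinstance(factor, str) and factor.strip().lower() == DILUTION_FAILED:
            keys.append(math.inf)
        elif factor in VALID_DILUTIONS:
            keys.append(float(factor))
        else:
            raise ValidationError(
                f"kit {kit!r}: unknown dilution factor token {factor!r}"
            )
    return dict(zip(kits, (int(r) for r in _min_ranks(keys))))


# ---------------------------------------------------------------------------
# criterion plumbing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CriterionValues:
    """Raw per-kit values for one ranking criterion.

    ``per_kit_values`` maps kit -> replicate list (or a scalar for
    kit-level criteria). Kits whose value is None (e.g. DIN measurement
    failure) are excluded from the criterion and imputed at worst + 1.
    """

    criterion: str
    per_kit_values: dict
    higher_is_better: bool

    def ranks(self) -> dict[str, int]:
        if self.criterion == "kit_contamination":
            return rank_contamination(self.per_kit_values)
        if self.criterion == "reproducibility":
            return rank_reproducibility(self.per_kit_values)
        if self.criterion == "dilution":
            return rank_dilution(self.per_kit_values)
        measured = {
            kit: v for kit, v in self.per_kit_values.items() if v is not None
        }
        missing = [kit for kit in self.per_kit_values if kit not in measured]
        if not measured:
            return {kit: 1 for kit in self.per_kit_values}
        ranks = rank_by_mean(measured, self.higher_is_better)
        worst = max(ranks.values())
        for kit in missing:
            ranks[kit] = worst + 1
        return {kit: ranks[kit] for kit in self.per_kit_values}


@dataclasses.dataclass
class RankTable:
    """Per-species criterion ranks plus Total and Quality aggregates."""

    species: str
    per_criterion_ranks: pd.DataFrame  # criteria x kits, integer ranks
    totals: pd.Series
    quality: pd.Series
    total_positions: pd.Series
    quality_positions: pd.Series

    @property
    def total_rank_order(self) -> list[str]:
        return list(self.totals.sort_values(kind="stable").index)

    @property
    def quality_rank_order(self) -> list[str]:
        return list(self.quality.sort_values(kind="stable").index)

    def best_total(self) -> list[str]:
        """Kits tied at Total position 1."""
        return list(self.total_positions.index[self.total_positions == 1])

    def best_quality(self) -> list[str]:
        return list(self.quality_positions.index[self.quality_positions == 1])

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_criterion_ranks.copy()
        frame.loc["total"] = self.totals
        frame.loc["quality"] = self.quality
        frame.loc["total_position"] = self.total_positions
        frame.loc["quality_position"] = self.quality_positions
        return frame

    def equals(self, other: "RankTable") -> bool:
        return (
            self.species == other.species
            and self.per_criterion_ranks.equals(other.per_criterion_ranks)
            and self.totals.equals(other.totals)
            and self.quality.equals(other.quality)
            and self.total_positions.equals(other.total_positions)
            and self.quality_positions.equals(other.quality_positions)
        )

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "per_criterion_ranks": {
                criterion: {k: int(v) for k, v in row.items()}
                for criterion, row in self.per_criterion_ranks.iterrows()
            },
            "total": {k: int(v) for k, v in self.totals.items()},
            "quality": {k: int(v) for k, v in self.quality.items()},
            "total_position": {k: int(v) for k, v in self.total_positions.items()},
            "quality_position": {k: int(v) for k, v in self.quality_positions.items()},
        }


def aggregate_ranks(
    criteria: Sequence[CriterionValues] | Mapping[str, Mapping[str, int]],
    species: str = "",
) -> RankTable:
    """Sum per-criterion ranks into Total and Quality rankings.

    Accepts either CriterionValues (ranked here) or precomputed
    criterion -> kit -> rank mappings. Every criterion must cover every
    kit. Tied sums share a position (min-rank convention), reported
    explicitly in ``total_positions`` / ``quality_positions``.
    """
    if isinstance(criteria, Mapping):
        per_criterion = {name: dict(ranks) for name, ranks in criteria.items()}
    else:
        per_criterion = {c.criterion: c.ranks() for c in criteria}
    if not per_criterion:
        raise ValidationError("aggregate_ranks requires at least one criterion")
    kits: list[str] = list(next(iter(per_criterion.values())))
    for name, ranks in per_criterion.items():
        missing = [kit for kit in kits if kit not in ranks]
        extra = [kit for kit in ranks if kit not in kits]
        if missing or extra:
            raise ValidationError(
                f"criterion {name!r} does not cover the same kits: "
                f"missing {missing!r}, extra {extra!r}"
            )
    frame = pd.DataFrame(per_criterion).T.loc[:, kits].astype(int)
    totals = frame.sum(axis=0)
    quality_rows = [c for c in frame.index if c not in NON_QUALITY_CRITERIA]
    quality = frame.loc[quality_rows].sum(axis=0)
    return RankTable(
        species=species,
        per_criterion_ranks=frame,
        totals=totals,
        quality=quality,
        total_positions=pd.Series(
            _min_ranks(totals.to_numpy()), index=totals.index
        ),
        quality_positions=pd.Series(
            _min_ranks(quality.to_numpy()), index=quality.index
        ),
    )


# ---------------------------------------------------------------------------
# presentation
# ---------------------------------------------------------------------------

def plot_rank_heatmap(rank_tables: Sequence[RankTable], path) -> None:
    """Render per-species criterion/Total/Quality ranks as a heatmap figure.

    Cosmetic output for reports; not meant to be compared bit-exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(rank_tables)
    fig, axes = plt.subplots(n, 1, figsize=(8, 3.2 * n), squeeze=False)
    for ax, table in zip(axes[:, 0], rank_tables):
        frame = table.to_frame()
        image = ax.imshow(frame.to_numpy(), cmap="viridis_r", aspect="auto")
        ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=45, ha="right")
        ax.set_yticks(range(frame.shape[0]), frame.index)
        for i in range(frame.shape[0]):
            for j in range(frame.shape[1]):
                ax.text(j, i, int(frame.iloc[i, j]), ha="center", va="center",
                        color="white", fontsize=8)
        ax.set_title(f"{table.species}: kit ranks (lower is better)")
        fig.colorbar(image, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
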