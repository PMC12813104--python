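"""Chloroplast removal, kitome contaminant calling and contamination levels.

Contaminant calling mirrors the interface of negative-control
decontamination in "either" mode with a score threshold of 0.3, but the two
per-OTU scores are deliberately simple, fully specified tests rather than a
reimplementation of the original mixture-model algorithm:

* ``score_p`` — one-sided Fisher exact p-value that the OTU is more
  prevalent (presence = count >= 1) in no-input controls than in real
  samples. Small values mean control-enriched, i.e. contaminant-like.
* ``score_f`` — seeded permutation p-value for a *negative* Spearman
  correlation between the OTU's relative abundance and the sample DNA
  concentration: reagent contaminants make up a larger share of reads when
  little template DNA is present.

An OTU is flagged when *either* score falls below the threshold, matching
the "either" combination rule. Both scores are reported per OTU.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    CHLOROPLAST_ORDER,
    OtuTable,
    SampleRecord,
    TaxonomyTable,
    ValidationError,
)

logger = logging.getLogger("kitbench")

DEFAULT_THRESHOLD = 0.3
DEFAULT_PERMUTATIONS = 999


# ---------------------------------------------------------------------------
# chloroplast filtering
# ---------------------------------------------------------------------------

def remove_chloroplast(
    table: OtuTable, taxonomy: TaxonomyTable
) -> tuple[OtuTable, pd.Series]:
    """Drop OTUs whose order-level taxonomy is exactly ``Chloroplast``.

    Returns the filtered table (retained counts unchanged) and the
    per-sample chloroplast read fraction (0 for empty samples). Idempotent.
    """
    missing = [o for o in table.otu_ids if o not in taxonomy.frame.index]
    if missing:
        raise ValidationError(f"OTUs without taxonomy rows: {missing!r}")
    orders = taxonomy.rank("order").loc[table.otu_ids]
    chloro = [otu for otu, order in orders.items() if order == CHLOROPLAST_ORDER]
    totals = table.totals().astype(float)
    chloro_reads = table.frame[chloro].sum(axis=1).astype(float) if chloro else pd.Series(0.0, index=table.frame.index)
    fraction = chloro_reads.div(totals.where(totals > 0, 1.0))
    fraction[totals == 0] = 0.0
    return table.drop_otus(chloro), fraction.rename("chloroplast_fraction")


# ---------------------------------------------------------------------------
# contaminant calling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContaminantCalls:
    """Per-OTU contaminant scores and the flagged set."""

    scores: pd.DataFrame  # columns: score_p, score_f, flagged
    threshold: float
    mode: str  # "kit-matched" or "pooled"

    @property
    def contaminant_otu_ids(self) -> frozenset[str]:
        return frozenset(self.scores.index[self.scores["flagged"]])


def _fisher_prevalence_scores(
    present_controls: np.ndarray,
    present_samples: np.ndarray,
    n_controls: int,
    n_samples: int,
) -> np.ndarray:
    """One-sided Fisher p per OTU; small means control-enriched.

    The 2x2 table is [[present-in-controls, absent-in-controls],
    [present-in-samples, absent-in-samples]] with alternative "greater",
    i.e. higher presence odds in controls than in samples.
    """
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(len(present_controls))
    for i, (a, c) in enumerate(zip(present_controls, present_samples)):
        key = (int(a), int(c))
        if key not in cache:
            table = [[key[0], n_controls - key[0]], [key[1], n_samples - key[1]]]
            cache[key] = float(stats.fisher_exact(table, alternative="greater")[1])
        out[i] = cache[key]
    return out


def _spearman_permutation_scores(
    concentrations: np.ndarray,
    relative_abundance: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Permutation p-values for negative Spearman rho, one per OTU.

    One shared set of permutations of the concentration vector is used for
    all OTUs; p = (1 + #{rho_perm <= rho_obs}) / (1 + n_permutations).
    OTUs with constant abundance (or constant concentrations) get p = 1.
    """
    n = len(concentrations)
    x = stats.rankdata(concentrations)
    y = stats.rankdata(relative_abundance, axis=0)
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    x_norm = np.linalg.norm(xc)
    y_norm = np.linalg.norm(yc, axis=0)
    valid = (x_norm > 0) & (y_norm > 0)
    if not valid.any() or n_permutations < 1:
        return np.ones(relative_abundance.shape[1])

    denom = np.where(y_norm > 0, y_norm, 1.0) * (x_norm if x_norm > 0 else 1.0)
    rho_obs = (xc @ yc) / denom

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x73706D6E]))
    exceed = np.zeros(relative_abundance.shape[1], dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        rho_perm = (xc[perm] @ yc) / denom
        exceed += rho_perm <= rho_obs + 1e-12
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p[~valid] = 1.0
    return p


def call_contaminants(
    table: OtuTable,
    records: Sequence[SampleRecord],
    threshold: float = DEFAULT_THRESHOLD,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    pooled: bool = False,
) -> ContaminantCalls:
    """Call kit-reagent contaminants from no-input kitome controls.

    With ``pooled=False`` (default) the prevalence and frequency tests use
    only samples from kits that contributed a control; ``pooled=True`` uses
    every sample against every control.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing!r}")
    control_ids = [s for s in table.sample_ids if by_id[s].is_control]
    if not control_ids:
        raise ValidationError("contaminant calling requires >= 1 control sample")
    if pooled:
        sample_ids = [s for s in table.sample_ids if not by_id[s].is_control]
    else:
        kits_with_controls = {by_id[s].kit for s in control_ids}
        sample_ids = [
            s
            for s in table.sample_ids
            if not by_id[s].is_control and by_id[s].kit in kits_with_controls
        ]
    if not sample_ids:
        raise ValidationError("contaminant calling requires >= 1 non-control sample")

    presence = table.presence()
    present_controls = presence.loc[control_ids].sum(axis=0).to_numpy()
    present_samples = presence.loc[sample_ids].sum(axis=0).to_numpy()
    score_p = _fisher_prevalence_scores(
        present_controls, present_samples, len(control_ids), len(sample_ids)
    )

    concentrations = []
    for s in sample_ids:
        conc = by_id[s].dna_conc
        if conc is None:
            raise ValidationError(
                f"sample {s!r} lacks dna_conc, required by the frequency test"
            )
        concentrations.append(conc)
    rel = table.relative_abundance().loc[sample_ids].to_numpy()
    score_f = _spearman_permutation_scores(
        np.asarray(concentrations), rel, n_permutations, seed
    )

    scores = pd.DataFrame(
        {
            "score_p": score_p,
            "score_f": score_f,
            "flagged": (score_p < threshold) | (score_f < threshold),
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
    return ContaminantCalls(
        scores=scores,
        threshold=threshold,
        mode="pooled" if pooled else "kit-matched",
    )


# ---------------------------------------------------------------------------
# contamination quantification
# ---------------------------------------------------------------------------

def contamination_level(table: OtuTable, contaminants: Iterable[str]) -> pd.Series:
    """Summed relative abundance of contaminant OTUs per sample.

    Additive over disjoint contaminant sets; 0 everywhere for the empty set.
    """
    contaminant_ids = list(dict.fromkeys(contaminants))
    unknown = [o for o in contaminant_ids if o not in table.frame.columns]
    if unknown:
        raise ValidationError(f"unknown OTU IDs in contaminant set: {unknown!r}")
    rel = table.relative_abundance()
    if not contaminant_ids:
        return pd.Series(0.0, index=rel.index, name="contamination_level")
    return rel[contaminant_ids].sum(axis=1).rename("contamination_level")


def mc_ratio(replicate_totals: Sequence[float], kitome_total: float) -> float:
    """Mean replicate read yield over the matched kitome read yield.

    A kitome with zero reads yields ``inf`` — the undefined-but-best case.
    """
    totals = list(replicate_totals)
    if not totals:
        raise ValidationError("mc_ratio requires at least one replicate total")
    if any(t < 0 for t in totals) or kitome_total < 0:
        raise ValidationError("read totals must be >= 0")
    mean_total = float(np.mean(totals))
    if kitome_total == 0:
        return math.inf
    return mean_total / kitome_total


def mc_ratio_table(
    table: OtuTable, records: Sequence[SampleRecord]
) -> pd.DataFrame:
    """M/C ratio per (kit, species) from raw read totals."""
    by_id = {r.sample_id: r for r in records}
    totals = table.totals()
    kitome_totals: dict[str, float] = {}
    for s in table.sample_ids:
        if by_id[s].is_control:
            kitome_totals[by_id[s].kit] = float(totals[s])
    rows = []
    pairs: dict[tuple[str, str], list[float]] = {}
    for s in table.sample_ids:
        record = by_id[s]
        if record.is_control:
            continue
        pairs.setdefault((record.kit, record.species), []).append(float(totals[s]))
    for (kit, species), replicate_totals in sorted(pairs.items()):
        if kit not in kitome_totals:
            continue
        rows.append(
            {
                "kit": kit,
                "species": species,
                "mc_ratio": mc_ratio(replicate_totals, kitome_totals[kit]),
            }
        )
    return pd.DataFrame(rows, columns=["kit", "species", "mc_ratio"])


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContaminationReport:
    """Everything the filtering stage learned about a dataset.

    Score orientation note: both contaminant scores behave like the
    reference decontamination tool's — low score means contaminant-like.
    """

    calls: ContaminantCalls
    per_sample_contamination: pd.Series
    per_sample_chloroplast: pd.Series
    mc_ratios: pd.DataFrame

    def to_dict(self) -> dict:
        def encode(value: float) -> float | str:
            return "undefined" if math.isinf(value) else value

        return {
            "score_orientation": "low score => contaminant-like",
            "threshold": self.calls.threshold,
            "control_mode": self.calls.mode,
            "contaminant_otu_ids": sorted(self.calls.contaminant_otu_ids),
            "scores": {
                otu: {
                    "score_p": float(row["score_p"]),
                    "score_f": float(row["score_f"]),
                    "flagged": bool(row["flagged"]),
                }
                for otu, row in self.calls.scores.iterrows()
            },
            "per_sample_contamination": self.per_sample_contamination.to_dict(),
            "per_sample_chloroplast": self.per_sample_chloroplast.to_dict(),
            "mc_ratio": [
                {
                    "kit": row["kit"],
                    "species": row["species"],
                    "mc_ratio": encode(row["mc_ratio"]),
                }
                for _, row in self.mc_ratios.iterrows()
            ],
        }
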