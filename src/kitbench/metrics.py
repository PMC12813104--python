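"""Alpha/beta diversity, reproducibility and OTU-sharing statistics.

Conventions match common amplicon practice: Shannon entropy uses the
natural logarithm; Bray–Curtis dissimilarities are computed on raw counts
without rarefaction; PCoA is classical scaling of the double-centred
squared-distance (Gower) matrix; PERMANOVA permutes sample labels freely
(single factor, no strata) and reports
p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import (
    TAXONOMY_RANKS,
    OtuTable,
    SampleRecord,
    TaxonomyTable,
    ValidationError,
)

logger = logging.getLogger("kitbench")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities in [0, 1]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValidationError("distances must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


@dataclasses.dataclass(frozen=True)
class SharingResult:
    """How many OTUs were detected by exactly m of the K kits."""

    counts: dict[int, int]
    universal_fraction: float
    unique_fraction: float
    other_fraction: float

    @property
    def total_detected(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over nonzero proportions."""
    values = np.asarray(counts, dtype=float)
    if values.size == 0 or (values < 0).any():
        raise ValidationError("counts must be a non-empty, non-negative vector")
    total = values.sum()
    if total == 0:
        raise ValidationError("Shannon index is undefined for an all-zero vector")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarities, d = 1 - 2 sum(min) / (sum x + sum y)."""
    if table.n_samples < 2:
        raise ValidationError("Bray–Curtis needs at least two samples")
    totals = table.totals()
    empty = list(totals.index[totals == 0])
    if empty:
        raise ValidationError(f"samples with zero total counts: {empty!r}")
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), table.sample_ids)


def pcoa(dist: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Eigendecomposes the double-centred Gower matrix of squared distances.
    Returns coordinates for up to ``k`` axes with positive eigenvalues and
    the full non-increasing eigenvalue vector (negative values reported,
    their axes dropped).
    """
    n = len(dist.sample_ids)
    if k >= n:
        raise ValidationError("number of axes k must be < number of samples")
    d2 = dist.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigenvalues, eigenvectors = np.linalg.eigh(gower)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    positive = eigenvalues > 1e-10
    n_axes = min(k, int(positive.sum()))
    coords = eigenvectors[:, :n_axes] * np.sqrt(eigenvalues[:n_axes])
    frame = pd.DataFrame(
        coords,
        index=dist.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    return frame, eigenvalues


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with free label permutation.

    pseudo-F = (SS_among / (a - 1)) / (SS_within / (n - a)) with sums of
    squared distances; the permutation p-value uses the standard +1
    correction, so p is in (0, 1].
    """
    labels = list(groups)
    n = len(dist.sample_ids)
    if len(labels) != n:
        raise ValidationError("groups must match the number of samples")
    codes, counts = np.unique(labels, return_counts=True)
    if len(codes) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        small = [str(c) for c, k in zip(codes, counts) if k < 2]
        raise ValidationError(f"groups of size 1 are not allowed: {small!r}")
    a = len(codes)
    index = {c: i for i, c in enumerate(codes)}
    onehot = np.zeros((n, a))
    onehot[np.arange(n), [index[lab] for lab in labels]] = 1.0
    within_weights = onehot @ np.diag(1.0 / counts) @ onehot.T

    d2 = dist.values**2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(weights: np.ndarray) -> float:
        ss_within = float((d2 * weights).sum()) / 2.0
        ss_among = max(ss_total - ss_within, 0.0)
        if ss_within <= 1e-12:
            return np.inf if ss_among > 1e-12 else 0.0
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_observed = pseudo_f(within_weights)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x70657276])
    )
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if pseudo_f(within_weights[np.ix_(perm, perm)]) >= f_observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_observed), p_value=float(p), n_permutations=n_permutations
    )


# ---------------------------------------------------------------------------
# reproducibility and sharing
# ---------------------------------------------------------------------------

def reproducibility_rate(
    table: OtuTable,
    replicate_ids: Sequence[str],
    denominator: str = "union",
    min_count: int = 1,
) -> float:
    """Fraction of OTUs shared by *all* technical replicates of a group.

    The numerator is the intersection of the replicates' presence sets
    (presence = count >= ``min_count``). The default denominator is the
    union of OTUs detected by the group; ``"mean-richness"`` divides by the
    mean per-replicate richness instead. A replicate with no detected OTUs
    gives rate 0 with a warning.
    """
    if len(replicate_ids) < 2:
        raise ValidationError("reproducibility needs at least two replicates")
    if denominator not in {"union", "mean-richness"}:
        raise ValidationError(f"unknown denominator {denominator!r}")
    presence = table.select_samples(replicate_ids).presence(min_count)
    sets = [frozenset(presence.columns[presence.loc[s]]) for s in replicate_ids]
    if any(not s for s in sets):
        logger.warning("replicate with zero detected OTUs in %r", list(replicate_ids))
        return 0.0
    intersection = frozenset.intersection(*sets)
    if denominator == "union":
        denom = len(frozenset.union(*sets))
    else:
        denom = float(np.mean([len(s) for s in sets]))
    return len(intersection) / denom if denom else 0.0


def otu_sharing(
    table: OtuTable,
    records: Sequence[SampleRecord],
    species: str,
    min_count: int = 1,
) -> SharingResult:
    """OTU sharing across kits for one species.

    A kit detects an OTU when it appears in at least one of the kit's
    replicates. ``counts[m]`` is the number of OTUs detected by exactly m of
    the K kits; the universal/unique/other fractions follow (universal =
    detected by all kits, unique = by exactly one).
    """
    by_kit: dict[str, list[str]] = {}
    for record in records:
        if record.species == species and not record.is_control:
            by_kit.setdefault(record.kit, []).append(record.sample_id)
    if not by_kit:
        raise ValidationError(f"unknown species label {species!r}")
    presence = table.presence(min_count)
    detection = pd.DataFrame(
        {kit: presence.loc[ids].any(axis=0) for kit, ids in by_kit.items()}
    )
    n_kits_detecting = detection.sum(axis=1)
    detected = n_kits_detecting[n_kits_detecting > 0]
    n_kits = len(by_kit)
    counts = {m: int((detected == m).sum()) for m in range(1, n_kits + 1)}
    total = len(detected)
    if total == 0:
        return SharingResult(counts, 0.0, 0.0, 0.0)
    universal = counts.get(n_kits, 0) / total
    unique = counts.get(1, 0) / total if n_kits > 1 else 0.0
    if n_kits == 1:
        universal, unique = 1.0, 0.0
    return SharingResult(
        counts=counts,
        universal_fraction=universal,
        unique_fraction=unique,
        other_fraction=1.0 - universal - unique,
    )


# ---------------------------------------------------------------------------
# taxonomic summarisation
# ---------------------------------------------------------------------------

def aggregate_taxa(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    level: str,
    min_display: float = 0.01,
) -> pd.DataFrame:
    """Taxa-by-sample relative abundances at a rank, pooling rare taxa.

    A taxon is displayed when its maximum per-sample relative abundance
    exceeds ``min_display``; everything else is pooled into ``other``.
    Unlabelled OTUs aggregate under ``unclassified``. Columns sum to 1 for
    samples with reads.
    """
    if level not in TAXONOMY_RANKS:
        raise ValidationError(f"unknown taxonomy rank {level!r}")
    missing = [o for o in table.otu_ids if o not in taxonomy.frame.index]
    if missing:
        raise ValidationError(f"OTUs without taxonomy rows: {missing!r}")
    labels = taxonomy.rank(level).loc[table.otu_ids].replace("", "unclassified")
    rel = table.relative_abundance()
    by_taxon = rel.T.groupby(labels).sum()  # taxa x samples
    keep = by_taxon.max(axis=1) > min_display
    shown = by_taxon.loc[keep]
    pooled = by_taxon.loc[~keep].sum(axis=0)
    if (pooled > 0).any() or (~keep).any():
        shown = pd.concat([shown, pooled.to_frame("other").T])
    shown.index.name = level
    return shown
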