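"""Quantitative microbiota profiling from amplicon counts + qPCR totals.

Pipeline order follows the published procedure: (1) collapse ASV counts
to species and drop unclassified ASVs (their read fraction is reported,
never silently discarded); (2) divide raw species counts by 16S rRNA
gene copy number (kept fractional — rounding after division would only
bias the renormalization); (3) renormalize per sample and scale to the
qPCR-measured total 16S copies, which simultaneously corrects for
sequencing depth. Samples failing a precondition (no classified reads,
zero corrected sum, missing qPCR total) are excluded with a recorded
reason, never zeroed.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iokit import (
    CopyNumberTable,
    QPCRTotals,
    ValidationError,
    _check_ids,
    _check_matrix,
)

__all__ = [
    "SpeciesCountTable",
    "AbsoluteAbundanceTable",
    "AggregationResult",
    "ScalingResult",
    "aggregate_species",
    "copy_number_correct",
    "scale_to_qpcr",
    "fold_change",
    "quantify",
]


@dataclass(frozen=True)
class SpeciesCountTable:
    """Species x samples read counts (fractional values permitted after correction)."""

    sample_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_species, n_samples)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        object.__setattr__(self, "species_ids", _check_ids(self.species_ids, "species"))
        counts = _check_matrix(self.counts, len(self.species_ids), len(self.sample_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.species_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class AbsoluteAbundanceTable:
    """Species x samples absolute abundances in 16S gene copies per sample."""

    sample_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        object.__setattr__(self, "species_ids", _check_ids(self.species_ids, "species"))
        values = _check_matrix(self.values, len(self.species_ids), len(self.sample_ids))
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.species_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class AggregationResult:
    table: SpeciesCountTable
    unclassified_fraction: dict[str, float]
    flagged_samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScalingResult:
    table: AbsoluteAbundanceTable
    excluded_samples: dict[str, str] = field(default_factory=dict)


def aggregate_species(
    asv_counts: SpeciesCountTable, asv_to_species: Mapping[str, str]
) -> AggregationResult:
    """Collapse ASV-level counts to species level.

    ASVs missing from the map are unclassified: their counts are dropped
    and their per-sample read fraction reported. Samples with zero
    classified reads are flagged (they must be excluded from scaling).
    Read counts are conserved: classified + unclassified = input total.
    """
    species_order: list[str] = []
    for asv in asv_counts.species_ids:
        sp = asv_to_species.get(asv)
        if sp is not None and sp not in species_order:
            species_order.append(sp)
    if not species_order:
        raise ValidationError("no ASV maps to any species")
    n_samples = asv_counts.n_samples
    agg = np.zeros((len(species_order), n_samples))
    unclassified = np.zeros(n_samples)
    for i, asv in enumerate(asv_counts.species_ids):
        sp = asv_to_species.get(asv)
        if sp is None:
            unclassified += asv_counts.counts[i]
        else:
            agg[species_order.index(sp)] += asv_counts.counts[i]
    totals = asv_counts.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, unclassified / totals, 0.0)
    flagged = tuple(
        asv_counts.sample_ids[j]
        for j in range(n_samples)
        if agg[:, j].sum() == 0
    )
    table = SpeciesCountTable(
        sample_ids=asv_counts.sample_ids,
        species_ids=tuple(species_order),
        counts=agg,
    )
    return AggregationResult(
        table=table,
        unclassified_fraction={
            s: float(frac[j]) for j, s in enumerate(asv_counts.sample_ids)
        },
        flagged_samples=flagged,
    )


def copy_number_correct(
    counts: SpeciesCountTable, cn: CopyNumberTable
) -> SpeciesCountTable:
    """Divide each species' raw counts by its 16S copy number."""
    missing = [s for s in counts.species_ids if s not in cn]
    if missing:
        raise ValidationError(f"species missing from copy-number table: {missing}")
    divisors = np.array([cn[s] for s in counts.species_ids], dtype=float)
    return SpeciesCountTable(
        sample_ids=counts.sample_ids,
        species_ids=counts.species_ids,
        counts=counts.counts / divisors[:, None],
    )


def scale_to_qpcr(corrected: SpeciesCountTable, totals: QPCRTotals) -> ScalingResult:
    """Renormalize corrected counts per sample and scale to the qPCR total.

    abs(s, sample) = corrected(s, sample) / sum_s' corrected(s', sample)
    * total(sample), so post-scaling column sums equal the qPCR totals.
    Samples with a zero corrected sum are excluded with a recorded
    reason; a sample without a qPCR total is an error.
    """
    missing = [s for s in corrected.sample_ids if s not in totals]
    if missing:
        raise ValidationError(f"samples missing a qPCR total: {missing}")
    keep: list[int] = []
    excluded: dict[str, str] = {}
    sums = corrected.counts.sum(axis=0)
    for j, sample in enumerate(corrected.sample_ids):
        if sums[j] <= 0:
            excluded[sample] = "zero corrected count sum"
        else:
            keep.append(j)
    if not keep:
        raise ValidationError("no sample has a positive corrected count sum")
    kept_ids = tuple(corrected.sample_ids[j] for j in keep)
    sub = corrected.counts[:, keep]
    scale = np.array([totals[s] for s in kept_ids]) / sums[keep]
    values = sub * scale[None, :]
    table = AbsoluteAbundanceTable(
        sample_ids=kept_ids, species_ids=corrected.species_ids, values=values
    )
    # invariant: column sums match the qPCR totals to 1e-6 relative tolerance
    col = table.values.sum(axis=0)
    want = np.array([totals[s] for s in kept_ids])
    if not np.allclose(col, want, rtol=1e-6, atol=0.0):
        raise ValidationError("post-scaling column sums drifted from qPCR totals")
    return ScalingResult(table=table, excluded_samples=excluded)


def fold_change(
    abund: AbsoluteAbundanceTable, t: str, t0: str
) -> dict[str, float]:
    """Per-species abundance ratio between samples ``t`` and baseline ``t0``.

    A zero baseline yields NaN (flagged undefined); a missing sample id
    raises ``KeyError``.
    """
    samples = list(abund.sample_ids)
    for s in (t, t0):
        if s not in samples:
            raise KeyError(f"sample {s!r} not in table")
    jt, j0 = samples.index(t), samples.index(t0)
    out: dict[str, float] = {}
    for i, sp in enumerate(abund.species_ids):
        base = abund.values[i, j0]
        out[sp] = abund.values[i, jt] / base if base > 0 else math.nan
    return out


def quantify(
    counts: SpeciesCountTable,
    cn: CopyNumberTable,
    totals: QPCRTotals,
    asv_to_species: Mapping[str, str] | None = None,
) -> ScalingResult:
    """Full profiling pipeline: [aggregate] -> copy-number correct -> qPCR scale."""
    if asv_to_species is not None:
        counts = aggregate_species(counts, asv_to_species).table
    return scale_to_qpcr(copy_number_correct(counts, cn), totals)
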