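"""Core-microbiota screening, co-occurrence, and consortium KO coverage.

Implements the design computations behind a core-based minimal
consortium: occupancy at a detection threshold, core selection
(inclusive thresholds: a taxon detected in at least ``occupancy_min`` of
samples at a relative abundance of at least ``detection`` is core),
probabilistic pairwise co-occurrence under the hypergeometric null, the
fraction of samples containing a whole focal consortium, core-KO
identification across metagenome profiles, and the fraction of core KOs
covered by a set of genomes.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .iokit import (
    KOProfile,
    PresenceAbsenceMatrix,
    TaxonTable,
    ValidationError,
)

__all__ = [
    "CoreScreenResult",
    "CooccurrencePair",
    "CoverageResult",
    "compute_occupancy",
    "select_core",
    "occupancy_abundance",
    "pair_cooccurrence",
    "all_pair_cooccurrences",
    "consortium_copresence",
    "positive_pair_fraction",
    "core_kos",
    "ko_coverage",
]


@dataclass(frozen=True)
class CoreScreenResult:
    occupancy: dict[str, float]
    detection: float
    occupancy_min: float
    core_taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        for t, occ in self.occupancy.items():
            if not (0.0 <= occ <= 1.0):
                raise ValidationError(f"occupancy of {t!r} outside [0, 1]")
        expected = tuple(
            t for t, occ in self.occupancy.items() if occ >= self.occupancy_min
        )
        if tuple(self.core_taxa) != expected:
            raise ValidationError("core_taxa inconsistent with occupancy threshold")


@dataclass(frozen=True)
class CooccurrencePair:
    """Hypergeometric co-occurrence test for one unordered taxon pair.

    ``p_lt``/``p_gt`` are the lower/upper tail probabilities, both
    including P(j_obs), so they sum to >= 1.
    """

    taxa: tuple[str, str]
    n_samples: int
    n_a: int
    n_b: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    classification: str  # positive | negative | random | excluded

    def __post_init__(self) -> None:
        lo = max(0, self.n_a + self.n_b - self.n_samples)
        hi = min(self.n_a, self.n_b)
        if not (lo <= self.j_obs <= hi):
            raise ValidationError("observed co-presence outside feasible range")
        if self.expected < 0:
            raise ValidationError("expected co-presence must be >= 0")
        if self.p_lt + self.p_gt < 1.0 - 1e-9:
            raise ValidationError("tail probabilities must overlap at j_obs")
        if self.classification not in ("positive", "negative", "random", "excluded"):
            raise ValidationError(f"bad classification {self.classification!r}")


@dataclass(frozen=True)
class CoverageResult:
    core_ko_set: frozenset[str]
    consortium_kos: frozenset[str]
    coverage: float
    prevalence_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValidationError("coverage outside [0, 1]")


# ---------------------------------------------------------------------------
# occupancy / core selection
# ---------------------------------------------------------------------------


def compute_occupancy(table: TaxonTable, detection: float) -> dict[str, float]:
    """Fraction of samples in which each taxon is at or above ``detection``."""
    if detection < 0:
        raise ValidationError("detection threshold must be >= 0")
    detected = table.values >= detection
    occ = detected.sum(axis=1) / table.n_samples
    return {t: float(occ[i]) for i, t in enumerate(table.taxon_ids)}


def select_core(
    table: TaxonTable, detection: float = 0.0001, occupancy_min: float = 0.5
) -> CoreScreenResult:
    """Select core taxa: occupancy >= ``occupancy_min`` at >= ``detection``.

    Defaults reproduce the published screen settings (50% occupancy at a
    minimum relative abundance of 0.0001); both comparisons are inclusive.
    """
    if not (0.0 <= detection <= 1.0) or not (0.0 <= occupancy_min <= 1.0):
        raise ValidationError("thresholds must be in [0, 1]")
    occupancy = compute_occupancy(table, detection)
    core = tuple(t for t, occ in occupancy.items() if occ >= occupancy_min)
    return CoreScreenResult(
        occupancy=occupancy,
        detection=detection,
        occupancy_min=occupancy_min,
        core_taxa=core,
    )


def occupancy_abundance(
    table: TaxonTable, detection: float
) -> dict[str, tuple[float, float | None]]:
    """Per-taxon (occupancy, mean abundance over detected samples).

    A taxon never detected gets occupancy 0.0 and mean ``None`` (flagged
    missing rather than propagating NaN).
    """
    occupancy = compute_occupancy(table, detection)
    out: dict[str, tuple[float, float | None]] = {}
    for i, t in enumerate(table.taxon_ids):
        row = table.values[i]
        detected = row[row >= detection]
        mean = float(detected.mean()) if detected.size else None
        out[t] = (occupancy[t], mean)
    return out


# ---------------------------------------------------------------------------
# probabilistic co-occurrence
# ---------------------------------------------------------------------------


def pair_cooccurrence(
    pa: PresenceAbsenceMatrix,
    taxon_a: str,
    taxon_b: str,
    alpha: float = 0.05,
    min_expected: float = 1.0,
) -> CooccurrencePair:
    """Hypergeometric co-occurrence test for one taxon pair.

    Under the null, the ``n_b`` presences of B fall uniformly at random
    among the N samples independently of A's ``n_a`` presences, so the
    co-presence count j is hypergeometric. Pairs whose expected
    co-presence ``n_a * n_b / N`` falls below ``min_expected`` are
    classified ``excluded``; otherwise ``positive`` if the upper tail
    P(J >= j_obs) < alpha, ``negative`` if the lower tail < alpha, else
    ``random``. Symmetric in (A, B).
    """
    if taxon_a == taxon_b:
        raise ValidationError("co-occurrence needs two distinct taxa")
    taxa = list(pa.taxon_ids)
    missing = [t for t in (taxon_a, taxon_b) if t not in taxa]
    if missing:
        raise KeyError(f"taxa absent from matrix: {missing}")
    ia, ib = taxa.index(taxon_a), taxa.index(taxon_b)
    n = pa.n_samples
    row_a, row_b = pa.values[ia], pa.values[ib]
    n_a, n_b = int(row_a.sum()), int(row_b.sum())
    j_obs = int((row_a * row_b).sum())
    expected = n_a * n_b / n
    dist = hypergeom(n, n_a, n_b)
    p_lt = float(min(1.0, dist.cdf(j_obs)))
    p_gt = float(min(1.0, dist.sf(j_obs - 1)))
    if expected < min_expected:
        classification = "excluded"
    elif p_gt < alpha:
        classification = "positive"
    elif p_lt < alpha:
        classification = "negative"
    else:
        classification = "random"
    return CooccurrencePair(
        taxa=(taxon_a, taxon_b),
        n_samples=n,
        n_a=n_a,
        n_b=n_b,
        j_obs=j_obs,
        expected=expected,
        p_lt=p_lt,
        p_gt=p_gt,
        classification=classification,
    )


def all_pair_cooccurrences(
    pa: PresenceAbsenceMatrix,
    taxa: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_expected: float = 1.0,
    bh_correct: bool = False,
) -> list[CooccurrencePair]:
    """Test all unordered pairs among ``taxa`` (default: all matrix taxa).

    With ``bh_correct`` the smaller tail p-value of each non-excluded pair
    is Benjamini-Hochberg adjusted across pairs before classification
    (off by default, matching the cited model's convention of no
    multiple-testing correction).
    """
    if taxa is None:
        taxa = list(pa.taxon_ids)
    pairs = [
        pair_cooccurrence(pa, a, b, alpha=alpha, min_expected=min_expected)
        for i, a in enumerate(taxa)
        for b in taxa[i + 1 :]
    ]
    if not bh_correct:
        return pairs
    testable = [p for p in pairs if p.classification != "excluded"]
    if not testable:
        return pairs
    raw = np.array([min(p.p_lt, p.p_gt) for p in testable])
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        idx = order[rank_pos]
        running = min(running, raw[idx] * m / (rank_pos + 1))
        adj[idx] = running
    corrected: list[CooccurrencePair] = []
    it = iter(range(m))
    for p in pairs:
        if p.classification == "excluded":
            corrected.append(p)
            continue
        q = adj[next(it)]
        if q < alpha:
            cls = "positive" if p.p_gt <= p.p_lt else "negative"
        else:
            cls = "random"
        corrected.append(
            CooccurrencePair(
                taxa=p.taxa,
                n_samples=p.n_samples,
                n_a=p.n_a,
                n_b=p.n_b,
                j_obs=p.j_obs,
                expected=p.expected,
                p_lt=p.p_lt,
                p_gt=p.p_gt,
                classification=cls,
            )
        )
    return corrected


def consortium_copresence(
    pa: PresenceAbsenceMatrix, focal_taxa: Sequence[str]
) -> tuple[float, np.ndarray]:
    """Fraction of samples containing every focal taxon, plus per-sample richness."""
    if len(focal_taxa) == 0:
        raise ValidationError("focal taxon set must be nonempty")
    taxa = list(pa.taxon_ids)
    missing = [t for t in focal_taxa if t not in taxa]
    if missing:
        raise KeyError(f"focal taxa absent from matrix: {missing}")
    idx = [taxa.index(t) for t in focal_taxa]
    richness = pa.values[idx].sum(axis=0)
    fraction = float((richness == len(idx)).mean())
    return fraction, richness.astype(int)


def positive_pair_fraction(
    pairs: Iterable[CooccurrencePair], include_excluded: bool = False
) -> float:
    """Fraction of positively co-occurring pairs.

    The denominator counts non-excluded pairs by default; set
    ``include_excluded`` to count all pairs (the source text does not pin
    the denominator, so both are available). Returns NaN (flagged
    missing) when the denominator is empty.
    """
    pairs = list(pairs)
    denom = [
        p for p in pairs if include_excluded or p.classification != "excluded"
    ]
    if not denom:
        return math.nan
    positive = sum(1 for p in denom if p.classification == "positive")
    return positive / len(denom)


# ---------------------------------------------------------------------------
# KO coverage
# ---------------------------------------------------------------------------


def core_kos(profiles: Sequence[KOProfile], prevalence: float = 0.75) -> frozenset[str]:
    """KOs present (abundance > 0) in at least ``prevalence`` of the profiles."""
    if len(profiles) == 0:
        raise ValidationError("need at least one KO profile")
    if not (0.0 <= prevalence <= 1.0):
        raise ValidationError("prevalence must be in [0, 1]")
    counts: dict[str, int] = {}
    for profile in profiles:
        for ko in profile.support():
            counts[ko] = counts.get(ko, 0) + 1
    n = len(profiles)
    return frozenset(ko for ko, c in counts.items() if c / n >= prevalence)


def ko_coverage(
    core: Iterable[str],
    genomes: Sequence[KOProfile],
    prevalence_threshold: float | None = None,
) -> CoverageResult:
    """Fraction of the core KO set covered by the union of the genomes' KOs."""
    core = frozenset(core)
    if not core:
        raise ValidationError("core KO set must be nonempty")
    union: set[str] = set()
    for genome in genomes:
        union |= genome.support()
    coverage = len(core & union) / len(core)
    return CoverageResult(
        core_ko_set=core,
        consortium_kos=frozenset(union),
        coverage=coverage,
        prevalence_threshold=prevalence_threshold,
    )
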