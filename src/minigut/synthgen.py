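"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and a single
integer seed (one fresh ``numpy.random.default_rng`` per call, no global
state), and returns its ground truth alongside the data so downstream
recovery tests never read hidden state.

Models, deliberately minimal:

* abundance tables — per-taxon Bernoulli presence at a target
  prevalence, lognormal abundances for present cells, renormalized per
  sample;
* presence/absence with planted pairs — a planted pair is drawn jointly
  from the 2x2 distribution with marginals ``base_prob`` and co-presence
  probability ``base_prob**2 +/- strength`` (a mixture construction with
  analytically known pairwise probabilities);
* amplicon experiments — multinomial reads with expected share
  proportional to abundance x 16S copy number, plus a lognormal-noised
  qPCR total of sum(abundance x copy number); no chimera or error model;
* reaction universes with plantable cross-feeding, and expressed-KO
  subsets of genomes.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .iokit import (
    CopyNumberTable,
    KOProfile,
    PresenceAbsenceMatrix,
    QPCRTotals,
    Reaction,
    ReactionUniverse,
    TaxonTable,
    ValidationError,
)
from .quantprof import SpeciesCountTable

__all__ = [
    "CommunityTruth",
    "PlantedAssociation",
    "AmpliconExperiment",
    "taxon_id",
    "sample_id",
    "gen_abundance_table",
    "gen_presence_absence",
    "gen_ko_profiles",
    "gen_community_truth",
    "gen_amplicon_experiment",
    "gen_reaction_universe",
    "gen_crossfeeding_pair",
    "gen_expression_subset",
]


def taxon_id(i: int) -> str:
    return f"T{i + 1:04d}"


def sample_id(j: int) -> str:
    return f"S{j + 1:04d}"


@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth for one synthetic community sample.

    ``abundances`` are cell-scale absolute abundances. The amplicon
    read share of a species is proportional to abundance x copy number,
    and the qPCR ground truth is ``total_copies`` = sum(abundance x
    copy number). Because the profiling pipeline divides by copy number
    and rescales to the qPCR total, the quantity it can recover exactly
    is ``absolute_profile`` — the relative cell abundances scaled to
    ``total_copies`` — which is therefore the recovery target.
    """

    abundances: Mapping[str, float]
    copy_numbers: CopyNumberTable
    sequencing_depth: int
    seed: int | None = None

    def __post_init__(self) -> None:
        ab = {str(k): float(v) for k, v in dict(self.abundances).items()}
        if not ab:
            raise ValidationError("truth must contain at least one species")
        for sp, a in ab.items():
            if not (a > 0 and math.isfinite(a)):
                raise ValidationError(f"abundance of {sp!r} must be > 0")
            if sp not in self.copy_numbers:
                raise ValidationError(f"species {sp!r} missing a copy number")
        if int(self.sequencing_depth) < 1:
            raise ValidationError("sequencing depth must be >= 1")
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "sequencing_depth", int(self.sequencing_depth))

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(self.abundances)

    @property
    def total_copies(self) -> float:
        return sum(a * self.copy_numbers[s] for s, a in self.abundances.items())

    @property
    def expected_read_shares(self) -> dict[str, float]:
        w = {s: a * self.copy_numbers[s] for s, a in self.abundances.items()}
        total = sum(w.values())
        return {s: v / total for s, v in w.items()}

    @property
    def absolute_profile(self) -> dict[str, float]:
        total_cells = sum(self.abundances.values())
        return {
            s: a / total_cells * self.total_copies
            for s, a in self.abundances.items()
        }


@dataclass(frozen=True)
class PlantedAssociation:
    """A taxon pair with a shifted co-presence probability."""

    taxa: tuple[str, str]
    direction: str  # positive | negative
    strength: float

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValidationError("direction must be 'positive' or 'negative'")
        if not (0.0 <= self.strength <= 1.0):
            raise ValidationError("strength must be in [0, 1]")
        if self.taxa[0] == self.taxa[1]:
            raise ValidationError("planted pair needs two distinct taxa")


@dataclass(frozen=True)
class AmpliconExperiment:
    counts: SpeciesCountTable
    qpcr: QPCRTotals
    truth: CommunityTruth


# ---------------------------------------------------------------------------
# abundance tables / presence-absence
# ---------------------------------------------------------------------------


def gen_abundance_table(
    n_samples: int,
    n_taxa: int,
    prevalence: float | Sequence[float],
    lognormal_mean: float = 0.0,
    lognormal_sd: float = 1.0,
    seed: int = 0,
) -> TaxonTable:
    """Relative-abundance table with prevalence-structured zeros.

    Taxon i is present in each sample independently with probability
    ``prevalence[i]``; present cells draw lognormal abundances which are
    renormalized per sample to sum to 1 (a sample where every taxon is
    absent keeps an all-zero column).
    """
    if n_samples < 1 or n_taxa < 1:
        raise ValidationError("n_samples and n_taxa must be >= 1")
    prev = np.broadcast_to(np.asarray(prevalence, dtype=float), (n_taxa,)).copy()
    if np.any((prev < 0) | (prev > 1)):
        raise ValidationError("prevalence values must be in [0, 1]")
    rng = np.random.default_rng(seed)
    present = rng.random((n_taxa, n_samples)) < prev[:, None]
    raw = rng.lognormal(lognormal_mean, lognormal_sd, size=(n_taxa, n_samples))
    raw *= present
    sums = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), 0.0)
    return TaxonTable(
        sample_ids=tuple(sample_id(j) for j in range(n_samples)),
        taxon_ids=tuple(taxon_id(i) for i in range(n_taxa)),
        values=values,
    )


def _joint_probs(p: float, p11: float) -> np.ndarray:
    probs = np.array([p11, p - p11, p - p11, 1 - 2 * p + p11])
    if np.any(probs < -1e-12):
        raise ValidationError(
            f"infeasible co-presence probability {p11} for marginal {p}"
        )
    return np.clip(probs, 0.0, 1.0) / np.clip(probs, 0.0, 1.0).sum()


def gen_presence_absence(
    n_samples: int,
    n_taxa: int,
    base_prob: float,
    planted: Sequence[PlantedAssociation] = (),
    seed: int = 0,
) -> PresenceAbsenceMatrix:
    """Presence/absence matrix with optional planted pairwise associations.

    Unplanted taxa are independent Bernoulli(``base_prob``). Each planted
    pair keeps marginal ``base_prob`` but is drawn jointly with
    co-presence probability ``base_prob**2 + strength`` (positive) or
    ``base_prob**2 - strength`` (negative); infeasible strengths (any
    cell probability leaving [0, 1]) raise an error. A taxon may belong
    to at most one planted pair.
    """
    if n_samples < 1 or n_taxa < 1:
        raise ValidationError("n_samples and n_taxa must be >= 1")
    if not (0.0 < base_prob < 1.0):
        raise ValidationError("base_prob must be in (0, 1)")
    ids = [taxon_id(i) for i in range(n_taxa)]
    index = {t: i for i, t in enumerate(ids)}
    used: set[str] = set()
    for assoc in planted:
        for t in assoc.taxa:
            if t not in index:
                raise ValidationError(f"planted taxon {t!r} not among generated taxa")
            if t in used:
                raise ValidationError(f"taxon {t!r} appears in more than one planted pair")
            used.add(t)
    rng = np.random.default_rng(seed)
    values = (rng.random((n_taxa, n_samples)) < base_prob).astype(float)
    for assoc in planted:
        p11 = base_prob**2 + (
            assoc.strength if assoc.direction == "positive" else -assoc.strength
        )
        probs = _joint_probs(base_prob, p11)
        cells = rng.choice(4, size=n_samples, p=probs)
        ia, ib = index[assoc.taxa[0]], index[assoc.taxa[1]]
        values[ia] = np.isin(cells, (0, 1)).astype(float)
        values[ib] = np.isin(cells, (0, 2)).astype(float)
    return PresenceAbsenceMatrix(
        sample_ids=tuple(sample_id(j) for j in range(n_samples)),
        taxon_ids=tuple(ids),
        values=values,
    )


# ---------------------------------------------------------------------------
# KO profiles
# ---------------------------------------------------------------------------


def gen_ko_profiles(
    n_samples: int,
    n_core_kos: int,
    n_variable_kos: int,
    core_prev: float = 0.9,
    var_prev: float = 0.3,
    seed: int = 0,
) -> tuple[list[KOProfile], dict[str, frozenset[str]]]:
    """Per-sample KO presence profiles with labelled core/variable KOs.

    Core KOs appear in each sample with probability ``core_prev``,
    variable KOs with ``var_prev``. Returns the profiles and the truth
    labels ``{"core": ..., "variable": ...}``.
    """
    if n_samples < 1 or n_core_kos < 0 or n_variable_kos < 0:
        raise ValidationError("sizes must be positive")
    for p in (core_prev, var_prev):
        if not (0.0 <= p <= 1.0):
            raise ValidationError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    core = [f"K{i + 1:05d}" for i in range(n_core_kos)]
    variable = [f"K{n_core_kos + i + 1:05d}" for i in range(n_variable_kos)]
    profiles = []
    for j in range(n_samples):
        kos = [k for k in core if rng.random() < core_prev]
        kos += [k for k in variable if rng.random() < var_prev]
        profiles.append(KOProfile.from_set(sample_id(j), kos))
    truth = {"core": frozenset(core), "variable": frozenset(variable)}
    return profiles, truth


# ---------------------------------------------------------------------------
# amplicon experiments
# ---------------------------------------------------------------------------


def gen_community_truth(
    n_species: int,
    sequencing_depth: int = 100_000,
    seed: int = 0,
    abundance_lognormal_mean: float = 10.0,
    abundance_lognormal_sd: float = 1.0,
    max_copy_number: int = 10,
) -> CommunityTruth:
    """Random ground-truth community (lognormal abundances, random copy numbers)."""
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"SP{i + 1:03d}" for i in range(n_species)]
    abundances = {
        s: float(rng.lognormal(abundance_lognormal_mean, abundance_lognormal_sd))
        for s in species
    }
    cns = CopyNumberTable(
        {s: int(rng.integers(1, max_copy_number + 1)) for s in species}
    )
    return CommunityTruth(
        abundances=abundances,
        copy_numbers=cns,
        sequencing_depth=sequencing_depth,
        seed=seed,
    )


def gen_amplicon_experiment(
    truth: CommunityTruth,
    qpcr_cv: float = 0.0,
    seed: int = 0,
    exact: bool = False,
    sample: str = "S0001",
) -> AmpliconExperiment:
    """Simulate one amplicon + qPCR experiment from a known community.

    Reads are multinomial at ``truth.sequencing_depth`` with per-species
    probability proportional to abundance x copy number (so copy numbers
    distort the read shares by construction). The qPCR total is
    ``truth.total_copies`` perturbed by multiplicative lognormal noise
    with coefficient of variation ``qpcr_cv`` (mean-one noise). With
    ``exact=True`` the expected fractional counts replace the multinomial
    draw (the infinite-depth limit); combined with ``qpcr_cv=0`` the
    profiling pipeline recovers ``truth.absolute_profile`` exactly.
    """
    if qpcr_cv < 0:
        raise ValidationError("qpcr_cv must be >= 0")
    rng = np.random.default_rng(seed)
    species = list(truth.species_ids)
    shares = np.array([truth.expected_read_shares[s] for s in species])
    if exact:
        counts = shares * truth.sequencing_depth
    else:
        counts = rng.multinomial(truth.sequencing_depth, shares).astype(float)
    total = truth.total_copies
    if qpcr_cv > 0:
        sigma = math.sqrt(math.log(1.0 + qpcr_cv**2))
        total *= rng.lognormal(-0.5 * sigma**2, sigma)
    table = SpeciesCountTable(
        sample_ids=(sample,), species_ids=tuple(species), counts=counts[:, None]
    )
    return AmpliconExperiment(
        counts=table, qpcr=QPCRTotals({sample: total}), truth=truth
    )


# ---------------------------------------------------------------------------
# reaction universes and cross-feeding
# ---------------------------------------------------------------------------


def gen_reaction_universe(
    n_compounds: int,
    n_reactions: int,
    max_arity: int = 2,
    reversible_prob: float = 0.2,
    seed: int = 0,
) -> ReactionUniverse:
    """Random reaction universe over ``n_compounds`` compounds.

    Each reaction gets 1-2 private KOs, disjoint substrate/product sets
    of size 1..``max_arity``, and is reversible with probability
    ``reversible_prob``.
    """
    if n_compounds < 2 or n_reactions < 1 or max_arity < 1:
        raise ValidationError("need >= 2 compounds, >= 1 reaction, arity >= 1")
    rng = np.random.default_rng(seed)
    compounds = [f"C{i + 1:05d}" for i in range(n_compounds)]
    reactions = []
    next_ko = 1
    for r in range(n_reactions):
        n_sub = int(rng.integers(1, max_arity + 1))
        n_prod = int(rng.integers(1, max_arity + 1))
        picks = rng.choice(
            n_compounds, size=min(n_sub + n_prod, n_compounds), replace=False
        )
        subs = picks[:n_sub]
        prods = picks[n_sub:]
        if len(prods) == 0:  # degenerate split when the universe is tiny
            subs, prods = picks[:-1], picks[-1:]
        n_kos = int(rng.integers(1, 3))
        kos = [f"K{next_ko + i:05d}" for i in range(n_kos)]
        next_ko += n_kos
        reactions.append(
            Reaction(
                reaction_id=f"R{r + 1:05d}",
                ko_ids=frozenset(kos),
                substrates=frozenset(compounds[i] for i in subs),
                products=frozenset(compounds[i] for i in prods),
                reversible=bool(rng.random() < reversible_prob),
            )
        )
    return ReactionUniverse(tuple(reactions))


def gen_crossfeeding_pair(
    universe: ReactionUniverse, seed: int = 0
) -> tuple[KOProfile, KOProfile, dict]:
    """Plant a cross-feeding pair (A, B) in ``universe``.

    Searches for an irreversible reaction giving B an internally produced
    compound x, and a second reaction giving A x as a required input, so
    that x is a seed of A and a non-seed of B by construction. The
    returned certificate names x and the reactions used; the construction
    is verified with the seed-set engine before returning. Raises when
    the universe admits no such pair.
    """
    from . import revecol

    rng = np.random.default_rng(seed)
    producers = [
        r
        for r in universe.reactions
        if not r.reversible and r.products - r.substrates
    ]
    consumers = list(universe.reactions)
    rng.shuffle(producers)
    for r_b in producers:
        xs = sorted(r_b.products)
        rng.shuffle(xs)
        for x in xs:
            candidates = [
                r_a
                for r_a in consumers
                if r_a.reaction_id != r_b.reaction_id
                and x in r_a.substrates
                and x not in r_a.products
            ]
            rng.shuffle(candidates)
            for r_a in candidates:
                prof_a = KOProfile.from_set("orgA", r_a.ko_ids)
                prof_b = KOProfile.from_set("orgB", r_b.ko_ids)
                seeds_a = revecol.seed_set(revecol.build_network(prof_a, universe))
                seeds_b = revecol.seed_set(revecol.build_network(prof_b, universe))
                if x in seeds_a.seeds and x in seeds_b.nonseeds:
                    certificate = {
                        "compound": x,
                        "reaction_a": r_a.reaction_id,
                        "reaction_b": r_b.reaction_id,
                    }
                    return prof_a, prof_b, certificate
    raise ValidationError("universe too small to plant a cross-feeding pair")


def gen_expression_subset(
    genome: KOProfile,
    expressed_fraction: float,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> KOProfile:
    """Counts-mode transcript profile over a subset of a genome's KOs.

    Samples ``round(expressed_fraction * |genome|)`` KOs (at least one)
    without replacement, optionally biased by ``weights``, and assigns
    each a positive count. The expressed KO set is always a subset of the
    genome's KO support.
    """
    if not (0.0 < expressed_fraction <= 1.0):
        raise ValidationError("expressed_fraction must be in (0, 1]")
    support = sorted(genome.support())
    if not support:
        raise ValidationError("genome profile has no KOs")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(expressed_fraction * len(support))))
    k = min(k, len(support))
    if weights is not None:
        w = np.array([max(0.0, float(weights.get(ko, 0.0))) for ko in support])
        if w.sum() <= 0:
            raise ValidationError("weights must give positive total mass")
        p = w / w.sum()
        n_positive = int((p > 0).sum())
        if n_positive < k:  # not enough weighted KOs: top up uniformly
            chosen = list(np.array(support)[p > 0])
            rest = [ko for ko in support if ko not in chosen]
            extra = rng.choice(len(rest), size=k - len(chosen), replace=False)
            chosen += [rest[i] for i in extra]
        else:
            chosen = list(
                np.array(support)[rng.choice(len(support), size=k, replace=False, p=p)]
            )
    else:
        chosen = list(
            np.array(support)[rng.choice(len(support), size=k, replace=False)]
        )
    counts = {ko: float(rng.integers(1, 50)) for ko in chosen}
    return KOProfile(unit_id=genome.unit_id, kos=counts, mode="counts")
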