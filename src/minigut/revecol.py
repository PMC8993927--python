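"""Reverse-ecology engine: metabolic networks, seed sets, interaction indices.

A KO set plus a reaction universe yields a directed compound graph (a
reaction is included when ANY of its KOs is present; reversible
reactions contribute edges in both directions). Seed compounds are the
members of the source components of the graph's condensation — the
strongly connected components with condensation in-degree 0 — i.e. the
metabolites the organism must acquire from its environment. Each seed's
confidence is 1/|its component|, so confidences sum to 1 within a source
component. Non-seeds are all remaining compounds (internally
producible).

Pairwise indices (asymmetric, reported as (focal A, partner B) with A
owning the numerator):

* competition(A, B)      = |seeds(A) ∩ seeds(B)|    / |seeds(A)|
* complementarity(A, B)  = |seeds(A) ∩ nonseeds(B)| / |seeds(A)|

``weighted=True`` replaces cardinalities with sums of A's seed
confidences. Both variants lie in [0, 1]; for any organism with at least
one seed, competition with itself is 1 and complementarity 0.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx

from .iokit import KOProfile, ReactionUniverse, ValidationError

__all__ = [
    "MetabolicNetwork",
    "SeedSet",
    "InteractionIndices",
    "build_network",
    "seed_set",
    "competition_index",
    "complementarity_index",
    "expressed_kos",
    "pairwise_matrix",
    "indices_to_frame",
]


@dataclass(frozen=True)
class MetabolicNetwork:
    """Directed compound graph derived from (KO set, reaction universe)."""

    organism_id: str
    graph: nx.DiGraph
    source_kos: frozenset[str]

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


@dataclass(frozen=True)
class SeedSet:
    """Seed compounds with confidences, and the complementary non-seed set."""

    organism_id: str
    seeds: Mapping[str, float]
    nonseeds: frozenset[str]

    def __post_init__(self) -> None:
        seeds = {str(c): float(w) for c, w in dict(self.seeds).items()}
        nonseeds = frozenset(map(str, self.nonseeds))
        for c, w in seeds.items():
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"seed confidence of {c!r} outside (0, 1]")
        if set(seeds) & nonseeds:
            raise ValidationError("seed and non-seed sets must be disjoint")
        object.__setattr__(self, "seeds", seeds)
        object.__setattr__(self, "nonseeds", nonseeds)

    @property
    def seed_compounds(self) -> frozenset[str]:
        return frozenset(self.seeds)

    @property
    def compounds(self) -> frozenset[str]:
        return self.seed_compounds | self.nonseeds


@dataclass(frozen=True)
class InteractionIndices:
    focal: str
    partner: str
    competition: float
    complementarity: float
    basis: str  # genome | expressed

    def __post_init__(self) -> None:
        for name, v in (
            ("competition", self.competition),
            ("complementarity", self.complementarity),
        ):
            if not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} index outside [0, 1]: {v}")


# ---------------------------------------------------------------------------
# network construction and seed detection
# ---------------------------------------------------------------------------


def build_network(
    kos: KOProfile | Iterable[str],
    universe: ReactionUniverse,
    organism_id: str | None = None,
    exclude_compounds: Iterable[str] = (),
) -> MetabolicNetwork:
    """Build the compound graph for one organism.

    A reaction is included iff the organism carries any of its KOs (OR
    semantics over ortholog annotations); every substrate -> product pair
    becomes an edge, with the reverse edges added for reversible
    reactions. ``exclude_compounds`` (e.g. a currency-metabolite
    blacklist) removes compounds before edges are formed. Compounds only
    ever enter via edges, so isolated compounds never appear. An empty
    result is returned as a flagged-empty network, not an error.
    """
    if isinstance(kos, KOProfile):
        ko_set = kos.support()
        oid = organism_id if organism_id is not None else kos.unit_id
    else:
        ko_set = frozenset(kos)
        oid = organism_id if organism_id is not None else "organism"
    excluded = frozenset(exclude_compounds)
    graph = nx.DiGraph()
    for reaction in universe.reactions:
        if not (ko_set & reaction.ko_ids):
            continue
        subs = reaction.substrates - excluded
        prods = reaction.products - excluded
        for s in subs:
            for p in prods:
                graph.add_edge(s, p)
                if reaction.reversible:
                    graph.add_edge(p, s)
    return MetabolicNetwork(organism_id=oid, graph=graph, source_kos=ko_set)


def seed_set(net: MetabolicNetwork) -> SeedSet:
    """Seed detection via condensation.

    Seeds are all compounds lying in strongly connected components whose
    condensation in-degree is 0; each such compound's confidence is
    1/|component|. An empty network yields an empty seed set.
    """
    if net.is_empty:
        return SeedSet(organism_id=net.organism_id, seeds={}, nonseeds=frozenset())
    cond = nx.condensation(net.graph)
    seeds: dict[str, float] = {}
    nonseeds: set[str] = set()
    for comp_id, data in cond.nodes(data=True):
        members = data["members"]
        if cond.in_degree(comp_id) == 0:
            conf = 1.0 / len(members)
            for c in members:
                seeds[c] = conf
        else:
            nonseeds.update(members)
    return SeedSet(organism_id=net.organism_id, seeds=seeds, nonseeds=frozenset(nonseeds))


# ---------------------------------------------------------------------------
# interaction indices
# ---------------------------------------------------------------------------


def competition_index(a: SeedSet, b: SeedSet, weighted: bool = False) -> float:
    """Fraction of A's seeds shared with B's seeds (resource overlap).

    Returns NaN (flagged undefined) when A has no seeds.
    """
    if not a.seeds:
        return math.nan
    shared = a.seed_compounds & b.seed_compounds
    if weighted:
        return sum(a.seeds[c] for c in shared) / sum(a.seeds.values())
    return len(shared) / len(a.seeds)


def complementarity_index(a: SeedSet, b: SeedSet, weighted: bool = False) -> float:
    """Fraction of A's seeds that B produces internally (B-to-A cross-feeding).

    Returns NaN (flagged undefined) when A has no seeds.
    """
    if not a.seeds:
        return math.nan
    fed = a.seed_compounds & b.nonseeds
    if weighted:
        return sum(a.seeds[c] for c in fed) / sum(a.seeds.values())
    return len(fed) / len(a.seeds)


def expressed_kos(expr: KOProfile, min_count: float = 1) -> KOProfile:
    """Reduce a counts-mode transcript profile to the actively expressed KO set.

    A KO is retained when its count is >= ``min_count`` (default 1 mapped
    read; configurable because "actively expressed" has no canonical
    threshold).
    """
    if expr.mode not in ("counts", "cpm"):
        raise ValidationError("expressed_kos expects a counts- or cpm-mode profile")
    return KOProfile.from_set(
        expr.unit_id, {k for k, v in expr.kos.items() if v >= min_count}
    )


def pairwise_matrix(
    organisms: Sequence[KOProfile],
    universe: ReactionUniverse,
    basis: str = "genome",
    weighted: bool = False,
    min_count: float = 1,
    exclude_compounds: Iterable[str] = (),
) -> list[InteractionIndices]:
    """Indices for all ordered organism pairs (including self pairs).

    ``basis="genome"`` uses each profile's KO support directly;
    ``basis="expressed"`` first thresholds counts-mode profiles at
    ``min_count``. Organisms whose network is empty yield NaN-flagged
    rows wherever they are the focal or partner organism.
    """
    if basis not in ("genome", "expressed"):
        raise ValidationError("basis must be 'genome' or 'expressed'")
    if len(organisms) < 2:
        raise ValidationError("need at least two organisms")
    ids = [o.unit_id for o in organisms]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate organism ids")
    seeds: dict[str, SeedSet] = {}
    for org in organisms:
        profile = expressed_kos(org, min_count) if basis == "expressed" else org
        net = build_network(profile, universe, exclude_compounds=exclude_compounds)
        seeds[org.unit_id] = seed_set(net)
    out: list[InteractionIndices] = []
    for fa in ids:
        for fb in ids:
            a, b = seeds[fa], seeds[fb]
            out.append(
                InteractionIndices(
                    focal=fa,
                    partner=fb,
                    competition=competition_index(a, b, weighted=weighted),
                    complementarity=complementarity_index(a, b, weighted=weighted),
                    basis=basis,
                )
            )
    return out


def indices_to_frame(indices: Sequence[InteractionIndices]):
    """Long-format table (focal, partner, basis, competition, complementarity)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "focal": x.focal,
                "partner": x.partner,
                "basis": x.basis,
                "competition": x.competition,
                "complementarity": x.complementarity,
            }
            for x in indices
        ]
    )
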