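"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: seed sets
via definitional pairwise reachability, hypergeometric tails via
exhaustive subset enumeration, and summaries via naive loops.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from minigut import iokit


# ---------------------------------------------------------------------------
# oracle: seed sets by definition (pairwise reachability)
# ---------------------------------------------------------------------------


def reachability(edges: set[tuple[str, str]], nodes: set[str]) -> dict[str, set[str]]:
    """reach[v] = set of nodes reachable from v (including v), by BFS."""
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
    reach: dict[str, set[str]] = {}
    for start in nodes:
        seen = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        reach[start] = seen
    return reach


def brute_force_seeds(
    edges: set[tuple[str, str]], nodes: set[str]
) -> tuple[dict[str, float], set[str]]:
    """Definitional seed computation.

    c is a seed iff every vertex that reaches c is mutually reachable
    from c; its confidence is 1 / |SCC(c)|.
    """
    reach = reachability(edges, nodes)
    seeds: dict[str, float] = {}
    nonseeds: set[str] = set()
    for c in nodes:
        scc = {v for v in nodes if c in reach[v] and v in reach[c]}
        ancestors = {v for v in nodes if c in reach[v]}
        if ancestors <= scc:
            seeds[c] = 1.0 / len(scc)
        else:
            nonseeds.add(c)
    return seeds, nonseeds


def random_digraph(rng: np.random.Generator, max_nodes: int = 12):
    """Random digraph as (edges, nodes) with at least one edge."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = {f"c{i}" for i in range(n)}
    p = rng.uniform(0.05, 0.4)
    edges = {
        (f"c{i}", f"c{j}")
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }
    if not edges:
        i, j = rng.choice(n, size=2, replace=False)
        edges = {(f"c{i}", f"c{j}")}
    nodes = {v for e in edges for v in e}
    return edges, nodes


# ---------------------------------------------------------------------------
# oracle: hypergeometric co-presence distribution by exhaustive enumeration
# ---------------------------------------------------------------------------


def enumerate_copresence_pmf(n: int, n_a: int, n_b: int) -> dict[int, float]:
    """P(|A ∩ B| = j) by enumerating every placement of B's presences.

    By symmetry A is fixed to the first ``n_a`` samples; all C(n, n_b)
    placements of B are enumerated and intersection sizes counted.
    """
    a = set(range(n_a))
    counts: Counter[int] = Counter()
    total = 0
    for b in itertools.combinations(range(n), n_b):
        counts[len(a & set(b))] += 1
        total += 1
    return {j: c / total for j, c in counts.items()}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table() -> iokit.TaxonTable:
    values = np.array(
        [
            [0.5, 0.2, 0.0],
            [0.3, 0.0, 0.6],
            [0.2, 0.8, 0.4],
        ]
    )
    return iokit.TaxonTable(
        sample_ids=("s1", "s2", "s3"),
        taxon_ids=("tA", "tB", "tC"),
        values=values,
    )


def random_taxon_table(rng: np.random.Generator, n_taxa=6, n_samples=8) -> iokit.TaxonTable:
    raw = rng.random((n_taxa, n_samples)) * (rng.random((n_taxa, n_samples)) < 0.7)
    sums = raw.sum(axis=0)
    sums[sums == 0] = 1.0
    return iokit.TaxonTable(
        sample_ids=tuple(f"s{j}" for j in range(n_samples)),
        taxon_ids=tuple(f"t{i}" for i in range(n_taxa)),
        values=raw / sums,
    )
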