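"""Backward-time coalescent simulator with instantaneous admixture.

Demographic model: two parental populations A and B diverged from a common
ancestor at time ``t1`` (coalescent units of 2·N_e generations).  At time
``t2 < t1`` the ancestors of A and B hybridized to found population H.
Tracing a sampled H lineage backward, at ``t2`` it joins the ancestral
population of B with probability ``gamma`` (the hybridization frequency)
and of A otherwise.  Within each population lineages coalesce as a standard
Kingman coalescent (rate ``C(k, 2)`` for ``k`` lineages); populations are
isolated between the admixture/divergence events and all population sizes
are equal.

Mutations follow the infinite-sites model: per locus the number of
mutations is Poisson with mean ``theta/2 ×`` total branch length, each
mutation lands uniformly at random on the genealogy and defines one
biallelic site whose derived-allele carriers are the leaves below it.
Loci are unlinked (an independent genealogy each) and sites within a locus
are completely linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import HaploidAlignment

__all__ = [
    "SimParams",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_alignment",
]

# Interpretive constants behind the coalescent time scale: the divergence
# time t1 = 3.0 corresponds to ~1.5 My at 2 generations/year with haploid
# effective size N_e = 2.5e5 (documentation only; the simulation runs
# entirely in coalescent units).
NE_INTERPRETATION = 2.5e5
GENERATIONS_PER_YEAR = 2.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of the three-population admixture coalescent.

    ``t1``/``t2`` are the divergence and hybridization times in coalescent
    units; ``gamma`` is the probability that a backward-traced H lineage
    joins ancestral B at ``t2``; ``theta_per_locus`` is the population-
    scaled mutation rate per locus; ``locus_length_bp`` is coordinate
    bookkeeping only (infinite sites never saturates a locus).
    """

    t1: float = 3.0
    t2: float = 2.0
    gamma: float = 0.5
    theta_per_locus: float = 25.0
    num_loci: int = 10
    locus_length_bp: int = 250
    n_A: int = 100
    n_B: int = 100
    n_H: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 < self.t2 < self.t1:
            raise ValueError("require 0 < t2 < t1")
        if self.theta_per_locus <= 0:
            raise ValueError("theta_per_locus must be positive")
        if min(self.n_A, self.n_B, self.n_H) < 0 or self.n_total < 2:
            raise ValueError("need at least two sampled lineages")
        if self.num_loci < 1 or self.locus_length_bp < 1:
            raise ValueError("num_loci and locus_length_bp must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_A + self.n_B + self.n_H


@dataclass
class Genealogy:
    """Rooted binary genealogy of one non-recombining locus.

    Nodes ``0 .. n-1`` are leaves (time 0); internal nodes are appended in
    coalescence order.  ``parent[root] == -1``.  ``leaf_population`` labels
    each leaf A/B/H; ``h_origin`` records, for each H leaf, whether its
    lineage entered ancestral A or ancestral B at the admixture time.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_population: list[str]
    h_origin: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> list[np.ndarray]:
        """Sorted leaf descendants of every node (leaves include themselves)."""
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for leaf in range(self.n_leaves):
            sets[leaf] = [leaf]
        # children appear before parents by construction, so one forward
        # pass over non-root nodes accumulates descendant sets bottom-up
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0:
                sets[p].extend(sets[node])
        return [np.array(sorted(s), dtype=np.int64) for s in sets]

    def tmrca(self) -> float:
        return float(self.time[self.root])


def _coalesce_epoch(
    groups: list[list[int]],
    t_start: float,
    t_end: float,
    next_node: int,
    parent: list[int],
    time: list[float],
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Run independent Kingman coalescents in each group until ``t_end``."""
    t = t_start
    while True:
        rates = np.array([len(g) * (len(g) - 1) / 2.0 for g in groups])
        total = rates.sum()
        if total == 0.0:
            return t_end, next_node
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_end:
            return t_end, next_node
        t = t_next
        g = groups[rng.choice(len(groups), p=rates / total)]
        i, j = rng.choice(len(g), size=2, replace=False)
        a, b = g[i], g[j]
        parent.append(-1)
        time.append(t)
        parent[a] = parent[b] = next_node
        for idx in sorted((i, j), reverse=True):
            g.pop(idx)
        g.append(next_node)
        next_node += 1


def simulate_genealogy(params: SimParams, rng: np.random.Generator) -> Genealogy:
    """Simulate one locus genealogy under the admixture coalescent.

    Epochs, backward in time: ``[0, t2)`` three isolated populations
    (A, B, H); at ``t2`` every surviving H lineage is reassigned to
    ancestral B with probability ``gamma`` (else ancestral A); ``[t2, t1)``
    two populations; from ``t1`` one population until the MRCA.
    """
    n = params.n_total
    leaf_population = (
        ["A"] * params.n_A + ["B"] * params.n_B + ["H"] * params.n_H
    )
    parent: list[int] = [-1] * n
    time: list[float] = [0.0] * n

    group_a = list(range(params.n_A))
    group_b = list(range(params.n_A, params.n_A + params.n_B))
    group_h = list(range(params.n_A + params.n_B, n))

    t, nxt = _coalesce_epoch(
        [group_a, group_b, group_h], 0.0, params.t2, n, parent, time, rng
    )

    # instantaneous admixture: each surviving H lineage picks a parental
    # ancestral population; the choice is inherited by all H leaves below
    h_assignment: list[tuple[int, str]] = []
    for lineage in group_h:
        origin = "B" if rng.random() < params.gamma else "A"
        h_assignment.append((lineage, origin))
        (group_b if origin == "B" else group_a).append(lineage)

    t, nxt = _coalesce_epoch(
        [group_a, group_b], t, params.t1, nxt, parent, time, rng
    )
    t, nxt = _coalesce_epoch(
        [group_a + group_b], t, np.inf, nxt, parent, time, rng
    )

    g = Genealogy(
        n_leaves=n,
        parent=np.array(parent, dtype=np.int64),
        time=np.array(time, dtype=float),
        leaf_population=leaf_population,
    )
    # propagate origins from the lineages alive at t2 down to H leaves
    sets = g.leaf_sets()
    for lineage, origin in h_assignment:
        for leaf in sets[lineage]:
            if leaf_population[leaf] == "H":
                g.h_origin[int(leaf)] = origin
    return g


def drop_mutations(
    g: Genealogy, theta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations on a genealogy.

    Returns ``(columns, positions)`` where ``columns`` is an
    ``(n_leaves, S)`` binary matrix (one column per mutation, carriers of
    the derived allele = leaves below the mutated branch) and ``positions``
    are sorted fractional positions in ``[0, 1)``.  ``S`` is Poisson with
    mean ``theta/2 ×`` total branch length.
    """
    lengths = g.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total) if total > 0 else 0
    positions = np.sort(rng.uniform(size=n_mut))
    columns = np.zeros((g.n_leaves, n_mut), dtype=np.int8)
    if n_mut:
        sets = g.leaf_sets()
        branches = rng.choice(g.n_nodes, size=n_mut, p=lengths / total)
        for s, node in enumerate(branches):
            columns[sets[node], s] = 1
    return columns, positions


def simulate_alignment(params: SimParams, rng=None) -> HaploidAlignment:
    """Simulate a full multi-locus alignment.

    Each locus draws an independent genealogy and mutations from its own
    deterministic substream of ``params.seed``, so loci are independent and
    the whole alignment is reproducible from the seed.  A locus with zero
    segregating sites is redrawn up to 100 times.
    """
    if rng is None:
        ss = np.random.SeedSequence(params.seed)
    elif isinstance(rng, np.random.SeedSequence):
        ss = rng
    else:  # a Generator: derive a child seed so loci still get substreams
        ss = np.random.SeedSequence(int(rng.integers(2**31)))
    locus_streams = ss.spawn(params.num_loci)

    blocks: list[np.ndarray] = []
    pos_blocks: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    locus_index: list[int] = []
    site_ids: list[str] = []
    start = 0
    for loc, child in enumerate(locus_streams):
        locus_rng = np.random.default_rng(child)
        for _ in range(100):
            genealogy = simulate_genealogy(params, locus_rng)
            cols, pos = drop_mutations(genealogy, params.theta_per_locus, locus_rng)
            if cols.shape[1] > 0:
                break
        else:
            raise RuntimeError(
                f"locus {loc}: no segregating sites after 100 redraws"
            )
        blocks.append(cols)
        pos_blocks.append(pos)
        k_loc = cols.shape[1]
        bounds.append((start, start + k_loc))
        locus_index.extend([loc] * k_loc)
        site_ids.extend(f"L{loc:02d}_S{j:03d}" for j in range(k_loc))
        start += k_loc

    sample_ids = (
        [f"A{i:03d}" for i in range(params.n_A)]
        + [f"B{i:03d}" for i in range(params.n_B)]
        + [f"H{i:03d}" for i in range(params.n_H)]
    )
    populations = (
        ["A"] * params.n_A + ["B"] * params.n_B + ["H"] * params.n_H
    )
    return HaploidAlignment(
        genotypes=np.concatenate(blocks, axis=1),
        sample_ids=sample_ids,
        populations=populations,
        site_ids=site_ids,
        locus_index=np.array(locus_index, dtype=np.int64),
        positions=np.concatenate(pos_blocks),
        locus_bounds=bounds,
    )
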