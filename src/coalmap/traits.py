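"""Quantitative-trait simulation with additive causal SNPs.

The trait of sample *i* is

    y_i = pi * sum_{j in Delta} Q_ij / |Delta| + (1 - pi) * e_i,
    e_i ~ N(0, 0.01)  (variance 0.01, i.e. s.d. 0.1),

where ``Delta`` is a set of causal SNPs (20 by default) drawn uniformly at
random from the eligible sites (minor allele frequency in [0.1, 0.3]) of
one, two, or all loci, and ``Q_ij`` indicates whether sample *i* carries
the derived allele at site *j*.  ``pi`` is the proportion of trait
variation contributed by genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import HaploidAlignment

__all__ = [
    "CONDITIONS",
    "TraitRealization",
    "InsufficientEligibleSNPsError",
    "select_causal_snps",
    "simulate_trait",
    "simulate_trait_realization",
]

CONDITIONS = ("single", "two", "all")
ENV_VARIANCE = 0.01  # variance of the environmental term N(0, 0.01)
_LOCUS_REDRAWS = 20  # attempts at drawing loci with enough eligible sites


class InsufficientEligibleSNPsError(ValueError):
    """Raised when no locus draw provides enough MAF-eligible sites."""


@dataclass
class TraitRealization:
    """A simulated phenotype together with its generating ground truth."""

    y: np.ndarray
    delta: np.ndarray  # causal site indices (column indices into genotypes)
    pi: float
    condition: str
    causal_loci: np.ndarray  # locus indices the causal SNPs were drawn from


def select_causal_snps(
    aln: HaploidAlignment,
    condition: str,
    count: int = 20,
    maf_lo: float = 0.1,
    maf_hi: float = 0.3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the causal set Delta for a trait architecture.

    ``condition`` selects how many loci contribute: ``"single"`` (one locus
    chosen uniformly at random), ``"two"`` (two distinct loci), or
    ``"all"``.  The ``count`` causal sites are then drawn uniformly without
    replacement from the eligible sites (MAF in ``[maf_lo, maf_hi]``,
    computed jointly over all samples) of the chosen loci.

    Returns ``(delta, causal_loci)`` with ``delta`` sorted.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng() if rng is None else rng
    maf = aln.minor_allele_freqs()
    eligible = (maf >= maf_lo) & (maf <= maf_hi)
    loci = np.unique(aln.locus_index)

    if condition == "all":
        pool = np.flatnonzero(eligible)
        if pool.size < count:
            raise InsufficientEligibleSNPsError(
                f"all loci together have {pool.size} eligible SNPs; need {count}"
            )
        delta = np.sort(rng.choice(pool, size=count, replace=False))
        return delta, loci

    n_loci = 1 if condition == "single" else 2
    if loci.size < n_loci:
        raise InsufficientEligibleSNPsError(
            f"alignment has {loci.size} loci; condition {condition!r} needs {n_loci}"
        )
    last_pool_size = -1
    last_choice = loci[:n_loci]
    for _ in range(_LOCUS_REDRAWS):
        chosen = rng.choice(loci, size=n_loci, replace=False)
        pool = np.flatnonzero(eligible & np.isin(aln.locus_index, chosen))
        if pool.size >= count:
            delta = np.sort(rng.choice(pool, size=count, replace=False))
            return delta, np.sort(chosen)
        last_pool_size, last_choice = pool.size, chosen
    raise InsufficientEligibleSNPsError(
        f"loci {sorted(int(l) for l in last_choice)} have only "
        f"{last_pool_size} eligible SNPs (MAF in [{maf_lo}, {maf_hi}]); "
        f"need {count}"
    )


def simulate_trait(
    aln: HaploidAlignment,
    delta: np.ndarray,
    pi: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Realize the additive trait for a fixed causal set."""
    delta = np.asarray(delta, dtype=np.int64)
    if delta.size == 0:
        raise ValueError("causal set Delta is empty")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    genetic = aln.genotypes[:, delta].mean(axis=1)
    noise = rng.normal(0.0, np.sqrt(ENV_VARIANCE), size=aln.n_samples)
    return pi * genetic + (1.0 - pi) * noise


def simulate_trait_realization(
    aln: HaploidAlignment,
    condition: str,
    pi: float = 0.9,
    count: int = 20,
    maf_lo: float = 0.1,
    maf_hi: float = 0.3,
    rng: np.random.Generator | None = None,
) -> TraitRealization:
    """Draw causal SNPs and a phenotype in one step."""
    rng = np.random.default_rng() if rng is None else rng
    delta, causal_loci = select_causal_snps(
        aln, condition, count=count, maf_lo=maf_lo, maf_hi=maf_hi, rng=rng
    )
    y = simulate_trait(aln, delta, pi, rng)
    return TraitRealization(
        y=y, delta=delta, pi=pi, condition=condition, causal_loci=causal_loci
    )
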