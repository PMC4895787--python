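"""Core in-memory container for haploid biallelic alignments.

The whole package operates on an *n* samples × *k* sites binary genotype
matrix (0 = ancestral allele, 1 = derived allele).  Sites are ordered by
(locus, fractional position); simulated alignments additionally carry the
true locus boundaries so that evaluation code can compare inferred
partitions against the generating loci.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_SITE_ID_RE = re.compile(r"^L(\d+)_S(\d+)$")


@dataclass
class HaploidAlignment:
    """Binary haploid genotype alignment with per-site metadata.

    Parameters
    ----------
    genotypes
        ``(n, k)`` array with entries in {0, 1}; rows are samples,
        columns are segregating sites.
    sample_ids
        Unique sample identifiers, length ``n``.
    populations
        Optional population label per sample (e.g. ``"A"``/``"B"``/``"H"``).
    site_ids
        Site identifiers, length ``k``.  Simulated data uses the pattern
        ``L<locus>_S<index>``.
    locus_index
        Integer locus index per site (0-based).
    positions
        Fractional position of each site within its locus, in ``[0, 1)``.
    locus_bounds
        True locus boundaries as 0-based half-open ``(start, end)`` site
        ranges — available for simulated data only.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    populations: list[str] | None = None
    site_ids: list[str] = field(default_factory=list)
    locus_index: np.ndarray | None = None
    positions: np.ndarray | None = None
    locus_bounds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, k = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length mismatch")
        if not self.site_ids:
            self.site_ids = [f"S{j}" for j in range(k)]
        if len(self.site_ids) != k:
            raise ValueError(f"{len(self.site_ids)} site ids for {k} columns")
        bad = ~np.isin(self.genotypes, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary genotype at sample {self.sample_ids[i]!r}, "
                f"site {self.site_ids[j]!r}"
            )
        if self.locus_index is None:
            self.locus_index = self._loci_from_site_ids()
        self.locus_index = np.asarray(self.locus_index, dtype=np.int64)
        if self.positions is None:
            # evenly spaced placeholder positions within each locus
            self.positions = np.zeros(k)
            for loc in np.unique(self.locus_index):
                idx = np.flatnonzero(self.locus_index == loc)
                self.positions[idx] = (np.arange(idx.size) + 0.5) / max(idx.size, 1)
        self.positions = np.asarray(self.positions, dtype=float)

    def _loci_from_site_ids(self) -> np.ndarray:
        loci = np.zeros(self.n_sites, dtype=np.int64)
        for j, sid in enumerate(self.site_ids):
            m = _SITE_ID_RE.match(sid)
            if m is None:
                return np.zeros(self.n_sites, dtype=np.int64)
            loci[j] = int(m.group(1))
        return loci

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def derived_freqs(self) -> np.ndarray:
        """Derived-allele frequency per site."""
        return self.genotypes.mean(axis=0)

    def minor_allele_freqs(self) -> np.ndarray:
        """Minor-allele frequency per site, folded at 0.5."""
        f = self.derived_freqs()
        return np.minimum(f, 1.0 - f)
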