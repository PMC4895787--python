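"""Principal-component covariates for global and local sample structure.

Genotypes are standardized EIGENSTRAT-style (per site subtract the derived
allele frequency p and divide by sqrt(p(1-p)); haploid 0/1 dosage).  For a
test SNP in local partition X_l, the *global* covariates are the top five
PC scores computed on all sites outside X_l, and the *local* covariates
the top (up to) five PC scores of X_l itself; their concatenation is the
"glocal" covariate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import HaploidAlignment
from .partition import PartitionSet

__all__ = [
    "CovariateBundle",
    "normalize_genotypes",
    "top_pcs",
    "build_covariates",
    "full_alignment_pcs",
    "CovariateBuilder",
]

_RANK_TOL = 1e-10


@dataclass
class CovariateBundle:
    """Global / local / concatenated PC covariates for one partition."""

    W_global: np.ndarray
    W_local: np.ndarray
    partition_id: int

    @property
    def W_glocal(self) -> np.ndarray:
        return np.column_stack([self.W_global, self.W_local])


def normalize_genotypes(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EIGENSTRAT standardization of a binary genotype matrix.

    Per column: subtract the allele frequency estimate ``p`` and divide by
    ``sqrt(p(1-p))``.  Monomorphic columns are dropped.  Returns the
    normalized matrix and the indices of the kept columns.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 samples")
    p = G.mean(axis=0)
    keep = np.flatnonzero((p > 0) & (p < 1))
    if keep.size < 2:
        raise ValueError("fewer than 2 polymorphic columns")
    p = p[keep]
    M = (G[:, keep] - p) / np.sqrt(p * (1.0 - p))
    return M, keep


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    if U.size == 0:
        return U
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def top_pcs(M: np.ndarray, m: int) -> np.ndarray:
    """Top-``m`` sample PC scores of a column-centred matrix.

    Returns the leading left singular vectors of ``M`` (equivalently the
    top eigenvectors of the n×n sample covariance), ordered by decreasing
    singular value.  If the rank of ``M`` is below ``m`` only rank-many
    columns are returned, with a warning.
    """
    M = np.asarray(M, dtype=float)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    if rank < m:
        warnings.warn(
            f"requested {m} PCs but matrix rank is {rank}; returning {rank}",
            stacklevel=2,
        )
    m_eff = min(m, rank)
    return _fix_signs(U[:, :m_eff])


def _pcs_from_gram(C: np.ndarray, m: int) -> np.ndarray:
    """Top-``m`` eigenvectors of a Gram matrix ``C = M M^T`` (scores)."""
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    top = vals[0] if vals.size else 0.0
    rank = int(np.sum(vals > max(top, 0.0) * _RANK_TOL**2 + 1e-12))
    m_eff = min(m, rank)
    return _fix_signs(vecs[:, :m_eff])


def full_alignment_pcs(aln: HaploidAlignment, m: int = 10) -> np.ndarray:
    """Top-``m`` PC scores of the whole alignment (EIGENSTRAT baseline)."""
    M, _ = normalize_genotypes(aln.genotypes)
    return top_pcs(M, m)


class CovariateBuilder:
    """Caches per-partition covariate bundles for one dataset.

    The global PCA excludes the local partition, so each partition needs
    its own decomposition; the builder computes the full Gram matrix
    ``M M^T`` once and obtains each leave-one-partition-out PCA from the
    downdate ``M M^T - M_l M_l^T`` (exact, since EIGENSTRAT normalization
    is per-column).
    """

    def __init__(
        self,
        aln: HaploidAlignment,
        parts: PartitionSet,
        n_global_pcs: int = 5,
        n_local_pcs: int = 5,
    ) -> None:
        if parts.n_sites != aln.n_sites:
            raise ValueError("partition set does not tile this alignment")
        self.aln = aln
        self.parts = parts
        self.n_global_pcs = n_global_pcs
        self.n_local_pcs = n_local_pcs
        M, kept = normalize_genotypes(aln.genotypes)
        # monomorphic sites carry no structure; partitions are mapped
        # onto the kept columns
        self._kept = kept
        self._col_partition = np.array(
            [parts.partition_of_site(int(j)) for j in kept]
        )
        self._M = M
        self._gram = M @ M.T
        self._cache: dict[int, CovariateBundle] = {}

    def bundle(self, ell: int) -> CovariateBundle:
        if ell not in self._cache:
            self._cache[ell] = self._build(ell)
        return self._cache[ell]

    def local_pcs_excluding(self, ell: int, site: int) -> np.ndarray:
        """Local PC scores of partition ``ell`` with one site left out
        (used to drop the test SNP itself from the local PCA)."""
        inside = self._col_partition == ell
        kept_sites = self._kept[inside]  # alignment coordinates
        keep_cols = self._M[:, inside]
        mask = np.ones(kept_sites.size, dtype=bool)
        hit = np.flatnonzero(kept_sites == site)
        if hit.size:
            mask[hit[0]] = False
        M_in = keep_cols[:, mask]
        if M_in.shape[1] == 0:
            return np.zeros((self.aln.n_samples, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return top_pcs(M_in, self.n_local_pcs)

    def _build(self, ell: int) -> CovariateBundle:
        inside = self._col_partition == ell
        M_in = self._M[:, inside]
        n_out = int((~inside).sum())
        if n_out < 2:
            raise ValueError(
                f"global covariates undefined: only {n_out} sites outside "
                f"partition {ell}"
            )
        C_out = self._gram - M_in @ M_in.T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W_global = _pcs_from_gram(C_out, self.n_global_pcs)
            if M_in.shape[1] == 0:
                W_local = np.zeros((self.aln.n_samples, 0))
            else:
                W_local = top_pcs(M_in, self.n_local_pcs)
        return CovariateBundle(W_global=W_global, W_local=W_local, partition_id=ell)


def build_covariates(
    aln: HaploidAlignment,
    parts: PartitionSet,
    ell: int,
    n_global_pcs: int = 5,
    n_local_pcs: int = 5,
) -> CovariateBundle:
    """Covariate bundle for one partition (uncached convenience wrapper)."""
    builder = CovariateBuilder(aln, parts, n_global_pcs, n_local_pcs)
    return builder.bundle(ell)
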