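"""Four-Gamete-Test compatibility and breakpoint inference."""

import itertools

import numpy as np
import pytest

from coalmap import HaploidAlignment, PartitionSet, four_gamete_compatible, infer_breakpoints


def _aln(columns):
    G = np.array(columns).T
    return HaploidAlignment(
        genotypes=G, sample_ids=[f"s{i}" for i in range(G.shape[0])]
    )


def brute_force_compatible(a, b):
    gametes = {(x, y) for x, y in zip(a, b)}
    return gametes != {(0, 0), (0, 1), (1, 0), (1, 1)}


def test_all_four_gametes_incompatible():
    assert not four_gamete_compatible([0, 0, 1, 1], [0, 1, 0, 1])


def test_identical_columns_compatible():
    for c in ([0, 1, 0, 1], [1, 1, 1, 1], [0, 0, 0, 0]):
        assert four_gamete_compatible(c, c)


def test_exhaustive_length_four_pairs_match_enumeration():
    """All 2^4 x 2^4 column pairs agree with direct gamete enumeration."""
    cols = list(itertools.product((0, 1), repeat=4))
    for a in cols:
        for b in cols:
            assert four_gamete_compatible(a, b) == brute_force_compatible(a, b)


def test_non_binary_rejected():
    with pytest.raises(ValueError):
        four_gamete_compatible([0, 2, 1], [0, 1, 1])


def test_fully_compatible_alignment_yields_single_partition():
    # nested clades: pairwise compatible
    aln = _aln([[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0]])
    parts = infer_breakpoints(aln)
    assert parts.ranges == ((0, 3),)


def test_toy_breakpoint_between_sites_two_and_three():
    # c1, c2 compatible; c3 shows all four gametes against both
    aln = _aln([[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1]])
    parts = infer_breakpoints(aln)
    assert parts.ranges == ((0, 2), (2, 3))


def test_single_site_alignment():
    aln = _aln([[0, 1, 1]])
    assert infer_breakpoints(aln).ranges == ((0, 1),)


def test_breakpoints_witnessed_and_blocks_compatible(small_alignment):
    """Each internal breakpoint is forced by an incompatible spanning pair,
    and each inferred block is internally compatible."""
    aln = small_alignment
    parts = infer_breakpoints(aln)
    G = aln.genotypes
    for ell in range(parts.n_partitions - 1):
        start, b = parts.ranges[ell]
        witnessed = any(
            not four_gamete_compatible(G[:, i], G[:, b])
            for i in range(start, b)
        )
        assert witnessed, f"breakpoint at {b} has no incompatible witness"
    rng = np.random.default_rng(0)
    for start, end in parts.ranges:
        idx = np.arange(start, end)
        if idx.size > 40:
            idx = np.sort(rng.choice(idx, 40, replace=False))
        for a, c in itertools.combinations(idx, 2):
            assert four_gamete_compatible(G[:, a], G[:, c])


def test_partitions_never_outnumber_true_loci(small_alignment):
    """True loci are compatible blocks, so the minimal greedy cover cannot
    use more blocks than there are loci."""
    parts = infer_breakpoints(small_alignment)
    assert parts.n_partitions <= len(small_alignment.locus_bounds)


def test_boundary_overshoot_only_through_ambiguous_sites(small_alignment):
    """A greedy block may absorb leading sites of the next locus only when
    those sites are compatible with every site of the block — i.e. the
    data cannot place the boundary any better."""
    aln = small_alignment
    parts = infer_breakpoints(aln)
    G = aln.genotypes
    true_starts = {s for s, _ in aln.locus_bounds}
    for (start, b) in parts.ranges[:-1]:
        if b in true_starts:
            continue
        # overshoot: every absorbed site back to the enclosing true locus
        # start must be compatible with the whole preceding block
        t = max(s for s, _ in aln.locus_bounds if s < b)
        for j in range(t, b):
            assert all(
                four_gamete_compatible(G[:, i], G[:, j])
                for i in range(start, t)
            )


def test_idempotence_on_single_block(small_alignment):
    aln = small_alignment
    parts = infer_breakpoints(aln)
    start, end = parts.ranges[0]
    sub = HaploidAlignment(
        genotypes=aln.genotypes[:, start:end],
        sample_ids=aln.sample_ids,
        site_ids=aln.site_ids[start:end],
        locus_index=aln.locus_index[start:end],
    )
    assert infer_breakpoints(sub).n_partitions == 1


def test_partition_set_validation():
    with pytest.raises(ValueError):
        PartitionSet.from_ranges([(0, 5), (6, 10)])  # gap
    with pytest.raises(ValueError):
        PartitionSet.from_ranges([(0, 5), (4, 10)])  # overlap
    with pytest.raises(ValueError):
        PartitionSet.from_ranges([(1, 5)])  # does not start at 0
    ps = PartitionSet.from_ranges([(0, 3), (3, 7)])
    assert ps.partition_of_site(2) == 0 and ps.partition_of_site(3) == 1
    np.testing.assert_array_equal(ps.breakpoints, [0, 3, 7])


# property-based check: the vectorized scan's per-pair logic agrees with
# the simple set-based predicate on arbitrary binary columns
from hypothesis import given, settings, strategies as st


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(2, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
))
def test_compatibility_matches_gamete_enumeration(cols):
    a, b = cols
    assert four_gamete_compatible(a, b) == brute_force_compatible(a, b)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.lists(st.integers(0, 1), min_size=5, max_size=5),
                min_size=1, max_size=8))
def test_scan_blocks_tile_and_are_compatible(columns):
    aln = _aln(columns)
    parts = infer_breakpoints(aln)
    assert parts.ranges[0][0] == 0 and parts.ranges[-1][1] == aln.n_sites
    for start, end in parts.ranges:
        for i in range(start, end):
            for j in range(i + 1, end):
                assert four_gamete_compatible(
                    aln.genotypes[:, i], aln.genotypes[:, j]
                )
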