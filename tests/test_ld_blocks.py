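"""D' estimation, CI classification and block detection."""

import numpy as np
import pytest

from hapsparse import classify_pair, estimate_pair_ld, find_blocks, segment_blocks
from hapsparse.ld_blocks import (
    NONINFORMATIVE,
    STRONG_LD,
    STRONG_RECOMB,
    PairLD,
    pair_class_matrix,
)

from conftest import make_genotypes


def test_perfect_coupling_dprime_one():
    pair = estimate_pair_ld(np.array([[50, 0], [0, 50]]))
    assert pair.d_prime == pytest.approx(1.0)
    assert pair.klass == STRONG_LD


def test_equilibrium_dprime_zero():
    pair = estimate_pair_ld(np.array([[25, 25], [25, 25]]))
    assert pair.d_prime == pytest.approx(0.0)
    assert pair.klass == STRONG_RECOMB


def test_monomorphic_counts_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        estimate_pair_ld(np.array([[50, 50], [0, 0]]))


def test_ci_against_direct_grid_likelihood_oracle():
    # independent oracle: plain loops over the same 1001-point |D'| grid,
    # likelihood in linear space
    counts = np.array([[40.0, 10.0], [10.0, 40.0]])
    tot = counts.sum()
    pA = counts[1].sum() / tot
    pB = counts[:, 1].sum() / tot
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    grid = np.linspace(0, 1, 1001)
    liks = []
    for dp in grid:
        p11 = pA * pB + dp * dmax
        ps = [1 - pA - pB + p11, pB - p11, pA - p11, p11]
        ns = [counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]]
        lik = 1.0
        for pr, nn in zip(ps, ns):
            lik *= max(pr, 1e-12) ** nn
        liks.append(lik)
    liks = np.array(liks)
    cum = np.cumsum(liks / liks.sum())
    lo = grid[np.searchsorted(cum, 0.05)]
    hi = grid[np.searchsorted(cum, 0.95)]
    pair = estimate_pair_ld(counts)
    assert pair.ci_low == pytest.approx(lo, abs=1e-9)
    assert pair.ci_high == pytest.approx(hi, abs=1e-9)


@pytest.mark.parametrize(
    "ci,expected",
    [
        ((0.75, 0.99), STRONG_LD),
        ((0.10, 0.60), STRONG_RECOMB),
        ((0.50, 0.95), NONINFORMATIVE),
        ((0.70, 0.98), STRONG_LD),  # boundary: >= on both thresholds
        ((0.50, 0.899), STRONG_RECOMB),
    ],
)
def test_classification_rule(ci, expected):
    pair = PairLD(0, 1, 0.9, ci[0], ci[1], "")
    assert classify_pair(pair) == expected


def _two_pair_instance():
    rng = np.random.default_rng(1)
    a = rng.choice([0.0, 2.0], size=40)
    c = rng.choice([0.0, 2.0], size=40)
    dosage = np.column_stack([a, a, c, c])
    return make_genotypes(dosage, pos=[1_000, 2_000, 120_000, 121_000])


def test_two_perfect_pairs_give_two_blocks():
    g = _two_pair_instance()
    blocks = find_blocks(g)
    assert len(blocks) == 2
    assert [b.n_snps for b in blocks] == [2, 2]
    assert list(blocks[0].snp_indices) == [0, 1]
    assert list(blocks[1].snp_indices) == [2, 3]


def test_pairs_outside_window_never_blocked():
    rng = np.random.default_rng(2)
    a = rng.choice([0.0, 2.0], size=40)
    g = make_genotypes(np.column_stack([a, a]), pos=[1_000, 251_000])
    assert find_blocks(g) == []


def _oracle_blocks(g, window_bp=200_000, strong_frac=0.95):
    """Exhaustive-span oracle: enumerate every contiguous span, apply the
    outermost-pair + fraction rule with explicit loops, then the same
    greedy length-descending acceptance."""
    out = []
    for c in np.unique(g.chrom.astype(str)):
        idx = np.flatnonzero(g.chrom.astype(str) == c)
        pos = g.pos_bp[idx]
        klass = pair_class_matrix(g, idx, window_bp)
        cands = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > window_bp or klass[a, b] != 1:
                    continue
                n_s = n_i = 0
                for i in range(a, b + 1):
                    for j in range(i + 1, b + 1):
                        if klass[i, j] == 1:
                            n_s += 1
                            n_i += 1
                        elif klass[i, j] == 0:
                            n_i += 1
                if n_i >= 1 and n_s >= strong_frac * n_i:
                    cands.append((a, b))
        cands.sort(key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), ab[0]))
        taken = set()
        for a, b in cands:
            if any(i in taken for i in range(a, b + 1)):
                continue
            taken.update(range(a, b + 1))
            out.append((str(c), tuple(idx[a : b + 1])))
    return sorted(out)


@pytest.mark.parametrize("seed", range(8))
def test_find_blocks_matches_exhaustive_span_oracle(seed):
    rng = np.random.default_rng(seed)
    n_snps = int(rng.integers(4, 9))
    # correlated columns produce a mix of classifications
    base = rng.choice([0.0, 2.0], size=(30, 1))
    cols = []
    for _ in range(n_snps):
        flip = rng.random(30) < rng.choice([0.0, 0.05, 0.3, 0.5])
        col = np.where(flip, 2.0 - base[:, 0], base[:, 0])
        cols.append(col)
        if rng.random() < 0.3:
            base = rng.choice([0.0, 2.0], size=(30, 1))
    g = make_genotypes(np.column_stack(cols), pos=np.sort(rng.choice(200_000, n_snps, replace=False)) + 1)
    got = sorted(
        (b.chrom, tuple(b.snp_indices)) for b in find_blocks(g)
    )
    assert got == _oracle_blocks(g)


def test_block_list_invariant_to_line_order(qc_geno):
    g = qc_geno
    perm = np.random.default_rng(0).permutation(g.n_lines)
    import dataclasses

    g2 = dataclasses.replace(
        g, line_ids=[g.line_ids[i] for i in perm], dosage=g.dosage[perm]
    )
    b1 = [(b.chrom, tuple(b.snp_indices)) for b in find_blocks(g)]
    b2 = [(b.chrom, tuple(b.snp_indices)) for b in find_blocks(g2)]
    assert b1 == b2


def test_segmentation_sizes_and_conservation():
    from hapsparse.ld_blocks import HaplotypeBlock

    bl6 = HaplotypeBlock("1", np.arange(6), 1, 600)
    bl7 = HaplotypeBlock("1", np.arange(10, 17), 700, 1400)
    bl2 = HaplotypeBlock("1", np.array([20, 21]), 2000, 2100)
    assert [f.n_snps for f in segment_blocks([bl6], 3)] == [3, 3]
    frags7 = segment_blocks([bl7], 3)
    assert [f.n_snps for f in frags7] == [3, 3, 1]
    np.testing.assert_array_equal(
        np.concatenate([f.snp_indices for f in frags7]), bl7.snp_indices
    )
    frags2 = segment_blocks([bl2], 2)
    assert len(frags2) == 1
    np.testing.assert_array_equal(frags2[0].snp_indices, bl2.snp_indices)
    with pytest.raises(ValueError):
        segment_blocks([bl6], 4)
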