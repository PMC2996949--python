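"""LD statistics: worked examples, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdld import ldcore
from herdld.containers import HaplotypePanel, SnpMap
from herdld.ldcore import HapFreqs, haplotype_freqs, pair_ld, pairwise_ld

from conftest import panel_from_counts, random_panel
from oracle import brute_force_ld


@pytest.mark.parametrize("freqs, expect", [
    # (pi_AB, pi_Ab, pi_aB, pi_ab) -> (D, |D'|, r2)
    ((0.40, 0.10, 0.10, 0.40), (0.15, 0.60, 0.36)),
    ((0.70, 0.10, 0.10, 0.10), (0.06, 0.375, 0.140625)),
    ((0.50, 0.00, 0.00, 0.50), (0.25, 1.0, 1.0)),
    ((0.25, 0.25, 0.25, 0.25), (0.0, 0.0, 0.0)),
])
def test_pair_ld_worked_examples(freqs, expect):
    stats = pair_ld(HapFreqs(*freqs, n=100))
    assert stats.defined
    assert stats.D == pytest.approx(expect[0], abs=1e-12)
    assert stats.abs_dprime == pytest.approx(expect[1], abs=1e-12)
    assert stats.r2 == pytest.approx(expect[2], abs=1e-12)


def test_haplotype_freqs_hand_count():
    panel = panel_from_counts(40, 10, 10, 40)
    f = haplotype_freqs(panel, 0, 1)
    assert f.pi_AB == pytest.approx(0.40)
    assert f.pi_A == pytest.approx(0.50)
    assert f.pi_B == pytest.approx(0.50)
    assert f.n == 100


def test_haplotype_freqs_single_class_and_pairwise_deletion():
    panel = panel_from_counts(5, 0, 0, 0)
    f = haplotype_freqs(panel, 0, 1)
    assert f.pi_AB == 1.0 and f.pi_Ab == f.pi_aB == f.pi_ab == 0.0
    # one unknown at marker j drops that haplotype
    alleles = panel.alleles.copy()
    alleles[0, 1] = -1
    f2 = haplotype_freqs(HaplotypePanel(alleles, panel.carrier), 0, 1)
    assert f2.n == f.n - 1


def test_haplotype_freqs_rejects_fewer_than_two_usable():
    alleles = np.array([[1, -1], [0, -1], [1, 1]], dtype=np.int8)
    with pytest.raises(ValueError):
        haplotype_freqs(HaplotypePanel(alleles, ["a", "b", "c"]), 0, 1)


def test_monomorphic_marker_flagged_undefined():
    panel = panel_from_counts(3, 0, 2, 0)  # marker B constant 1
    stats = pair_ld(haplotype_freqs(panel, 0, 1))
    assert not stats.defined


def test_oracle_equivalence_random_panels():
    """pair_ld matches the brute-force counting oracle to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        panel = random_panel(rng, int(rng.integers(2, 50)),
                             p_unknown=float(rng.choice([0.0, 0.1])))
        try:
            f = haplotype_freqs(panel, 0, 1)
        except ValueError:
            continue
        mine = pair_ld(f)
        D, dp, r2, defined = brute_force_ld(panel.alleles, 0, 1)
        assert mine.defined == defined
        if defined:
            assert mine.D == pytest.approx(D, abs=1e-12)
            assert mine.abs_dprime == pytest.approx(dp, abs=1e-12)
            assert mine.r2 == pytest.approx(r2, abs=1e-12)
            assert mine.r2 <= mine.abs_dprime ** 2 + 1e-12
            assert mine.abs_dprime <= 1 + 1e-12


def test_symmetry_and_label_invariance():
    rng = np.random.default_rng(7)
    for _ in range(50):
        panel = random_panel(rng, 30)
        try:
            s_ij = pair_ld(haplotype_freqs(panel, 0, 1))
            s_ji = pair_ld(haplotype_freqs(panel, 1, 0))
        except ValueError:
            continue
        if not s_ij.defined:
            continue
        assert s_ij.r2 == pytest.approx(s_ji.r2, abs=1e-12)
        assert s_ij.abs_dprime == pytest.approx(s_ji.abs_dprime, abs=1e-12)
        # flipping allele labels at one marker flips the sign of D only
        flipped = panel.alleles.copy()
        flipped[:, 0] = 1 - flipped[:, 0]
        s_fl = pair_ld(haplotype_freqs(HaplotypePanel(flipped, panel.carrier), 0, 1))
        assert s_fl.D == pytest.approx(-s_ij.D, abs=1e-12)
        assert s_fl.r2 == pytest.approx(s_ij.r2, abs=1e-12)
        assert s_fl.abs_dprime == pytest.approx(s_ij.abs_dprime, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                 st.integers(0, 200), st.integers(0, 200)))
def test_ld_inequality_chain_property(counts):
    """r² <= |D'|² <= |D'| and both lie in [0, 1] for any count vector."""
    a, b, c, d = counts
    n = a + b + c + d
    if n < 2:
        return
    stats = pair_ld(HapFreqs(a / n, b / n, c / n, d / n, n))
    if not stats.defined:
        return
    assert 0 <= stats.r2 <= stats.abs_dprime ** 2 + 1e-12
    assert stats.abs_dprime ** 2 <= stats.abs_dprime + 1e-12
    assert stats.abs_dprime <= 1 + 1e-12
    oracle = brute_force_ld(panel_from_counts(a, b, c, d).alleles, 0, 1)
    assert stats.r2 == pytest.approx(oracle[2], abs=1e-12)


def _scope_map():
    return SnpMap([f"m{k}" for k in range(5)], ["1", "1", "1", "2", "2"],
                  [1, 40_001, 200_001, 10, 20])


def test_pairwise_scopes_pair_counts():
    rng = np.random.default_rng(0)
    panel = random_panel(rng, 40, n_markers=5)
    sm = _scope_map()
    adj = pairwise_ld(panel, sm, scope="adjacent", drop_undefined=False)
    assert len(adj) == 3  # 2 on chrom 1 + 1 on chrom 2
    non = pairwise_ld(panel, sm, scope="non_syntenic", drop_undefined=False)
    assert len(non) == 6  # 3 x 2 cross-chromosome
    assert non["distance_bp"].isna().all()
    syn = pairwise_ld(panel, sm, scope="syntenic", max_distance_bp=50_000,
                      drop_undefined=False)
    # chrom1: only the 0-40 kb pair; chrom2: the 10 bp pair
    assert len(syn) == 2
    assert (syn["distance_bp"] <= 50_000).all()


def test_pairwise_rejects_unknown_scope_and_misalignment():
    rng = np.random.default_rng(1)
    panel = random_panel(rng, 10, n_markers=5)
    with pytest.raises(ValueError, match="scope"):
        pairwise_ld(panel, _scope_map(), scope="bogus")
    with pytest.raises(ValueError, match="misaligned"):
        pairwise_ld(panel.subset_markers(np.arange(3)), _scope_map())


def test_ld_matrix_agrees_with_pair_engine():
    rng = np.random.default_rng(3)
    panel = random_panel(rng, 60, n_markers=6, p_unknown=0.05)
    cols = np.arange(6)
    r2m, dpm, Dm, nm, defm = ldcore.ld_matrix(panel, cols)
    for i in range(6):
        for j in range(i + 1, 6):
            D, dp, r2, defined = brute_force_ld(panel.alleles, i, j)
            assert bool(defm[i, j]) == defined
            if defined:
                assert r2m[i, j] == pytest.approx(r2, abs=1e-12)
                assert dpm[i, j] == pytest.approx(dp, abs=1e-12)
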