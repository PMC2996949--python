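"""Sliding windows, misplaced-marker calls, gene-context classification."""

import numpy as np
import pandas as pd
import pytest

from herdld import genome_scan, ldcore, phasing
from herdld.containers import HaplotypePanel, SnpMap
from herdld.genome_scan import (apply_relocations, classify_gene_context,
                                detect_misplaced, gene_context_summary,
                                relocate_misplaced, sliding_window_ld)

from conftest import random_panel


def test_window_count_invariant():
    rng = np.random.default_rng(0)
    m = 50
    sm = SnpMap([f"m{k}" for k in range(m)], ["1"] * m,
                [(k + 1) * 100_000 for k in range(m)])
    panel = random_panel(rng, 40, n_markers=m)
    win, step = 2_000_000, 100_000
    table = sliding_window_ld(panel, sm, window=win, step=step)
    L = int(sm.pos[-1])
    assert len(table) == (L - win) // step + 1


def test_short_chromosome_single_window():
    rng = np.random.default_rng(1)
    sm = SnpMap(["a", "b"], ["1", "1"], [1000, 500_000])
    panel = random_panel(rng, 30, n_markers=2)
    table = sliding_window_ld(panel, sm)
    assert len(table) == 1 and table.iloc[0]["start"] == 0


def test_window_min_pairs_gate():
    """A window with fewer than min_pairs qualifying pairs is uninformative."""
    rng = np.random.default_rng(2)
    m = 30
    sm = SnpMap([f"m{k}" for k in range(m)], ["1"] * m,
                [(k + 1) * 50_000 for k in range(m)])
    panel = random_panel(rng, 60, n_markers=m)
    table = sliding_window_ld(panel, sm, window=1_500_000, step=1_500_000,
                              pair_min=200_000, pair_max=600_000,
                              min_pairs=10_000)
    assert not table["informative"].any()
    assert table["mean_r2"].isna().all()


def test_window_rejects_bad_params():
    rng = np.random.default_rng(3)
    sm = SnpMap(["a", "b"], ["1", "1"], [1, 2])
    with pytest.raises(ValueError):
        sliding_window_ld(random_panel(rng, 4, 2), sm, window=0)


def test_monomorphic_panel_gives_uninformative_windows():
    sm = SnpMap([f"m{k}" for k in range(10)], ["1"] * 10,
                [(k + 1) * 300_000 for k in range(10)])
    panel = HaplotypePanel(np.ones((20, 10), dtype=np.int8),
                           [f"a{i}" for i in range(20)])
    table = sliding_window_ld(panel, sm)
    assert not table["informative"].any()


def _perfect_ld_panel(n_markers, n_hap=40):
    """All markers perfectly correlated: two complementary haplotypes."""
    base = np.array([0, 1] * (n_hap // 2), dtype=np.int8)
    alleles = np.tile(base[:, None], (1, n_markers))
    return HaplotypePanel(alleles, [f"a{i}" for i in range(n_hap)])


def test_two_distant_markers_in_perfect_ld_both_flagged():
    sm = SnpMap(["a", "b"], ["1", "1"], [1_000_000, 51_000_000])
    calls = detect_misplaced(_perfect_ld_panel(2), sm, flag_distance=10_000_000)
    assert sorted(c.marker_id for c in calls) == ["a", "b"]


def test_close_best_partners_no_flags():
    rng = np.random.default_rng(4)
    sm = SnpMap([f"m{k}" for k in range(5)], ["1"] * 5,
                [(k + 1) * 10_000 for k in range(5)])
    calls = detect_misplaced(random_panel(rng, 30, 5), sm)
    assert calls == []


def test_detect_deterministic_and_order_invariant():
    rng = np.random.default_rng(5)
    m = 20
    pos = [(k + 1) * 800_000 for k in range(m)]
    sm = SnpMap([f"m{k}" for k in range(m)], ["1"] * m, pos)
    panel = random_panel(rng, 50, n_markers=m)
    calls1 = detect_misplaced(panel, sm, flag_distance=3_000_000)
    calls2 = detect_misplaced(panel, sm, flag_distance=3_000_000)
    assert [vars(c) for c in calls1] == [vars(c) for c in calls2]
    # markers fed in shuffled row order: SnpMap re-sorts to the same map,
    # so the same sorted-aligned panel yields identical calls
    perm = rng.permutation(m)
    sm2 = SnpMap(sm.ids[perm], sm.chrom[perm], sm.pos[perm])
    assert sm2 == sm
    calls3 = detect_misplaced(panel, sm2, flag_distance=3_000_000)
    assert [vars(c) for c in calls1] == [vars(c) for c in calls3]


def test_relocate_midpoint_convention():
    """Two top partners at 5.0 and 5.2 Mb -> corrected position 5.1 Mb."""
    sm = SnpMap(["p1", "p2", "bad"], ["1", "1", "1"],
                [5_000_000, 5_200_000, 60_000_000])
    panel = _perfect_ld_panel(3)
    calls = detect_misplaced(panel, sm, flag_distance=10_000_000)
    call = next(c for c in calls if c.marker_id == "bad")
    assert relocate_misplaced(panel, sm, call) == 5_100_000
    fixed = apply_relocations(sm, [call])
    assert fixed.pos[fixed.index_of("bad")] == 5_100_000
    assert list(fixed.ids) == ["p1", "bad", "p2"]  # re-sorted by position


def test_relocate_with_single_partner_warns_and_skips():
    sm = SnpMap(["p1", "bad"], ["1", "1"], [5_000_000, 60_000_000])
    panel = _perfect_ld_panel(2)
    calls = detect_misplaced(panel, sm, flag_distance=10_000_000)
    call = next(c for c in calls if c.marker_id == "bad")
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert relocate_misplaced(panel, sm, call) is None


def _gene_fixture():
    sm = SnpMap(["in1", "in2", "out1", "out2", "edge"], ["1"] * 5,
                [1_100, 1_900, 9_000, 9_500, 2_050])
    genes = pd.DataFrame({"chrom": ["1", "1"], "start": [1_000, 2_000],
                          "end": [2_000, 3_000], "name": ["gA", "gB"]})
    return sm, genes


def test_gene_context_labels():
    sm, genes = _gene_fixture()
    pairs = pd.DataFrame({
        "id1": ["in1", "out1", "in1", "in1"],
        "id2": ["in2", "out2", "out1", "edge"],
        "distance_bp": [800, 500, 7_900, 950],
        "r2": [0.2, 0.3, 0.1, 0.4], "abs_dprime": [0.5] * 4,
        "chrom1": "1", "chrom2": "1", "mean_maf": 0.3,
    })
    labeled = classify_gene_context(sm, genes, pairs)
    assert list(labeled["gene_context"]) == [
        "intragenic",   # both inside gA
        "intergenic",   # both outside all genes
        "mixed",        # one in, one out
        "mixed",        # in1 in gA, edge in gB only: no shared gene
    ]
    summary = gene_context_summary(labeled)
    both = summary[summary["n"] > 0]
    assert set(both["context"]) == {"intragenic", "intergenic"}


def test_post_correction_adjacent_ld_not_worse(small_study):
    """Relocating displaced markers restores (or improves) adjacent LD."""
    from herdld import qc, simdata
    study, _ = small_study
    stq, _ = qc.filter_snps(study)
    bad, ledger = simdata.inject_artifacts(stq, n_misplaced=4,
                                           min_displacement_bp=2_000_000,
                                           seed=17)
    mat, _ = phasing.split_parental(bad.truth.panel)
    calls = detect_misplaced(mat, bad.snp_map, flag_distance=2_000_000)
    for c in calls:
        relocate_misplaced(mat, bad.snp_map, c)
    fixed_map = apply_relocations(bad.snp_map, calls)
    before = ldcore.pairwise_ld(mat, bad.snp_map, scope="adjacent").r2.mean()
    perm = fixed_map._input_order
    after = ldcore.pairwise_ld(mat.subset_markers(perm), fixed_map,
                               scope="adjacent").r2.mean()
    assert after >= before - 1e-9
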