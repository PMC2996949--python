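"""Synthetic-population generator: founders, meiosis, families, artifacts."""

import numpy as np
import pytest

from herdld import qc, simdata
from herdld.containers import MISSING, SnpMap
from herdld.simdata import (SimConfig, fixed_maf_law, inject_artifacts,
                            evolve_population, make_halfsib_study,
                            simulate_founders, simulate_gametes,
                            synthetic_snp_map)


def tiny_map(n=3):
    return SnpMap([f"m{k}" for k in range(n)], ["1"] * n,
                  [(k + 1) * 1000 for k in range(n)])


def test_founder_shape_and_determinism():
    cfg = SimConfig(snp_map=tiny_map(3), n_founder_haplotypes=2, seed=9)
    panel = simulate_founders(cfg)
    assert panel.alleles.shape == (2, 3)
    assert set(np.unique(panel.alleles)) <= {0, 1}
    again = simulate_founders(SimConfig(snp_map=tiny_map(3),
                                        n_founder_haplotypes=2, seed=9))
    assert np.array_equal(panel.alleles, again.alleles)


def test_founder_frequencies_follow_the_law():
    cfg = SimConfig(snp_map=tiny_map(5), n_founder_haplotypes=10_000,
                    maf_law=fixed_maf_law(0.5), seed=1)
    panel = simulate_founders(cfg)
    freqs = panel.alleles.mean(axis=0)
    assert np.all(np.abs(freqs - 0.5) < 0.02)


def test_founders_reject_zero_markers():
    with pytest.raises(ValueError):
        SimConfig(snp_map=SnpMap([], [], []), seed=0)


def test_no_recombination_transmits_whole_parental_gametes():
    rng = np.random.default_rng(0)
    sm = tiny_map(20)
    parents = rng.integers(0, 2, (50, 2, 20)).astype(np.int8)
    gametes, n_xo = simulate_gametes(parents, sm, cm_per_mb=0.0, rng=rng)
    assert n_xo.sum() == 0
    for g in range(50):
        assert (np.array_equal(gametes[g], parents[g, 0])
                or np.array_equal(gametes[g], parents[g, 1]))


def test_crossover_count_matches_poisson_rate():
    """1-Mb chromosome at 1.25 cM/Mb: mean crossovers = 0.0125 +/- 3 SE."""
    rng = np.random.default_rng(11)
    sm = SnpMap([f"m{k}" for k in range(10)], ["1"] * 10,
                [int(p) for p in np.linspace(100_000, 1_000_000, 10)])
    parents = rng.integers(0, 2, (10_000, 2, 10)).astype(np.int8)
    _, n_xo = simulate_gametes(parents, sm, cm_per_mb=1.25, rng=rng)
    lam = 0.0125
    se = np.sqrt(lam / 10_000)
    assert abs(n_xo.mean() - lam) < 3 * se


def test_male_meiosis_transmits_single_x_outside_par():
    sm = synthetic_snp_map(n_autosomes=1, markers_per_chrom=5, include_x=True,
                           x_markers=40, par_fraction=0.2, seed=2)
    rng = np.random.default_rng(3)
    parents = rng.integers(0, 2, (200, 2, len(sm))).astype(np.int8)
    gametes, _ = simulate_gametes(parents, sm, cm_per_mb=10.0, rng=rng,
                                  male=True)
    xs = np.flatnonzero((sm.chrom == "X") & (sm.region == "x_specific"))
    assert np.array_equal(gametes[:, xs], parents[:, 1, :][:, xs])


def test_evolve_rejects_tiny_population():
    cfg = SimConfig(snp_map=tiny_map(), pop_size=2, seed=0)
    cfg.pop_size = 1
    with pytest.raises(ValueError):
        evolve_population(simulate_founders(cfg), cfg)


def test_halfsib_study_structure(small_study):
    study, cfg = small_study
    assert len(study.study_ids) == cfg.n_sires * cfg.progeny_per_sire
    ped = study.pedigree.frame.set_index("id")
    sires = {f"SIRE{k}" for k in range(cfg.n_sires)}
    for aid in study.study_ids:
        assert ped.loc[aid, "sire"] in sires
    # genotype equals the sum of the true haplotypes on autosomes
    auto = np.flatnonzero(study.snp_map.chrom != "X")
    panel = study.truth.panel
    for aid in list(study.study_ids)[:10]:
        rows = np.flatnonzero(panel.carrier == aid)
        hap_sum = panel.alleles[rows][:, auto].sum(axis=0)
        geno = study.genotypes[study.animal_index(aid)][auto]
        assert np.array_equal(hap_sum, geno)
    # males are never heterozygous at X-specific markers
    xs = np.flatnonzero(study.snp_map.chrom == "X")
    x_specific = xs[study.snp_map.pos[xs] < study.truth.par_start]
    g = study.genotypes[:, x_specific]
    assert not np.any(g == 1)


def test_halfsib_rejects_oversized_family_request():
    sm = tiny_map(5)
    cfg = SimConfig(snp_map=sm, pop_size=10, n_generations=2,
                    n_sires=50, progeny_per_sire=2, seed=0)
    pop = evolve_population(simulate_founders(cfg), cfg)
    with pytest.raises(ValueError):
        make_halfsib_study(pop, cfg)


def test_inject_artifacts_identity(small_study):
    study, _ = small_study
    out, ledger = inject_artifacts(study, n_misplaced=0, mendel_rate=0.0,
                                   missing_rate=0.0, seed=1)
    assert ledger.is_empty()
    assert np.array_equal(out.genotypes, study.genotypes)
    assert out.snp_map == study.snp_map


def test_inject_artifacts_displacement_and_ledger(small_study):
    study, _ = small_study
    out, ledger = inject_artifacts(study, n_misplaced=3,
                                   min_displacement_bp=2_000_000, seed=2)
    assert len(ledger.misplaced) == 3
    for mk, true_pos, shown_pos in ledger.misplaced:
        assert abs(shown_pos - true_pos) >= 2_000_000
        k = out.snp_map.index_of(mk)
        assert out.snp_map.pos[k] == shown_pos
    # genotype columns moved with their markers
    for mk, _, _ in ledger.misplaced:
        old = study.genotypes[:, study.snp_map.index_of(mk)]
        new = out.genotypes[:, out.snp_map.index_of(mk)]
        assert np.array_equal(old, new)


def test_injected_mendel_errors_fail_the_check(small_study):
    """Every ledgered Mendelian conflict is caught by the qc oracle."""
    study, _ = small_study
    out, ledger = inject_artifacts(study, mendel_rate=0.002, seed=3)
    assert len(ledger.mendel_errors) > 0
    _, flagged = qc.mendelian_check(out, correct=False)
    flagged_set = set(flagged)
    for entry in ledger.mendel_errors:
        assert entry in flagged_set


def test_inject_artifacts_missing_masks_calls(small_study):
    study, _ = small_study
    out, ledger = inject_artifacts(study, missing_rate=0.01, seed=4)
    assert len(ledger.missing) > 0
    for aid, mk in ledger.missing:
        assert out.genotypes[out.animal_index(aid),
                             out.snp_map.index_of(mk)] == MISSING


def test_inject_artifacts_rejects_bad_rates(small_study):
    study, _ = small_study
    with pytest.raises(ValueError):
        inject_artifacts(study, mendel_rate=1.5, seed=0)


def test_monomorphic_markers_tolerated_and_tagged(small_study):
    """Drift can fix markers; the study must expose them via MAF = 0."""
    study, _ = small_study
    maf = study.marker_maf()
    assert np.all(np.isfinite(maf))
    assert np.all(maf >= 0)


def test_adjacent_ld_exceeds_distant_ld(small_study):
    """The decay structure the analysis assumes: near pairs beat far pairs."""
    from herdld import ldcore, phasing
    study, _ = small_study
    mat, _ = phasing.split_parental(study.truth.panel)
    adj = ldcore.pairwise_ld(mat, study.snp_map, scope="adjacent")
    syn = ldcore.pairwise_ld(mat, study.snp_map, scope="syntenic")
    far = syn[syn.distance_bp > 3_000_000]
    assert adj.r2.mean() > far.r2.mean()
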