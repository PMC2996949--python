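import numpy as np
import pytest

from herdld import simdata
from herdld.containers import HaplotypePanel, SnpMap


@pytest.fixture(scope="session")
def small_study():
    """A small seeded half-sib study with an X chromosome (shared, read-only)."""
    snp_map = simdata.synthetic_snp_map(
        n_autosomes=2, markers_per_chrom=80, mean_spacing_bp=66_000,
        include_x=True, x_markers=80, x_mean_spacing_bp=215_000,
        par_fraction=0.15, seed=5)
    cfg = simdata.SimConfig(snp_map=snp_map, n_generations=40, pop_size=80,
                            n_sires=20, progeny_per_sire=8, seed=5)
    founders = simdata.simulate_founders(cfg)
    pop = simdata.evolve_population(founders, cfg)
    return simdata.make_halfsib_study(pop, cfg), cfg


def random_panel(rng, n_hap, n_markers=2, p_unknown=0.0):
    alleles = rng.integers(0, 2, (n_hap, n_markers)).astype(np.int8)
    if p_unknown > 0:
        alleles[rng.random(alleles.shape) < p_unknown] = -1
    return HaplotypePanel(alleles, [f"a{i}" for i in range(n_hap)])


def panel_from_counts(a, b, c, d):
    """Two-marker panel realizing haplotype counts (AB, Ab, aB, ab)."""
    rows = ([[1, 1]] * a) + ([[1, 0]] * b) + ([[0, 1]] * c) + ([[0, 0]] * d)
    alleles = np.array(rows, dtype=np.int8)
    return HaplotypePanel(alleles, [f"h{i}" for i in range(len(rows))])


def two_marker_map():
    return SnpMap(["m1", "m2"], ["1", "1"], [1000, 2000])
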