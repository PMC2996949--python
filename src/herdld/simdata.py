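"""Forward-time synthetic populations for LD pipeline testing.

The generator emulates the statistical structure of a dairy-cattle SNP-chip
study: founders in linkage equilibrium with a near-uniform MAF spectrum,
LD built up by drift over discrete Wright-Fisher generations with
recombination at a per-Mb genetic rate, a terminal pseudo-autosomal region
(PAR) on the X that is the only X segment recombining in males, and a
half-sib family structure (many bulls per sire). Artifact injectors add
misplaced markers, Mendelian conflicts and missing calls with a ground-truth
ledger so the detectors downstream can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import (MISSING, ORIGIN_MATERNAL, ORIGIN_PATERNAL,
                         REGION_PAR, REGION_X_SPECIFIC, REGION_AUTOSOMAL,
                         REGION_UNKNOWN, SEX_FEMALE, SEX_MALE, X_CHROM,
                         ArtifactLedger, HaplotypePanel, Pedigree, SnpMap,
                         Study, StudyTruth)

__all__ = ["SimConfig", "Population", "synthetic_snp_map", "simulate_founders",
           "evolve_population", "make_halfsib_study", "inject_artifacts",
           "simulate_gametes", "default_config"]


def uniform_maf_law(lo: float = 0.05, hi: float = 0.5) -> Callable:
    """Founder allele-frequency law: frequency of allele 1 ~ U[lo, hi]."""
    def draw(rng: np.random.Generator, m: int) -> np.ndarray:
        return rng.uniform(lo, hi, m)
    return draw


def fixed_maf_law(p: float) -> Callable:
    def draw(rng: np.random.Generator, m: int) -> np.ndarray:
        return np.full(m, p)
    return draw


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``cm_per_mb`` is the genome-average recombination density
    (1.25 cM/Mb for cattle); ``maf_law`` draws founder allele-1 frequencies
    (near-uniform MAF spectrum by default). LD arises from ``n_generations``
    of drift in a population of ``pop_size`` diploids.
    """

    snp_map: SnpMap
    n_founder_haplotypes: int = 200
    n_generations: int = 100
    pop_size: int = 100
    cm_per_mb: float = 1.25
    maf_law: Callable = field(default_factory=uniform_maf_law)
    n_sires: int = 72
    progeny_per_sire: int = 12
    seed: int = 0
    #: breed the last generation at this size (herd expansion); None = pop_size
    final_pop_size: int | None = None
    #: genetic length (cM) of the PAR in male meiosis; the PAR pairs with the
    #: Y and carries an (near-)obligate crossover, so its male genetic length
    #: far exceeds physical-rate expectation
    male_par_cm: float = 25.0

    def __post_init__(self):
        for name in ("n_founder_haplotypes", "n_generations", "pop_size",
                     "n_sires", "progeny_per_sire"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be >= 0")
        if len(self.snp_map) == 0:
            raise ValueError("snp_map has zero markers")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific substream of the single global seed."""
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class Population:
    """One generation of diploids with fully known gametes.

    ``haplotypes`` has shape (n_individuals, 2, n_markers); slot 0 is the
    paternal gamete, slot 1 the maternal. For males the X-specific segment
    exists in one copy only (slot 0 mirrors slot 1 there, so allele sums
    outside chip coding must use the hemizygosity helpers).
    """

    ids: np.ndarray
    sex: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    snp_map: SnpMap

    @property
    def n(self) -> int:
        return len(self.ids)

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == SEX_MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == SEX_FEMALE)


def synthetic_snp_map(n_autosomes: int = 10, markers_per_chrom: int = 280,
                      mean_spacing_bp: int = 66_000,
                      include_x: bool = False, x_markers: int = 200,
                      x_mean_spacing_bp: int = 215_000,
                      par_fraction: float = 0.15,
                      seed: int = 0) -> SnpMap:
    """Build a marker map with jittered spacing around a mean.

    Inter-marker gaps are uniform on [0.1, 1.9] x mean spacing, giving the
    distance variety the decay bins need. With ``include_x`` an X chromosome
    is appended whose terminal ``par_fraction`` of markers is tagged PAR.
    """
    rng = np.random.default_rng([seed, 90])
    ids, chroms, pos, region = [], [], [], []
    for c in range(1, n_autosomes + 1):
        gaps = rng.uniform(0.1, 1.9, markers_per_chrom) * mean_spacing_bp
        p = np.cumsum(gaps).astype(np.int64) + 1
        for k in range(markers_per_chrom):
            ids.append(f"snp{c}_{k}")
            chroms.append(str(c))
            pos.append(int(p[k]))
            region.append(REGION_AUTOSOMAL)
    if include_x:
        gaps = rng.uniform(0.1, 1.9, x_markers) * x_mean_spacing_bp
        p = np.cumsum(gaps).astype(np.int64) + 1
        n_par = max(1, int(round(par_fraction * x_markers)))
        for k in range(x_markers):
            ids.append(f"snpX_{k}")
            chroms.append(X_CHROM)
            pos.append(int(p[k]))
            region.append(REGION_PAR if k >= x_markers - n_par else REGION_X_SPECIFIC)
    return SnpMap(ids, chroms, pos, region)


def default_config(seed: int = 0, include_x: bool = False) -> SimConfig:
    """The package's default study conditions: a desk-scale half-sib study
    of 400 bulls (40 sires x 10) on ~3,000 markers at 66 kb mean spacing,
    bred from 150 generations of drift at population size 300 with a final
    herd expansion so every bull has a distinct dam."""
    snp_map = synthetic_snp_map(n_autosomes=10, markers_per_chrom=300,
                                include_x=include_x, seed=seed)
    return SimConfig(snp_map=snp_map, n_generations=150, pop_size=300,
                     final_pop_size=900, n_sires=40, progeny_per_sire=10,
                     seed=seed)


def simulate_founders(config: SimConfig) -> HaplotypePanel:
    """Draw founder haplotypes in linkage equilibrium.

    Per-marker allele-1 frequencies come from ``config.maf_law``; alleles
    are independent across markers, so all LD downstream is drift-generated.
    """
    m = len(config.snp_map)
    rng = config.rng(1)
    freqs = np.asarray(config.maf_law(rng, m), dtype=float)
    alleles = (rng.random((config.n_founder_haplotypes, m)) < freqs).astype(np.int8)
    carriers = [f"founder{i}" for i in range(config.n_founder_haplotypes)]
    return HaplotypePanel(alleles, carriers)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _chrom_blocks(snp_map: SnpMap):
    """(chrom, column indices, length_bp) per chromosome; length = last marker."""
    out = []
    for c in snp_map.chromosomes():
        idx = snp_map.chrom_indices(c)
        out.append((c, idx, int(snp_map.pos[idx[-1]])))
    return out


def _crossover_choosers(n_gam: int, pos: np.ndarray, lo_bp: float, hi_bp: float,
                        morgans_per_bp: float, rng: np.random.Generator,
                        start: np.ndarray, lam_override: float | None = None):
    """Parental-slot chooser matrix from a Poisson crossover process.

    Crossovers per gamete ~ Poisson(rate x segment length), positions
    uniform on (lo_bp, hi_bp] (Haldane, no interference). Returns the
    (n_gam x m) slot matrix and the per-gamete crossover counts.
    """
    m = len(pos)
    lam = (lam_override if lam_override is not None
           else max(0.0, (hi_bp - lo_bp)) * morgans_per_bp)
    counts = rng.poisson(lam, n_gam)
    total = int(counts.sum())
    if total == 0:
        return np.broadcast_to(start[:, None], (n_gam, m)).copy(), counts
    xpos = rng.uniform(lo_bp, hi_bp, total)
    gam_id = np.repeat(np.arange(n_gam), counts)
    # idx = first marker with position > crossover point
    idx = np.searchsorted(pos, xpos, side="left")
    flat = np.bincount(gam_id * (m + 1) + idx, minlength=n_gam * (m + 1))
    per_interval = flat.reshape(n_gam, m + 1)
    before = np.cumsum(per_interval, axis=1)[:, :m]
    return (start[:, None] + before) % 2, counts


def simulate_gametes(parent_haps: np.ndarray, snp_map: SnpMap, cm_per_mb: float,
                     rng: np.random.Generator, male: bool = False,
                     male_par_cm: float = 25.0):
    """Form one gamete per parent-haplotype pair.

    ``parent_haps`` is (n_gam, 2, m). Male gametes recombine on the X only
    within the PAR segment — at the elevated genetic length ``male_par_cm``
    the X/Y pairing imposes — and always transmit the slot-1 (maternal)
    allele on the X-specific segment, a male's single X. Returns (gametes,
    crossover counts per gamete summed over chromosomes).
    """
    n_gam, _, m = parent_haps.shape
    morgans_per_bp = cm_per_mb / 100.0 / 1e6
    gametes = np.empty((n_gam, m), dtype=np.int8)
    n_xo = np.zeros(n_gam, dtype=np.int64)
    for chrom, idx, length in _chrom_blocks(snp_map):
        pos = snp_map.pos[idx].astype(float)
        if male and chrom == X_CHROM:
            region = snp_map.region[idx]
            par_cols = np.flatnonzero(region == REGION_PAR)
            lo = float(snp_map.pos[idx[par_cols[0]]]) - 1.0 if len(par_cols) else float(length)
            start = np.ones(n_gam, dtype=np.int64)  # the single (maternal) X
            lam = male_par_cm / 100.0 if len(par_cols) else 0.0
            chooser, counts = _crossover_choosers(
                n_gam, pos, lo, float(length), morgans_per_bp, rng, start,
                lam_override=lam)
        else:
            start = rng.integers(0, 2, n_gam)
            chooser, counts = _crossover_choosers(
                n_gam, pos, 0.0, float(length), morgans_per_bp, rng, start)
        block = parent_haps[:, :, idx]
        gametes[:, idx] = np.where(chooser == 0, block[:, 0, :], block[:, 1, :])
        n_xo += counts
    return gametes, n_xo


def _x_specific_cols(snp_map: SnpMap) -> np.ndarray:
    return np.flatnonzero((snp_map.chrom == X_CHROM)
                          & (snp_map.region == REGION_X_SPECIFIC))


def _mirror_male_x(haps: np.ndarray, male_rows: np.ndarray, xs_cols: np.ndarray):
    """Represent male hemizygosity: slot 0 mirrors the single maternal X."""
    if len(xs_cols) and len(male_rows):
        haps[np.ix_(male_rows, [0], xs_cols)] = haps[np.ix_(male_rows, [1], xs_cols)]


def _assign_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.array([SEX_MALE, SEX_FEMALE] * (n // 2 + 1))[:n]
    return rng.permutation(sex)


def evolve_population(founders: HaplotypePanel, config: SimConfig) -> Population:
    """Random-mating Wright-Fisher generations from the founder panel.

    Gametes recombine by the Poisson/Haldane model; male X gametes only in
    the PAR. Returns the final generation.
    """
    if founders.n_haplotypes == 0:
        raise ValueError("founder panel is empty")
    if config.pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    rng = config.rng(2)
    m = len(config.snp_map)
    if founders.n_markers != m:
        raise ValueError("founder panel and snp_map are misaligned")
    N = config.pop_size
    # pair founder haplotypes into the generation-0 diploids
    if founders.n_haplotypes >= 2 * N:
        picks = rng.choice(founders.n_haplotypes, 2 * N, replace=False)
    else:
        picks = rng.choice(founders.n_haplotypes, 2 * N, replace=True)
    haps = founders.alleles[picks].reshape(N, 2, m).copy()
    sex = _assign_sexes(N, rng)
    xs = _x_specific_cols(config.snp_map)
    _mirror_male_x(haps, np.flatnonzero(sex == SEX_MALE), xs)
    ids = np.array([f"G0_{k}" for k in range(N)], dtype=object)
    sire = np.full(N, "0", dtype=object)
    dam = np.full(N, "0", dtype=object)
    for g in range(1, config.n_generations + 1):
        if g == config.n_generations and config.final_pop_size is not None:
            N = int(config.final_pop_size)
        males = np.flatnonzero(sex == SEX_MALE)
        females = np.flatnonzero(sex == SEX_FEMALE)
        if len(males) == 0 or len(females) == 0:  # guard tiny populations
            sex[0] = SEX_MALE if len(males) == 0 else SEX_FEMALE
            males = np.flatnonzero(sex == SEX_MALE)
            females = np.flatnonzero(sex == SEX_FEMALE)
        sires = rng.choice(males, N)
        dams = rng.choice(females, N)
        pat, _ = simulate_gametes(haps[sires], config.snp_map, config.cm_per_mb,
                                  rng, male=True, male_par_cm=config.male_par_cm)
        mat, _ = simulate_gametes(haps[dams], config.snp_map, config.cm_per_mb,
                                  rng, male=False)
        new_haps = np.stack([pat, mat], axis=1)
        new_sex = _assign_sexes(N, rng)
        _mirror_male_x(new_haps, np.flatnonzero(new_sex == SEX_MALE), xs)
        sire = ids[sires]
        dam = ids[dams]
        ids = np.array([f"G{g}_{k}" for k in range(N)], dtype=object)
        haps, sex = new_haps, new_sex
    return Population(ids, sex, sire, dam, haps, config.snp_map)


def make_halfsib_study(pop: Population, config: SimConfig) -> Study:
    """Sample sires and dams and breed half-sib families of male progeny.

    Sires are genotyped alongside the progeny (dams are not, as in
    bull-only chip datasets). Male X-specific genotypes are coded as the
    homozygote of the single allele, mimicking chip calls. The returned
    study carries the true progeny haplotypes with parent-of-origin labels.
    """
    rng = config.rng(3)
    males, females = pop.males(), pop.females()
    if config.n_sires > len(males):
        raise ValueError("requested more sires than males in the population")
    if config.progeny_per_sire > len(females):
        raise ValueError("requested more dams per sire than females available")
    snp_map = pop.snp_map
    m = len(snp_map)
    xs = _x_specific_cols(snp_map)
    sire_rows = rng.choice(males, config.n_sires, replace=False)

    sire_ids = [f"SIRE{k}" for k in range(config.n_sires)]
    prog_ids, prog_sire, prog_dam = [], [], []
    dam_ids_all: list[str] = []
    pat_parent_rows, mat_parent_rows = [], []
    # one dam per bull when the herd allows it (the usual dairy structure);
    # otherwise dams are distinct within a sire but reused across sires
    n_dams_needed = config.n_sires * config.progeny_per_sire
    global_dams = None
    if n_dams_needed <= len(females):
        global_dams = rng.choice(females, n_dams_needed, replace=False)
    for s, srow in enumerate(sire_rows):
        if global_dams is not None:
            dam_rows = global_dams[s * config.progeny_per_sire:
                                   (s + 1) * config.progeny_per_sire]
        else:
            dam_rows = rng.choice(females, config.progeny_per_sire, replace=False)
        for k, drow in enumerate(dam_rows):
            aid = f"BULL{s}_{k}"
            did = f"DAM{s}_{k}"
            prog_ids.append(aid)
            prog_sire.append(sire_ids[s])
            prog_dam.append(did)
            dam_ids_all.append(did)
            pat_parent_rows.append(srow)
            mat_parent_rows.append(drow)
    pat, _ = simulate_gametes(pop.haplotypes[np.array(pat_parent_rows)],
                              snp_map, config.cm_per_mb, rng, male=True,
                              male_par_cm=config.male_par_cm)
    mat, _ = simulate_gametes(pop.haplotypes[np.array(mat_parent_rows)],
                              snp_map, config.cm_per_mb, rng, male=False)
    n_prog = len(prog_ids)

    # truth panel: paternal row then maternal row per bull; the paternal
    # X-specific segment does not exist in a male and is marked unknown
    truth_alleles = np.empty((2 * n_prog, m), dtype=np.int8)
    truth_alleles[0::2] = pat
    truth_alleles[1::2] = mat
    if len(xs):
        truth_alleles[0::2][:, xs] = MISSING
    carriers = np.repeat(prog_ids, 2)
    origin = np.tile([ORIGIN_PATERNAL, ORIGIN_MATERNAL], n_prog)
    truth_panel = HaplotypePanel(truth_alleles, carriers, origin)

    # genotypes: male X-specific = homozygote of the single (maternal) allele
    prog_geno = (pat + mat).astype(np.int8)
    if len(xs):
        prog_geno[:, xs] = (2 * mat[:, xs]).astype(np.int8)
    sire_haps = pop.haplotypes[sire_rows]
    sire_geno = (sire_haps[:, 0, :] + sire_haps[:, 1, :]).astype(np.int8)
    if len(xs):
        sire_geno[:, xs] = (2 * sire_haps[:, 1, xs]).astype(np.int8)

    genotypes = np.vstack([sire_geno, prog_geno])
    animal_ids = np.array(sire_ids + prog_ids, dtype=object)

    ped_ids = sire_ids + sorted(set(dam_ids_all), key=dam_ids_all.index) + prog_ids
    ped_sire = ["0"] * config.n_sires + ["0"] * len(set(dam_ids_all)) + prog_sire
    ped_dam = ["0"] * config.n_sires + ["0"] * len(set(dam_ids_all)) + prog_dam
    ped_sex = ([SEX_MALE] * config.n_sires + [SEX_FEMALE] * len(set(dam_ids_all))
               + [SEX_MALE] * n_prog)
    pedigree = Pedigree(ped_ids, ped_sire, ped_dam, ped_sex)

    par_pos = snp_map.pos[(snp_map.chrom == X_CHROM) & (snp_map.region == REGION_PAR)]
    truth = StudyTruth(truth_panel, ArtifactLedger(),
                       par_start=int(par_pos.min()) if len(par_pos) else None)
    # displayed map hides the X region tags: inferring them is an analysis task
    shown_region = np.where(snp_map.chrom == X_CHROM, REGION_UNKNOWN, snp_map.region)
    shown_map = snp_map.with_regions(shown_region)
    return Study(genotypes, animal_ids, shown_map, pedigree,
                 study_ids=prog_ids, truth=truth)


def inject_artifacts(study: Study, n_misplaced: int = 0,
                     min_displacement_bp: int = 10_000_000,
                     mendel_rate: float = 0.0, missing_rate: float = 0.0,
                     seed: int = 0) -> tuple[Study, ArtifactLedger]:
    """Corrupt a study with known, ledgered artifacts.

    Misplaced markers get a new displayed position >= ``min_displacement_bp``
    away on the same chromosome (map re-sorted); Mendelian conflicts are
    created by flipping progeny calls against a homozygous sire; missing
    calls are masked at ``missing_rate`` among progeny.
    """
    if not (0 <= mendel_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng([seed, 4])
    ledger = ArtifactLedger()
    snp_map = study.snp_map
    geno = study.genotypes.copy()
    ids = snp_map.ids.copy()
    chrom = snp_map.chrom.copy()
    pos = snp_map.pos.copy().astype(np.int64)
    region = snp_map.region.copy()

    if n_misplaced > 0:
        # candidates: autosomal markers with room for the displacement
        spans = {c: (int(pos[snp_map.chrom == c].min()),
                     int(pos[snp_map.chrom == c].max()))
                 for c in snp_map.chromosomes() if c != X_CHROM}
        cand = [k for k in np.flatnonzero(snp_map.chrom != X_CHROM)
                if (pos[k] - spans[chrom[k]][0] >= min_displacement_bp
                    or spans[chrom[k]][1] - pos[k] >= min_displacement_bp)]
        if n_misplaced > len(cand):
            raise ValueError(
                "n_misplaced exceeds markers displaceable by the minimum "
                "distance on their chromosome")
        chosen = rng.choice(np.asarray(cand), n_misplaced, replace=False)
        for k in chosen:
            lo, hi = spans[chrom[k]]
            true_pos = int(pos[k])
            segs = [(lo, true_pos - min_displacement_bp),
                    (true_pos + min_displacement_bp, hi)]
            segs = [(a, b) for a, b in segs if b > a]
            taken = set(pos[snp_map.chrom == chrom[k]].tolist())
            lengths = np.array([b - a for a, b in segs], dtype=float)
            while True:
                a, b = segs[rng.choice(len(segs), p=lengths / lengths.sum())]
                new = int(rng.integers(a, b + 1))
                if new not in taken:
                    break
            pos[k] = new
            ledger.misplaced.append((str(ids[k]), true_pos, new))

    new_map = SnpMap(ids, chrom, pos, region)
    perm = new_map._input_order  # old column index per new column
    geno = geno[:, perm]
    truth = study.truth
    if truth is not None:
        truth = StudyTruth(truth.panel.subset_markers(perm), truth.ledger,
                           truth.par_start)

    prog_rows = np.array([study.animal_index(a) for a in study.study_ids])
    id_by_row = study.animal_ids
    if mendel_rate > 0 and study.pedigree is not None:
        sire_map = dict(zip(study.pedigree.frame["id"], study.pedigree.frame["sire"]))
        auto_cols = np.flatnonzero(new_map.chrom != X_CHROM)
        n_target = int(round(mendel_rate * len(prog_rows) * len(auto_cols)))
        for _ in range(n_target):
            r = int(rng.choice(prog_rows))
            sire = sire_map.get(id_by_row[r], "0")
            if sire == "0" or not study.has_animal(sire):
                continue
            srow = study.animal_index(sire)
            hom = auto_cols[np.isin(geno[srow, auto_cols], (0, 2))]
            if len(hom) == 0:
                continue
            ccol = int(rng.choice(hom))
            geno[r, ccol] = 2 if geno[srow, ccol] == 0 else 0
            ledger.mendel_errors.append((str(id_by_row[r]), str(new_map.ids[ccol])))

    if missing_rate > 0:
        mendel_set = {(a, mk) for a, mk in ledger.mendel_errors}
        mask = rng.random((len(prog_rows), len(new_map))) < missing_rate
        rr, cc = np.nonzero(mask)
        for r, ccol in zip(prog_rows[rr], cc):
            key = (str(id_by_row[r]), str(new_map.ids[ccol]))
            if key in mendel_set:
                continue
            geno[r, ccol] = MISSING
            ledger.missing.append(key)

    out = Study(geno, study.animal_ids, new_map, study.pedigree,
                study.study_ids, truth)
    return out, ledger
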