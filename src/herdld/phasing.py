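"""Pedigree-rule haplotype phasing and parental-origin splitting.

The phasing rules are sound but deliberately incomplete: homozygous and
missing genotypes phase trivially; a heterozygote is resolved only when the
animal's genotyped sire is homozygous (the paternal allele is then forced).
Heterozygotes under a heterozygous or ungenotyped sire stay unknown, and
LD counting downstream drops unknown-phase haplotypes pairwise. Analyses of
simulated studies normally use the simulator's true phase; this module is
the path for real genotype data.
"""

from __future__ import annotations

import numpy as np

from .containers import (MISSING, ORIGIN_MATERNAL, ORIGIN_PATERNAL,
                         REGION_X_SPECIFIC, SEX_MALE, HaplotypePanel, Study,
                         X_CHROM)


def phase_by_family_rules(study: Study) -> HaplotypePanel:
    """Phase the study cohort by simple sire rules.

    Returns a panel with two rows per study animal (paternal first,
    maternal second); unresolved entries are marked unknown. On tagged
    X-specific markers a male's single X is labeled maternal and his
    paternal slot left unknown (sons inherit the X from the dam).
    """
    sm = study.snp_map
    n = len(study.study_ids)
    m = study.n_markers
    pat = np.full((n, m), MISSING, dtype=np.int8)
    mat = np.full((n, m), MISSING, dtype=np.int8)
    sire_of, sex_of = {}, {}
    if study.pedigree is not None:
        ped = study.pedigree.frame
        sire_of = dict(zip(ped["id"], ped["sire"]))
        sex_of = dict(zip(ped["id"], ped["sex"]))
    xs = (sm.chrom == X_CHROM) & (sm.region == REGION_X_SPECIFIC)
    for r, aid in enumerate(study.study_ids):
        g = study.genotypes[study.animal_index(aid)]
        hom0 = g == 0
        hom2 = g == 2
        pat[r, hom0] = 0
        mat[r, hom0] = 0
        pat[r, hom2] = 1
        mat[r, hom2] = 1
        het = g == 1
        sid = sire_of.get(aid, "0")
        if sid != "0" and study.has_animal(sid):
            sg = study.genotypes[study.animal_index(sid)]
            forced0 = het & (sg == 0)
            forced1 = het & (sg == 2)
            pat[r, forced0] = 0
            mat[r, forced0] = 1
            pat[r, forced1] = 1
            mat[r, forced1] = 0
        if sex_of.get(aid) == SEX_MALE and xs.any():
            # hemizygous: the single X allele is the maternal haplotype
            known = xs & (g != MISSING) & (g != 1)
            mat[r, known] = (g[known] // 2).astype(np.int8)
            pat[r, xs] = MISSING
    alleles = np.empty((2 * n, m), dtype=np.int8)
    alleles[0::2] = pat
    alleles[1::2] = mat
    carrier = np.repeat(np.asarray(study.study_ids, dtype=object), 2)
    origin = np.tile([ORIGIN_PATERNAL, ORIGIN_MATERNAL], n)
    return HaplotypePanel(alleles, carrier, origin)


def split_parental(panel: HaplotypePanel) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Split a panel into (maternal, paternal) sub-panels by origin label."""
    if np.any(~np.isin(panel.origin, (ORIGIN_MATERNAL, ORIGIN_PATERNAL))):
        raise ValueError("panel contains unlabeled haplotypes")
    mat = panel.subset_rows(np.flatnonzero(panel.origin == ORIGIN_MATERNAL))
    pat = panel.subset_rows(np.flatnonzero(panel.origin == ORIGIN_PATERNAL))
    return mat, pat


def check_phase_against_truth(panel: HaplotypePanel,
                              truth: HaplotypePanel) -> float:
    """Fraction of phased (non-unknown) alleles that match the true phase.

    Rows are matched by (carrier, origin). Used as the rule-soundness
    diagnostic on simulated studies.
    """
    key = {(c, o): i for i, (c, o) in enumerate(zip(truth.carrier, truth.origin))}
    total, good = 0, 0
    for h in range(panel.n_haplotypes):
        t = key.get((panel.carrier[h], panel.origin[h]))
        if t is None:
            continue
        known = (panel.alleles[h] != MISSING) & (truth.alleles[t] != MISSING)
        total += int(known.sum())
        good += int((panel.alleles[h][known] == truth.alleles[t][known]).sum())
    return good / total if total else float("nan")
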