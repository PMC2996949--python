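"""Marker quality control: location/MAF/missingness filters and
Mendelian-consistency checks against the pedigree.

Filters are applied in a fixed order — unknown location, then MAF, then
missingness — and each marker is charged to the first rule it fails, so the
report counts are reproducible. MAF is computed from non-missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, REGION_PAR, SEX_MALE, Study, X_CHROM


@dataclass
class QcReport:
    n_input: int
    n_removed_location: int
    n_removed_maf: int
    n_removed_missing: int
    maf_before: float
    maf_after: float
    marker_maf: np.ndarray
    call_rate: np.ndarray
    n_mendel_corrected: int = 0

    @property
    def n_kept(self) -> int:
        return (self.n_input - self.n_removed_location - self.n_removed_maf
                - self.n_removed_missing)


def _unknown_location(study: Study) -> np.ndarray:
    sm = study.snp_map
    return (sm.chrom == "0") | (sm.pos <= 0)


def filter_snps(study: Study, maf_min: float = 0.05,
                max_missing: float = 0.10) -> tuple[Study, QcReport]:
    """Remove markers with unknown location, MAF < maf_min, or more than
    ``max_missing`` missing genotypes (in that order)."""
    if study.n_markers == 0:
        raise ValueError("study has no markers")
    maf = study.marker_maf()
    call = study.call_rate()
    bad_loc = _unknown_location(study)
    bad_maf = ~bad_loc & (np.isnan(maf) | (maf < maf_min))
    bad_miss = ~bad_loc & ~bad_maf & ((1.0 - call) > max_missing)
    keep = ~(bad_loc | bad_maf | bad_miss)
    report = QcReport(
        n_input=study.n_markers,
        n_removed_location=int(bad_loc.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_removed_missing=int(bad_miss.sum()),
        maf_before=float(np.nanmean(maf)) if study.n_markers else float("nan"),
        maf_after=float(np.nanmean(maf[keep])) if keep.any() else float("nan"),
        marker_maf=maf, call_rate=call)
    if not keep.any():
        counts = {"MAF": report.n_removed_maf,
                  "missingness": report.n_removed_missing,
                  "location": report.n_removed_location}
        dominant = max(counts, key=counts.get)
        raise ValueError(f"all markers removed (dominant rule: {dominant})")
    return study.subset_markers(np.flatnonzero(keep)), report


# transmissible gamete alleles per diploid genotype
_GAMETES = {0: {0}, 1: {0, 1}, 2: {1}}


def mendelian_check(study: Study, correct: bool = True
                    ) -> tuple[Study, list[tuple[str, str]]]:
    """Flag offspring genotypes incompatible with a genotyped parent.

    A single genotyped parent constrains the offspring only through the
    transmitted allele (parent 0 with offspring 2 is impossible; a
    heterozygous parent never conflicts). With both parents genotyped the
    offspring genotype must be a sum of transmissible gametes. Sire->son
    checks are skipped on X markers outside a tagged PAR segment, because
    sons inherit their X from the dam. With ``correct=True`` the offspring
    call is set to missing at every flagged (animal, marker).
    """
    if study.pedigree is None:
        return study, []
    sm = study.snp_map
    geno = study.genotypes.copy() if correct else study.genotypes
    ped = study.pedigree.frame
    sire_of = dict(zip(ped["id"], ped["sire"]))
    dam_of = dict(zip(ped["id"], ped["dam"]))
    sex_of = dict(zip(ped["id"], ped["sex"]))
    x_not_par = (sm.chrom == X_CHROM) & (sm.region != REGION_PAR)
    flagged: list[tuple[str, str]] = []
    for aid in study.study_ids:
        r = study.animal_index(aid)
        off = study.genotypes[r]
        bad = np.zeros(study.n_markers, dtype=bool)
        for parent_id, is_sire in ((sire_of.get(aid, "0"), True),
                                   (dam_of.get(aid, "0"), False)):
            if parent_id == "0" or not study.has_animal(parent_id):
                continue
            pg = study.genotypes[study.animal_index(parent_id)]
            conflict = (((pg == 0) & (off == 2)) | ((pg == 2) & (off == 0)))
            if is_sire and sex_of.get(aid) == SEX_MALE:
                conflict &= ~x_not_par  # son's X comes from the dam
            bad |= conflict
        # both parents genotyped: offspring must be a sum of gametes
        sid, did = sire_of.get(aid, "0"), dam_of.get(aid, "0")
        if (sid != "0" and did != "0" and study.has_animal(sid)
                and study.has_animal(did)):
            sg = study.genotypes[study.animal_index(sid)]
            dg = study.genotypes[study.animal_index(did)]
            both = (sg != MISSING) & (dg != MISSING) & (off != MISSING)
            for k in np.flatnonzero(both & ~bad):
                sums = {a + b for a in _GAMETES[int(sg[k])]
                        for b in _GAMETES[int(dg[k])]}
                if int(off[k]) not in sums:
                    if not (x_not_par[k] and sex_of.get(aid) == SEX_MALE):
                        bad[k] = True
        for k in np.flatnonzero(bad):
            flagged.append((aid, str(sm.ids[k])))
            if correct:
                geno[r, k] = MISSING
    if correct:
        out = Study(geno, study.animal_ids, sm, study.pedigree,
                    study.study_ids, study.truth)
        return out, flagged
    return study, flagged
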