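"""X chromosome: pseudo-autosomal boundary inference and stratified LD.

In a male-only genotype panel an X-specific SNP has no Y counterpart, so
males show at most the two homozygous genotype classes there (the
hemizygous call is coded as a homozygote). PAR SNPs sit on both X and Y
and can show all three classes — in particular heterozygotes, which are
impossible on the X-specific segment. Markers are therefore classified
PAR-like when heterozygous males are observed; at large sample sizes this
coincides with the three-genotype rule and it stays informative when the
rare homozygote class is absent by chance. The boundary is located by
walking from the terminal (high-bp) end toward the centromere until a
sustained run of two-class markers begins; the first marker terminal-ward
of that run is the first PAR marker. The run-length guard (default 5)
keeps a single PAR marker that happens to be monomorphic-in-males from
truncating the PAR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (MISSING, REGION_PAR, REGION_X_SPECIFIC, SEX_MALE,
                         HaplotypePanel, SnpMap, Study, X_CHROM)
from . import ldcore
from .decay import BinSpec, bin_by_distance, summarize_bins


@dataclass
class ParBoundary:
    """Inferred X-specific/PAR split: ``boundary_pos`` is the position of
    the first PAR marker (None when no PAR is detected)."""

    boundary_pos: int | None
    n_x_specific: int
    n_par: int
    min_run: int
    evidence: pd.DataFrame  # per X marker: id, pos, n genotype classes


def _male_rows(study: Study) -> np.ndarray:
    if study.pedigree is None:
        raise ValueError("pedigree with sexes required")
    sex = dict(zip(study.pedigree.frame["id"], study.pedigree.frame["sex"]))
    rows = [study.animal_index(a) for a in study.animal_ids
            if sex.get(a) == SEX_MALE]
    return np.asarray(rows, dtype=np.intp)


def find_par_boundary(study: Study, min_run: int = 5) -> ParBoundary:
    """Locate the first PAR marker on X from male genotype-class counts."""
    sm = study.snp_map
    x_idx = sm.chrom_indices(X_CHROM)
    if len(x_idx) == 0:
        raise ValueError("no X markers in the map")
    males = _male_rows(study)
    if len(males) == 0:
        raise ValueError("no males in the study")
    g = study.genotypes[np.ix_(males, x_idx)]
    n_classes = np.array([len(np.unique(col[col != MISSING]))
                          for col in g.T])
    het = (g == 1).any(axis=0)
    three = het | (n_classes >= 3)
    n = len(x_idx)
    evidence = pd.DataFrame({"id": sm.ids[x_idx], "pos": sm.pos[x_idx],
                             "n_classes": n_classes, "het_observed": het})
    boundary_idx: int | None = None
    run = 0
    for i in range(n - 1, -1, -1):
        if three[i]:
            run = 0
            continue
        run += 1
        if run >= min_run:
            boundary_idx = i + run  # first marker terminal-ward of the run
            break
    if boundary_idx is None:
        # no sustained two-class run: treat the whole chromosome as PAR
        # only if three-class markers exist at all
        boundary_idx = 0 if three.any() else n
    if boundary_idx >= n or not three[boundary_idx:].any():
        return ParBoundary(None, n, 0, min_run, evidence)
    pos = int(sm.pos[x_idx[boundary_idx]])
    return ParBoundary(pos, int(boundary_idx), n - int(boundary_idx),
                       min_run, evidence)


def tag_x_regions(snp_map: SnpMap, boundary: ParBoundary | int | None) -> SnpMap:
    """Return a map whose X markers are tagged by the boundary position."""
    bpos = boundary.boundary_pos if isinstance(boundary, ParBoundary) else boundary
    region = snp_map.region.copy()
    on_x = snp_map.chrom == X_CHROM
    if bpos is None:
        region[on_x] = REGION_X_SPECIFIC
    else:
        region[on_x & (snp_map.pos >= bpos)] = REGION_PAR
        region[on_x & (snp_map.pos < bpos)] = REGION_X_SPECIFIC
    return snp_map.with_regions(region)


def stratify_x_ld(panel: HaplotypePanel, snp_map: SnpMap,
                  boundary: ParBoundary | int | None,
                  binspec: BinSpec | None = None,
                  max_distance_bp: int | None = None) -> dict:
    """Within-region LD tables and bin summaries for X-specific and PAR.

    Cross-boundary pairs are excluded. The panel is expected to carry a
    male's single X as his maternal haplotype with the paternal X-specific
    slot unknown (the simulator's and phaser's convention), so hemizygosity
    is handled by pairwise deletion.
    """
    tagged = tag_x_regions(snp_map, boundary)
    out = {}
    for region in (REGION_X_SPECIFIC, REGION_PAR):
        cols = np.flatnonzero((tagged.chrom == X_CHROM) & (tagged.region == region))
        if len(cols) < 2:
            warnings.warn(f"fewer than 2 markers in region {region}")
            out[region] = {"table": pd.DataFrame(columns=ldcore.LD_COLUMNS),
                           "summary": None}
            continue
        sub_map = SnpMap(tagged.ids[cols], tagged.chrom[cols],
                         tagged.pos[cols], tagged.region[cols])
        sub_panel = panel.subset_markers(cols)
        table = ldcore.pairwise_ld(sub_panel, sub_map, scope="syntenic",
                                   max_distance_bp=max_distance_bp)
        summary = (summarize_bins(bin_by_distance(table, binspec))
                   if len(table) else None)
        out[region] = {"table": table, "summary": summary}
    return out
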