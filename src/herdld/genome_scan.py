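"""Genome scans over the LD landscape: sliding-window averages, detection
and relocation of misplaced markers via syntenic LD, and intragenic /
intergenic classification of SNP pairs.

A marker is called misplaced when its strongest same-chromosome LD partner
(largest r²) lies further away than a flag distance (10 Mb by default): at
that range genuine LD is essentially absent, so a distant best partner
points to an assembly-coordinate error. The corrected position is the
midpoint between the two partners with the highest r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import HaplotypePanel, SnpMap
from . import ldcore

MB = 1_000_000


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def sliding_window_ld(panel: HaplotypePanel, snp_map: SnpMap,
                      window: int = 2 * MB, step: int = 100_000,
                      pair_min: int = 200_000, pair_max: int = 600_000,
                      min_pairs: int = 20) -> pd.DataFrame:
    """Mean r²/|D'| per overlapping window along each chromosome.

    A window [s, s+window) uses pairs with both markers inside and
    inter-marker distance in [pair_min, pair_max]; windows with fewer than
    ``min_pairs`` such pairs are marked uninformative (no means reported).
    Also reports the SNP count per window and the fraction of window SNPs
    with MAF < 0.1.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    maf = panel.marker_maf()
    rows = []
    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        pos = snp_map.pos[idx]
        L = int(pos[-1])
        if L >= window:
            starts = np.arange(0, L - window + 1, step, dtype=np.int64)
        else:
            starts = np.array([0], dtype=np.int64)
        # candidate pairs once per chromosome
        ii, jj = np.triu_indices(len(idx), k=1)
        d = pos[jj] - pos[ii]
        keep = (d >= pair_min) & (d <= pair_max)
        ii, jj = ii[keep], jj[keep]
        if len(ii):
            tab = ldcore.ld_table_for_pairs(panel, snp_map, idx[ii], idx[jj],
                                            drop_undefined=False)
            pr2 = tab["r2"].to_numpy()
            pdp = tab["abs_dprime"].to_numpy()
            pdef = ~np.isnan(pr2)
            p_lo = pos[ii]
            p_hi = pos[jj]
        for s in starts:
            in_w = (pos >= s) & (pos < s + window)
            n_snps = int(in_w.sum())
            if n_snps:
                w_maf = maf[idx[in_w]]
                frac_low = float(np.nanmean(w_maf < 0.1))
            else:
                frac_low = np.nan
            if len(ii):
                sel = (p_lo >= s) & (p_hi < s + window) & pdef
                n_pairs = int(sel.sum())
            else:
                n_pairs = 0
            informative = n_pairs >= min_pairs
            rows.append({
                "chrom": chrom, "start": int(s), "end": int(s + window),
                "n_snps": n_snps, "n_pairs": n_pairs,
                "mean_r2": float(np.mean(pr2[sel])) if informative else np.nan,
                "mean_dprime": float(np.mean(pdp[sel])) if informative else np.nan,
                "frac_maf_lt_0.1": frac_low,
                "informative": informative,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# misplaced markers
# ---------------------------------------------------------------------------

@dataclass
class MisplacedCall:
    marker_id: str
    chrom: str
    displayed_pos: int
    best_partner: str
    best_r2: float
    distance_bp: int
    corrected_pos: int | None = None


def _best_partner(r2_row: np.ndarray, dist_row: np.ndarray,
                  defined_row: np.ndarray, self_k: int) -> int | None:
    """Index of the best LD partner: max r², ties by smaller distance then
    smaller index. Returns None when no defined partner exists."""
    cand = np.flatnonzero(defined_row)
    cand = cand[cand != self_k]
    if len(cand) == 0:
        return None
    order = np.lexsort((cand, dist_row[cand], -r2_row[cand]))
    return int(cand[order[0]])


def detect_misplaced(panel: HaplotypePanel, snp_map: SnpMap,
                     flag_distance: int = 10 * MB) -> list[MisplacedCall]:
    """Flag markers whose strongest same-chromosome r² partner is further
    than ``flag_distance`` away. Markers with no defined pair are skipped."""
    calls: list[MisplacedCall] = []
    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        if len(idx) < 2:
            continue
        r2, _, _, _, defined = ldcore.ld_matrix(panel, idx)
        pos = snp_map.pos[idx].astype(np.int64)
        dist = np.abs(pos[:, None] - pos[None, :])
        for k in range(len(idx)):
            b = _best_partner(r2[k], dist[k], defined[k], k)
            if b is None:
                continue
            if dist[k, b] > flag_distance:
                calls.append(MisplacedCall(
                    marker_id=str(snp_map.ids[idx[k]]), chrom=chrom,
                    displayed_pos=int(pos[k]),
                    best_partner=str(snp_map.ids[idx[b]]),
                    best_r2=float(r2[k, b]), distance_bp=int(dist[k, b])))
    return calls


def relocate_misplaced(panel: HaplotypePanel, snp_map: SnpMap,
                       call: MisplacedCall) -> int | None:
    """Approximate a flagged marker's true position.

    The marker is assumed to lie between its two highest-r² partners on the
    best partner's chromosome; the midpoint of their positions is returned
    (and stored on the call). With fewer than 2 defined partners the call
    is left uncorrected.
    """
    k = snp_map.index_of(call.marker_id)
    chrom = snp_map.chrom[snp_map.index_of(call.best_partner)]
    idx = snp_map.chrom_indices(chrom)
    r2, _, _, _, defined = ldcore.ld_matrix(panel, idx)
    krow = np.flatnonzero(idx == k)
    if len(krow):  # marker displayed on the partner's chromosome
        kk = int(krow[0])
        r2_row, def_row = r2[kk], defined[kk]
    else:
        tab_i = np.full(len(idx), k)
        a, b, c, d = ldcore._pair_counts(panel, tab_i, idx)
        _, _, r2_row, def_row = ldcore._ld_from_counts(a, b, c, d)
        def_row = def_row & ~np.isnan(r2_row)
        kk = -1
    pos = snp_map.pos[idx].astype(np.int64)
    dist = np.abs(pos - call.displayed_pos)
    cand = np.flatnonzero(def_row)
    cand = cand[cand != kk]
    if len(cand) < 2:
        warnings.warn(f"{call.marker_id}: fewer than 2 defined partners; "
                      "left uncorrected")
        return None
    order = np.lexsort((cand, dist[cand], -r2_row[cand]))
    p1, p2 = cand[order[0]], cand[order[1]]
    corrected = int(round((pos[p1] + pos[p2]) / 2))
    call.corrected_pos = corrected
    return corrected


def apply_relocations(snp_map: SnpMap, calls: list[MisplacedCall]) -> SnpMap:
    """Corrected map (re-sorted) after moving every corrected call."""
    pos = snp_map.pos.copy()
    taken = set(pos.tolist())
    for call in calls:
        if call.corrected_pos is None:
            continue
        k = snp_map.index_of(call.marker_id)
        new = int(call.corrected_pos)
        while new in taken:  # avoid exact collisions with existing markers
            new += 1
        taken.add(new)
        pos[k] = new
    return snp_map.with_positions(pos)


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

def classify_gene_context(snp_map: SnpMap, genes: pd.DataFrame,
                          table: pd.DataFrame) -> pd.DataFrame:
    """Label syntenic pairs intragenic / intergenic / mixed.

    A pair is intragenic when both markers lie within the same gene's
    [start, end] (1-based closed); intergenic when both lie outside all
    genes; anything else is mixed (excluded from two-group summaries).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, name) for s, e, name
            in zip(grp["start"], grp["end"], grp["name"]))
    gene_sets: dict[str, frozenset] = {}
    for mid, chrom, pos in zip(snp_map.ids, snp_map.chrom, snp_map.pos):
        tree = trees.get(chrom)
        hits = frozenset(iv.data for iv in tree[int(pos)]) if tree else frozenset()
        gene_sets[str(mid)] = hits
    labels = []
    for row in table.itertuples(index=False):
        g1 = gene_sets.get(str(row.id1), frozenset())
        g2 = gene_sets.get(str(row.id2), frozenset())
        if g1 and g2 and (g1 & g2):
            labels.append("intragenic")
        elif not g1 and not g2:
            labels.append("intergenic")
        else:
            labels.append("mixed")
    out = table.copy()
    out["gene_context"] = labels
    return out


GENE_DISTANCE_CLASSES = ((0, 40_000), (40_000, 60_000),
                         (60_000, 80_000), (80_000, 100_000))


def gene_context_summary(labeled: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of r² by gene context and short-distance class (mixed pairs
    excluded)."""
    rows = []
    for lo, hi in GENE_DISTANCE_CLASSES:
        sel = (labeled["distance_bp"] >= lo) & (labeled["distance_bp"] < hi)
        for ctx in ("intergenic", "intragenic"):
            grp = labeled[sel & (labeled["gene_context"] == ctx)]
            r2 = grp["r2"].dropna().to_numpy()
            rows.append({"distance_class": f"{lo // 1000}-{hi // 1000} kb",
                         "context": ctx, "n": len(r2),
                         "mean_r2": float(np.mean(r2)) if len(r2) else np.nan,
                         "sd_r2": float(np.std(r2, ddof=1)) if len(r2) > 1
                         else (0.0 if len(r2) == 1 else np.nan)})
    return pd.DataFrame(rows)
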