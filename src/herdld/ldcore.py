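"""Pairwise linkage disequilibrium: D, |D'| and r² from phased haplotypes.

All statistics are computed by direct counting over phased haplotypes
(pairwise deletion of unknown-phase rows). With haplotype counts
``a = n(AB), b = n(Ab), c = n(aB), d = n(ab)`` and ``n = a+b+c+d``:

    D   = pi_AB - pi_A * pi_B = (a*d - b*c) / n^2
    r^2 = D^2 / (pi_A * pi_a * pi_B * pi_b)
    D'  = D / D_max,  D_max = min(pi_A*pi_b, pi_a*pi_B)  if D > 0
                      D_max = min(pi_A*pi_B, pi_a*pi_b)  if D < 0

Working on the integer counts keeps |D'| = 1 exact whenever a haplotype
class is absent, and r² = 1 exact when only two complementary classes are
present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HaplotypePanel, SnpMap

#: column layout of an LD table
LD_COLUMNS = ["id1", "id2", "chrom1", "chrom2", "pos1", "pos2",
              "distance_bp", "D", "abs_dprime", "r2", "mean_maf", "n"]

SCOPES = ("syntenic", "adjacent", "non_syntenic")


@dataclass
class HapFreqs:
    """Two-locus haplotype and allele frequencies from direct counting."""

    pi_AB: float
    pi_Ab: float
    pi_aB: float
    pi_ab: float
    n: int

    @property
    def pi_A(self) -> float:
        return self.pi_AB + self.pi_Ab

    @property
    def pi_B(self) -> float:
        return self.pi_AB + self.pi_aB

    @property
    def pi_a(self) -> float:
        return 1.0 - self.pi_A

    @property
    def pi_b(self) -> float:
        return 1.0 - self.pi_B

    def counts(self) -> tuple[float, float, float, float]:
        return (self.pi_AB * self.n, self.pi_Ab * self.n,
                self.pi_aB * self.n, self.pi_ab * self.n)


@dataclass
class LDStats:
    D: float
    abs_dprime: float
    r2: float
    defined: bool


def haplotype_freqs(panel: HaplotypePanel, i: int, j: int) -> HapFreqs:
    """Count two-locus haplotype frequencies at markers ``i`` and ``j``.

    Haplotypes with unknown phase at either marker are dropped pairwise.
    Raises ``ValueError`` when fewer than 2 usable haplotypes remain.
    """
    x = panel.alleles[:, i]
    y = panel.alleles[:, j]
    use = (x >= 0) & (y >= 0)
    n = int(use.sum())
    if n < 2:
        raise ValueError(f"fewer than 2 usable haplotypes for markers {i},{j}")
    x, y = x[use], y[use]
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = n - a - b - c
    return HapFreqs(a / n, b / n, c / n, d / n, n)


def _ld_from_counts(a, b, c, d):
    """Vectorized D/|D'|/r² from (possibly array) haplotype counts.

    Returns (D, abs_dprime, r2, defined); undefined entries (a monomorphic
    locus or n < 2) are NaN with defined=False.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    nA, na = a + b, c + d
    nB, nb = a + c, b + d
    defined = (n >= 2) & (nA > 0) & (na > 0) & (nB > 0) & (nb > 0)
    det = a * d - b * c
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(defined, det / (n * n), np.nan)
        r2 = np.where(defined, det * det / (nA * na * nB * nb), np.nan)
        dmax_pos = np.minimum(nA * nb, na * nB)
        dmax_neg = np.minimum(nA * nB, na * nb)
        dmax = np.where(det > 0, dmax_pos, dmax_neg)
        absdp = np.where(det == 0, 0.0, np.abs(det) / dmax)
        absdp = np.where(defined, absdp, np.nan)
    return D, absdp, r2, defined


def pair_ld(f: HapFreqs) -> LDStats:
    """LD statistics for one pair of loci from its haplotype frequencies."""
    a, b, c, d = f.counts()
    D, absdp, r2, defined = _ld_from_counts(a, b, c, d)
    return LDStats(float(D), float(absdp), float(r2), bool(defined))


def _pair_counts(panel: HaplotypePanel, i_idx: np.ndarray, j_idx: np.ndarray,
                 chunk: int = 200_000):
    """Haplotype counts (a,b,c,d) for explicit marker pairs, chunked."""
    H = panel.alleles
    out = [np.empty(len(i_idx)) for _ in range(4)]
    for s in range(0, len(i_idx), chunk):
        ii = i_idx[s:s + chunk]
        jj = j_idx[s:s + chunk]
        X = H[:, ii]
        Y = H[:, jj]
        use = (X >= 0) & (Y >= 0)
        x1 = (X == 1) & use
        y1 = (Y == 1) & use
        n = use.sum(axis=0).astype(np.float64)
        a = (x1 & y1).sum(axis=0).astype(np.float64)
        nA = x1.sum(axis=0).astype(np.float64)
        nB = y1.sum(axis=0).astype(np.float64)
        out[0][s:s + chunk] = a
        out[1][s:s + chunk] = nA - a
        out[2][s:s + chunk] = nB - a
        out[3][s:s + chunk] = n - nA - nB + a
    return out


def ld_matrix(panel: HaplotypePanel, cols: np.ndarray):
    """All-pairs LD among the markers ``cols`` via count matrices.

    Returns (r2, abs_dprime, D, n, defined) square matrices of side
    ``len(cols)`` (diagonal included, generally r²=1 there).
    """
    H = panel.alleles[:, cols]
    A = (H == 1).astype(np.float64)
    K = (H >= 0).astype(np.float64)
    n = K.T @ K
    a = A.T @ A
    nA = A.T @ K
    nB = K.T @ A
    b = nA - a
    c = nB - a
    d = n - nA - nB + a
    D, absdp, r2, defined = _ld_from_counts(a, b, c, d)
    return r2, absdp, D, n, defined


def _syntenic_pairs(snp_map: SnpMap, max_distance_bp=None):
    i_all, j_all = [], []
    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        gi, gj = idx[ii], idx[jj]
        if max_distance_bp is not None:
            keep = np.abs(snp_map.pos[gi] - snp_map.pos[gj]) <= max_distance_bp
            gi, gj = gi[keep], gj[keep]
        i_all.append(gi)
        j_all.append(gj)
    if not i_all:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    return np.concatenate(i_all), np.concatenate(j_all)


def _adjacent_pairs(snp_map: SnpMap):
    i_all, j_all = [], []
    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        if len(idx) >= 2:
            i_all.append(idx[:-1])
            j_all.append(idx[1:])
    if not i_all:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    return np.concatenate(i_all), np.concatenate(j_all)


def _non_syntenic_pairs(snp_map: SnpMap, fraction=None, seed=None):
    chroms = np.asarray(snp_map.chrom)
    m = len(snp_map)
    ii, jj = np.triu_indices(m, k=1)
    keep = chroms[ii] != chroms[jj]
    ii, jj = ii[keep], jj[keep]
    if fraction is not None and fraction < 1.0:
        rng = np.random.default_rng(seed)
        take = rng.random(len(ii)) < fraction
        ii, jj = ii[take], jj[take]
    return ii.astype(np.intp), jj.astype(np.intp)


def pairwise_ld(panel: HaplotypePanel, snp_map: SnpMap, scope: str = "syntenic",
                max_distance_bp: int | None = None,
                subsample_fraction: float | None = None,
                seed: int | None = None,
                drop_undefined: bool = True) -> pd.DataFrame:
    """Run the pairwise LD engine and return an LD table.

    Parameters
    ----------
    scope
        ``"syntenic"`` — all within-chromosome pairs (optionally capped at
        ``max_distance_bp``); ``"adjacent"`` — consecutive markers per
        chromosome; ``"non_syntenic"`` — cross-chromosome pairs, optionally
        thinned to ``subsample_fraction`` with ``seed``.
    drop_undefined
        drop pairs where either marker is monomorphic among usable
        haplotypes (default); otherwise keep them with NaN statistics.
    """
    if panel.n_markers != len(snp_map):
        raise ValueError("panel and map are misaligned")
    if scope == "syntenic":
        i_idx, j_idx = _syntenic_pairs(snp_map, max_distance_bp)
    elif scope == "adjacent":
        i_idx, j_idx = _adjacent_pairs(snp_map)
    elif scope == "non_syntenic":
        i_idx, j_idx = _non_syntenic_pairs(snp_map, subsample_fraction, seed)
    else:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    return ld_table_for_pairs(panel, snp_map, i_idx, j_idx,
                              drop_undefined=drop_undefined)


def ld_table_for_pairs(panel: HaplotypePanel, snp_map: SnpMap,
                       i_idx: np.ndarray, j_idx: np.ndarray,
                       drop_undefined: bool = True) -> pd.DataFrame:
    """LD table for an explicit list of marker-index pairs."""
    a, b, c, d = _pair_counts(panel, i_idx, j_idx)
    D, absdp, r2, defined = _ld_from_counts(a, b, c, d)
    n = a + b + c + d
    nA, nB = a + b, a + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = nA / n
        fB = nB / n
    mean_maf = 0.5 * (np.minimum(fA, 1 - fA) + np.minimum(fB, 1 - fB))
    syntenic = snp_map.chrom[i_idx] == snp_map.chrom[j_idx]
    dist = np.abs(snp_map.pos[i_idx] - snp_map.pos[j_idx]).astype(float)
    dist = np.where(syntenic, dist, np.nan)
    table = pd.DataFrame({
        "id1": snp_map.ids[i_idx], "id2": snp_map.ids[j_idx],
        "chrom1": snp_map.chrom[i_idx], "chrom2": snp_map.chrom[j_idx],
        "pos1": snp_map.pos[i_idx], "pos2": snp_map.pos[j_idx],
        "distance_bp": dist, "D": D, "abs_dprime": absdp, "r2": r2,
        "mean_maf": mean_maf, "n": n.astype(int),
    })
    if drop_undefined:
        table = table[defined].reset_index(drop=True)
    return table
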