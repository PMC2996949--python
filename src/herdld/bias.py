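"""Bias diagnostics for LD estimates.

Three tools: the sample-size experiment (bootstrap subsamples of animals,
LD recomputed per subsample — |D'| inflates in small samples, r² is robust),
residual LD by MAF group (pairwise LD centred on its distance-bin mean —
|D'| is inflated at low MAF, r² is not), and a χ² contrast of paternal
against maternal haplotype frequencies (heavy sire use makes the paternal
pool unrepresentative in half-sib designs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HaplotypePanel, SnpMap
from . import ldcore
from .decay import BinSpec, bin_by_distance

DEFAULT_SIZES = (22, 55, 111, 222, 444, 665, "all")

#: distance ranges (bp) over which subsample means are reported
DEFAULT_DISTANCE_RANGES = ((0, 100_000), (100_000, 500_000),
                           (500_000, 1_000_000), (1_000_000, 2_000_000))


def subsample_experiment(panel: HaplotypePanel, snp_map: SnpMap,
                         sizes=DEFAULT_SIZES, n_rep: int = 200, seed: int = 0,
                         distance_ranges=DEFAULT_DISTANCE_RANGES,
                         max_pairs_per_range: int = 2000) -> pd.DataFrame:
    """Mean r² and |D'| per (sample size, distance range), averaged over
    bootstrap subsamples of animals.

    Sampling is by animal, drawn with replacement; each draw contributes
    all of the animal's haplotypes in the panel. The sentinel size
    ``"all"`` evaluates the full panel once without resampling. LD is
    evaluated on a fixed, seeded set of pairs (at most
    ``max_pairs_per_range`` per range) so sizes are compared like-for-like.
    """
    carriers = pd.unique(panel.carrier)
    n_animals = len(carriers)
    for s in sizes:
        if s != "all" and int(s) > n_animals:
            raise ValueError(f"subsample size {s} exceeds the {n_animals} animals")
    rng = np.random.default_rng([seed, 7])
    rows_of = {c: [] for c in carriers}
    for h, c in enumerate(panel.carrier):
        rows_of[c].append(h)
    rows_arr = {c: np.array(v) for c, v in rows_of.items()}

    # fixed pair set per distance range
    pair_sets = []
    for lo, hi in distance_ranges:
        i_idx, j_idx = ldcore._syntenic_pairs(snp_map, hi)
        d = np.abs(snp_map.pos[i_idx] - snp_map.pos[j_idx])
        keep = (d >= lo) & (d < hi)
        i_idx, j_idx = i_idx[keep], j_idx[keep]
        if len(i_idx) > max_pairs_per_range:
            take = rng.choice(len(i_idx), max_pairs_per_range, replace=False)
            i_idx, j_idx = i_idx[take], j_idx[take]
        pair_sets.append((lo, hi, i_idx, j_idx))

    def range_means(p: HaplotypePanel):
        out = []
        for lo, hi, i_idx, j_idx in pair_sets:
            if len(i_idx) == 0:
                out.append((np.nan, np.nan))
                continue
            a, b, c, d = ldcore._pair_counts(p, i_idx, j_idx)
            _, absdp, r2, defined = ldcore._ld_from_counts(a, b, c, d)
            if defined.any():
                out.append((float(np.nanmean(r2[defined])),
                            float(np.nanmean(absdp[defined]))))
            else:
                out.append((np.nan, np.nan))
        return out

    results = []
    for size in sizes:
        if size == "all":
            per_range = [range_means(panel)]
        else:
            per_range = []
            for _ in range(n_rep):
                picks = rng.choice(n_animals, int(size), replace=True)
                rows = np.concatenate([rows_arr[carriers[p]] for p in picks])
                per_range.append(range_means(panel.subset_rows(rows)))
        arr = np.array(per_range, dtype=float)  # (reps, ranges, 2)
        for ri, (lo, hi, i_idx, _) in enumerate(pair_sets):
            results.append({
                "size": size, "range_lo": lo, "range_hi": hi,
                "n_pairs": len(i_idx),
                "mean_r2": float(np.nanmean(arr[:, ri, 0])),
                "mean_dprime": float(np.nanmean(arr[:, ri, 1])),
                "n_replicates": 1 if size == "all" else n_rep,
            })
    return pd.DataFrame(results)


def residual_ld_by_maf(table: pd.DataFrame, binspec: BinSpec | None = None,
                       maf_group_width: float = 0.05) -> pd.DataFrame:
    """Mean residual r² and |D'| per mean-MAF group.

    The residual of a pair is its LD value minus the mean of its distance
    bin, removing the distance trend so the MAF effect stands alone. MAF
    groups are [k*w, (k+1)*w) on the mean MAF of the pair.
    """
    binned = bin_by_distance(table, binspec)
    out = binned[["r2", "abs_dprime", "mean_maf", "bin"]].dropna().copy()
    for col in ("r2", "abs_dprime"):
        out[f"resid_{col}"] = out[col] - out.groupby("bin", observed=True)[col].transform("mean")
    w = maf_group_width
    grp_idx = np.floor(out["mean_maf"].to_numpy() / w).astype(int)
    # a MAF of exactly 0.5 belongs to the top group
    grp_idx = np.minimum(grp_idx, int(np.ceil(0.5 / w)) - 1)
    out["maf_group"] = grp_idx
    rows = []
    for g, grp in out.groupby("maf_group"):
        rows.append({
            "maf_lo": g * w, "maf_hi": (g + 1) * w, "n": len(grp),
            "mean_resid_r2": float(grp["resid_r2"].mean()),
            "mean_resid_dprime": float(grp["resid_abs_dprime"].mean()),
        })
    return pd.DataFrame(rows)


def compare_parental_freqs(maternal: HaplotypePanel, paternal: HaplotypePanel,
                           snp_map: SnpMap, alpha: float = 0.01,
                           scope: str = "syntenic",
                           max_distance_bp: int | None = None,
                           i_idx: np.ndarray | None = None,
                           j_idx: np.ndarray | None = None
                           ) -> tuple[pd.DataFrame, float]:
    """χ² contrast of paternal vs maternal haplotype frequencies per pair.

    Maternal frequencies are taken as the expected law; the observed
    paternal class counts are tested against expected = maternal frequency
    x paternal count, df = (classes after pooling) - 1. Classes with zero
    maternal frequency are pooled into the smallest non-zero class. Pairs
    whose classes all pool away are skipped. Returns the per-pair table and
    the fraction of testable pairs with P < alpha.
    """
    if maternal.n_markers != paternal.n_markers or maternal.n_markers != len(snp_map):
        raise ValueError("panels and map are misaligned")
    if i_idx is None or j_idx is None:
        if scope == "syntenic":
            i_idx, j_idx = ldcore._syntenic_pairs(snp_map, max_distance_bp)
        elif scope == "adjacent":
            i_idx, j_idx = ldcore._adjacent_pairs(snp_map)
        else:
            raise ValueError(f"unsupported scope {scope!r}")
    Mc = np.stack(ldcore._pair_counts(maternal, i_idx, j_idx), axis=1)  # (p,4)
    Pc = np.stack(ldcore._pair_counts(paternal, i_idx, j_idx), axis=1)
    n_m = Mc.sum(axis=1, keepdims=True)
    n_p = Pc.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = Mc / n_m * n_p
    zero = Mc == 0
    # pool observations of zero-expected classes into the smallest non-zero class
    M_for_min = np.where(zero, np.inf, Mc)
    target = np.argmin(M_for_min, axis=1)
    pooled_obs = (Pc * zero).sum(axis=1)
    Pp = Pc.copy().astype(float)
    Pp[np.arange(len(Pp)), target] += pooled_obs
    Pp[zero] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(zero | (expected == 0), 0.0,
                         (Pp - expected) ** 2 / expected)
    chi2 = terms.sum(axis=1)
    df = (~zero).sum(axis=1) - 1
    valid = (df >= 1) & (n_m[:, 0] > 0) & (n_p[:, 0] > 0)
    pvals = np.full(len(chi2), np.nan)
    pvals[valid] = stats.chi2.sf(chi2[valid], df[valid])
    table = pd.DataFrame({
        "id1": snp_map.ids[i_idx], "id2": snp_map.ids[j_idx],
        "chi2": np.where(valid, chi2, np.nan), "df": df, "p": pvals,
    })
    frac = float(np.mean(pvals[valid] < alpha)) if valid.any() else float("nan")
    return table, frac
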