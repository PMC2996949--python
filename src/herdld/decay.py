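"""LD decay with physical distance: distance bins, per-bin summaries and
percentile-bootstrap confidence intervals for the bin means.

Bins are lower-closed, upper-open ``[lo, hi)``; the default edges follow
the standard chip-study layout from 0-40 kb out to >100 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KB = 1_000
MB = 1_000_000

DEFAULT_EDGES = (0, 40 * KB, 60 * KB, 100 * KB, 200 * KB, 500 * KB,
                 1 * MB, 2 * MB, 5 * MB, 10 * MB, 20 * MB, 50 * MB,
                 100 * MB, np.inf)


def _fmt_bp(x: float) -> str:
    if np.isinf(x):
        return "inf"
    if x >= MB:
        v = x / MB
        return f"{v:g} Mb"
    if x >= KB:
        return f"{x / KB:g} kb"
    return f"{x:g} bp"


@dataclass
class BinSpec:
    """Distance-bin edges in bp; ``[lo, hi)`` convention."""

    edges: tuple = DEFAULT_EDGES

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        self.edges = tuple(e)

    @property
    def labels(self) -> list[str]:
        return [f"{_fmt_bp(lo)}-{_fmt_bp(hi)}" if np.isfinite(hi)
                else f">{_fmt_bp(lo)}"
                for lo, hi in zip(self.edges[:-1], self.edges[1:])]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def bin_by_distance(table: pd.DataFrame, spec: BinSpec | None = None) -> pd.DataFrame:
    """Assign each syntenic pair to exactly one distance bin.

    Adds a categorical ``bin`` column; rejects tables containing
    non-syntenic records (missing distance).
    """
    spec = spec or BinSpec()
    if table["distance_bp"].isna().any():
        raise ValueError("non-syntenic records present; bin syntenic tables only")
    idx = np.searchsorted(spec.edges, table["distance_bp"].to_numpy(),
                          side="right") - 1
    idx = np.clip(idx, 0, spec.n_bins - 1)
    out = table.copy()
    out["bin"] = pd.Categorical.from_codes(idx, categories=spec.labels)
    return out


DEFAULT_THRESHOLDS = {"r2": (0.3, 0.15), "dprime": (0.8,)}


def summarize_bins(binned: pd.DataFrame,
                   thresholds: dict | None = None) -> pd.DataFrame:
    """Per-bin n, mean/SD/median of r² and |D'| and threshold fractions.

    Pairs with undefined statistics are excluded; empty bins report n=0
    with NaN statistics; single-pair bins report SD = 0.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    rows = []
    for label, grp in binned.groupby("bin", observed=False):
        r2 = grp["r2"].to_numpy(dtype=float)
        dp = grp["abs_dprime"].to_numpy(dtype=float)
        ok = ~(np.isnan(r2) | np.isnan(dp))
        r2, dp = r2[ok], dp[ok]
        n = len(r2)
        row = {"bin": label, "n": n}
        for name, v in (("r2", r2), ("dprime", dp)):
            row[f"mean_{name}"] = float(np.mean(v)) if n else np.nan
            row[f"sd_{name}"] = (float(np.std(v, ddof=1)) if n > 1
                                 else (0.0 if n == 1 else np.nan))
            row[f"median_{name}"] = float(np.median(v)) if n else np.nan
            for t in thresholds.get(name, ()):
                row[f"frac_{name}_gt_{t:g}"] = (float(np.mean(v > t))
                                                if n else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_ci(binned: pd.DataFrame, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> pd.DataFrame:
    """Percentile-bootstrap CI of the per-bin mean r² and mean |D'|.

    Each bin is resampled with replacement at its own size ``n_boot``
    times; the CI is the (1-level)/2 and (1+level)/2 percentile of the
    bootstrap means. Also reports the bootstrap SE (SD of the means).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    lo_q = 100 * (1 - level) / 2
    hi_q = 100 - lo_q
    rows = []
    for label, grp in binned.groupby("bin", observed=False):
        vals = grp[["r2", "abs_dprime"]].dropna().to_numpy(dtype=float)
        n = len(vals)
        row = {"bin": label, "n": n}
        if n == 0:
            for name in ("r2", "dprime"):
                row.update({f"{name}_ci_lo": np.nan, f"{name}_ci_hi": np.nan,
                            f"{name}_boot_se": np.nan})
            rows.append(row)
            continue
        # chunk the bootstrap to bound memory on large bins
        max_cells = 20_000_000
        step = max(1, min(n_boot, max_cells // max(n, 1)))
        means = np.empty((n_boot, 2))
        for s in range(0, n_boot, step):
            k = min(step, n_boot - s)
            picks = rng.integers(0, n, (k, n))
            means[s:s + k] = vals[picks].mean(axis=1)
        for c, name in enumerate(("r2", "dprime")):
            row[f"{name}_ci_lo"] = float(np.percentile(means[:, c], lo_q))
            row[f"{name}_ci_hi"] = float(np.percentile(means[:, c], hi_q))
            row[f"{name}_boot_se"] = float(np.std(means[:, c], ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def decay_summary(table: pd.DataFrame, spec: BinSpec | None = None,
                  n_boot: int = 1000, seed: int = 0,
                  thresholds: dict | None = None) -> pd.DataFrame:
    """Bin a syntenic LD table and attach summaries plus bootstrap CIs."""
    spec = spec or BinSpec()
    binned = bin_by_distance(table, spec)
    summary = summarize_bins(binned, thresholds)
    ci = bootstrap_ci(binned, n_boot=n_boot, seed=seed)
    return summary.merge(ci.drop(columns=["n"]), on="bin")
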