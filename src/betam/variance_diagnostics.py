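"""Heteroscedasticity diagnostics: replicate mean-SD relations and histograms.

The Beta-value is bounded in [0, 1], and on technical replicates its standard
deviation is strongly compressed near the boundaries: the measure is severely
heteroscedastic at highly methylated or unmethylated sites. The logit-scale
M-value is approximately homoscedastic. The diagnostic here is the classic
mean-versus-SD plot: per-site replicate means and SDs, sites ranked by mean and
split into 20 equal-occupancy bins, and the median SD reported per bin. A
histogram summary with a simple smoothed-local-maxima mode count supports the
companion observation that the M-value histogram is clearly bimodal (one
unmethylated, negative mode and one methylated, positive mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from betam.core_metrics import MethylationMatrix

__all__ = [
    "MeanSdBinTable",
    "HistogramSummary",
    "replicate_mean_sd",
    "bin_mean_sd",
    "histogram_summary",
]


@dataclass
class MeanSdBinTable:
    """Equal-occupancy mean-SD bins plus the per-site pairs they summarize.

    ``bins`` has one row per bin: bin_index, mean_low, mean_high, n_sites,
    median_sd, ordered by mean. ``pairs`` holds the per-site (mean, sd) pairs
    used, indexed by site id.
    """

    bins: pd.DataFrame
    pairs: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False, float_format="%.9g")


@dataclass
class HistogramSummary:
    """Histogram counts plus a descriptive bimodality indicator.

    ``n_modes`` counts local maxima of the counts after 3-bin moving-average
    smoothing; ``mode_centers`` are the corresponding bin centers ordered by
    decreasing peak height, so the signs of the first two entries identify the
    methylated (positive) and unmethylated (negative) modes on the M scale.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    n_modes: int
    mode_centers: np.ndarray

    @property
    def top_mode_signs(self) -> list[int]:
        return [int(np.sign(c)) for c in self.mode_centers[:2]]

    def to_tsv(self, path) -> None:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        pd.DataFrame(
            {"bin_center": centers, "count": self.counts, "smoothed": self.smoothed}
        ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def replicate_mean_sd(
    values: MethylationMatrix,
    replicate_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-site replicate mean and standard deviation, pooled across groups.

    ``replicate_groups`` maps a group label to the array ids of one set of
    technical replicates; only groups with at least two arrays contribute. Per
    site and group the mean and sample (n-1) SD are computed over arrays with
    non-missing values (a site missing any cell in a group is excluded from
    that group); the pooled per-site SD is the degrees-of-freedom-weighted
    root mean square of the within-group SDs, and the pooled mean is the
    unweighted mean of group means.
    """
    col = {a: j for j, a in enumerate(values.array_ids)}
    used = []
    for label, arrays in replicate_groups.items():
        missing = [a for a in arrays if a not in col]
        if missing:
            raise KeyError(f"group {label!r} references unknown arrays {missing}")
        if len(arrays) >= 2:
            used.append([col[a] for a in arrays])
    if not used:
        raise ValueError("need at least one replicate group with >= 2 arrays")

    n_sites = values.n_sites
    sum_means = np.zeros(n_sites)
    n_groups = np.zeros(n_sites)
    sum_df_var = np.zeros(n_sites)
    sum_df = np.zeros(n_sites)
    for idx in used:
        sub = values.values[:, idx]
        ok = np.all(np.isfinite(sub), axis=1)
        g_mean = sub.mean(axis=1)
        g_sd = sub.std(axis=1, ddof=1)
        df = len(idx) - 1
        sum_means[ok] += g_mean[ok]
        n_groups[ok] += 1
        sum_df_var[ok] += df * g_sd[ok] ** 2
        sum_df[ok] += df
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_groups > 0, sum_means / n_groups, np.nan)
        sd = np.where(sum_df > 0, np.sqrt(sum_df_var / np.maximum(sum_df, 1)), np.nan)
    return pd.DataFrame({"mean": mean, "sd": sd},
                        index=pd.Index(values.site_ids, name="TargetID"))


def bin_mean_sd(pairs: pd.DataFrame, n_bins: int = 20) -> MeanSdBinTable:
    """Rank sites by replicate mean and split into equal-occupancy bins.

    Sites with missing mean or SD are dropped first. Occupancies differ by at
    most one site (earlier bins take the extras); ties in mean are broken by
    site id for determinism. Each bin reports its mean range and median SD.
    """
    usable = pairs.dropna(subset=["mean", "sd"])
    n = len(usable)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} usable sites, got {n}")
    order = np.lexsort((usable.index.to_numpy(), usable["mean"].to_numpy()))
    mean_sorted = usable["mean"].to_numpy()[order]
    sd_sorted = usable["sd"].to_numpy()[order]

    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    rows = []
    start = 0
    for b, size in enumerate(sizes):
        stop = start + size
        rows.append(
            {
                "bin_index": b,
                "mean_low": mean_sorted[start],
                "mean_high": mean_sorted[stop - 1],
                "n_sites": size,
                "median_sd": float(np.median(sd_sorted[start:stop])),
            }
        )
        start = stop
    return MeanSdBinTable(bins=pd.DataFrame(rows), pairs=usable)


def histogram_summary(values: MethylationMatrix, n_breaks: int = 50) -> HistogramSummary:
    """Histogram of all non-missing values with a smoothed mode count.

    Counts are binned into ``n_breaks`` equal-width bins, smoothed with a
    3-bin moving average, and local maxima of the smoothed profile are counted
    as modes. This is a descriptive indicator of bimodality, not a formal test.
    """
    flat = values.values[np.isfinite(values.values)]
    if np.unique(flat).size < 2:
        raise ValueError("need at least two distinct values to form a histogram")
    counts, edges = np.histogram(flat, bins=n_breaks)
    # moving average with proper edge windows (2 bins at the ends, 3 inside)
    kernel_sum = np.convolve(counts, np.ones(3), mode="same")
    window = np.convolve(np.ones_like(counts, dtype=float), np.ones(3), mode="same")
    smoothed = kernel_sum / window

    is_max = np.zeros(len(smoothed), dtype=bool)
    for i in range(len(smoothed)):
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < len(smoothed) - 1 else -np.inf
        is_max[i] = smoothed[i] > left and smoothed[i] > right
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_idx = np.flatnonzero(is_max)
    peak_idx = peak_idx[np.argsort(-smoothed[peak_idx], kind="stable")]
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        smoothed=smoothed,
        n_modes=int(is_max.sum()),
        mode_centers=centers[peak_idx],
    )
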