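"""BSA-seq genome scan: SNP/InDel index, ED statistic, windows, intervals.

Per site, two statistics compare the extreme bulks:

* SNP/InDel index — the fraction of a bulk's reads carrying the
  yellow-parent allele; the scan statistic is the absolute difference of
  the two bulks' indices (delta), which peaks near causal loci.
* ED — the Euclidean distance between the bulks' allele-frequency
  vectors over the four nucleotides (indels: the two abstract alleles),
  squared (ED^2) to sharpen signal.

Per-site values are averaged in sliding windows (default 3 Mb, stepping
300 kb, anchored at position 1 of each chromosome, half-open), smoothed
with LOESS, and thresholded at a quantile of window values (default top
1%).  Runs of significant windows merge into candidate intervals.

The threshold is taken per chromosome by default.  On heavily
scaled-down genomes where every chromosome carries a causal locus, a
genome-wide top-1% cut is monopolised by windows linked to the strongest
locus and weaker loci can never reach significance; a per-chromosome cut
keeps the two modes equivalent at full genome scale while remaining
informative when only a few chromosomes are simulated.  ``genome_wide``
scope is available via configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .variantio import VariantTable

logger = logging.getLogger(__name__)

MAX_ED = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the genome scan."""

    window_bp: int = 3_000_000
    step_bp: int = 300_000
    quantile: float = 0.99
    min_markers: int = 10
    min_depth: int = 10
    loess_span: float = 0.1
    loess_degree: int = 1
    loess_iterations: int = 1
    smooth: bool = True
    threshold_scope: Literal["per_chromosome", "genome_wide"] = "per_chromosome"
    orientation: Literal["yellow", "green"] = "yellow"
    threshold_override: float | None = None  # explicit threshold, bypasses quantile

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie strictly in (0, 1)")
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")


@dataclass(frozen=True)
class CandidateInterval:
    """A maximal run of significant windows putatively holding a causal gene."""

    chrom: str
    start: int  # bp, half-open [start, end)
    end: int
    peak_value: float
    statistic: Literal["delta_index", "ed2"]

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class ScanResult:
    """All per-site tracks, window tracks and intervals of one scan."""

    sites: pd.DataFrame
    windows_delta: pd.DataFrame
    windows_ed2: pd.DataFrame
    intervals_delta: list[CandidateInterval]
    intervals_ed2: list[CandidateInterval]
    threshold_delta: dict[str, float]
    threshold_ed2: dict[str, float]
    jaccard: float
    config: ScanConfig = field(default_factory=ScanConfig)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def snp_index(depths, yellow_allele: str, bulk: str, min_depth: int = 10) -> float:
    """Read fraction of the yellow-parent allele in one bulk.

    Returns NaN (masked) when the bulk's total depth is below
    ``min_depth``.  The green-parent orientation is the complement.
    """
    counts = depths.sample(bulk)
    total = sum(counts.values())
    if total < min_depth:
        return float("nan")
    return counts.get(yellow_allele, 0) / total


def delta_index(index_d1: float, index_d2: float) -> float:
    """|index(D1) - index(D2)|; NaN if either input is masked."""
    if np.isnan(index_d1) or np.isnan(index_d2):
        return float("nan")
    return abs(index_d1 - index_d2)


def euclidean_distance(depths, alleles: Sequence[str] | None = None
                       ) -> tuple[float, float]:
    """(ED, ED^2) between the bulks' allele-frequency vectors.

    For SNPs the vectors run over the four nucleotides; for indels over
    the two abstract ref/alt alleles (all other components are zero and
    drop out).  Masked (NaN, NaN) when either bulk has zero depth.
    """
    d1, d2 = depths.d1, depths.d2
    t1, t2 = sum(d1.values()), sum(d2.values())
    if t1 == 0 or t2 == 0:
        return float("nan"), float("nan")
    if alleles is None:
        alleles = sorted(set(d1) | set(d2))
    ed2 = sum((d1.get(a, 0) / t1 - d2.get(a, 0) / t2) ** 2 for a in alleles)
    return float(np.sqrt(ed2)), float(ed2)


# ---------------------------------------------------------------------------
# windowed aggregation
# ---------------------------------------------------------------------------

def window_starts(chrom_length: int, window_bp: int, step_bp: int) -> np.ndarray:
    """1-based window anchors: 1, 1+step, ... while start <= length."""
    return np.arange(1, chrom_length + 1, step_bp, dtype=np.int64)


def sliding_windows(sites: pd.DataFrame,
                    chrom_lengths: dict[str, int],
                    value_col: str,
                    window_bp: int = 3_000_000,
                    step_bp: int = 300_000,
                    min_markers: int = 10) -> pd.DataFrame:
    """Mean of a per-site value over sliding windows.

    ``sites`` needs columns chrom, pos and ``value_col``; NaN values are
    masked sites and do not contribute.  Windows are half-open
    [start, start + window_bp) in bp, truncated at the chromosome end;
    windows with fewer than ``min_markers`` contributing sites are
    flagged ``eligible=False`` and excluded from thresholding.
    """
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        val = sub[value_col].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        ok = ~np.isnan(val)
        cum_n = np.concatenate([[0], np.cumsum(ok)])
        cum_v = np.concatenate([[0.0], np.cumsum(np.where(ok, val, 0.0))])
        starts = window_starts(length, window_bp, step_bp)
        ends = np.minimum(starts + window_bp, length + 1)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n = cum_n[hi] - cum_n[lo]
        total = cum_v[hi] - cum_v[lo]
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_markers": n, "mean": mean,
            "eligible": n >= min_markers,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_markers", "mean", "eligible"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# LOESS smoothing
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def loess_smooth(positions: np.ndarray, values: np.ndarray,
                 span: float = 0.1, degree: int = 1,
                 iterations: int = 1) -> np.ndarray:
    """Locally weighted polynomial regression along a chromosome.

    Tricube neighbourhood weights over the ``span`` fraction of nearest
    points, polynomial of the given ``degree``, with ``iterations``
    robustness passes (bisquare residual reweighting).  NaN inputs are
    ignored for fitting; the output is aligned with ``positions`` and is
    NaN wherever no fit is possible.  With fewer than
    ``max(5, degree + 2)`` finite points the input is returned unchanged
    (identity pass-through) with a warning.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    x, y = positions[finite], values[finite]
    n = x.size
    if n < max(5, degree + 2):
        logger.warning("loess: only %d finite points; returning input unchanged", n)
        return values.copy()
    k = max(int(np.ceil(span * n)), degree + 1)
    robust = np.ones(n)
    fitted = np.empty(n)
    for it in range(iterations + 1):
        for i in range(n):
            dist = np.abs(x - x[i])
            h = np.partition(dist, min(k - 1, n - 1))[min(k - 1, n - 1)]
            if h == 0:
                h = 1.0
            w = _tricube(dist / h) * robust
            if w.sum() == 0 or np.count_nonzero(w) <= degree:
                fitted[i] = y[i]
                continue
            coeffs = np.polynomial.polynomial.polyfit(
                x - x[i], y, degree, w=np.sqrt(w)
            )
            fitted[i] = coeffs[0]
        if it < iterations:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s == 0:
                break
            robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    out = np.full(values.shape, np.nan)
    out[finite] = fitted
    return out


def smooth_windows(windows: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Add a ``smoothed`` column (per-chromosome LOESS of window means)."""
    windows = windows.copy()
    smoothed = np.full(len(windows), np.nan)
    centers = (windows["start"].to_numpy() + windows["end"].to_numpy()) / 2.0
    for chrom in windows["chrom"].unique():
        mask = (windows["chrom"] == chrom).to_numpy()
        smoothed[mask] = loess_smooth(
            centers[mask], windows["mean"].to_numpy()[mask],
            span=config.loess_span, degree=config.loess_degree,
            iterations=config.loess_iterations,
        )
    windows["smoothed"] = smoothed
    return windows


# ---------------------------------------------------------------------------
# thresholding and interval calling
# ---------------------------------------------------------------------------

def _merge_windows(sig: pd.DataFrame, statistic: str) -> list[CandidateInterval]:
    intervals: list[CandidateInterval] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        cur_peak = -np.inf
        for _, row in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, cur_peak = row["start"], row["end"], row["value"]
            elif row["start"] <= cur_end:  # overlapping or touching
                cur_end = max(cur_end, row["end"])
                cur_peak = max(cur_peak, row["value"])
            else:
                intervals.append(CandidateInterval(
                    chrom, int(cur_start), int(cur_end), float(cur_peak), statistic))
                cur_start, cur_end, cur_peak = row["start"], row["end"], row["value"]
        if cur_start is not None:
            intervals.append(CandidateInterval(
                chrom, int(cur_start), int(cur_end), float(cur_peak), statistic))
    return intervals


def call_intervals(windows: pd.DataFrame,
                   quantile: float = 0.99,
                   statistic: str = "delta_index",
                   value_col: str | None = None,
                   scope: str = "genome_wide",
                   threshold_override: float | None = None
                   ) -> tuple[list[CandidateInterval], dict[str, float]]:
    """Threshold window values at a quantile and merge significant runs.

    The threshold is the ``quantile`` of eligible window values, computed
    genome-wide or per chromosome; windows with value >= threshold (ties
    included) merge into maximal intervals when they overlap or touch.
    Returns ``(intervals, thresholds per chromosome)``.
    """
    value_col = value_col or ("smoothed" if "smoothed" in windows else "mean")
    eligible = windows[windows["eligible"] & windows[value_col].notna()].copy()
    eligible["value"] = eligible[value_col]
    if len(eligible) == 0:
        return [], {}
    if len(eligible) < 100:
        logger.warning(
            "only %d eligible windows; quantile threshold may be unstable",
            len(eligible),
        )
    thresholds: dict[str, float] = {}
    if threshold_override is not None:
        for chrom in eligible["chrom"].unique():
            thresholds[chrom] = float(threshold_override)
    elif scope == "genome_wide":
        t = float(np.quantile(eligible["value"], quantile))
        for chrom in eligible["chrom"].unique():
            thresholds[chrom] = t
    elif scope == "per_chromosome":
        for chrom, sub in eligible.groupby("chrom", sort=False):
            thresholds[chrom] = float(np.quantile(sub["value"], quantile))
    else:
        raise ValueError(f"unknown threshold scope {scope!r}")
    sig = eligible[
        eligible["value"] >= eligible["chrom"].map(thresholds)
    ]
    return _merge_windows(sig, statistic), thresholds


# ---------------------------------------------------------------------------
# the full scan
# ---------------------------------------------------------------------------

def compute_site_tracks(table: VariantTable, config: ScanConfig) -> pd.DataFrame:
    """Per-site index, delta and ED tracks for a filtered variant table."""
    if table.yellow_allele is None:
        raise ValueError(
            "table lacks yellow-parent allele annotation; run "
            "filter_parental_informative first"
        )
    rows = []
    for i, (site, d) in enumerate(table):
        yellow = table.yellow_allele[i]
        i1 = snp_index(d, yellow, "D1", config.min_depth)
        i2 = snp_index(d, yellow, "D2", config.min_depth)
        if config.orientation == "green":
            i1, i2 = 1.0 - i1, 1.0 - i2
        ed, ed2 = euclidean_distance(d)
        rows.append((site.chrom, site.pos, site.vtype, i1, i2,
                     delta_index(i1, i2), ed, ed2))
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "vtype", "index_D1", "index_D2", "delta", "ed", "ed2"])
    df["masked"] = df["delta"].isna()
    return df


def interval_jaccard(a: list[CandidateInterval], b: list[CandidateInterval]) -> float:
    """Jaccard overlap (bp) between two interval sets; 1.0 if both empty."""
    if not a and not b:
        return 1.0

    def total_and_union(ivals_a, ivals_b):
        inter = 0
        for x in ivals_a:
            for y in ivals_b:
                if x.chrom == y.chrom:
                    inter += max(0, min(x.end, y.end) - max(x.start, y.start))
        span = sum(i.end - i.start for i in ivals_a) + \
            sum(i.end - i.start for i in ivals_b)
        return inter, span - inter

    inter, union = total_and_union(a, b)
    return inter / union if union > 0 else 1.0


def run_scan(table: VariantTable, config: ScanConfig | None = None) -> ScanResult:
    """Run both statistics end to end on a filtered variant table.

    Deterministic given the table and configuration.  Reports windowed
    and smoothed tracks, candidate intervals for the delta-index and ED^2
    statistics, and logs their Jaccard concordance.
    """
    config = config or ScanConfig()
    sites = compute_site_tracks(table, config)
    results = {}
    for stat, col in (("delta_index", "delta"), ("ed2", "ed2")):
        win = sliding_windows(sites, table.chrom_lengths, col,
                              config.window_bp, config.step_bp,
                              config.min_markers)
        if config.smooth:
            win = smooth_windows(win, config)
        intervals, thresholds = call_intervals(
            win, config.quantile, stat,
            scope=config.threshold_scope,
            threshold_override=config.threshold_override,
        )
        results[stat] = (win, intervals, thresholds)
        logger.info("%s: %d candidate interval(s), thresholds %s",
                    stat, len(intervals),
                    {c: round(t, 4) for c, t in thresholds.items()})
    jac = interval_jaccard(results["delta_index"][1], results["ed2"][1])
    logger.info("delta-index / ED^2 interval concordance (Jaccard): %.3f", jac)
    return ScanResult(
        sites=sites,
        windows_delta=results["delta_index"][0],
        windows_ed2=results["ed2"][0],
        intervals_delta=results["delta_index"][1],
        intervals_ed2=results["ed2"][1],
        threshold_delta=results["delta_index"][2],
        threshold_ed2=results["ed2"][2],
        jaccard=jac,
        config=config,
    )


# ---------------------------------------------------------------------------
# writers and plotting
# ---------------------------------------------------------------------------

def write_site_tsv(result: ScanResult, path: str | Path) -> None:
    cols = ["chrom", "pos", "index_D1", "index_D2", "delta", "ed", "ed2"]
    result.sites[cols].to_csv(path, sep="\t", index=False, float_format="%.6g",
                              lineterminator="\n")


def write_window_tsv(result: ScanResult, path: str | Path) -> None:
    wd = result.windows_delta.rename(columns={"mean": "mean_delta",
                                              "smoothed": "smoothed_delta"})
    we = result.windows_ed2[["mean"] + (["smoothed"] if "smoothed" in
                                        result.windows_ed2 else [])]
    we = we.rename(columns={"mean": "mean_ed2", "smoothed": "smoothed_ed2"})
    pd.concat([wd, we], axis=1).to_csv(path, sep="\t", index=False,
                                       float_format="%.6g", lineterminator="\n")


def write_intervals_bed(intervals: list[CandidateInterval],
                        path: str | Path) -> None:
    """BED output: 0-based half-open, name = statistic, score = peak value."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end - 1}\t"
                     f"{iv.statistic}\t{iv.peak_value:.6g}\n")


def plot_scan(result: ScanResult, path: str | Path) -> None:
    """Static per-chromosome plot of both window tracks and thresholds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(result.windows_delta["chrom"].unique())
    fig, axes = plt.subplots(2, max(len(chroms), 1),
                             figsize=(5 * max(len(chroms), 1), 6),
                             squeeze=False, sharey="row")
    for j, chrom in enumerate(chroms):
        for i, (label, win, thr, ivals) in enumerate((
            ("delta index", result.windows_delta, result.threshold_delta,
             result.intervals_delta),
            ("ED$^2$", result.windows_ed2, result.threshold_ed2,
             result.intervals_ed2),
        )):
            ax = axes[i][j]
            sub = win[win["chrom"] == chrom]
            mid = (sub["start"] + sub["end"]) / 2e6
            ax.plot(mid, sub["mean"], ".", ms=3, alpha=0.5, label="window mean")
            if "smoothed" in sub:
                ax.plot(mid, sub["smoothed"], "-", label="LOESS")
            if chrom in thr:
                ax.axhline(thr[chrom], ls="--", color="grey", lw=1)
            for iv in ivals:
                if iv.chrom == chrom:
                    ax.axvspan(iv.start / 1e6, iv.end / 1e6, alpha=0.15,
                               color="red")
            ax.set_xlabel(f"{chrom} (Mb)")
            ax.set_ylabel(label)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
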