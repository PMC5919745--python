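"""Sliding-window pooled heterozygosity (Hp) and fixation index (Fst), with Z-transforms.

The scan slides fixed-width windows (default 100 kb) along each
chromosome in fixed steps (default 10 kb), so consecutive windows
overlap and every SNP contributes to several windows.

Per window, in the scanned (case) population:

    Hp = 2 * sum(nMaj) * sum(nMin) / (sum(nMaj) + sum(nMin))**2

where nMaj and nMin are the counts of the more and less frequent allele
among that population's called haplotypes at each SNP. Hp ranges from 0
(every SNP fixed) to 0.5 (every SNP exactly balanced); a selective sweep
drags it toward 0.

Per site, between the two populations:

    Fst = 1 - (p1*q1 + p2*q2) / (2 * pr * qr)

with p/q the two allele frequencies in each population and pr/qr the
pooled frequencies over all callable chromosomes (count-weighted, which
reduces to the simple average with equal samples and no missingness).
Window Fst is the mean of per-site Fst over usable sites.

Both window statistics are Z-standardised genome-wide over qualifying
windows (at least ``min_snps_per_window`` SNPs and a defined value),
using the population standard deviation, so fixed outlier cut-offs such
as ZHp < -5 and ZFst > 4.5 select the distribution tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import (
    MISSING,
    ConfigurationError,
    PopulationMap,
    SiteRecord,
    SweepScanError,
)


class DegenerateScanError(SweepScanError):
    """Raised when the window statistic has zero spread (no Z-transform)."""


@dataclass
class ScanConfig:
    """Window-scan geometry, qualification rule and outlier thresholds.

    window_size, step
        Window width and slide step, in bp. The literature this scan
        follows uses 100-kb windows; step conventions vary between 10 kb
        and half-window, so the step is configurable.
    min_snps_per_window
        Windows with fewer assigned SNPs are excluded from statistics
        and from the Z-transform (default 20, the density below which
        window statistics become unstable).
    zfst_threshold, zhp_threshold
        Strict outlier cut-offs applied to the Z-scores.
    hp_population
        Population label whose heterozygosity is scanned; ``None`` means
        the first label of the population map (the case population).
    fst_aggregator
        ``"mean"`` (unweighted mean of per-site Fst, default) or
        ``"weighted"`` (weighted by each site's callable chromosome count).
    overlap_rule
        How the two outlier sets combine: ``"genomic"`` intersects their
        merged genomic footprints; ``"same_window"`` requires a single
        window to pass both thresholds.
    """

    window_size: int = 100_000
    step: int = 10_000
    min_snps_per_window: int = 20
    zfst_threshold: float = 4.5
    zhp_threshold: float = -5.0
    hp_population: str | None = None
    fst_aggregator: str = "mean"
    overlap_rule: str = "genomic"

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_size):
            raise ConfigurationError("require 0 < step <= window_size")
        if self.min_snps_per_window < 1:
            raise ConfigurationError("min_snps_per_window must be >= 1")
        if self.fst_aggregator not in ("mean", "weighted"):
            raise ConfigurationError(f"unknown fst_aggregator {self.fst_aggregator!r}")
        if self.overlap_rule not in ("genomic", "same_window"):
            raise ConfigurationError(f"unknown overlap_rule {self.overlap_rule!r}")


@dataclass
class AlleleFrequencies:
    """Biallelic frequencies in two populations and pooled over both.

    ``p`` tracks the alternate allele and ``q = 1 - p`` the reference;
    the Fst formula is symmetric under swapping the labels. ``n1``/``n2``
    are callable chromosome (haplotype) counts, and the pooled
    frequencies are count-weighted: pr = (n1*p1 + n2*p2) / (n1 + n2).
    """

    p1: float
    q1: float
    p2: float
    q2: float
    pr: float
    qr: float
    n1: int
    n2: int

    @classmethod
    def from_counts(cls, alt1: int, n1: int, alt2: int, n2: int) -> "AlleleFrequencies":
        if n1 <= 0 or n2 <= 0:
            raise ValueError("need at least one callable chromosome per population")
        p1 = alt1 / n1
        p2 = alt2 / n2
        pr = (alt1 + alt2) / (n1 + n2)
        return cls(p1=p1, q1=1.0 - p1, p2=p2, q2=1.0 - p2,
                   pr=pr, qr=1.0 - pr, n1=n1, n2=n2)


@dataclass
class WindowStats:
    """One sliding window's aggregated counts, statistics and Z-scores."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0
    sum_nmaj: int = 0
    sum_nmin: int = 0
    n_fst_sites: int = 0
    hp: float = math.nan
    fst: float = math.nan
    zhp: float = math.nan
    zfst: float = math.nan
    qualifies: bool = False


@dataclass
class ZTransformSummary:
    """Mean and population SD used to standardise a window statistic."""

    mu: float
    sigma: float
    n_windows: int


# ---------------------------------------------------------------------------
# Window construction and per-site counts
# ---------------------------------------------------------------------------


def make_windows(
    chrom_lengths: dict[str, int], cfg: ScanConfig
) -> list[tuple[str, int, int]]:
    """Build the sliding-window grid: starts 1, 1+step, ... per chromosome.

    Only windows lying wholly inside the chromosome are kept, so a
    chromosome shorter than the window size yields none.
    """
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 1:
            raise ConfigurationError(f"chromosome {chrom} has length {length}")
        start = 1
        while start + cfg.window_size - 1 <= length:
            windows.append((chrom, start, start + cfg.window_size - 1))
            start += cfg.step
    return windows


def site_allele_counts(site: SiteRecord, indices: np.ndarray) -> tuple[int, int]:
    """(alt count, callable haplotype count) among the given sample columns."""
    alleles = site.genotypes[indices].ravel()
    called = alleles != MISSING
    return int((alleles == 1).sum()), int(called.sum())


def site_major_minor(site: SiteRecord, indices: np.ndarray) -> tuple[int, int]:
    """(nMaj, nMin) for one population at one site; ties give nMaj == nMin."""
    alt, n = site_allele_counts(site, indices)
    ref = n - alt
    return max(ref, alt), min(ref, alt)


def _windows_covering(pos: int, starts: np.ndarray, window_size: int) -> range:
    """Indices (into sorted equal-width windows) whose span contains pos."""
    lo = int(np.searchsorted(starts, pos - window_size + 1, side="left"))
    hi = int(np.searchsorted(starts, pos, side="right"))
    return range(lo, hi)


def aggregate_window_counts(
    sites: Sequence[SiteRecord],
    windows: Sequence[tuple[str, int, int]],
    popmap: PopulationMap,
    samples: Sequence[str],
    population: str,
) -> list[tuple[int, int, int]]:
    """Per-window (n_snps, sum_nmaj, sum_nmin) for one population.

    Every SNP contributes to every window containing its position —
    windows overlap by design. Sites monomorphic within the population
    still count (they add to the major-allele sum with nMin = 0); sites
    with zero callable haplotypes in the population are skipped.
    """
    if population not in popmap.labels():
        raise ConfigurationError(f"unknown population label {population!r}")
    idx = popmap.indices(population, samples)

    by_chrom: dict[str, list[int]] = {}
    for wi, (chrom, _, _) in enumerate(windows):
        by_chrom.setdefault(chrom, []).append(wi)
    starts_by_chrom = {
        chrom: np.array([windows[wi][1] for wi in wis])
        for chrom, wis in by_chrom.items()
    }

    counts = [[0, 0, 0] for _ in windows]
    for site in sites:
        wis = by_chrom.get(site.chrom)
        if wis is None:
            continue
        nmaj, nmin = site_major_minor(site, idx)
        if nmaj + nmin == 0:
            continue
        starts = starts_by_chrom[site.chrom]
        wsize = windows[wis[0]][2] - windows[wis[0]][1] + 1
        for k in _windows_covering(site.pos, starts, wsize):
            wi = wis[k]
            _, wstart, wend = windows[wi]
            if wstart <= site.pos <= wend:
                c = counts[wi]
                c[0] += 1
                c[1] += nmaj
                c[2] += nmin
    return [tuple(c) for c in counts]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def pooled_heterozygosity(sum_nmaj: int, sum_nmin: int) -> float:
    """Hp = 2*ΣnMaj*ΣnMin / (ΣnMaj+ΣnMin)²; NaN when the window is empty."""
    total = sum_nmaj + sum_nmin
    if total == 0:
        return math.nan
    return 2.0 * sum_nmaj * sum_nmin / (total * total)


def site_fst(freqs: AlleleFrequencies) -> float | None:
    """Two-population fixation index 1 - (p1q1 + p2q2) / (2*pr*qr).

    Returns ``None`` when the site is monomorphic in the pooled sample
    (pr*qr = 0), in which case the site carries no differentiation
    information and is skipped. Small negative values (within-population
    diversity exceeding pooled diversity) are returned unclamped.
    """
    denom = 2.0 * freqs.pr * freqs.qr
    if denom == 0.0:
        return None
    return 1.0 - (freqs.p1 * freqs.q1 + freqs.p2 * freqs.q2) / denom


def window_fst(site_fsts: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Aggregate per-site Fst into a window value (mean; NaN if empty)."""
    if len(site_fsts) == 0:
        return math.nan
    if weights is None:
        return float(np.mean(site_fsts))
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return math.nan
    return float(np.average(site_fsts, weights=w))


def z_transform(values: Sequence[float]) -> tuple[np.ndarray, ZTransformSummary]:
    """Standardise window values to Z-scores using the population SD.

    Requires at least two values with nonzero spread; a zero-spread scan
    has no meaningful tails and raises :class:`DegenerateScanError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateScanError(
            f"Z-transform needs >= 2 qualifying windows, got {arr.size}"
        )
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateScanError("degenerate scan: window statistic has zero SD")
    return (arr - mu) / sigma, ZTransformSummary(mu=mu, sigma=sigma, n_windows=arr.size)


# ---------------------------------------------------------------------------
# Full per-window computation
# ---------------------------------------------------------------------------


def compute_window_stats(
    sites: Sequence[SiteRecord],
    windows: Sequence[tuple[str, int, int]],
    popmap: PopulationMap,
    samples: Sequence[str],
    cfg: ScanConfig,
    counters: dict | None = None,
) -> list[WindowStats]:
    """Compute Hp, Fst and their Z-scores for every window of the grid.

    Hp is evaluated in ``cfg.hp_population`` (default: the first, case,
    population); Fst between the two populations, pooling frequencies by
    callable chromosome counts. Windows with fewer than
    ``cfg.min_snps_per_window`` SNPs, or with no usable statistic, do not
    qualify and receive no Z-score.
    """
    labels = popmap.labels()
    hp_pop = cfg.hp_population if cfg.hp_population is not None else labels[0]
    if hp_pop not in labels:
        raise ConfigurationError(f"unknown hp_population {hp_pop!r}")
    idx1 = popmap.indices(labels[0], samples)
    idx2 = popmap.indices(labels[1], samples)

    counts = aggregate_window_counts(sites, windows, popmap, samples, hp_pop)

    # Per-site Fst, then distribute to covering windows.
    by_chrom: dict[str, list[int]] = {}
    for wi, (chrom, _, _) in enumerate(windows):
        by_chrom.setdefault(chrom, []).append(wi)
    starts_by_chrom = {
        chrom: np.array([windows[wi][1] for wi in wis])
        for chrom, wis in by_chrom.items()
    }
    fst_sums = np.zeros(len(windows))
    fst_wsums = np.zeros(len(windows))
    fst_wtotals = np.zeros(len(windows))
    fst_ns = np.zeros(len(windows), dtype=int)
    n_fst_skipped = 0
    for site in sites:
        wis = by_chrom.get(site.chrom)
        if wis is None:
            continue
        alt1, n1 = site_allele_counts(site, idx1)
        alt2, n2 = site_allele_counts(site, idx2)
        if n1 == 0 or n2 == 0:
            n_fst_skipped += 1
            continue
        freqs = AlleleFrequencies.from_counts(alt1, n1, alt2, n2)
        f = site_fst(freqs)
        if f is None:
            n_fst_skipped += 1
            continue
        starts = starts_by_chrom[site.chrom]
        wsize = windows[wis[0]][2] - windows[wis[0]][1] + 1
        w = float(n1 + n2)
        for k in _windows_covering(site.pos, starts, wsize):
            wi = wis[k]
            _, wstart, wend = windows[wi]
            if wstart <= site.pos <= wend:
                fst_sums[wi] += f
                fst_wsums[wi] += f * w
                fst_wtotals[wi] += w
                fst_ns[wi] += 1

    stats: list[WindowStats] = []
    for wi, (chrom, start, end) in enumerate(windows):
        n_snps, sum_nmaj, sum_nmin = counts[wi]
        hp = pooled_heterozygosity(sum_nmaj, sum_nmin)
        if fst_ns[wi] > 0:
            if cfg.fst_aggregator == "weighted":
                fst = float(fst_wsums[wi] / fst_wtotals[wi])
            else:
                fst = float(fst_sums[wi] / fst_ns[wi])
        else:
            fst = math.nan
        qualifies = (
            n_snps >= cfg.min_snps_per_window
            and not math.isnan(hp)
            and not math.isnan(fst)
        )
        stats.append(
            WindowStats(chrom=chrom, start=start, end=end, n_snps=n_snps,
                        sum_nmaj=sum_nmaj, sum_nmin=sum_nmin,
                        n_fst_sites=int(fst_ns[wi]), hp=hp, fst=fst,
                        qualifies=qualifies)
        )

    qualifying = [w for w in stats if w.qualifies]
    if qualifying:
        zhp, _ = z_transform([w.hp for w in qualifying])
        zfst, _ = z_transform([w.fst for w in qualifying])
        for w, zh, zf in zip(qualifying, zhp, zfst):
            w.zhp = float(zh)
            w.zfst = float(zf)
    if counters is not None:
        counters["windows_total"] = len(stats)
        counters["windows_qualifying"] = len(qualifying)
        counters["fst_sites_skipped_monomorphic"] = n_fst_skipped
    return stats
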