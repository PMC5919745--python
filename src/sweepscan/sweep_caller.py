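"""Candidate sweep regions from Z-scored windows.

Windows extreme in both statistics mark putative sweeps: a sweep in the
case population depresses its heterozygosity (low ZHp) while pushing
allele frequencies apart between populations (high ZFst). The caller
thresholds each Z-score strictly, takes the genomic intersection of the
two outlier footprints, merges touching pieces into maximal regions and
annotates overlapping genes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

from .variant_io import (
    FilterConfig,
    GeneModel,
    PopulationMap,
    SweepScanError,
    apply_proximity_filter,
    apply_quality_filter,
    load_gene_models,
    parse_vcf,
    write_outputs,
)
from .window_stats import (
    ScanConfig,
    WindowStats,
    compute_window_stats,
    make_windows,
)

Interval = tuple[str, int, int]  # chrom, 1-based inclusive start/end


@dataclass
class OutlierSet:
    """Windows whose Z-score lies strictly beyond a one-sided threshold."""

    statistic: str  # "zfst" or "zhp"
    direction: str  # "upper" or "lower"
    threshold: float
    windows: list[WindowStats]

    def intervals(self) -> list[Interval]:
        return [(w.chrom, w.start, w.end) for w in self.windows]


@dataclass
class CandidateRegion:
    """Merged interval supported by windows extreme in both statistics."""

    chrom: str
    start: int
    end: int
    support_windows: list[WindowStats] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


class PipelineError(SweepScanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Outlier selection and interval algebra
# ---------------------------------------------------------------------------


def select_outlier_windows(
    windows: Sequence[WindowStats], cfg: ScanConfig
) -> tuple[OutlierSet, OutlierSet]:
    """Strictly threshold ZFst (upper tail) and ZHp (lower tail).

    Windows without a Z-score (not enough SNPs, undefined statistic)
    never qualify; a window sitting exactly on a threshold is excluded.
    """
    fst_windows = [
        w for w in windows
        if not math.isnan(w.zfst) and w.zfst > cfg.zfst_threshold
    ]
    hp_windows = [
        w for w in windows
        if not math.isnan(w.zhp) and w.zhp < cfg.zhp_threshold
    ]
    return (
        OutlierSet("zfst", "upper", cfg.zfst_threshold, fst_windows),
        OutlierSet("zhp", "lower", cfg.zhp_threshold, hp_windows),
    )


def union_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals; overlapping or book-ended
    (adjacent by 1 bp) pieces merge. Output sorted and disjoint."""
    out: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect_window_sets(a: OutlierSet, b: OutlierSet) -> list[Interval]:
    """Genomic intersection of the two outlier-window footprints.

    Each set's windows are first merged into a union of disjoint
    intervals per chromosome; the result is the maximal disjoint set of
    intervals covered by both unions.
    """
    ua = union_intervals(a.intervals())
    ub = union_intervals(b.intervals())
    out: list[Interval] = []
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in ub:
        by_chrom_b.setdefault(iv[0], []).append(iv)
    for chrom, s1, e1 in ua:
        for _, s2, e2 in by_chrom_b.get(chrom, []):
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((chrom, lo, hi))
    return sorted(out)


def merge_regions(intervals: Sequence[Interval]) -> list[CandidateRegion]:
    """Merge overlapping or book-ended intervals into candidate regions."""
    return [
        CandidateRegion(chrom=c, start=s, end=e)
        for c, s, e in union_intervals(intervals)
    ]


def attach_support_windows(
    regions: Sequence[CandidateRegion],
    outliers: Sequence[OutlierSet],
) -> None:
    """Record, per region, the outlier windows overlapping it (deduplicated)."""
    for region in regions:
        seen: set[tuple[str, int, int]] = set()
        support: list[WindowStats] = []
        for oset in outliers:
            for w in oset.windows:
                key = (w.chrom, w.start, w.end)
                if key in seen:
                    continue
                if w.chrom == region.chrom and w.start <= region.end and w.end >= region.start:
                    support.append(w)
                    seen.add(key)
        region.support_windows = sorted(support, key=lambda w: (w.chrom, w.start))


def annotate_genes(
    regions: Sequence[CandidateRegion], genes: Sequence[GeneModel]
) -> list[CandidateRegion]:
    """Assign each gene sharing >= 1 bp with a region; lists sorted by gene start."""
    for region in regions:
        hits = [
            g for g in genes
            if g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
        ]
        region.genes = [g.name for g in sorted(hits, key=lambda g: g.start)]
    return list(regions)


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    windows: list[WindowStats]
    regions: list[CandidateRegion]
    summary: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_scan(
    vcf_path: str | os.PathLike,
    popmap: PopulationMap | str | os.PathLike,
    genes: Sequence[GeneModel] | str | os.PathLike | None,
    cfg: ScanConfig | None = None,
    filter_cfg: FilterConfig | None = None,
    outdir: str | os.PathLike | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> ScanResult:
    """Run the whole scan: parse, filter, window, score, call, annotate, write.

    ``popmap`` and ``genes`` may be given as paths (TSV / BED / GFF3) or
    as already-loaded objects; ``genes`` may be ``None`` to skip
    annotation. Chromosome lengths come from the VCF contig headers when
    present, otherwise from the last SNP per chromosome. When ``outdir``
    is given, the window table and region BED/TSV are written there.

    The returned summary holds stage counters (sites parsed, surviving
    each filter, windows built/qualifying, outliers per statistic,
    regions, annotated genes); counts along the filter chain are
    monotone non-increasing. The whole run is deterministic given its
    inputs.
    """
    cfg = cfg or ScanConfig()
    filter_cfg = filter_cfg or FilterConfig()
    counters: dict = {}

    with _stage("popmap"):
        if not isinstance(popmap, PopulationMap):
            popmap = PopulationMap.from_tsv(popmap)

    with _stage("parse_vcf"):
        sites, samples = parse_vcf(vcf_path, popmap, counters)
        if chrom_lengths is None:
            chrom_lengths = _vcf_chrom_lengths(vcf_path, sites)

    with _stage("quality_filter"):
        sites = apply_quality_filter(sites, popmap, samples, filter_cfg, counters)
    with _stage("proximity_filter"):
        sites = apply_proximity_filter(sites, filter_cfg, counters)

    with _stage("window_stats"):
        grid = make_windows(chrom_lengths, cfg)
        windows = compute_window_stats(sites, grid, popmap, samples, cfg, counters)

    with _stage("sweep_call"):
        fst_set, hp_set = select_outlier_windows(windows, cfg)
        counters["outlier_windows_zfst"] = len(fst_set.windows)
        counters["outlier_windows_zhp"] = len(hp_set.windows)
        if cfg.overlap_rule == "same_window":
            both = [
                w for w in windows
                if not math.isnan(w.zfst) and not math.isnan(w.zhp)
                and w.zfst > cfg.zfst_threshold and w.zhp < cfg.zhp_threshold
            ]
            intervals = [(w.chrom, w.start, w.end) for w in both]
        else:
            intervals = intersect_window_sets(fst_set, hp_set)
        regions = merge_regions(intervals)
        attach_support_windows(regions, [fst_set, hp_set])
        counters["regions"] = len(regions)

    with _stage("annotate"):
        if genes is not None:
            if not isinstance(genes, (list, tuple)):
                genes = load_gene_models(genes)
            annotate_genes(regions, genes)
        counters["genes_annotated"] = sum(len(r.genes) for r in regions)

    if outdir is not None:
        with _stage("write_outputs"):
            write_outputs(windows, regions, outdir)

    return ScanResult(windows=windows, regions=regions, summary=counters)


def _vcf_chrom_lengths(vcf_path, sites) -> dict[str, int]:
    """Contig lengths from the VCF header, else max SNP position per chrom."""
    from cyvcf2 import VCF

    lengths: dict[str, int] = {}
    try:
        v = VCF(str(vcf_path))
        names, lens = v.seqnames, v.seqlens
        if names and lens and len(names) == len(lens):
            lengths = {n: int(l) for n, l in zip(names, lens) if l > 0}
    except Exception:
        lengths = {}
    if not lengths:
        for s in sites:
            lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.pos)
    return lengths
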