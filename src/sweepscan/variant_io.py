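"""Variant and interval I/O: VCF parsing, SNP quality/proximity filters, gene models, tabular outputs.

The scan operates on biallelic SNPs only. Two filters mirror common
resequencing practice for low-coverage pooled designs: per-call genotype
quality (calls with GQ below a threshold are set missing, and sites that
become uncallable in either population are dropped) and SNP proximity
(clusters of SNPs closer than a minimum spacing are removed wholesale,
since tight clusters are enriched for alignment artefacts).

All in-memory coordinates are 1-based inclusive (VCF convention); BED's
0-based half-open convention is applied only at the file boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

MISSING = -1  # sentinel for a missing haplotype allele or absent GQ


class SweepScanError(Exception):
    """Base class for scan pipeline errors."""


class ConfigurationError(SweepScanError):
    """Invalid configuration or sample bookkeeping."""


class VcfParseError(SweepScanError):
    """Malformed VCF or annotation input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One biallelic SNP with per-sample diploid calls and genotype qualities.

    ``genotypes`` has shape ``(n_samples, 2)`` with allele codes 0 (ref),
    1 (alt) or ``MISSING``; ``gq`` has shape ``(n_samples,)`` with
    ``MISSING`` where the VCF carried no GQ for that call.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray
    gq: np.ndarray

    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def called_mask(self) -> np.ndarray:
        """Samples whose diploid call is fully non-missing."""
        return np.all(self.genotypes != MISSING, axis=1)


@dataclass
class PopulationMap:
    """Assignment of VCF samples to exactly two population labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        labels = self.labels()
        if len(labels) != 2:
            raise ConfigurationError(
                f"population map must define exactly two populations, got {labels!r}"
            )

    def labels(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: list[str] = []
        for lab in self.assignments.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def samples(self, label: str) -> list[str]:
        return [s for s, lab in self.assignments.items() if lab == label]

    def indices(self, label: str, sample_order: Sequence[str]) -> np.ndarray:
        """Column indices of this population's samples in ``sample_order``."""
        wanted = set(self.samples(label))
        idx = [i for i, s in enumerate(sample_order) if s in wanted]
        if not idx:
            raise ConfigurationError(f"no samples of population {label!r} in VCF")
        return np.asarray(idx, dtype=np.intp)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PopulationMap":
        """Read a two-column sample<TAB>population table (no header)."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise VcfParseError(f"{path}:{lineno}: expected 2 columns")
                sample, pop = parts[0], parts[1]
                if sample in assignments:
                    raise ConfigurationError(
                        f"{path}:{lineno}: sample {sample!r} listed twice"
                    )
                assignments[sample] = pop
        return cls(assignments)


@dataclass
class GeneModel:
    """Named gene interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int


@dataclass
class FilterConfig:
    """SNP filter thresholds.

    min_gq
        Per-call genotype quality floor; calls below it become missing.
    min_snp_distance
        Minimum spacing in bp; SNPs with a same-chromosome neighbour
        strictly closer than this are removed.
    min_called_per_pop
        A site must retain at least this many non-missing diploid calls
        in *each* population to survive the quality filter.
    proximity_mode
        ``"drop_both"`` removes every member of a close cluster
        (order-independent); ``"keep_first"`` greedily keeps the leftmost
        member of each cluster.
    missing_gq_passes
        Whether a call with no GQ field counts as passing the GQ filter.
    """

    min_gq: int = 20
    min_snp_distance: int = 5
    min_called_per_pop: int = 4
    proximity_mode: str = "drop_both"
    missing_gq_passes: bool = True

    def __post_init__(self) -> None:
        if self.min_gq < 0 or self.min_snp_distance < 0 or self.min_called_per_pop < 0:
            raise ConfigurationError("filter thresholds must be >= 0")
        if self.proximity_mode not in ("drop_both", "keep_first"):
            raise ConfigurationError(
                f"unknown proximity_mode {self.proximity_mode!r}"
            )


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------


def parse_vcf(
    path: str | os.PathLike,
    popmap: PopulationMap,
    counters: dict | None = None,
) -> tuple[list[SiteRecord], list[str]]:
    """Read a multi-sample VCF into SiteRecords, keeping biallelic SNPs only.

    Returns the records sorted by (chrom, pos) plus the VCF sample order
    that genotype columns follow. Multiallelic sites, indels and other
    non-SNP lines are skipped and counted. Missing GQ values are stored
    as ``MISSING``; how they interact with filtering is decided by
    :class:`FilterConfig`.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise VcfParseError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise VcfParseError(f"malformed VCF header in {path}: {exc}") from exc

    absent = [s for s in popmap.assignments if s not in samples]
    if absent:
        raise ConfigurationError(
            f"population-map samples absent from VCF header: {absent}"
        )

    sites: list[SiteRecord] = []
    n_skipped = 0
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF not in "ACGT"
            or variant.ALT[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        gts = np.asarray(variant.genotypes, dtype=np.int16)[:, :2]
        gts = np.where(gts < 0, MISSING, gts).astype(np.int8)
        gq_raw = variant.format("GQ")
        if gq_raw is None:
            gq = np.full(len(samples), MISSING, dtype=np.int32)
        else:
            gq = np.asarray(gq_raw, dtype=np.int64).reshape(len(samples))
            gq = np.where((gq < 0) | (gq > 10**6), MISSING, gq).astype(np.int32)
        sites.append(
            SiteRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref_allele=variant.REF,
                alt_allele=variant.ALT[0],
                genotypes=gts,
                gq=gq,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    if n_skipped:
        logger.info("parse_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if counters is not None:
        counters["sites_parsed"] = len(sites)
        counters["records_skipped_non_snp"] = n_skipped
    return sites, samples


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def apply_quality_filter(
    sites: list[SiteRecord],
    popmap: PopulationMap,
    samples: Sequence[str],
    cfg: FilterConfig,
    counters: dict | None = None,
) -> list[SiteRecord]:
    """Mask low-GQ calls and drop sites left uncallable in either population.

    A call whose GQ is below ``cfg.min_gq`` is set to missing (both
    haplotypes). A site survives only if each population keeps at least
    ``cfg.min_called_per_pop`` fully called genotypes. Input order is
    preserved; input records are never mutated.
    """
    lab1, lab2 = popmap.labels()
    idx1 = popmap.indices(lab1, samples)
    idx2 = popmap.indices(lab2, samples)

    out: list[SiteRecord] = []
    n_masked_calls = 0
    for site in sites:
        low = (site.gq != MISSING) & (site.gq < cfg.min_gq)
        if not cfg.missing_gq_passes:
            low = low | (site.gq == MISSING)
        if low.any():
            gts = site.genotypes.copy()
            gts[low, :] = MISSING
            n_masked_calls += int(low.sum())
            site = SiteRecord(site.chrom, site.pos, site.ref_allele,
                              site.alt_allele, gts, site.gq)
        called = site.called_mask()
        if (called[idx1].sum() >= cfg.min_called_per_pop
                and called[idx2].sum() >= cfg.min_called_per_pop):
            out.append(site)
    if counters is not None:
        counters["calls_masked_low_gq"] = n_masked_calls
        counters["sites_after_gq_filter"] = len(out)
    return out


def _check_sorted(sites: Sequence[SiteRecord]) -> None:
    for a, b in zip(sites, sites[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise VcfParseError(
                f"sites not sorted: {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def apply_proximity_filter(
    sites: list[SiteRecord],
    cfg: FilterConfig,
    counters: dict | None = None,
) -> list[SiteRecord]:
    """Remove SNPs closer than ``cfg.min_snp_distance`` to a neighbour.

    Distances are compared strictly (a gap exactly equal to the threshold
    survives) and never across chromosome boundaries. In the default
    ``drop_both`` mode every member of a close cluster is removed, which
    makes the filter symmetric and idempotent; ``keep_first`` retains the
    leftmost member of each cluster instead.
    """
    _check_sorted(sites)
    d = cfg.min_snp_distance
    keep: list[SiteRecord] = []
    i = 0
    n = len(sites)
    while i < n:
        j = i
        while j < n and sites[j].chrom == sites[i].chrom:
            j += 1
        chrom_sites = sites[i:j]
        pos = np.array([s.pos for s in chrom_sites])
        if cfg.proximity_mode == "drop_both":
            gaps = np.diff(pos)
            close_prev = np.concatenate([[False], gaps < d])
            close_next = np.concatenate([gaps < d, [False]])
            ok = ~(close_prev | close_next)
            keep.extend(s for s, k in zip(chrom_sites, ok) if k)
        else:  # keep_first
            last = None
            for s in chrom_sites:
                if last is None or s.pos - last >= d:
                    keep.append(s)
                    last = s.pos
        i = j
    if counters is not None:
        counters["sites_after_proximity_filter"] = len(keep)
    return keep


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def load_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Load genes from BED4+ (0-based half-open) or GFF3 (1-based inclusive).

    Format is chosen by extension (.gff/.gff3 vs BED otherwise). Records
    whose start exceeds their end after conversion are rejected with a
    logged warning naming the record; such coordinate swaps do occur in
    published gene tables.
    """
    if not os.path.exists(path):
        raise VcfParseError(f"gene model file not found: {path}")
    ext = os.path.splitext(str(path))[1].lower()
    is_gff = ext in (".gff", ".gff3", ".gtf")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                    name = _gff_attribute(fields[8])
                else:
                    if len(fields) < 4:
                        raise ValueError("BED needs >= 4 columns")
                    chrom = fields[0]
                    start = int(fields[1]) + 1  # 0-based half-open -> 1-based
                    end = int(fields[2])
                    name = fields[3]
            except (ValueError, IndexError) as exc:
                raise VcfParseError(f"{path}:{lineno}: unparseable line ({exc})")
            if not name:
                raise VcfParseError(f"{path}:{lineno}: gene record without a name")
            if start > end:
                logger.warning(
                    "rejecting gene %s (%s:%d-%d): start > end", name, chrom, start, end
                )
                continue
            genes.append(GeneModel(name=name, chrom=chrom, start=start, end=end))
    return genes


def _gff_attribute(attrs: str) -> str:
    pairs = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            pairs[k.strip()] = v.strip()
    return pairs.get("Name") or pairs.get("ID") or ""


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "sum_nmaj", "sum_nmin",
    "hp", "fst", "zhp", "zfst",
]


def write_outputs(windows, regions, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the per-window table, region BED/TSV and return their paths.

    Windows go to ``windows.tsv`` (1-based inclusive coordinates);
    candidate regions go to ``regions.bed`` (6-column, 0-based half-open)
    and ``regions.tsv`` (1-based, with the per-region gene list). Row
    order is deterministic: (chrom, start).
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "windows": os.path.join(outdir, "windows.tsv"),
        "regions_bed": os.path.join(outdir, "regions.bed"),
        "regions_tsv": os.path.join(outdir, "regions.tsv"),
    }

    wrows = [
        {
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_snps": w.n_snps, "sum_nmaj": w.sum_nmaj, "sum_nmin": w.sum_nmin,
            "hp": w.hp, "fst": w.fst, "zhp": w.zhp, "zfst": w.zfst,
        }
        for w in sorted(windows, key=lambda w: (w.chrom, w.start))
    ]
    wdf = pd.DataFrame(wrows, columns=WINDOW_COLUMNS)
    wdf.to_csv(paths["windows"], sep="\t", index=False,
               float_format="%.6g", na_rep="NA")

    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(paths["regions_bed"], "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t"
                     f"{len(r.support_windows)}\t.\n")
    rrows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_windows": len(r.support_windows),
            "genes": ";".join(r.genes) if r.genes else "NA",
        }
        for r in regions
    ]
    rdf = pd.DataFrame(rrows, columns=["chrom", "start", "end", "n_windows", "genes"])
    rdf.to_csv(paths["regions_tsv"], sep="\t", index=False)
    return paths


def read_region_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read a region BED back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out
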