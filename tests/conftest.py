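"""Shared builders and independent brute-force oracles for the test suite."""

import numpy as np
import pytest

from sweepscan import MISSING, PopulationMap, SiteRecord


def make_site(chrom, pos, dosages, gq=None, ref="A", alt="C"):
    """SiteRecord from per-sample alt-allele dosages (0/1/2, None=missing)."""
    gts = []
    for d in dosages:
        if d is None:
            gts.append((MISSING, MISSING))
        else:
            gts.append((1 if d == 2 else 0, 1 if d >= 1 else 0))
    g = np.asarray(gts, dtype=np.int8)
    if gq is None:
        gq = [99] * len(dosages)
    return SiteRecord(chrom, pos, ref, alt, g, np.asarray(gq, dtype=np.int32))


def write_vcf(path, rows, samples, contigs=()):
    """Write a minimal VCF v4.2; rows are (chrom, pos, ref, alt, calls)
    where calls is a list of 'GT:GQ' strings or (gt, gq) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, calls in rows:
            rendered = [
                c if isinstance(c, str) else f"{c[0]}:{c[1]}" for c in calls
            ]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ\t"
                     + "\t".join(rendered) + "\n")
    return path


@pytest.fixture
def popmap_4v4():
    return PopulationMap({f"a{i}": "case" for i in range(4)}
                         | {f"b{i}": "control" for i in range(4)})


@pytest.fixture
def popmap_8v8():
    return PopulationMap({f"a{i}": "case" for i in range(8)}
                         | {f"b{i}": "control" for i in range(8)})


def samples_of(popmap):
    return list(popmap.assignments)


# ---------------------------------------------------------------------------
# Independent oracles (re-scan everything per window / per base pair)
# ---------------------------------------------------------------------------


def brute_force_window_counts(sites, windows, sample_indices):
    """(n_snps, sum_nmaj, sum_nmin) per window by re-scanning all sites."""
    out = []
    for chrom, start, end in windows:
        n = nmaj_sum = nmin_sum = 0
        for s in sites:
            if s.chrom != chrom or not (start <= s.pos <= end):
                continue
            alleles = [int(a) for i in sample_indices for a in s.genotypes[i]]
            called = [a for a in alleles if a != MISSING]
            if not called:
                continue
            alt = sum(1 for a in called if a == 1)
            refc = len(called) - alt
            n += 1
            nmaj_sum += max(refc, alt)
            nmin_sum += min(refc, alt)
        out.append((n, nmaj_sum, nmin_sum))
    return out


def brute_force_window_fst(sites, windows, idx1, idx2):
    """Mean per-site Fst per window, recomputed from first principles."""
    out = []
    for chrom, start, end in windows:
        vals = []
        for s in sites:
            if s.chrom != chrom or not (start <= s.pos <= end):
                continue
            f = _plain_site_fst(s, idx1, idx2)
            if f is not None:
                vals.append(f)
        out.append(sum(vals) / len(vals) if vals else None)
    return out


def _plain_site_fst(site, idx1, idx2):
    def freqs(idx):
        alleles = [int(a) for i in idx for a in site.genotypes[i] if a != MISSING]
        return (sum(alleles), len(alleles))

    a1, n1 = freqs(idx1)
    a2, n2 = freqs(idx2)
    if n1 == 0 or n2 == 0:
        return None
    p1, p2 = a1 / n1, a2 / n2
    pr = (a1 + a2) / (n1 + n2)
    if pr in (0.0, 1.0):
        return None
    return 1 - (p1 * (1 - p1) + p2 * (1 - p2)) / (2 * pr * (1 - pr))


def brute_force_regions(windows, zfst_threshold, zhp_threshold, genome_lengths):
    """Per-basepair region calls: mark every bp covered by a ZFst outlier
    window AND by a ZHp outlier window, then extract maximal runs."""
    import math

    regions = []
    for chrom in sorted(genome_lengths):
        L = genome_lengths[chrom]
        cov_fst = np.zeros(L + 2, dtype=bool)  # index 1..L
        cov_hp = np.zeros(L + 2, dtype=bool)
        for w in windows:
            if w.chrom != chrom:
                continue
            if not math.isnan(w.zfst) and w.zfst > zfst_threshold:
                cov_fst[w.start:w.end + 1] = True
            if not math.isnan(w.zhp) and w.zhp < zhp_threshold:
                cov_hp[w.start:w.end + 1] = True
        both = cov_fst & cov_hp
        start = None
        for bp in range(1, L + 2):
            if both[bp] and start is None:
                start = bp
            elif not both[bp] and start is not None:
                regions.append((chrom, start, bp - 1))
                start = None
    return regions


def covered_bp(intervals):
    """Total base pairs covered by a set of (chrom, start, end) intervals."""
    seen = set()
    for chrom, start, end in intervals:
        for bp in range(start, end + 1):
            seen.add((chrom, bp))
    return len(seen)


def reciprocal_overlap(a, b):
    """min(overlap/len(a), overlap/len(b)) for two (chrom,start,end) intervals."""
    if a[0] != b[0]:
        return 0.0
    lo, hi = max(a[1], b[1]), min(a[2], b[2])
    ov = max(0, hi - lo + 1)
    return min(ov / (a[2] - a[1] + 1), ov / (b[2] - b[1] + 1))
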