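"""Two-population diploid genotype simulator with planted selective sweeps.

Generates the statistical structure the scan assumes — two populations
sharing background allele frequencies with mild divergence, plus sweep
intervals where population 1 is near fixation while population 2 stays
intermediate — and emits a VCF, a population map, toy gene models and a
ground-truth BED so every downstream module can be tested end to end
without external data.

Background divergence follows the Balding–Nichols model: an ancestral
frequency pi ~ Beta(b, b) is drawn per SNP, then each population's
frequency is drawn from Beta(pi*(1-F)/F, (1-pi)*(1-F)/F), giving
expected differentiation F between the populations. Inside sweep
intervals population 1's minor-allele frequency is capped near zero
(near fixation, hence low heterozygosity) while population 2 draws from
an intermediate range (hence high Fst). Low-GQ calls and sub-spacing
SNP pairs are planted deliberately so both SNP filters are exercised by
every simulated dataset. There is no linkage, recombination or
demographic history: sites are independent given their frequencies.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .variant_io import ConfigurationError


def _default_sweeps() -> list[tuple[str, int, int]]:
    # one 150-kb sweep per genome, centred on chromosome 1
    return [("1", 925_001, 1_075_000)]


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror an 8-vs-8 resequencing design.

    seed
        RNG seed; everything downstream is byte-reproducible from it.
    n_chroms, chrom_length
        Genome geometry (default 2 chromosomes x 2 Mb — a desk-scale
        stand-in for a whole genome).
    snp_density
        Expected SNPs per bp (default 1/500, i.e. ~200 SNPs per 100-kb
        window, comfortably above the scan's qualification floor).
    n_per_pop
        Diploid individuals per population (default 8 + 8).
    background_fst
        Balding–Nichols divergence parameter F (default 0.05, mild
        background structure between related populations).
    beta_shape
        Shape of the symmetric ancestral-frequency Beta (default 0.8,
        slightly U-shaped as site-frequency spectra are).
    sweep_intervals
        Planted sweep intervals, 1-based inclusive.
    sweep_case_minor_freq_max
        Ceiling on population 1's minor-allele frequency inside sweeps.
    sweep_control_freq_range
        Population 2's allele-frequency range inside sweeps.
    gq_low_fraction
        Fraction of genotype calls given GQ below 20.
    close_pair_fraction
        Fraction of SNPs planted < 5 bp from a neighbour.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    snp_density: float = 1.0 / 500.0
    n_per_pop: int = 8
    background_fst: float = 0.05
    beta_shape: float = 0.8
    sweep_intervals: list[tuple[str, int, int]] = field(default_factory=_default_sweeps)
    sweep_case_minor_freq_max: float = 0.02
    sweep_control_freq_range: tuple[float, float] = (0.3, 0.7)
    gq_low_fraction: float = 0.01
    close_pair_fraction: float = 0.005

    def __post_init__(self) -> None:
        for frac in (self.gq_low_fraction, self.close_pair_fraction,
                     self.sweep_case_minor_freq_max):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.n_per_pop < 2:
            raise ConfigurationError("need >= 2 diploids per population")
        chroms = set(self.chrom_names())
        for chrom, start, end in self.sweep_intervals:
            if chrom not in chroms or not (1 <= start <= end <= self.chrom_length):
                raise ConfigurationError(
                    f"sweep interval {(chrom, start, end)} outside the genome"
                )

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chroms)]


@dataclass
class SweepTruth:
    """A planted sweep interval and the realised case-population MAF."""

    chrom: str
    start: int
    end: int
    mean_case_maf: float


@dataclass
class SiteFrequencies:
    """Per-chromosome SNP positions and population allele frequencies."""

    chrom: str
    pos: np.ndarray  # 1-based, sorted, unique
    p1: np.ndarray   # alt-allele frequency, population 1 (case)
    p2: np.ndarray   # alt-allele frequency, population 2 (control)
    in_sweep: np.ndarray  # bool mask


@dataclass
class DatasetPaths:
    vcf: str
    popmap: str
    genes_bed: str
    truth_bed: str
    config_json: str


# ---------------------------------------------------------------------------
# Frequency and genotype simulation
# ---------------------------------------------------------------------------


def simulate_frequencies(cfg: SimConfig) -> list[SiteFrequencies]:
    """Draw SNP positions and two-population allele frequencies.

    Positions follow a Poisson process at ``snp_density`` with an extra
    ``close_pair_fraction`` of companion SNPs planted 1–4 bp from a
    random neighbour. Background frequencies follow Balding–Nichols;
    sweep sites override population 1 with a near-fixed frequency and
    population 2 with an intermediate draw. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    F = cfg.background_fst
    out: list[SiteFrequencies] = []
    for chrom in cfg.chrom_names():
        n = rng.poisson(cfg.chrom_length * cfg.snp_density)
        pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=n))
        n_close = int(round(cfg.close_pair_fraction * pos.size))
        if n_close > 0:
            anchors = rng.choice(pos, size=n_close, replace=False)
            offsets = rng.integers(1, 5, size=n_close)
            companions = np.clip(anchors + offsets, 1, cfg.chrom_length)
            pos = np.unique(np.concatenate([pos, companions]))
        m = pos.size

        pi = np.clip(rng.beta(cfg.beta_shape, cfg.beta_shape, size=m), 1e-3, 1 - 1e-3)
        if F > 0:
            a = pi * (1 - F) / F
            b = (1 - pi) * (1 - F) / F
            p1 = rng.beta(a, b)
            p2 = rng.beta(a, b)
        else:
            p1 = pi.copy()
            p2 = pi.copy()

        in_sweep = np.zeros(m, dtype=bool)
        for sw_chrom, sw_start, sw_end in cfg.sweep_intervals:
            if sw_chrom == chrom:
                in_sweep |= (pos >= sw_start) & (pos <= sw_end)
        k = int(in_sweep.sum())
        if k:
            maf = rng.uniform(0.0, cfg.sweep_case_minor_freq_max, size=k)
            # swept (alt) allele near fixation in the case population
            p1[in_sweep] = 1.0 - maf
            lo, hi = cfg.sweep_control_freq_range
            p2[in_sweep] = rng.uniform(lo, hi, size=k)

        out.append(SiteFrequencies(chrom=chrom, pos=pos, p1=p1, p2=p2,
                                   in_sweep=in_sweep))
    return out


def sample_genotypes(
    freqs: SiteFrequencies, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw diploid genotypes and GQ values for one chromosome.

    Returns ``(genotypes, gq)`` with shapes ``(n_sites, 2*n_per_pop, 2)``
    and ``(n_sites, 2*n_per_pop)``; population 1 occupies the first
    ``n_per_pop`` sample columns. Each individual's alt-allele dosage is
    Binomial(2, p) for its population's frequency; GQ is drawn in 60–99
    except for a ``gq_low_fraction`` of calls drawn in 0–19.
    """
    m = freqs.pos.size
    npp = cfg.n_per_pop
    dosage1 = rng.binomial(2, freqs.p1[:, None], size=(m, npp))
    dosage2 = rng.binomial(2, freqs.p2[:, None], size=(m, npp))
    dosage = np.concatenate([dosage1, dosage2], axis=1)
    # dosage -> unphased allele pair: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1
    gts = np.zeros((m, 2 * npp, 2), dtype=np.int8)
    gts[:, :, 0] = (dosage == 2).astype(np.int8)
    gts[:, :, 1] = (dosage >= 1).astype(np.int8)

    gq = rng.integers(60, 100, size=(m, 2 * npp)).astype(np.int32)
    low = rng.random(size=(m, 2 * npp)) < cfg.gq_low_fraction
    gq[low] = rng.integers(0, 20, size=int(low.sum()))
    return gts, gq


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def emit_dataset(cfg: SimConfig, outdir: str | os.PathLike) -> tuple[DatasetPaths, list[SweepTruth]]:
    """Simulate and write a complete dataset: VCF, popmap, genes, truth, config.

    The VCF is v4.2 with contig headers and GT:GQ per call; samples are
    ``pop1_1..pop1_n`` then ``pop2_1..pop2_n``. The gene BED contains
    one gene inside each sweep interval plus decoys elsewhere; the truth
    BED records the planted intervals with the realised case-population
    minor-allele frequency in the score column. Byte-reproducible from
    the seed.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = DatasetPaths(
        vcf=os.path.join(outdir, "sim.vcf"),
        popmap=os.path.join(outdir, "popmap.tsv"),
        genes_bed=os.path.join(outdir, "genes.bed"),
        truth_bed=os.path.join(outdir, "truth.bed"),
        config_json=os.path.join(outdir, "sim_config.json"),
    )
    freqs = simulate_frequencies(cfg)
    rng = np.random.default_rng([cfg.seed, 7])

    samples = [f"pop1_{i+1}" for i in range(cfg.n_per_pop)] + \
              [f"pop2_{i+1}" for i in range(cfg.n_per_pop)]

    with open(paths.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulator\n")
        for chrom in cfg.chrom_names():
            fh.write(f"##contig=<ID={chrom},length={cfg.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom_freqs in freqs:
            gts, gq = sample_genotypes(chrom_freqs, cfg, rng)
            ref_idx = rng.integers(0, 4, size=chrom_freqs.pos.size)
            alt_shift = rng.integers(1, 4, size=chrom_freqs.pos.size)
            refs = _BASES[ref_idx]
            alts = _BASES[(ref_idx + alt_shift) % 4]
            for i, pos in enumerate(chrom_freqs.pos):
                calls = "\t".join(
                    f"{gts[i, j, 0]}/{gts[i, j, 1]}:{gq[i, j]}"
                    for j in range(len(samples))
                )
                fh.write(f"{chrom_freqs.chrom}\t{pos}\t.\t{refs[i]}\t{alts[i]}\t"
                         f".\tPASS\t.\tGT:GQ\t{calls}\n")

    with open(paths.popmap, "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{s.split('_')[0]}\n")

    truths = _realized_truths(cfg, freqs)
    with open(paths.truth_bed, "w") as fh:
        for i, t in enumerate(truths, 1):
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\tsweep_{i}\t"
                     f"{t.mean_case_maf:.6g}\t.\n")

    _write_gene_bed(cfg, paths.genes_bed)

    with open(paths.config_json, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)
        fh.write("\n")
    return paths, truths


def _realized_truths(cfg: SimConfig, freqs: list[SiteFrequencies]) -> list[SweepTruth]:
    truths = []
    by_chrom = {f.chrom: f for f in freqs}
    for chrom, start, end in cfg.sweep_intervals:
        f = by_chrom[chrom]
        mask = (f.pos >= start) & (f.pos <= end)
        maf = np.minimum(f.p1[mask], 1 - f.p1[mask])
        truths.append(SweepTruth(chrom=chrom, start=start, end=end,
                                 mean_case_maf=float(maf.mean()) if mask.any() else 0.0))
    return truths


def _write_gene_bed(cfg: SimConfig, path: str) -> None:
    """One gene centred in each sweep plus three fixed decoys per chromosome."""
    rows = []
    for i, (chrom, start, end) in enumerate(cfg.sweep_intervals, 1):
        mid = (start + end) // 2
        half = max((end - start) // 4, 1)
        rows.append((chrom, mid - half - 1, mid + half, f"SWEPT{i}"))
    for chrom in cfg.chrom_names():
        L = cfg.chrom_length
        for j, frac in enumerate((0.05, 0.35, 0.85), 1):
            g_start = int(L * frac)
            rows.append((chrom, g_start - 1, g_start + 20_000, f"DECOY{chrom}_{j}"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, s0, e, name in rows:
            fh.write(f"{chrom}\t{s0}\t{e}\t{name}\n")


def load_truth_bed(path: str | os.PathLike) -> list[SweepTruth]:
    """Read a truth BED back into SweepTruth records (1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(SweepTruth(chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                                  mean_case_maf=float(f[4]) if len(f) > 4 else 0.0))
    return out
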