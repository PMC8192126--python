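"""Sliding windows over empirical multi-panel VCF/BCF data.

Coordinates presented to users are 1-based inclusive (matching the
reported interval convention); internal arithmetic is half-open and
converted at the boundary.  Windows are 100 kbp by default, stepping
20 kbp, so window starts are congruent to 1 modulo the step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from introscan.encode import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)

WINDOW_SIZE = 100_000
WINDOW_STEP = 20_000


@dataclass(frozen=True)
class GenomeWindow:
    """One genomic window, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    step: int = WINDOW_STEP

    def __post_init__(self):
        if self.end < self.start or self.start < 1:
            raise ValueError("invalid window coordinates")
        if self.start % self.step != 1 % self.step:
            raise ValueError("window start must be congruent to 1 modulo the step")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def iter_windows(
    chrom_length: int,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    chrom: str = "1",
) -> list[GenomeWindow]:
    """Overlapping windows starting at 1, 1+step, ...; windows running
    past the chromosome end are omitted."""
    if size % step != 0:
        raise ValueError("window size must be a multiple of the step")
    out = []
    start = 1
    while start + size - 1 <= chrom_length:
        out.append(GenomeWindow(chrom, start, start + size - 1, step))
        start += step
    return out


class VcfDataset:
    """A set of indexed VCF/BCF files holding the population panels.

    ``panels`` maps population name to an ordered list of sample names;
    each sample must be present in exactly one of the files.
    """

    def __init__(self, paths: list, panels: dict[str, list[str]]):
        self.paths = [str(p) for p in paths]
        self.panels = panels
        self._vcfs = [VCF(p) for p in self.paths]
        self._where: dict[str, tuple[int, int]] = {}
        for vi, vcf in enumerate(self._vcfs):
            for si, name in enumerate(vcf.samples):
                self._where.setdefault(name, (vi, si))
        for pop, names in panels.items():
            for name in names:
                if name not in self._where:
                    raise ValueError(f"sample {name!r} (panel {pop}) not in any VCF")
        self.n_multiallelic_dropped = 0

    def _check_contig(self, chrom: str) -> None:
        for path, vcf in zip(self.paths, self._vcfs):
            if chrom not in set(vcf.seqnames):
                raise ValueError(f"contig {chrom!r} missing from {path}")

    def _site_genotypes(self, region: str | None):
        """Per-file dict position -> genotype row (biallelic SNPs only)."""
        per_file = []
        for vcf in self._vcfs:
            records = {}
            it = vcf(region) if region else vcf
            for var in it:
                if len(var.ALT) != 1:
                    self.n_multiallelic_dropped += 1
                    continue
                gts = np.asarray(var.genotypes)[:, :2]
                records[var.POS] = gts
            per_file.append(records)
        return per_file


def intersect_sites(vcf_set: VcfDataset, region: str | None = None) -> np.ndarray:
    """Positions (1-based) present in every file of the dataset."""
    if region:
        vcf_set._check_contig(region.split(":")[0])
    per_file = vcf_set._site_genotypes(region)
    common = set(per_file[0])
    for records in per_file[1:]:
        common &= set(records)
    return np.asarray(sorted(common), dtype=np.int64)


def load_window(
    vcf_set: VcfDataset,
    window: GenomeWindow,
    freq_min: float = 0.05,
    missing_max: float = 0.10,
    min_seg: int = 20,
) -> HaplotypePanel | None:
    """Build the haplotype panel for one window, or None if it fails QC.

    Sites are intersected across files, then filtered: pooled
    minor-allele frequency below ``freq_min`` (sites at exactly the
    threshold are retained) or more than ``missing_max`` of genotype
    calls missing.  Windows with fewer than ``min_seg`` surviving
    segregating sites are rejected.  Genotypes are treated as phased
    according to the VCF allele columns (archaic panels included).
    """
    if not (0 <= freq_min <= 1 and 0 <= missing_max <= 1 and min_seg >= 0):
        raise ValueError("filters out of range")
    vcf_set._check_contig(window.chrom)
    per_file = vcf_set._site_genotypes(window.region)
    common = set(per_file[0])
    for records in per_file[1:]:
        common &= set(records)
    positions = sorted(common)
    if not positions:
        return None

    rows = []
    pops = []
    for pop, names in vcf_set.panels.items():
        for name in names:
            vi, si = vcf_set._where[name]
            hap0 = np.array([per_file[vi][pos][si, 0] for pos in positions])
            hap1 = np.array([per_file[vi][pos][si, 1] for pos in positions])
            rows.extend([hap0, hap1])
            pops.extend([pop, pop])
    alleles = np.array(rows, dtype=np.int8)
    alleles[alleles < 0] = MISSING
    positions = np.asarray(positions, dtype=np.int64)

    called = alleles != MISSING
    n_called = called.sum(axis=0)
    # a genotype (individual) is missing when either allele is uncalled
    miss_ind = (alleles[0::2] == MISSING) | (alleles[1::2] == MISSING)
    miss_frac = miss_ind.mean(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(called, alleles, 0).sum(axis=0) / np.maximum(n_called, 1)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep = (n_called > 0) & (maf >= freq_min) & (miss_frac <= missing_max)
    alleles, positions = alleles[:, keep], positions[keep]
    seg = [
        i
        for i in range(alleles.shape[1])
        if len(np.unique(alleles[alleles[:, i] != MISSING, i])) > 1
    ]
    if len(seg) < min_seg:
        return None
    return HaplotypePanel(
        alleles=alleles,
        positions=positions - window.start,  # 0-based within the window
        populations=np.asarray(pops),
        phased=True,
    )


# ---------------------------------------------------------------------------
# VCF output (used for round-tripping simulations and building test genomes)
# ---------------------------------------------------------------------------


def write_vcf(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    populations: np.ndarray,
    path,
    chrom: str = "1",
    offset: int = 0,
    contig_length: int | None = None,
    sample_names: list[str] | None = None,
) -> list[str]:
    """Write phased diploid haplotypes to an uncompressed VCF text file.

    Consecutive haplotype rows (2i, 2i+1) form one sample.  Positions
    are written 1-based with ``offset`` added.  Returns sample names.
    """
    hap = np.asarray(haplotypes)
    n_ind = hap.shape[0] // 2
    if sample_names is None:
        counters: dict[str, int] = {}
        sample_names = []
        for i in range(n_ind):
            pop = str(populations[2 * i])
            counters[pop] = counters.get(pop, 0) + 1
            sample_names.append(f"{pop}{counters[pop]}")
    if contig_length is None:
        contig_length = int(offset + (positions.max() if len(positions) else 0) + 2)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j, pos in enumerate(positions):
            gts = []
            for i in range(n_ind):
                a, b = hap[2 * i, j], hap[2 * i + 1, j]
                fmt = lambda v: "." if v == MISSING else str(int(v))
                gts.append(f"{fmt(a)}|{fmt(b)}")
            fh.write(
                f"{chrom}\t{int(pos) + offset + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return sample_names


def compress_and_index(path) -> str:
    """bgzip + tabix a VCF text file, returning the .gz path."""
    import pysam

    gz = str(path) + ".gz"
    pysam.tabix_compress(str(path), gz, force=True)
    pysam.tabix_index(gz, preset="vcf", force=True)
    return gz
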