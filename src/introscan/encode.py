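"""Convert haplotype data for one window into the CNN input matrix.

The encoding follows a fixed pipeline: polarise alleles so the pooled
minor allele is 1, drop low-frequency sites and the selected site,
count minor alleles per haplotype in ``m`` equal-width genomic bins,
optionally collapse chromosome pairs into diploid genotypes, then
concatenate the population blocks (non-donor archaic, donor, recipient,
outgroup), sorting each block by similarity to the donor population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from introscan.simulate.engine import SimulationResult

MISSING = -1


@dataclass
class HaplotypePanel:
    """Raw allele matrix for one genomic window.

    ``alleles`` is (n_haplotypes, n_sites) with values 0/1 or
    :data:`MISSING`; ``pairing`` lists the row-index tuples forming each
    diploid individual (defaults to consecutive pairs).
    """

    alleles: np.ndarray
    positions: np.ndarray
    populations: np.ndarray
    phased: bool = True
    pairing: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles)
        self.positions = np.asarray(self.positions)
        self.populations = np.asarray(self.populations)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted ascending")
        if self.pairing is None:
            n = self.alleles.shape[0]
            if n % 2:
                raise ValueError("odd haplotype count needs an explicit pairing")
            self.pairing = tuple((2 * i, 2 * i + 1) for i in range(n // 2))

    @classmethod
    def from_simulation(cls, result: SimulationResult) -> "HaplotypePanel":
        return cls(
            alleles=result.haplotypes,
            positions=result.positions,
            populations=result.sample_populations,
            phased=True,
        )


@dataclass
class ResizedMatrix:
    """The n x m minor-allele-count image consumed by the classifier.

    Rows are haplotypes (phased) or individuals (unphased), grouped into
    population blocks in encoder order; ``block_bounds`` maps population
    name to its ``(start, stop)`` row range.
    """

    matrix: np.ndarray
    block_bounds: dict[str, tuple[int, int]]
    bin_width: float
    phased: bool

    def __post_init__(self):
        if np.any(self.matrix < 0):
            raise ValueError("count matrix entries must be non-negative")

    def block(self, pop: str) -> np.ndarray:
        a, b = self.block_bounds[pop]
        return self.matrix[a:b]


def polarise_minor(
    panel: HaplotypePanel, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Recode alleles so the pooled minor allele is 1 and the major is 0.

    The major allele at each site is the one with pooled frequency
    > 0.5 after merging all individuals; at exactly 0.5 the major allele
    is chosen at random (deterministic per rng state).  Missing calls
    are excluded from the frequency denominator and recoded to 0.

    Returns ``(binary matrix, pooled minor-allele frequency per site)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    alleles = panel.alleles
    called = alleles != MISSING
    n_called = called.sum(axis=0)
    if np.any(n_called == 0):
        raise ValueError("site with no called alleles; filter upstream")
    ones = np.where(called, alleles, 0).sum(axis=0)
    freq1 = ones / n_called
    flip = freq1 > 0.5
    tie = freq1 == 0.5
    if np.any(tie):
        # position-keyed tie break: deterministic per rng state yet
        # independent of which other sites are present, so filtered and
        # unfiltered views of the same data polarise identically
        salt = np.uint64(rng.integers(0, 2**63))
        h = panel.positions.astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15) + salt
        h ^= h >> np.uint64(31)
        h *= np.uint64(0xBF58476D1CE4E5B9)
        h ^= h >> np.uint64(29)
        flip = flip | (tie & ((h >> np.uint64(62)) & np.uint64(1)).astype(bool))
    out = np.where(called, np.where(flip[None, :], 1 - alleles, alleles), 0)
    maf = np.where(flip, 1 - freq1, freq1)
    return out.astype(np.int8), maf


def filter_sites(
    matrix: np.ndarray,
    positions: np.ndarray,
    maf: float,
    selected_pos: int | None = None,
    freq: np.ndarray | None = None,
    keep_equal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop sites at or below the minor-allele-frequency threshold, and
    the selected site when its position is given.

    By default sites with pooled MAF <= ``maf`` are removed (strictly
    greater retained); ``keep_equal=True`` retains MAF == maf.
    """
    if not 0 <= maf <= 0.5:
        raise ValueError("maf threshold must be in [0, 0.5]")
    if freq is None:
        freq = (matrix == 1).sum(axis=0) / np.maximum((matrix != MISSING).sum(axis=0), 1)
    keep = freq >= maf if keep_equal else freq > maf
    if selected_pos is not None:
        keep = keep & (positions != selected_pos)
    return matrix[:, keep], positions[keep]


def bin_counts(
    matrix: np.ndarray,
    positions: np.ndarray,
    window_start: int,
    window_len: int,
    m: int,
) -> np.ndarray:
    """Count minor alleles per haplotype in ``m`` equal-width bins.

    Bin ``b`` covers ``[start + b*len/m, start + (b+1)*len/m)``.  Unlike
    interpolation resizing, no site is discarded: each row sum equals
    that haplotype's total minor-allele count.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    off = np.asarray(positions) - window_start
    if np.any(off < 0) or np.any(off >= window_len):
        raise ValueError("position outside window")
    idx = (off.astype(np.int64) * m) // window_len
    n = matrix.shape[0]
    counts = np.zeros((n, m), dtype=np.int64)
    vals = np.where(matrix == 1, 1, 0)
    np.add.at(counts, (np.arange(n)[:, None], idx[None, :]), vals)
    return counts


def collapse_unphased(
    counts: np.ndarray, pairing: tuple[tuple[int, ...], ...]
) -> np.ndarray:
    """Sum per-bin minor-allele counts over the chromosomes of each
    individual.  ``pairing`` must cover every row exactly once."""
    seen = [r for grp in pairing for r in grp]
    if sorted(seen) != list(range(counts.shape[0])):
        raise ValueError("pairing must partition haplotype rows")
    return np.stack([counts[list(grp)].sum(axis=0) for grp in pairing])


def sort_by_donor_similarity(
    block: np.ndarray, donor_mean_density: np.ndarray
) -> np.ndarray:
    """Permutation ordering block rows by ascending Euclidean distance to
    the donor's mean per-bin minor-allele density (most donor-like
    first).  Ties keep their original order."""
    donor_mean_density = np.asarray(donor_mean_density, dtype=float)
    if donor_mean_density.shape[0] != block.shape[1]:
        raise ValueError("donor mean density must have one entry per bin")
    d = np.linalg.norm(block - donor_mean_density[None, :], axis=1)
    return np.argsort(d, kind="stable")


def assemble_input(
    panels: dict[str, np.ndarray],
    order: tuple[str, ...],
    donor: str,
    phased: bool,
    bin_width: float,
) -> ResizedMatrix:
    """Concatenate per-population count blocks in encoder order, sorting
    each block against the donor's mean density."""
    widths = {p.shape[1] for p in panels.values()}
    if len(widths) != 1:
        raise ValueError("all panels must share the same number of bins")
    donor_mean = panels[donor].mean(axis=0)
    blocks, bounds, at = [], {}, 0
    for pop in order:
        block = panels[pop]
        block = block[sort_by_donor_similarity(block, donor_mean)]
        blocks.append(block)
        bounds[pop] = (at, at + block.shape[0])
        at += block.shape[0]
    full = np.concatenate(blocks, axis=0)
    if full.max(initial=0) > 255:
        raise ValueError("bin counts exceed 8-bit range; increase m")
    return ResizedMatrix(
        matrix=full.astype(np.uint8),
        block_bounds=bounds,
        bin_width=bin_width,
        phased=phased,
    )


def encode_panel(
    panel: HaplotypePanel,
    order: tuple[str, ...],
    donor: str,
    *,
    m: int = 256,
    maf: float = 0.05,
    window_start: int = 0,
    window_len: int = 100_000,
    selected_pos: int | None = None,
    phased: bool = True,
    rng: np.random.Generator | None = None,
    keep_equal_maf: bool = False,
) -> ResizedMatrix:
    """Run the full encoding pipeline on a raw haplotype panel."""
    mat, freq = polarise_minor(panel, rng)
    mat, pos = filter_sites(
        mat, panel.positions, maf, selected_pos, freq=freq, keep_equal=keep_equal_maf
    )
    counts = bin_counts(mat, pos, window_start, window_len, m)
    pops = panel.populations
    if not phased:
        counts = collapse_unphased(counts, panel.pairing)
        pops = np.asarray([pops[grp[0]] for grp in panel.pairing])
    blocks = {pop: counts[pops == pop] for pop in order}
    return assemble_input(blocks, order, donor, phased, window_len / m)


def encode_simulation(
    result: SimulationResult,
    *,
    m: int = 256,
    maf: float = 0.05,
    phased: bool = True,
    rng: np.random.Generator | None = None,
) -> ResizedMatrix:
    """Encode a :class:`SimulationResult` (ties seeded from the result's
    own RNG seed for reproducibility)."""
    if rng is None:
        rng = np.random.default_rng(result.seed + 0x9E3779B9)
    panel = HaplotypePanel.from_simulation(result)
    return encode_panel(
        panel,
        result.panel_order,
        result.panel_order[-3],
        m=m,
        maf=maf,
        window_len=result.length,
        selected_pos=result.selected_pos,
        phased=phased,
        rng=rng,
    )
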