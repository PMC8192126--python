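"""HapMap-format genetic map input and random chunk sampling."""

from __future__ import annotations

import numpy as np
import msprime


def read_hapmap(path) -> msprime.RateMap:
    """Read a HapMap-format genetic map text file.

    Expected columns: ``Chromosome  Position(bp)  Rate(cM/Mb)  Map(cM)``
    with a single header line.  Delegates parsing to
    :meth:`msprime.RateMap.read_hapmap`.
    """
    return msprime.RateMap.read_hapmap(path)


def sample_map_chunk(
    rate_map: msprime.RateMap, length: int, rng: np.random.Generator
) -> msprime.RateMap:
    """Draw a random ``length``-bp chunk of a genetic map, re-origined to 0.

    The chunk start is uniform over the map; the returned RateMap spans
    ``[0, length)``.  Missing-rate intervals are filled with the map's
    mean rate so the chunk is fully defined.
    """
    total = rate_map.sequence_length
    if total < length:
        raise ValueError("genetic map shorter than the requested chunk")
    start = float(rng.uniform(0, total - length))
    chunk = rate_map.slice(left=start, right=start + length, trim=True)
    rate = np.nan_to_num(np.asarray(chunk.rate), nan=rate_map.mean_rate)
    pos = np.asarray(chunk.position, dtype=float).copy()
    pos[0], pos[-1] = 0.0, float(length)  # pin endpoints against float drift
    return msprime.RateMap(position=pos, rate=rate)


def scale_rate_map(rate_map: msprime.RateMap, Q: float) -> msprime.RateMap:
    """Multiply all rates by the scaling factor Q."""
    return msprime.RateMap(
        position=rate_map.position, rate=np.asarray(rate_map.rate) * Q
    )


def crossover_positions(
    rate_map: msprime.RateMap | float,
    length: int,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n`` crossover breakpoints, distributed along the region
    in proportion to the local recombination rate (uniform for a flat
    rate)."""
    if n == 0:
        return np.empty(0)
    if isinstance(rate_map, msprime.RateMap):
        mass = np.asarray(rate_map.rate) * np.diff(rate_map.position)
        cum = np.concatenate([[0.0], np.cumsum(mass)])
        u = rng.uniform(0, cum[-1], size=n)
        idx = np.searchsorted(cum, u, side="right") - 1
        idx = np.clip(idx, 0, len(mass) - 1)
        left = rate_map.position[idx]
        span = np.diff(rate_map.position)[idx]
        frac = np.where(mass[idx] > 0, (u - cum[idx]) / np.where(mass[idx] > 0, mass[idx], 1), rng.uniform(size=n))
        return left + frac * span
    return rng.uniform(0, length, size=n)


def total_map_length(rate_map: msprime.RateMap | float, length: int) -> float:
    """Expected crossovers per meiosis over the region (Morgans)."""
    if isinstance(rate_map, msprime.RateMap):
        return float(rate_map.total_mass)
    return float(rate_map) * length
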