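"""Archaic-admixture summary statistics and empirical p-values.

Baselines against which the classifier is compared: the U and Q95
site-count statistics of donor-shared high-frequency alleles, the f_d
introgression-fraction estimator, and empirical p-values of observed
window statistics against a neutral null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from introscan.simulate.engine import SimulationResult


@dataclass
class SiteFrequencies:
    """Per-site allele frequencies in the panels used by the statistics.

    ``outgroup`` (A / w-condition), ``recipient`` (B / x-condition) and
    ``donor`` (C / y-condition), optionally a second modern panel for
    f_d.  Frequencies must be polarised consistently across panels
    (derived-allele, or donor-consensus when ancestral states are
    unknown).
    """

    outgroup: np.ndarray
    recipient: np.ndarray
    donor: np.ndarray
    positions: np.ndarray | None = None
    sister: np.ndarray | None = None  # P1 panel for f_d
    n_donor_haplotypes: int | None = None

    def __post_init__(self):
        arrs = [self.outgroup, self.recipient, self.donor]
        if self.sister is not None:
            arrs.append(self.sister)
        lengths = {len(a) for a in arrs}
        if len(lengths) > 1:
            raise ValueError("frequency arrays must have equal length")
        for a in arrs:
            a = np.asarray(a)
            if a.size and (a.min() < 0 or a.max() > 1):
                raise ValueError("frequencies must lie in [0, 1]")

    @classmethod
    def from_simulation(
        cls, result: SimulationResult, polarise: str = "donor"
    ) -> "SiteFrequencies":
        """Compute panel frequencies from a simulated region.

        ``polarise="donor"`` reports frequencies of the donor-consensus
        allele (used when true ancestral states are unavailable);
        ``polarise="derived"`` reports the simulator's derived allele 1.
        """
        donor_pop = result.panel_order[-3]
        rec_pop = result.panel_order[-2]
        out_pop = result.panel_order[-1]
        hap = result.haplotypes
        f = {}
        for pop in (donor_pop, rec_pop, out_pop):
            rows = hap[result.sample_populations == pop]
            f[pop] = rows.mean(axis=0)
        n_don = int((result.sample_populations == donor_pop).sum())
        if polarise == "donor":
            # report the frequency of the allele the donor consensus carries
            consensus = (f[donor_pop] >= 0.5).astype(float)
            for pop in f:
                f[pop] = np.where(consensus == 1, f[pop], 1 - f[pop])
        elif polarise != "derived":
            raise ValueError("polarise must be 'donor' or 'derived'")
        return cls(
            outgroup=f[out_pop],
            recipient=f[rec_pop],
            donor=f[donor_pop],
            positions=result.positions,
            n_donor_haplotypes=n_don,
        )


def _y_tolerance(freqs: SiteFrequencies) -> float:
    # "= y" is tested to half a haplotype count of frequency resolution
    if freqs.n_donor_haplotypes:
        return 0.5 / freqs.n_donor_haplotypes + 1e-12
    return 1e-9


def stat_U(freqs: SiteFrequencies, w: float, x: float, y: float) -> int:
    """Count sites with outgroup frequency < w, recipient frequency > x
    and donor frequency = y (within half-a-haplotype tolerance)."""
    for v in (w, x, y):
        if not 0 <= v <= 1:
            raise ValueError("w, x, y must be in [0, 1]")
    tol = _y_tolerance(freqs)
    mask = (
        (np.asarray(freqs.outgroup) < w)
        & (np.asarray(freqs.recipient) > x)
        & (np.abs(np.asarray(freqs.donor) - y) <= tol)
    )
    return int(mask.sum())


def stat_Q95(freqs: SiteFrequencies, w: float, y: float) -> float:
    """95th percentile of recipient frequencies at sites with outgroup
    frequency < w and donor frequency = y; NaN when no site qualifies.
    Linear interpolation between order statistics."""
    tol = _y_tolerance(freqs)
    mask = (np.asarray(freqs.outgroup) < w) & (
        np.abs(np.asarray(freqs.donor) - y) <= tol
    )
    if not mask.any():
        return float("nan")
    return float(np.quantile(np.asarray(freqs.recipient)[mask], 0.95))


def stat_fd(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p_out: np.ndarray
) -> float:
    """f_d introgression-fraction estimate for one window.

    ``p1`` is the non-introgressed sister panel, ``p2`` the recipient,
    ``p3`` the donor and ``p_out`` the outgroup, as derived-allele
    frequencies.  The denominator replaces p2 and p3 site-wise by
    max(p2, p3); NaN is returned when it is zero.
    """
    p1, p2, p3, po = (np.asarray(a, dtype=float) for a in (p1, p2, p3, p_out))
    num = np.sum((1 - p1) * p2 * p3 * (1 - po) - p1 * (1 - p2) * p3 * (1 - po))
    pd = np.maximum(p2, p3)
    den = np.sum((1 - p1) * pd * pd * (1 - po) - p1 * (1 - pd) * pd * (1 - po))
    if den == 0:
        return float("nan")
    return float(num / den)


def stat_fd_from(freqs: SiteFrequencies) -> float:
    """f_d with the outgroup panel doubling as P1 and the ancestral
    allele (frequency-0 everywhere by polarisation) as O."""
    sister = freqs.sister if freqs.sister is not None else freqs.outgroup
    zero = np.zeros_like(np.asarray(freqs.recipient))
    return stat_fd(sister, freqs.recipient, freqs.donor, zero)


def empirical_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Upper-tail empirical p-value: (1 + #{null >= obs}) / (1 + #null)."""
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[~np.isnan(null_values)]
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))


def window_statistics(
    freqs: SiteFrequencies,
    w: float = 0.01,
    x: float = 0.2,
    y: float = 1.0,
) -> dict[str, float]:
    """The standard battery for one window: U(w,x,y), Q95(w,y) and f_d."""
    return {
        "U": stat_U(freqs, w, x, y),
        "Q95": stat_Q95(freqs, w, y),
        "fd": stat_fd_from(freqs),
    }
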