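"""Region simulator: coalescent history plus forward-in-time selection.

One simulated region is produced in two stages.  First msprime generates
the neutral genealogy of (a) the archaic/outgroup panels at their
sampling times and (b) the *entire* recipient population at the moment
the selected dynamics begin ("founders"): the admixture pulse for AI, or
the origin of the de novo mutation for sweeps.  Neutral mutations are
overlaid on this genealogy.  Second, the recipient population alone is
evolved forward in time to the present with a discrete Wright-Fisher
model (random mating, recombination, new mutations and viability
selection on the focal allele).  Because the demographic models contain
no continuous migration, the recipient is a closed population after the
admixture pulse, so every other panel is exactly described by the
coalescent stage.

For AI, the beneficial mutation is placed on a branch of the genealogy
at the region midpoint that is ancestral to introgressed recipient
lineages and resides in the donor population at the drawn mutation time
(located via a census recorded at the pulse).  Rejection sampling with
checkpoint/restore conditions on the allele surviving to the present:
the forward stage restarts from the saved founder state whenever the
allele is lost or ends below the in-simulation frequency condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from introscan.simulate.demography import DemographicModel
from introscan.simulate.genmap import (
    crossover_positions,
    scale_rate_map,
    total_map_length,
)
from introscan.simulate.params import (
    DFEConfig,
    SelectionParams,
    draw_dfe_effects,
    draw_selection_params,
)


class SimulationError(RuntimeError):
    """Raised when rejection sampling exceeds its restore-attempt cap."""


@dataclass
class SimulationResult:
    """Haplotypes and metadata for one simulated region.

    ``haplotypes`` is (n_haplotypes, n_sites) with alleles 0/1; rows are
    grouped by population in ``panel_order`` and consecutive row pairs
    (2i, 2i+1) form one diploid individual.  ``positions`` are strictly
    increasing base-pair coordinates in ``[0, length)``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    length: int
    sample_populations: np.ndarray
    params: SelectionParams
    selected_pos: int | None
    seed: int
    model_name: str
    Q: float
    panel_order: tuple[str, ...]

    def __post_init__(self):
        pos = np.asarray(self.positions)
        if pos.size and not (np.all(np.diff(pos) > 0) and 0 <= pos[0] and pos[-1] < self.length):
            raise ValueError("positions must be strictly increasing within [0, length)")
        if self.haplotypes.shape[1] != pos.size:
            raise ValueError("haplotype matrix and positions disagree")
        if self.haplotypes.shape[0] != len(self.sample_populations):
            raise ValueError("every haplotype needs a population label")

    def panel_rows(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.sample_populations == pop)

    def save(self, path) -> None:
        """Write to a compressed npz archive (a runtime cache format)."""
        p = self.params
        np.savez_compressed(
            path,
            haplotypes=self.haplotypes,
            positions=self.positions,
            sample_populations=self.sample_populations.astype("U"),
            length=self.length,
            scenario=p.scenario,
            s=p.s,
            T_mut=p.T_mut,
            T_sel=p.T_sel,
            pulse_index=-1 if p.pulse_index is None else p.pulse_index,
            final_freq=np.nan if p.final_freq is None else p.final_freq,
            selected_pos=-1 if self.selected_pos is None else self.selected_pos,
            seed=self.seed,
            model_name=self.model_name,
            Q=self.Q,
            panel_order=np.asarray(self.panel_order, dtype="U"),
        )

    @classmethod
    def load(cls, path) -> "SimulationResult":
        with np.load(path) as z:
            pulse = int(z["pulse_index"])
            freq = float(z["final_freq"])
            params = SelectionParams(
                scenario=str(z["scenario"]),
                s=float(z["s"]),
                T_mut=float(z["T_mut"]),
                T_sel=float(z["T_sel"]),
                pulse_index=None if pulse < 0 else pulse,
                final_freq=None if np.isnan(freq) else freq,
            )
            sel = int(z["selected_pos"])
            return cls(
                haplotypes=z["haplotypes"],
                positions=z["positions"],
                length=int(z["length"]),
                sample_populations=z["sample_populations"],
                params=params,
                selected_pos=None if sel < 0 else sel,
                seed=int(z["seed"]),
                model_name=str(z["model_name"]),
                Q=float(z["Q"]),
                panel_order=tuple(z["panel_order"]),
            )


def post_filter_af(results: list[SimulationResult], cutoff: float) -> list[SimulationResult]:
    """Drop sweep/AI results whose final beneficial allele frequency is
    below ``cutoff``; neutral and DFE results pass unchanged.  The
    filter is order-preserving and idempotent."""
    kept = []
    for r in results:
        if r.params.scenario in ("sweep", "ai"):
            if r.params.final_freq is None or r.params.final_freq < cutoff:
                continue
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# forward Wright-Fisher machinery
# ---------------------------------------------------------------------------


class _HaplotypePool:
    """Append-only store of distinct haplotypes over a growing site set.

    Rows are only created on recombination or mutation; identical
    gametes share a row id, which keeps per-generation cost low at the
    small crossover/mutation rates typical of a 100 kbp region.
    """

    def __init__(self, founders: np.ndarray, positions: np.ndarray, length: int):
        nrow, ncol = founders.shape
        self._data = np.zeros((max(2 * nrow, 64), max(2 * ncol, 64)), dtype=np.int8)
        self._data[:nrow, :ncol] = founders
        self.n_rows = nrow
        self.n_cols = ncol
        self.positions = list(positions)
        self._used = set(int(p) for p in positions)
        self.length = length
        self._pos_cache: np.ndarray | None = None

    def row(self, i: int) -> np.ndarray:
        return self._data[i, : self.n_cols]

    def column(self, j: int) -> np.ndarray:
        return self._data[: self.n_rows, j]

    def values(self, row_ids: np.ndarray, col: int) -> np.ndarray:
        return self._data[row_ids, col]

    def submatrix(self, row_ids: np.ndarray, cols) -> np.ndarray:
        return self._data[np.ix_(row_ids, cols)]

    def add_row(self, values: np.ndarray) -> int:
        if self.n_rows == self._data.shape[0]:
            self._data = np.concatenate([self._data, np.zeros_like(self._data)], axis=0)
        self._data[self.n_rows, : self.n_cols] = values
        self.n_rows += 1
        return self.n_rows - 1

    def add_site(self, position: int) -> int:
        if self.n_cols == self._data.shape[1]:
            self._data = np.concatenate([self._data, np.zeros_like(self._data)], axis=1)
        self.positions.append(position)
        self._used.add(position)
        self._pos_cache = None
        self.n_cols += 1
        return self.n_cols - 1

    @property
    def position_array(self) -> np.ndarray:
        if self._pos_cache is None:
            self._pos_cache = np.asarray(self.positions)
        return self._pos_cache

    def fresh_position(self, rng: np.random.Generator) -> int:
        while True:
            p = int(rng.integers(0, self.length))
            if p not in self._used:
                return p


@dataclass
class _ForwardSpec:
    """Everything the forward stage needs, fixed across restore attempts."""

    scenario: str
    founder_time: int
    sizes: np.ndarray  # diploid size at each generation 0..founder_time
    t_sel: float
    s_scaled: float
    mu_site: float  # scaled per-site per-generation rate
    map_len: float  # Morgans per meiosis (scaled)
    rec: object  # msprime.RateMap (scaled) or float rate
    length: int
    focal_col: int
    condition_freq: float
    dfe: DFEConfig | None = None


def _meiosis(pool, hap_a, hap_b, n_co, spec, rng):
    """Return the haplotype row values of one recombinant gamete."""
    a = pool.row(hap_a)
    if n_co == 0:
        return a.copy() if rng.integers(2) == 0 else pool.row(hap_b).copy()
    b = pool.row(hap_b)
    bp = np.sort(crossover_positions(spec.rec, spec.length, n_co, rng))
    pos = pool.position_array
    parity = np.searchsorted(bp, pos, side="right") % 2
    if rng.integers(2):
        parity = 1 - parity
    return np.where(parity == 0, a, b).astype(np.int8)


def _run_forward(founders, positions, spec: _ForwardSpec, rng):
    """One forward attempt.  Returns (pool, final_ids, final_freq, del_info)
    or None when the focal allele was lost / missed the condition."""
    pool = _HaplotypePool(founders, positions, spec.length)
    selection = spec.scenario in ("sweep", "ai")
    if spec.scenario == "sweep":
        # introduce the de novo mutation on a random founder haplotype
        carrier = int(rng.integers(founders.shape[0]))
        pool._data[carrier, spec.focal_col] = 1
    del_cols: list[int] = []
    del_s: list[float] = []
    del_h: list[float] = []

    ids = np.arange(founders.shape[0])
    for t in range(spec.founder_time, 0, -1):
        n_parents = len(ids) // 2
        n_child = int(spec.sizes[t - 1])
        # viability/fertility weights of the parent generation
        w = np.ones(n_parents)
        if selection and t <= spec.t_sel:
            g = pool.values(ids[0::2], spec.focal_col).astype(np.int64) + pool.values(
                ids[1::2], spec.focal_col
            )
            w = 1.0 + 0.5 * spec.s_scaled * g
        if spec.dfe is not None and del_cols:
            gd = pool.submatrix(ids[0::2], del_cols).astype(np.int16) + pool.submatrix(
                ids[1::2], del_cols
            )
            sarr = np.asarray(del_s)
            harr = np.asarray(del_h)
            logw = (gd == 1) @ np.log1p(harr * sarr) + (gd == 2) @ np.log1p(sarr)
            w = w * np.exp(logw)
        parents = rng.choice(n_parents, size=2 * n_child, p=w / w.sum())
        n_co = rng.poisson(spec.map_len, size=2 * n_child)
        n_mut = rng.poisson(spec.mu_site * spec.length, size=2 * n_child)

        child_ids = np.empty(2 * n_child, dtype=np.int64)
        plain = (n_co == 0) & (n_mut == 0)
        pick = rng.integers(2, size=2 * n_child)
        child_ids[plain] = ids[2 * parents[plain] + pick[plain]]
        for i in np.flatnonzero(~plain):
            j = parents[i]
            row = _meiosis(pool, ids[2 * j], ids[2 * j + 1], int(n_co[i]), spec, rng)
            for _ in range(int(n_mut[i])):
                p = pool.fresh_position(rng)
                col = pool.add_site(p)
                if col >= row.size:
                    row = np.concatenate([row, np.zeros(col + 1 - row.size, np.int8)])
                row[col] = 1
                if spec.dfe is not None:
                    s_m, h_m = draw_dfe_effects(spec.dfe, 1, rng)
                    if s_m[0] < 0:
                        del_cols.append(col)
                        del_s.append(float(s_m[0]))
                        del_h.append(float(h_m[0]))
            if row.size < pool.n_cols:
                row = np.concatenate([row, np.zeros(pool.n_cols - row.size, np.int8)])
            child_ids[i] = pool.add_row(row)
        ids = child_ids
        if selection:
            if pool.values(ids, spec.focal_col).sum() == 0:
                return None
    freq = float(pool.values(ids, spec.focal_col).mean()) if selection else 0.0
    if selection and freq < spec.condition_freq:
        return None
    return pool, ids, freq


# ---------------------------------------------------------------------------
# coalescent stage helpers
# ---------------------------------------------------------------------------


def _find_ai_branch(ts, mid, donor_id, founder_nodes, t_mut, rng):
    """Pick a branch of the midpoint tree carrying the AI mutation.

    Candidates are branches that (a) span the mutation time, and (b) lie
    on the donor-side ancestry of a census lineage that was in the donor
    population at the pulse and has introgressed recipient-founder
    descendants.  Returns the set of carrier sample nodes, or None.
    """
    tree = ts.at(mid)
    founder_set = set(int(n) for n in founder_nodes)
    node_pop = ts.tables.nodes.population
    node_flags = ts.tables.nodes.flags
    node_time = ts.tables.nodes.time
    candidates = []
    seen = set()
    for u in tree.nodes():
        if not node_flags[u] & msprime.NODE_IS_CEN_EVENT:
            continue
        if node_pop[u] != donor_id:
            continue
        if not any(s in founder_set for s in tree.samples(u)):
            continue
        v = u
        while True:
            p = tree.parent(v)
            if p == tskit.NULL:
                break
            if node_time[v] < t_mut <= node_time[p]:
                if v not in seen:
                    seen.add(v)
                    candidates.append(v)
                break
            if node_time[v] >= t_mut:
                break
            v = p
    if not candidates:
        return None
    v = candidates[int(rng.integers(len(candidates)))]
    return set(int(s) for s in tree.samples(v))


def _build_sample_sets(model, forward: bool, founder_n: int, founder_time: int):
    """Panel sample sets in panel order (recipient's present-day panel is
    replaced by a whole-population founder draw when a forward stage is
    used).  Returns (sample_sets, row_slices, n_panel_haps)."""
    sets, labels = [], []
    for pop in model.panel_order:
        for n, t in model.samples.get(pop, ()):
            if forward and pop == model.recipient:
                continue
            sets.append(msprime.SampleSet(n, population=pop, time=t, ploidy=2))
            labels.extend([pop] * (2 * n))
    n_panel = len(labels)
    if forward:
        sets.append(
            msprime.SampleSet(
                founder_n, population=model.recipient, time=founder_time, ploidy=2
            )
        )
    return sets, np.asarray(labels), n_panel


def simulate_region(
    model: DemographicModel,
    params: SelectionParams,
    *,
    Q: float = 10.0,
    length: int = 100_000,
    mu: float | None = None,
    rec=None,
    seed: int | None = None,
    max_attempts: int = 200,
    condition_freq: float = 0.01,
    dfe: DFEConfig | None = None,
) -> SimulationResult:
    """Simulate one region under the given scenario parameters.

    Parameters
    ----------
    model : DemographicModel
        Unscaled demographic model (times in generations, diploid N).
    params : SelectionParams
        Scenario and selection parameters at the unscaled scale.
    Q : float
        Scaling factor; N and T are divided by Q, mu/r/s multiplied.
    rec : float or msprime.RateMap, optional
        Unscaled recombination rate or genetic map for the region.
    max_attempts : int
        Cap on checkpoint restores plus genealogy redraws before a
        :class:`SimulationError` is raised.
    condition_freq : float
        In-simulation rejection condition on the beneficial allele's
        final frequency in the recipient (higher thresholds should be
        applied afterwards with :func:`post_filter_af`).

    Returns
    -------
    SimulationResult
    """
    if params.scenario == "dfe" and dfe is None:
        dfe = DFEConfig()
    rng = np.random.default_rng(seed)
    seed = int(seed) if seed is not None else int(rng.integers(2**31))
    mu = model.mutation_rate if mu is None else mu
    rec = model.recombination_rate if rec is None else rec
    scaled = model.scale(Q)
    mu_s = mu * Q
    rec_s = scale_rate_map(rec, Q) if isinstance(rec, msprime.RateMap) else rec * Q
    mid = length // 2
    forward = params.scenario in ("sweep", "ai", "dfe")

    # ---- forward start time (scaled generations) ----
    founder_time = 0
    if forward:
        if params.scenario == "sweep":
            split_s = scaled.split_time(scaled.recipient)
            founder_time = min(int(round(params.T_mut / Q)), int(np.ceil(split_s)) - 1)
        else:
            idx = params.pulse_index if params.pulse_index is not None else model.ai_pulse_indices[0]
            pulse_t = scaled.pulses[idx].time
            founder_time = int(np.floor(pulse_t))
            if founder_time >= pulse_t:
                founder_time -= 1
        founder_time = max(founder_time, 1)

    donor_pulse_t = None
    if params.scenario == "ai":
        donor_pulse_t = scaled.pulses[params.pulse_index].time

    founder_n = int(scaled.population(scaled.recipient).size_at(founder_time)) if forward else 0
    sample_sets, panel_labels, n_panel = _build_sample_sets(
        scaled, forward, founder_n, founder_time
    )
    census = [donor_pulse_t + 0.25] if params.scenario == "ai" else []
    dem, _ = scaled.to_msprime(census_times=census)
    donor_id = [p.name for p in scaled.populations].index(scaled.donor)
    ancestry_model = (
        [
            msprime.DiscreteTimeWrightFisher(duration=founder_time + 25),
            msprime.StandardCoalescent(),
        ]
        if forward
        else msprime.StandardCoalescent()
    )

    attempts = 0
    while True:
        if attempts > max_attempts:
            raise SimulationError(
                f"{params.scenario} simulation failed after {max_attempts} attempts "
                f"(s={params.s:.4g}, T_sel={params.T_sel:.4g}); parameter draw may be "
                "near-impossible"
            )
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=length,
            recombination_rate=rec_s,
            discrete_genome=True,
            model=ancestry_model,
            random_seed=int(rng.integers(1, 2**31)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mu_s,
            model=msprime.BinaryMutationModel(),
            discrete_genome=True,
            random_seed=int(rng.integers(1, 2**31)),
        )
        G = mts.genotype_matrix().T.astype(np.int8)  # (sample nodes, sites)
        positions = mts.tables.sites.position.astype(np.int64)

        focal = np.zeros(G.shape[0], dtype=np.int8)
        if params.scenario in ("sweep", "ai"):
            keep = positions != mid  # focal site gets its own column
            G, positions = G[:, keep], positions[keep]
        if params.scenario == "ai":
            carriers = _find_ai_branch(
                mts, mid, donor_id, np.arange(n_panel, G.shape[0]), params.T_mut / Q, rng
            )
            if carriers is None or not any(c >= n_panel for c in carriers):
                attempts += 1
                continue  # no introgressed donor lineage at the midpoint: redraw genealogy
            focal[list(carriers)] = 1

        if not forward:
            hap = G
            labels = panel_labels
            result_params = params
            break

        # ---- forward stage with checkpoint/restore ----
        founders = np.concatenate(
            [G[n_panel:], focal[n_panel:, None]], axis=1, dtype=np.int8
        )
        fpos = np.concatenate([positions, [mid]])
        sizes = np.array(
            [
                scaled.population(scaled.recipient).size_at(t)
                for t in range(founder_time + 1)
            ]
        )
        spec = _ForwardSpec(
            scenario=params.scenario,
            founder_time=founder_time,
            sizes=sizes,
            t_sel=params.T_sel / Q,
            s_scaled=params.s * Q,
            mu_site=mu_s,
            map_len=total_map_length(rec_s, length),
            rec=rec_s,
            length=length,
            focal_col=G.shape[1],
            condition_freq=condition_freq,
            dfe=dfe if params.scenario == "dfe" else None,
        )
        out = None
        while out is None and attempts <= max_attempts:
            out = _run_forward(founders, fpos, spec, rng)
            if out is None:
                attempts += 1  # restore to the pre-mutation / post-pulse checkpoint
        if out is None:
            continue
        pool, final_ids, final_freq = out

        # draw the recipient panel from the final full population
        n_rec = sum(n for n, _ in model.samples[model.recipient])
        chosen = rng.permutation(len(final_ids) // 2)[:n_rec]
        rec_rows = np.empty(2 * n_rec, dtype=np.int64)
        rec_rows[0::2] = final_ids[2 * chosen]
        rec_rows[1::2] = final_ids[2 * chosen + 1]
        rec_hap = pool.submatrix(rec_rows, np.arange(pool.n_cols))

        n_fwd = pool.n_cols - founders.shape[1]
        panel_hap = np.concatenate(
            [
                G[:n_panel],
                focal[:n_panel, None],
                np.zeros((n_panel, n_fwd), dtype=np.int8),
            ],
            axis=1,
        )
        # stitch panels and recipient rows back into panel order
        rows, labels = [], []
        for pop in model.panel_order:
            if pop == model.recipient:
                rows.append(rec_hap)
                labels.extend([pop] * rec_hap.shape[0])
            else:
                sel = panel_labels == pop
                rows.append(panel_hap[sel])
                labels.extend([pop] * int(sel.sum()))
        hap = np.concatenate(rows, axis=0)
        labels = np.asarray(labels)
        positions = np.asarray(pool.positions, dtype=np.int64)
        result_params = (
            params.with_final_freq(final_freq)
            if params.scenario in ("sweep", "ai")
            else params
        )
        break

    order = np.argsort(positions, kind="stable")
    hap, positions = hap[:, order], positions[order]
    seg = (hap.sum(axis=0) > 0) & (hap.sum(axis=0) < hap.shape[0])
    hap, positions = hap[:, seg], positions[seg]
    return SimulationResult(
        haplotypes=np.ascontiguousarray(hap),
        positions=positions,
        length=length,
        sample_populations=labels,
        params=result_params,
        selected_pos=mid if params.scenario in ("sweep", "ai") else None,
        seed=seed,
        model_name=model.name,
        Q=Q,
        panel_order=model.panel_order,
    )


def simulate_scenario(
    model: DemographicModel,
    scenario: str,
    n_reps: int,
    *,
    Q: float = 10.0,
    length: int = 100_000,
    seed: int = 1,
    s_range: tuple[float, float] | None = None,
    rec=None,
    max_attempts: int = 200,
    condition_freq: float = 0.01,
) -> list[SimulationResult]:
    """Simulate ``n_reps`` regions of one scenario, drawing selection
    parameters per replicate.  Each replicate gets an independent seed
    derived from ``seed``; failed parameter draws are redrawn."""
    ss = np.random.SeedSequence(seed)
    out = []
    child_iter = iter(ss.spawn(4 * n_reps + 16))
    while len(out) < n_reps:
        child = next(child_iter, None)
        if child is None:
            raise SimulationError(f"too many failed draws for scenario {scenario}")
        rng = np.random.default_rng(child)
        rep_seed = int(rng.integers(2**31))
        if scenario in ("sweep", "ai"):
            params = draw_selection_params(scenario, model, s_range, rng)
        else:
            params = SelectionParams(scenario)
        try:
            res = simulate_region(
                model,
                params,
                Q=Q,
                length=length,
                rec=rec,
                seed=rep_seed,
                max_attempts=max_attempts,
                condition_freq=condition_freq,
            )
        except SimulationError:
            continue  # near-impossible draw: redraw parameters
        out.append(res)
    return out
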