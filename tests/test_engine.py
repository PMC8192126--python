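import textwrap

import msprime
import numpy as np
import pytest

from introscan.simulate import (
    SelectionParams,
    SimulationError,
    SimulationResult,
    get_model,
    post_filter_af,
    read_hapmap,
    sample_map_chunk,
    simulate_region,
    simulate_scenario,
)
from introscan.simulate.demography import DemographicModel, Population


def _result_invariants(r: SimulationResult):
    assert np.all(np.diff(r.positions) > 0)
    assert r.positions.min() >= 0 and r.positions.max() < r.length
    assert r.haplotypes.shape == (len(r.sample_populations), len(r.positions))
    assert set(np.unique(r.haplotypes)) <= {0, 1}
    # every sample belongs to exactly one declared panel
    assert set(r.sample_populations) <= set(r.panel_order)


def test_neutral_no_selected_site(small_fixtures):
    for r in small_fixtures["neutral"]:
        assert r.selected_pos is None
        assert r.params.scenario == "neutral"
        _result_invariants(r)


def test_ai_beneficial_allele_in_recipient(small_fixtures):
    for r in small_fixtures["ai"]:
        _result_invariants(r)
        assert r.params.final_freq >= 0.01  # in-simulation rejection condition
        rec = r.haplotypes[r.sample_populations == "CEU"]
        if r.selected_pos in r.positions:
            col = np.searchsorted(r.positions, r.selected_pos)
            # rejection sampling: allele segregates in the recipient population
            # (the sampled panel usually carries it when final_freq is high)
            if r.params.final_freq > 0.5:
                assert rec[:, col].sum() > 0


def test_sweep_confined_to_recipient(small_fixtures):
    for r in small_fixtures["sweep"]:
        _result_invariants(r)
        if r.selected_pos in r.positions:
            col = np.searchsorted(r.positions, r.selected_pos)
            outside = r.haplotypes[r.sample_populations != "CEU"]
            assert outside[:, col].sum() == 0  # de novo in the recipient only


def test_scenario_label_consistency(small_fixtures):
    for scen, results in small_fixtures.items():
        for r in results:
            assert r.params.scenario == scen


class TestPostFilter:
    def _fake(self, scenario, freq):
        params = SelectionParams(scenario, s=0.01, T_mut=300, T_sel=200)
        if scenario in ("sweep", "ai"):
            params = params.with_final_freq(freq)
        return SimulationResult(
            haplotypes=np.zeros((2, 0), dtype=np.int8),
            positions=np.empty(0, dtype=np.int64),
            length=1000,
            sample_populations=np.asarray(["p", "p"]),
            params=params,
            selected_pos=None,
            seed=0,
            model_name="toy",
            Q=1,
            panel_order=("p",),
        )

    def test_retained_and_removed(self):
        hi = self._fake("ai", 0.30)
        lo = self._fake("ai", 0.10)
        out = post_filter_af([hi, lo], 0.25)
        assert out == [hi]

    def test_neutral_passes(self):
        n = self._fake("neutral", None)
        assert post_filter_af([n], 0.9) == [n]

    def test_zero_cutoff_identity(self):
        items = [self._fake("ai", f) for f in (0.01, 0.5, 1.0)]
        assert post_filter_af(items, 0.0) == items

    def test_idempotent_order_preserving(self):
        items = [self._fake("ai", f) for f in (0.9, 0.1, 0.6, 0.3)]
        once = post_filter_af(items, 0.25)
        assert post_filter_af(once, 0.25) == once
        freqs = [r.params.final_freq for r in once]
        assert freqs == [0.9, 0.6, 0.3]


def test_attempt_cap_raises():
    model = get_model("A1")
    params = SelectionParams("sweep", s=1e-4, T_mut=120, T_sel=110)
    with pytest.raises(SimulationError, match="attempts"):
        # weak selection + demand near-fixation: effectively impossible
        simulate_region(
            model, params, Q=20, seed=9, max_attempts=3, condition_freq=0.999
        )


def test_reproducible_per_seed():
    model = get_model("A1")
    params = SelectionParams("ai", s=0.05, T_mut=2500, T_sel=1000, pulse_index=0)
    a = simulate_region(model, params, Q=30, seed=42)
    b = simulate_region(model, params, Q=30, seed=42)
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    np.testing.assert_array_equal(a.positions, b.positions)
    assert a.params.final_freq == b.params.final_freq


def test_dfe_scenario_runs():
    model = get_model("A1")
    r = simulate_region(model, SelectionParams("dfe"), Q=50, seed=11)
    _result_invariants(r)
    assert r.selected_pos is None


def test_neutral_diversity_matches_coalescent():
    # single-population collapse: E[pi] per site = 4*N*mu
    N, mu, L = 5000, 1.29e-8, 50_000
    model = DemographicModel(
        name="one",
        populations=(Population("p", ((0, N),)),),
        splits=(),
        pulses=(),
        samples={"p": ((8, 0),)},
        donor="p",
        recipient="p",
        outgroup="p",
        ai_pulse_indices=(),
        mutation_rate=mu,
    )
    pis = []
    for seed in range(80):
        r = simulate_region(
            model, SelectionParams("neutral"), Q=5, length=L, seed=1000 + seed
        )
        hap = r.haplotypes
        n = hap.shape[0]
        freq = hap.mean(axis=0)
        pi = np.sum(2 * freq * (1 - freq) * n / (n - 1)) / L
        pis.append(pi)
    expected = 4 * N * mu
    assert np.mean(pis) == pytest.approx(expected, rel=0.15)


def test_save_load_roundtrip(tmp_path, small_fixtures):
    r = small_fixtures["ai"][0]
    path = tmp_path / "sim.npz"
    r.save(path)
    r2 = SimulationResult.load(path)
    np.testing.assert_array_equal(r.haplotypes, r2.haplotypes)
    np.testing.assert_array_equal(r.positions, r2.positions)
    assert r2.params == r.params
    assert r2.panel_order == r.panel_order
    assert r2.selected_pos == r.selected_pos


HAPMAP_TEXT = textwrap.dedent(
    """\
    Chromosome Position(bp) Rate(cM/Mb) Map(cM)
    chr1 0 0.5 0.0
    chr1 100000 2.0 0.05
    chr1 300000 0.1 0.45
    chr1 500000 0 0.47
    """
)


def test_hapmap_read_and_chunk(tmp_path):
    path = tmp_path / "map.txt"
    path.write_text(HAPMAP_TEXT)
    rate_map = read_hapmap(path)
    assert rate_map.sequence_length == 500_000
    rng = np.random.default_rng(0)
    chunk = sample_map_chunk(rate_map, 100_000, rng)
    assert chunk.sequence_length == 100_000
    assert np.all(np.asarray(chunk.rate) >= 0)
    r = simulate_region(
        get_model("A1"), SelectionParams("neutral"), Q=50, seed=3, rec=chunk
    )
    _result_invariants(r)


def test_simulate_scenario_batch_sizes():
    model = get_model("A1")
    out = simulate_scenario(model, "neutral", 5, Q=50, seed=77)
    assert len(out) == 5
    assert len({r.seed for r in out}) == 5  # independent per-replicate seeds
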