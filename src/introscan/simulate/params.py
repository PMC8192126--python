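"""Selection-parameter draws for sweep/AI scenarios and the DFE mode."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from introscan.simulate.demography import DemographicModel

SCENARIOS = ("neutral", "sweep", "ai", "dfe")


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the selected mutation for one simulated region.

    Times are in generations before present, at the unscaled (Q=1)
    scale of the demographic model.  ``final_freq`` is filled in by the
    simulator with the beneficial allele's frequency in the full
    recipient population at the end of the simulation.
    """

    scenario: str
    s: float = 0.0
    T_mut: float = 0.0
    T_sel: float = 0.0
    pulse_index: int | None = None
    final_freq: float | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario in ("sweep", "ai"):
            if self.s <= 0:
                raise ValueError("sweep/AI require s > 0")
            if self.T_sel > self.T_mut:
                raise ValueError("selection onset must not precede the mutation")

    def with_final_freq(self, freq: float) -> "SelectionParams":
        return replace(self, final_freq=freq)


def draw_selection_params(
    scenario: str,
    model: DemographicModel,
    s_range: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionParams:
    """Draw (s, T_mut, T_sel) for a sweep or AI simulation.

    The selection coefficient is log-uniform on ``s_range``.  Mutation
    and selection-onset times are uniform, with ordering enforced by
    rejection:

    * sweep: both times older than 1 kya and younger than the
      recipient/outgroup split, with T_sel <= T_mut;
    * AI: T_mut in the donor, older than 1 kya before the admixture
      pulse and younger than the donor's ancestral split; T_sel in the
      recipient, after the pulse and older than 1 kya.  For models with
      several AI pulses the pulse is chosen uniformly, so that about
      half of the draws use each pulse.
    """
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = s_range if s_range is not None else model.s_range
    if not (0 < lo <= hi <= 0.1):
        raise ValueError("s_range must satisfy 0 < lo <= hi <= 0.1")
    s = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    kya = model.kya_generations(1.0)

    if scenario == "sweep":
        t_max = model.split_time(model.recipient)
        while True:
            t_mut = rng.uniform(kya, t_max)
            t_sel = rng.uniform(kya, t_max)
            if t_sel <= t_mut:
                break
        return SelectionParams("sweep", s=s, T_mut=float(t_mut), T_sel=float(t_sel))

    if scenario == "ai":
        idx = int(rng.choice(model.ai_pulse_indices))
        pulse = model.pulses[idx]
        t_donor_split = model.split_time(model.donor)
        t_mut = rng.uniform(pulse.time + kya, t_donor_split)
        t_sel = rng.uniform(kya, pulse.time)
        return SelectionParams(
            "ai", s=s, T_mut=float(t_mut), T_sel=float(t_sel), pulse_index=idx
        )

    raise ValueError(f"draw_selection_params: scenario must be sweep or ai, got {scenario!r}")


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects for background mutations.

    A fraction ``p_neutral`` of new mutations is neutral; the rest draw
    a negative selection coefficient from a reflected gamma with the
    given shape and expected value.  All deleterious mutations share a
    fixed dominance coefficient h = 0.5 / (1 - 7071.07 * E[s]), which
    makes them effectively recessive.
    """

    p_neutral: float = 0.3
    p_deleterious: float = 0.7
    gamma_shape: float = 0.186
    gamma_mean: float = -0.01314833

    def __post_init__(self):
        if abs(self.p_neutral + self.p_deleterious - 1.0) > 1e-12:
            raise ValueError("mutation-class proportions must sum to 1")
        if self.gamma_mean >= 0:
            raise ValueError("gamma expected value must be negative (deleterious)")

    @property
    def dominance(self) -> float:
        return 0.5 / (1.0 - 7071.07 * self.gamma_mean)


def draw_dfe_mutation(
    cfg: DFEConfig, rng: np.random.Generator
) -> tuple[str, float, float]:
    """Draw one background mutation: ``(class, s, h)``.

    Neutral with probability ``p_neutral`` (s=0, h=0.5); otherwise s<0
    from the reflected gamma and the fixed dominance coefficient.
    """
    if rng.uniform() < cfg.p_neutral:
        return "neutral", 0.0, 0.5
    scale = -cfg.gamma_mean / cfg.gamma_shape
    s = -float(rng.gamma(cfg.gamma_shape, scale))
    s = max(s, -0.99)  # fitness must stay positive
    return "deleterious", s, cfg.dominance


def draw_dfe_effects(
    cfg: DFEConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised version of :func:`draw_dfe_mutation` for ``n`` mutations.

    Returns ``(s, h)`` arrays; neutral mutations have s=0, h=0.5.
    """
    s = np.zeros(n)
    h = np.full(n, 0.5)
    deleterious = rng.uniform(size=n) >= cfg.p_neutral
    k = int(deleterious.sum())
    if k:
        scale = -cfg.gamma_mean / cfg.gamma_shape
        s[deleterious] = np.maximum(-rng.gamma(cfg.gamma_shape, scale, size=k), -0.99)
        h[deleterious] = cfg.dominance
    return s, h
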