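"""Demographic models: populations, splits, admixture pulses and scaling.

Models are specified forwards-in-time (sizes per epoch, split times,
pulses) and converted to :class:`msprime.Demography` on demand.  All
times are in generations before present; sizes are diploid.  Three
named presets are provided:

``A1``
    Three-population out-of-Africa model with a single pulse of
    Neanderthal gene flow into Europeans.
``A2``
    Variant of ``A1`` with an additional archaic pulse into the
    African population (used for misspecification experiments).
``B``
    Four-population model with two pulses of Denisovan gene flow into
    Melanesians plus Neanderthal gene flow.

Every numeric parameter lives in the preset functions below and can be
edited or overridden by constructing a :class:`DemographicModel`
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime


@dataclass(frozen=True)
class Population:
    """A population with a piecewise-constant size history.

    ``epochs`` is a list of ``(time, diploid_size)`` pairs, sorted by
    ascending time, with the first entry at time 0.  The size at query
    time ``t`` is that of the most recent epoch whose start is ``<= t``.
    """

    name: str
    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.epochs or self.epochs[0][0] != 0:
            raise ValueError(f"population {self.name}: first epoch must start at time 0")
        times = [t for t, _ in self.epochs]
        if times != sorted(times):
            raise ValueError(f"population {self.name}: epochs must be time-sorted")
        if any(n < 2 for _, n in self.epochs):
            raise ValueError(f"population {self.name}: diploid size below 2")

    def size_at(self, time: float) -> float:
        size = self.epochs[0][1]
        for t, n in self.epochs:
            if t <= time:
                size = n
            else:
                break
        return size


@dataclass(frozen=True)
class Pulse:
    """A single admixture pulse (forwards in time): at ``time``, a
    fraction ``proportion`` of ``dest`` is replaced by migrants from
    ``source``."""

    time: float
    source: str
    dest: str
    proportion: float


@dataclass(frozen=True)
class ScalingFactor:
    """Simulation rescaling factor Q.

    Dividing N and T by Q while multiplying mu, r and s by Q leaves
    theta = 4*N*mu, rho = 4*N*r and N*s invariant (up to rounding).
    """

    Q: float = 10.0

    def __post_init__(self):
        if self.Q < 1:
            raise ValueError("scaling factor Q must be >= 1")


@dataclass(frozen=True)
class DemographicModel:
    """A forwards-time demographic model plus panel roles and defaults.

    Attributes
    ----------
    populations : tuple of Population
    splits : tuple of (time, derived, ancestral)
        At ``time`` (backwards) the ``derived`` population merges into
        ``ancestral``, which persists.
    pulses : tuple of Pulse
    samples : dict
        Maps population name to a tuple of ``(n_individuals, time)``
        sampling events.
    donor, recipient, outgroup : str
        Panel roles used by the encoder and the AI scenario.
    extra_archaics : tuple of str
        Non-donor archaic panels (placed left of the donor block).
    ai_pulse_indices : tuple of int
        Indices into ``pulses`` eligible to carry the AI haplotype.
    generation_time : float
        Years per generation (used only to convert "1 kya" bounds).
    mutation_rate, recombination_rate : float
        Per-site per-generation defaults at unscaled (Q=1) scale.
    s_range : tuple of float
        Default log-uniform range for selection coefficients.
    """

    name: str
    populations: tuple[Population, ...]
    splits: tuple[tuple[float, str, str], ...]
    pulses: tuple[Pulse, ...]
    samples: dict[str, tuple[tuple[int, float], ...]]
    donor: str
    recipient: str
    outgroup: str
    ai_pulse_indices: tuple[int, ...]
    extra_archaics: tuple[str, ...] = ()
    generation_time: float = 29.0
    mutation_rate: float = 1.29e-8
    recombination_rate: float = 1e-8
    s_range: tuple[float, float] = (1e-4, 0.1)

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for t, derived, anc in self.splits:
            if t <= 0:
                raise ValueError("split times must be strictly positive")
            if derived not in names or anc not in names:
                raise ValueError(f"split references unknown population: {derived}/{anc}")
        for pulse in self.pulses:
            if pulse.time <= 0:
                raise ValueError("pulse times must be strictly positive")
            if not 0 < pulse.proportion < 1:
                raise ValueError("pulse proportion must be in (0, 1)")
            # a pulse is only meaningful while both populations exist
            for pop in (pulse.source, pulse.dest):
                t_split = self.split_time(pop)
                if t_split is not None and pulse.time >= t_split:
                    raise ValueError(
                        f"pulse at {pulse.time} is older than the split of {pop}"
                    )
        for role in (self.donor, self.recipient, self.outgroup):
            events = self.samples.get(role, ())
            if sum(n for n, _ in events) < 1:
                raise ValueError(f"at least one sample required for {role}")

    # -- queries ---------------------------------------------------------

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def split_time(self, name: str) -> float | None:
        """Time at which ``name`` merges into its ancestor (None for the root)."""
        for t, derived, _ in self.splits:
            if derived == name:
                return t
        return None

    @property
    def panel_order(self) -> tuple[str, ...]:
        """Population block order used by the encoder: non-donor archaic
        panels, then donor, recipient, unadmixed outgroup."""
        return (*self.extra_archaics, self.donor, self.recipient, self.outgroup)

    def n_haplotypes(self, pop: str) -> int:
        return 2 * sum(n for n, _ in self.samples.get(pop, ()))

    def kya_generations(self, kya: float = 1.0) -> float:
        return 1000.0 * kya / self.generation_time

    # -- transforms ------------------------------------------------------

    def scale(self, Q: float) -> "DemographicModel":
        """Return a copy with N <- N/Q (rounded) and T <- T/Q."""
        if Q < 1:
            raise ValueError("Q must be >= 1")
        pops = []
        for p in self.populations:
            epochs = []
            for t, n in p.epochs:
                n_scaled = round(n / Q)
                if n_scaled < 2:
                    raise ValueError(
                        f"Q={Q} drives population {p.name} below 2 diploids"
                    )
                epochs.append((t / Q, n_scaled))
            pops.append(Population(p.name, tuple(epochs)))
        splits = tuple((t / Q, d, a) for t, d, a in self.splits)
        pulses = tuple(replace(pu, time=pu.time / Q) for pu in self.pulses)
        samples = {
            k: tuple((n, t / Q) for n, t in v) for k, v in self.samples.items()
        }
        return replace(
            self,
            populations=tuple(pops),
            splits=splits,
            pulses=pulses,
            samples=samples,
        )

    def with_samples(self, **counts: int) -> "DemographicModel":
        """Return a copy with present-day sample counts replaced.

        Sampling times of ancient panels are preserved; only the
        individual counts change for the named populations.
        """
        samples = dict(self.samples)
        for pop, n in counts.items():
            events = samples[pop]
            if len(events) == 1:
                samples[pop] = ((n, events[0][1]),)
            else:
                raise ValueError(f"{pop} has multiple sampling events; edit directly")
        return replace(self, samples=samples)

    def to_msprime(
        self,
        extra_sample_sets: list[msprime.SampleSet] | None = None,
        census_times: list[float] = (),
    ) -> tuple[msprime.Demography, list[msprime.SampleSet]]:
        """Build an msprime Demography plus the default panel sample sets.

        Panel sample sets are returned in :attr:`panel_order`; any
        ``extra_sample_sets`` (e.g. whole-population founder draws) are
        appended after them, so sample node order is predictable.
        """
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(name=p.name, initial_size=p.epochs[0][1])
            for t, n in p.epochs[1:]:
                dem.add_population_parameters_change(
                    time=t, population=p.name, initial_size=n
                )
        for pulse in self.pulses:
            # backwards in time: lineages in dest move to source
            dem.add_mass_migration(
                time=pulse.time,
                source=pulse.dest,
                dest=pulse.source,
                proportion=pulse.proportion,
            )
        for t, derived, anc in self.splits:
            dem.add_mass_migration(time=t, source=derived, dest=anc, proportion=1.0)
        for t in census_times:
            dem.add_census(time=t)
        dem.sort_events()

        sample_sets = []
        for pop in self.panel_order:
            for n, t in self.samples.get(pop, ()):
                sample_sets.append(
                    msprime.SampleSet(n, population=pop, time=t, ploidy=2)
                )
        if extra_sample_sets:
            sample_sets.extend(extra_sample_sets)
        return dem, sample_sets


def scale_model(
    model: DemographicModel,
    rates: dict[str, float] | None = None,
    s: float | None = None,
    Q: ScalingFactor | float = ScalingFactor(),
) -> tuple[DemographicModel, dict[str, float], float | None]:
    """Apply scaling factor Q to a model, its rates and a selection coefficient.

    Returns ``(scaled_model, scaled_rates, scaled_s)`` with N <- N/Q,
    T <- T/Q, mu <- mu*Q, r <- r*Q and s <- s*Q, preserving theta, rho
    and N*s up to the rounding of population sizes.

    Raises
    ------
    ValueError
        If Q < 1 or Q drives any population below 2 diploids.
    """
    q = Q.Q if isinstance(Q, ScalingFactor) else float(Q)
    if rates is None:
        rates = {"mu": model.mutation_rate, "r": model.recombination_rate}
    scaled = model.scale(q)
    scaled_rates = {k: v * q for k, v in rates.items()}
    scaled_s = None if s is None else s * q
    return scaled, scaled_rates, scaled_s


# ---------------------------------------------------------------------------
# Named presets.  Parameter values are a composite of published estimates
# for human/archaic demography; generation time 29 y.  Desk-scale presets
# use small present-day panels; "paper"-scale presets match the panel
# sizes of the empirical datasets the models are meant to mimic.
# ---------------------------------------------------------------------------

_GEN = 29.0


def _years(y: float) -> float:
    return y / _GEN


def model_A1(desk: bool = True) -> DemographicModel:
    """Out-of-Africa + single Neanderthal pulse into Europeans."""
    n_ceu, n_yri = (16, 16) if desk else (99, 108)
    return DemographicModel(
        name="A1",
        populations=(
            # African lineage carries the ancestral human and root sizes
            Population("YRI", ((0, 27600), (_years(550e3), 18500))),
            Population("CEU", ((0, 8500), (_years(30e3), 1861))),
            Population("Nea", ((0, 3400),)),
        ),
        splits=(
            (_years(65.7e3), "CEU", "YRI"),
            (_years(550e3), "Nea", "YRI"),
        ),
        pulses=(Pulse(time=_years(55e3), source="Nea", dest="CEU", proportion=0.0225),),
        samples={
            # two Neanderthals sampled at their estimated ages (~110 kya, ~50 kya)
            "Nea": ((1, _years(110e3)), (1, _years(50e3))),
            "CEU": ((n_ceu, 0),),
            "YRI": ((n_yri, 0),),
        },
        donor="Nea",
        recipient="CEU",
        outgroup="YRI",
        ai_pulse_indices=(0,),
        s_range=(1e-4, 0.1),
    )


def model_A2(desk: bool = True) -> DemographicModel:
    """A1 plus archaic admixture into the African population."""
    a1 = model_A1(desk=desk)
    pulses = a1.pulses + (
        Pulse(time=_years(100e3), source="Nea", dest="YRI", proportion=0.01),
    )
    return replace(a1, name="A2", pulses=pulses)


def model_B(desk: bool = True) -> DemographicModel:
    """Two-pulse Denisovan gene flow into Melanesians, plus a Neanderthal pulse."""
    n_mel, n_yri = (16, 16) if desk else (139, 108)
    return DemographicModel(
        name="B",
        populations=(
            Population("YRI", ((0, 48433), (_years(522e3), 32670))),
            Population("Mel", ((0, 8834),)),
            # Neanderthal lineage carries the Nea/Den ancestor size
            Population("Nea", ((0, 826), (_years(435e3), 13249))),
            Population("Den", ((0, 5083),)),
        ),
        splits=(
            (_years(64.3e3), "Mel", "YRI"),
            (_years(435e3), "Den", "Nea"),
            (_years(522e3), "Nea", "YRI"),
        ),
        pulses=(
            # index 0: older Denisovan pulse; index 1: younger pulse
            Pulse(time=_years(45.7e3), source="Den", dest="Mel", proportion=0.022),
            Pulse(time=_years(29.8e3), source="Den", dest="Mel", proportion=0.018),
            Pulse(time=_years(53.7e3), source="Nea", dest="Mel", proportion=0.025),
        ),
        samples={
            "Nea": ((1, _years(110e3)),),
            "Den": ((1, _years(72e3)),),
            "Mel": ((n_mel, 0),),
            "YRI": ((n_yri, 0),),
        },
        donor="Den",
        recipient="Mel",
        outgroup="YRI",
        ai_pulse_indices=(0, 1),
        extra_archaics=("Nea",),
        s_range=(1e-3, 0.1),
    )


_PRESETS = {"A1": model_A1, "A2": model_A2, "B": model_B}


def get_model(name: str, desk: bool = True) -> DemographicModel:
    """Look up a demographic model preset by name ("A1", "A2" or "B")."""
    try:
        return _PRESETS[name](desk=desk)
    except KeyError:
        raise KeyError(f"unknown model preset {name!r}; choose from {sorted(_PRESETS)}")
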