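"""Run configuration (TOML) and miniature fixture generation."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from introscan.simulate import SimulationResult, get_model, simulate_scenario


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Only ``model`` is required; everything else has the documented
    defaults.  ``panels`` maps population names to sample-name lists
    for empirical scans.
    """

    model: str
    Q: float = 10.0
    length: int = 100_000
    seed: int = 1
    m: int = 256
    k: int = 7
    phased: bool = True
    maf: float = 0.05
    af_cutoff: float = 0.25
    s_lo: float | None = None
    s_hi: float | None = None
    epochs: int = 3
    batch_size: int = 64
    split_fraction: float = 0.9
    calibration_method: str = "beta"
    ratios: str = "1:0.1:0.02"
    panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        from introscan.calibrate import ClassRatios

        get_model(self.model)  # must name a known preset
        ClassRatios.parse(self.ratios)  # must parse
        if self.calibration_method not in ("beta", "isotonic", "platt"):
            raise ValueError(f"unknown calibration method {self.calibration_method!r}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        stages = ("simulate", "encode", "split", "train", "calibrate", "scan")
        if stage not in stages:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(stages.index(stage),))
        return int(ss.generate_state(1)[0])


_SECTIONS = {
    "run": ("model", "Q", "length", "seed"),
    "encode": ("m", "phased", "maf", "af_cutoff"),
    "train": ("k", "epochs", "batch_size", "split_fraction", "s_lo", "s_hi"),
    "calibrate": ("calibration_method", "ratios"),
    "panels": None,  # free-form population -> sample list
}


def load_config(path) -> RunConfig:
    """Read and validate a TOML run configuration.

    Unknown sections or keys are rejected; a missing required key
    raises an error naming it.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs = {}
    for section, content in data.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        if section == "panels":
            if not all(isinstance(v, list) for v in content.values()):
                raise ValueError("[panels] entries must be sample-name lists")
            kwargs["panels"] = {k: [str(s) for s in v] for k, v in content.items()}
            continue
        allowed = _SECTIONS[section]
        for key, value in content.items():
            if key not in allowed:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            kwargs[key] = value
    if "model" not in kwargs:
        raise ValueError("missing required key 'model' in section [run]")
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    """Write a config back to TOML (inverse of :func:`load_config`)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        return repr(v)

    lines = []
    for section, keys in _SECTIONS.items():
        if section == "panels":
            if cfg.panels:
                lines.append("[panels]")
                for pop, names in cfg.panels.items():
                    inner = ", ".join(f'"{n}"' for n in names)
                    lines.append(f"{pop} = [{inner}]")
                lines.append("")
            continue
        body = []
        for key in keys:
            value = getattr(cfg, key)
            if value is None:
                continue
            body.append(f"{key} = {fmt(value)}")
        if body:
            lines.append(f"[{section}]")
            lines.extend(body)
            lines.append("")
    Path(path).write_text("\n".join(lines))


def make_fixtures(
    seed: int,
    n_per_scenario: int = 12,
    Q: float = 50.0,
    s_range: tuple[float, float] = (0.03, 0.1),
    model_name: str = "A1",
) -> dict[str, list[SimulationResult]]:
    """Generate a miniature labelled three-scenario dataset.

    Heavily scaled (Q=50 by default) so the whole set simulates in
    seconds; deterministic per seed.  Intended for tests and smoke runs,
    not for training production classifiers.
    """
    model = get_model(model_name)
    out = {}
    for i, scenario in enumerate(("neutral", "sweep", "ai")):
        out[scenario] = simulate_scenario(
            model,
            scenario,
            n_per_scenario,
            Q=Q,
            seed=seed + 1000 * i,
            s_range=s_range,
        )
    return out
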