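"""Simulation configuration.

All tunables live in one packaged YAML document (``defaults.yaml``); a user
config file or keyword overrides are merged on top of it.  ``SimConfig``
validates the merged document and exposes typed parameter blocks for the
demography and predation modules.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .demography import GrowthParams
from .predation import PredationParams

__all__ = ["SimConfig", "load_config", "SCENARIOS"]

SCENARIOS = (
    "newborn_start",
    "random_ages",
    "random_ages_with_delays",
    "single_patch",
    "twenty_patch_random",
    "clonal",
)


def _defaults() -> dict:
    text = importlib.resources.files("cicadasim").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class SimConfig:
    n_patches: int
    cycle_lengths: tuple[int, ...]
    scenario: str
    burn_in_years: int
    main_years: int
    migration_prob: float
    mutation_prob: float
    fecundity: int
    initial_fill: float
    clonal: bool
    N: int
    growth: GrowthParams
    predation: PredationParams
    p_delay: float
    d: int
    seed: int | None = None
    #: record a census row every year even when nothing changed (small runs)
    record_every_year: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario in ("newborn_start", "random_ages", "random_ages_with_delays"):
            if len(self.cycle_lengths) != self.n_patches:
                raise ValueError("one cycle length per patch is required")
            if len(set(self.cycle_lengths)) != len(self.cycle_lengths):
                raise ValueError(
                    "fair-competition scenarios require distinct cycle lengths"
                )
        if any(c < 1 for c in self.cycle_lengths):
            raise ValueError("cycle lengths must be >= 1")
        for name, value in (
            ("migration_prob", self.migration_prob),
            ("mutation_prob", self.mutation_prob),
            ("p_delay", self.p_delay),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.N < 1 or self.fecundity < 0 or self.d < 1:
            raise ValueError("invalid N, fecundity or delay length")
        if not 0.0 < self.initial_fill <= 1.0:
            raise ValueError("initial_fill must be in (0, 1]")
        if self.burn_in_years < 0 or self.main_years < 0:
            raise ValueError("year counts must be >= 0")

    @property
    def total_years(self) -> int:
        return self.burn_in_years + self.main_years

    @property
    def delays_enabled(self) -> bool:
        return self.p_delay > 0.0

    @property
    def clonal_mode(self) -> bool:
        return self.clonal or self.scenario == "clonal"


def load_config(path: str | None = None, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from the packaged defaults, an optional
    YAML file and keyword overrides (checked in that order).

    Nested blocks can be overridden with the keywords ``N`` (patch size),
    ``growth``, ``predation``, ``p_delay`` and ``d``, or by passing nested
    dicts matching the YAML layout.
    """
    doc = _defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        doc = _deep_merge(doc, user)
    # Flat keyword conveniences.
    flat = dict(overrides)
    if "N" in flat:
        doc["patch"] = _deep_merge(doc["patch"], {"N": flat.pop("N")})
    for block in ("growth", "predation", "patch", "delay"):
        if block in flat:
            doc[block] = _deep_merge(doc[block], flat.pop(block))
    for key in ("p_delay", "d"):
        if key in flat:
            doc["delay"][key] = flat.pop(key)
    doc.update(flat)

    growth = GrowthParams(
        mu=float(doc["growth"]["mu"]),
        sigma=float(doc["growth"]["sigma"]),
        size_threshold=float(doc["growth"]["size_threshold"]),
    )
    predation = PredationParams(
        p=float(doc["predation"]["p"]),
        a=float(doc["predation"]["a"]),
        h=float(doc["predation"]["h"]),
        ramp_years=int(doc["predation"]["ramp_years"]),
    )
    return SimConfig(
        n_patches=int(doc["n_patches"]),
        cycle_lengths=tuple(int(c) for c in doc["cycle_lengths"]),
        scenario=str(doc["scenario"]),
        burn_in_years=int(doc["burn_in_years"]),
        main_years=int(doc["main_years"]),
        migration_prob=float(doc["migration_prob"]),
        mutation_prob=float(doc["mutation_prob"]),
        fecundity=int(doc["fecundity"]),
        initial_fill=float(doc["initial_fill"]),
        clonal=bool(doc.get("clonal", False)),
        N=int(doc["patch"]["N"]),
        growth=growth,
        predation=predation,
        p_delay=float(doc["delay"]["p_delay"]),
        d=int(doc["delay"]["d"]),
        seed=doc.get("seed"),
        record_every_year=bool(doc.get("record_every_year", False)),
    )
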