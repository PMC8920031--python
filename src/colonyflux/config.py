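"""Colony and run configuration.

All tunable quantities of the pipeline live in :class:`ColonyConfig`
(the synthetic colony and the analysis windows) and :class:`MRConfig`
(activity-specific metabolic rates for the energy model).  Both load
from / dump to a single YAML document so a run is fully described by
one config file plus one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

STAGES = ("pre_laying", "incubation", "chick_rearing")
SEXES = ("female", "male")
#: Behavioural states in canonical order; ties in decoding break toward
#: the lower index, i.e. flight first.
BEHAVIOURS = ("flight", "colony", "water")

SIMPLEX_TOL = 1e-9


class ConfigError(ValueError):
    """Raised on invalid configuration; ``errors`` lists every violation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class MRConfig:
    """Activity-specific metabolic rates, in ml CO2 g^-1 day^-1.

    Rates are mass-specific; multiplying the resulting daily energy
    expenditure by body mass gives the whole-animal value.  The caloric
    equivalent converts respired CO2 volume to energy (J per ml CO2).
    """

    mr_flight: float = 159.18078674481934
    mr_colony: float = 32.008819034684824
    mr_water: float = 42.634153094463964
    caloric_equivalent: float = 27.63

    def as_vector(self) -> np.ndarray:
        """Rates ordered like :data:`BEHAVIOURS` (flight, colony, water)."""
        return np.array([self.mr_flight, self.mr_colony, self.mr_water], float)

    def validate(self) -> list[str]:
        errs = []
        for name in ("mr_flight", "mr_colony", "mr_water", "caloric_equivalent"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                errs.append(f"mr.{name}: must be positive, got {v!r}")
        return errs


def _default_budgets() -> dict[str, tuple[float, float, float]]:
    # Pre-laying baseline is a free parameter; incubation / chick rearing
    # apply the stage shifts (+11/+15 flight, -19/-16 colony points) with
    # the residue renormalised onto water.
    return {
        "pre_laying": (0.20, 0.62, 0.18),
        "incubation": (0.31, 0.43, 0.26),
        "chick_rearing": (0.35, 0.46, 0.19),
    }


@dataclass
class ColonyConfig:
    """Everything the synthetic colony generator and pipeline need.

    Defaults describe a sub-arctic kittiwake colony: a fixed nest site
    on Middleton Island, ~2.4-day tag deployments spread over the
    breeding season, 3-min GPS fixes and 25 Hz tri-axial acceleration.
    """

    colony_lat: float = 58.4167
    colony_lon: float = -146.3167
    season_start: str = "2019-05-19"
    season_end: str = "2019-07-27"

    n_birds: dict = field(
        default_factory=lambda: {"pre_laying": 20, "incubation": 20, "chick_rearing": 32}
    )
    female_fraction: float = 34 / 72

    # behaviour budgets: per stage, proportions (flight, colony, water)
    stage_budgets: dict = field(default_factory=_default_budgets)
    budget_concentration: float = 100.0  # Dirichlet concentration across birds
    dwell_s: float = 240.0  # mean behavioural persistence

    trip_range_km: float = 40.0
    flight_speed_ms: float = 10.0
    gps_period_s: float = 180.0
    accel_rate_hz: float = 25.0
    flap_freq_hz: float = 3.5
    flap_amp_g: float = 1.0
    accel_noise_sd_g: float = 0.05
    swell_freq_hz: float = 0.3
    swell_amp_g: float = 0.15

    t3_mean: dict = field(
        default_factory=lambda: {"pre_laying": 2.66, "incubation": 4.71, "chick_rearing": 3.16}
    )
    t3_sd: dict = field(
        default_factory=lambda: {"pre_laying": 1.30, "incubation": 1.97, "chick_rearing": 2.85}
    )
    mass_mean: dict = field(default_factory=lambda: {"female": 392.0, "male": 425.0})
    mass_sd: dict = field(default_factory=lambda: {"female": 7.0, "male": 7.7})
    mass_change_mean: float = 0.0  # deployment effect on mass (g)
    mass_change_sd: float = 0.0

    deployment_days_mean: float = 2.42
    deployment_days_min: float = 1.77
    deployment_days_max: float = 2.98

    window_s: float = 15.0  # analysis window for features and states
    band_hz: tuple = (1.5, 8.0)  # wingbeat search band
    dominance_min: float = 0.2

    ud_cell_m: float = 250.0
    ud_levels: tuple = (0.50, 0.75, 0.85, 0.95)

    mr: MRConfig = field(default_factory=MRConfig)
    seed: int = 0

    # ---- validation -------------------------------------------------

    def validate(self) -> list[str]:
        errs: list[str] = []
        if not -90 <= self.colony_lat <= 90 or not -180 <= self.colony_lon <= 180:
            errs.append("colony coordinates out of range")
        for stage in STAGES:
            if stage not in self.n_birds:
                errs.append(f"n_birds missing stage {stage!r}")
            elif int(self.n_birds[stage]) <= 0:
                errs.append(f"n_birds[{stage}]: must be >= 1, got {self.n_birds[stage]}")
            b = np.asarray(self.stage_budgets.get(stage, ()), float)
            if b.shape != (3,):
                errs.append(f"stage_budgets[{stage}]: need 3 proportions")
            elif (b < 0).any() or abs(b.sum() - 1.0) > SIMPLEX_TOL:
                errs.append(
                    f"stage_budgets[{stage}]: proportions must be >= 0 and sum to 1 "
                    f"(got sum {b.sum():.12g})"
                )
            if self.t3_sd.get(stage, 0.0) < 0:
                errs.append(f"t3_sd[{stage}]: must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            errs.append("female_fraction must be in [0, 1]")
        for name in ("gps_period_s", "accel_rate_hz", "window_s", "dwell_s",
                     "trip_range_km", "flight_speed_ms", "flap_freq_hz",
                     "budget_concentration", "ud_cell_m"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}: must be positive")
        if self.accel_rate_hz <= 2 * self.flap_freq_hz:
            errs.append("accel_rate_hz must exceed twice flap_freq_hz (Nyquist)")
        if self.dwell_s <= self.window_s:
            errs.append("dwell_s must exceed window_s")
        if not all(0 < lv < 1 for lv in self.ud_levels):
            errs.append("ud_levels must lie in (0, 1)")
        if not (0 < self.deployment_days_min <= self.deployment_days_max):
            errs.append("deployment day range invalid")
        errs.extend(self.mr.validate())
        return errs

    def budget(self, stage: str) -> np.ndarray:
        return np.asarray(self.stage_budgets[stage], float)

    # ---- (de)serialisation ------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["ud_levels"] = list(self.ud_levels)
        d["stage_budgets"] = {k: list(v) for k, v in self.stage_budgets.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColonyConfig":
        d = dict(d)
        if "mr" in d and isinstance(d["mr"], Mapping):
            d["mr"] = MRConfig(**d["mr"])
        for key in ("band_hz", "ud_levels"):
            if key in d:
                d[key] = tuple(d[key])
        if "stage_budgets" in d:
            d["stage_budgets"] = {k: tuple(v) for k, v in d["stage_budgets"].items()}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ColonyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def validate_config(cfg: ColonyConfig | Mapping) -> ColonyConfig:
    """Normalise and validate a config; raise :class:`ConfigError` listing
    every violation, otherwise return the (defaults-filled) config."""
    if not isinstance(cfg, ColonyConfig):
        cfg = ColonyConfig.from_dict(cfg)
    errs = cfg.validate()
    if errs:
        raise ConfigError(errs)
    return cfg
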