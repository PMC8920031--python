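"""Core data containers and their delimited-text (logger dialect) I/O.

Time is stored as a reference timestamp ``t0`` plus float seconds, which
keeps arithmetic on 25 Hz series cheap; file writers emit ISO-8601
timestamps so the on-disk formats match what tag loggers produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import BEHAVIOURS, SEXES, STAGES

_ISO = "%Y-%m-%dT%H:%M:%S.%f"


def _iso(t0: pd.Timestamp, t: np.ndarray) -> pd.Series:
    return pd.Series(t0 + pd.to_timedelta(np.asarray(t, float), unit="s")).dt.strftime(_ISO)


def _from_iso(col: pd.Series) -> tuple[pd.Timestamp, np.ndarray]:
    ts = pd.to_datetime(col, format="ISO8601")
    if len(ts) == 0:
        return pd.Timestamp(0), np.empty(0)
    t0 = ts.iloc[0]
    return t0, (ts - t0).dt.total_seconds().to_numpy()


@dataclass
class BirdRecord:
    """One deployed bird: identity, stage, masses and hormone samples."""

    bird_id: str
    sex: str
    stage: str
    mass_pre: float
    mass_post: float
    deployment_start: pd.Timestamp
    deployment_end: pd.Timestamp
    t3_samples: tuple = ()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (self.mass_pre > 0 and self.mass_post > 0):
            raise ValueError("masses must be positive")
        if not self.deployment_end > self.deployment_start:
            raise ValueError("deployment_end must follow deployment_start")
        if len(self.t3_samples) > 2:
            raise ValueError("at most two T3 samples per bird")


@dataclass
class AccelTrace:
    """Tri-axial acceleration in g-units at a nominal constant rate."""

    t0: pd.Timestamp
    t: np.ndarray  # seconds since t0, strictly increasing
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate: float

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate if len(self.t) else 0.0


@dataclass
class GpsTrack:
    """Position fixes at a nominal cadence (decimal degrees)."""

    t0: pd.Timestamp
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        if len(self.lat) and (
            np.abs(self.lat).max() > 90 or np.abs(self.lon).max() > 180
        ):
            raise ValueError("coordinates out of range")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrueStateSequence:
    """Ground-truth behaviour per analysis window (generator output)."""

    t0: pd.Timestamp
    midpoints: np.ndarray  # window midpoints, seconds since t0
    states: np.ndarray  # int indices into BEHAVIOURS
    window: float

    def __post_init__(self):
        s = np.asarray(self.states)
        if len(s) and (s.min() < 0 or s.max() >= len(BEHAVIOURS)):
            raise ValueError("state labels outside the 3-state vocabulary")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(BEHAVIOURS)[self.states]


@dataclass
class FeatureSeries:
    """Per-window HMM observations: wingbeat stream + colony-distance stream.

    ``wingbeat`` is 0.0 where no dominant spectral peak was found and NaN
    where the window could not be evaluated (missing observation).  The
    distance stream is NaN outside GPS coverage; ``near`` mirrors it.
    """

    t0: pd.Timestamp
    midpoints: np.ndarray
    wingbeat: np.ndarray
    dominance: np.ndarray
    dist_m: np.ndarray
    window: float

    @property
    def near(self) -> np.ndarray:
        """1.0 where distance < 500 m, 0.0 where >= 500 m, NaN where missing."""
        out = np.where(self.dist_m < 500.0, 1.0, 0.0)
        out[np.isnan(self.dist_m)] = np.nan
        return out

    @property
    def missing(self) -> np.ndarray:
        """Windows with neither observation stream available."""
        return np.isnan(self.wingbeat) & np.isnan(self.dist_m)

    def __len__(self) -> int:
        return len(self.midpoints)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "midpoint_iso": _iso(self.t0, self.midpoints),
                "wingbeat_hz": self.wingbeat,
                "dominance": self.dominance,
                "dist_m": self.dist_m,
                "near": self.near,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path, window: float = 15.0) -> "FeatureSeries":
        df = pd.read_csv(path)
        t0, t = _from_iso(df["midpoint_iso"])
        return cls(
            t0=t0,
            midpoints=t,
            wingbeat=df["wingbeat_hz"].to_numpy(float),
            dominance=df["dominance"].to_numpy(float),
            dist_m=df["dist_m"].to_numpy(float),
            window=window,
        )


@dataclass
class StatePath:
    """Decoded behaviour sequence with posterior state probabilities."""

    t0: pd.Timestamp
    midpoints: np.ndarray
    states: np.ndarray  # int indices into BEHAVIOURS
    posterior: np.ndarray  # (T, 3)
    missing: np.ndarray  # bool, True where both streams were absent
    bird_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(BEHAVIOURS)[self.states]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "midpoint_iso": _iso(self.t0, self.midpoints),
                "state": self.labels,
                "missing": self.missing.astype(int),
            }
        )
        for i, b in enumerate(BEHAVIOURS):
            df[f"p_{b}"] = self.posterior[:, i]
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path, bird_id: Optional[str] = None) -> "StatePath":
        df = pd.read_csv(path)
        t0, t = _from_iso(df["midpoint_iso"])
        lookup = {b: i for i, b in enumerate(BEHAVIOURS)}
        return cls(
            t0=t0,
            midpoints=t,
            states=df["state"].map(lookup).to_numpy(np.int64),
            posterior=df[[f"p_{b}" for b in BEHAVIOURS]].to_numpy(float),
            missing=df["missing"].to_numpy(bool),
            bird_id=bird_id,
        )


@dataclass
class TimeActivityBudget:
    """Proportions of (non-missing) deployment time per behaviour."""

    proportions: np.ndarray  # ordered like BEHAVIOURS
    bird_id: Optional[str] = None

    def __post_init__(self):
        p = np.asarray(self.proportions, float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("budget must be 3 non-negative proportions summing to 1")
        self.proportions = p

    def __getitem__(self, behaviour: str) -> float:
        return float(self.proportions[BEHAVIOURS.index(behaviour)])


@dataclass
class DeeEstimate:
    """Activity-based daily energy expenditure, mass-specific."""

    dee_act: float  # kJ g^-1 day^-1
    bird_id: Optional[str] = None
    dee_absolute: Optional[float] = None  # kJ day^-1, given body mass


# ---- logger-dialect files ------------------------------------------------


def write_accel(trace: AccelTrace, path) -> None:
    pd.DataFrame(
        {
            "timestamp_iso": _iso(trace.t0, trace.t),
            "ax_g": trace.ax,
            "ay_g": trace.ay,
            "az_g": trace.az,
        }
    ).to_csv(path, index=False)


def read_accel(path, rate: float = 25.0) -> AccelTrace:
    df = pd.read_csv(path)
    t0, t = _from_iso(df["timestamp_iso"])
    return AccelTrace(
        t0=t0,
        t=t,
        ax=df["ax_g"].to_numpy(float),
        ay=df["ay_g"].to_numpy(float),
        az=df["az_g"].to_numpy(float),
        rate=rate,
    )


def write_gps(track: GpsTrack, path) -> None:
    pd.DataFrame(
        {
            "timestamp_iso": _iso(track.t0, track.t),
            "lat_dd": track.lat,
            "lon_dd": track.lon,
        }
    ).to_csv(path, index=False, float_format="%.8f")


def read_gps(path) -> GpsTrack:
    df = pd.read_csv(path)
    t0, t = _from_iso(df["timestamp_iso"])
    return GpsTrack(
        t0=t0, t=t, lat=df["lat_dd"].to_numpy(float), lon=df["lon_dd"].to_numpy(float)
    )


def write_metadata(birds: list[BirdRecord], path) -> None:
    rows = []
    for b in birds:
        rows.append(
            {
                "bird_id": b.bird_id,
                "sex": b.sex,
                "stage": b.stage,
                "mass_pre_g": b.mass_pre,
                "mass_post_g": b.mass_post,
                "deployment_start": b.deployment_start.strftime(_ISO),
                "deployment_end": b.deployment_end.strftime(_ISO),
                "t3_1_pg_ml": b.t3_samples[0] if len(b.t3_samples) > 0 else np.nan,
                "t3_2_pg_ml": b.t3_samples[1] if len(b.t3_samples) > 1 else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> list[BirdRecord]:
    df = pd.read_csv(path)
    birds = []
    for _, r in df.iterrows():
        t3 = tuple(v for v in (r["t3_1_pg_ml"], r["t3_2_pg_ml"]) if np.isfinite(v))
        birds.append(
            BirdRecord(
                bird_id=str(r["bird_id"]),
                sex=r["sex"],
                stage=r["stage"],
                mass_pre=float(r["mass_pre_g"]),
                mass_post=float(r["mass_post_g"]),
                deployment_start=pd.to_datetime(r["deployment_start"]),
                deployment_end=pd.to_datetime(r["deployment_end"]),
                t3_samples=t3,
            )
        )
    return birds
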