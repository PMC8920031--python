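"""Synthetic breeding-colony generator.

Produces, per bird, a ground-truth behaviour sequence on the analysis
window grid, a 25 Hz tri-axial acceleration trace with state-dependent
signatures (flapping oscillation in flight, swell on water, quiet at the
colony), a central-place GPS track of out-and-back foraging trips, and
physiology draws (masses, free-T3 samples).  Every stochastic quantity
comes from a per-bird stream keyed by bird id, so outputs are
reproducible regardless of iteration order.
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import BEHAVIOURS, SIMPLEX_TOL, ColonyConfig
from .containers import (
    AccelTrace,
    BirdRecord,
    GpsTrack,
    TrueStateSequence,
    write_accel,
    write_gps,
)
from .spaceuse import unproject_from_plane

COLONY = BEHAVIOURS.index("colony")
FLIGHT = BEHAVIOURS.index("flight")

_FLAP_JITTER_SD = 0.1  # per-window wingbeat frequency jitter, Hz
_COLONY_JITTER_M = 30.0  # GPS scatter around the nest site


def bird_rng(bird_id: str, root_seed: int) -> np.random.Generator:
    """Independent per-bird stream, stable under iteration order."""
    return np.random.default_rng([zlib.crc32(bird_id.encode()), root_seed & 0x7FFFFFFF])


def _check_simplex(budget: np.ndarray) -> np.ndarray:
    b = np.asarray(budget, float)
    if b.shape != (3,) or (b < 0).any() or abs(b.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError("budget must be a 3-vector on the probability simplex")
    return b


def budget_transition_matrix(budget, window_s: float, dwell_s: float) -> np.ndarray:
    """Row-stochastic 3x3 matrix with stationary distribution ``budget``.

    Reversible family P_ij = a*pi_j (i != j), P_ii = 1 - a*(1 - pi_i)
    with switching intensity a = window/dwell; detailed balance gives the
    requested stationary distribution exactly.  Realized mean sojourn in
    state i is dwell/(1 - pi_i): ``dwell_s`` sets the mean time between
    switching attempts rather than the sojourn itself.
    """
    pi = _check_simplex(budget)
    if dwell_s <= window_s:
        raise ValueError("dwell_s must exceed window_s")
    a = window_s / dwell_s
    P = a * np.tile(pi, (3, 1))
    np.fill_diagonal(P, 1.0 - a * (1.0 - pi))
    return P


def simulate_behaviour_sequence(
    budget,
    duration_s: float,
    window_s: float,
    dwell_s: float,
    rng: np.random.Generator,
    t0: pd.Timestamp = pd.Timestamp("2019-06-01"),
) -> TrueStateSequence:
    """First-order Markov chain over (flight, colony, water) on the window grid."""
    pi = _check_simplex(budget)
    P = budget_transition_matrix(pi, window_s, dwell_s)
    n = int(round(duration_s / window_s))
    states = np.empty(n, dtype=np.int64)
    cum_init = np.cumsum(pi)
    states[0] = np.searchsorted(cum_init, rng.random())
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    for k in range(1, n):
        states[k] = np.searchsorted(cum[states[k - 1]], u[k])
    mid = (np.arange(n) + 0.5) * window_s
    return TrueStateSequence(t0=t0, midpoints=mid, states=states, window=window_s)


def simulate_accel(
    states: TrueStateSequence,
    rate: float,
    flap_freq: float,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    flap_amp: float = 1.0,
    swell_freq: float = 0.3,
    swell_amp: float = 0.15,
) -> AccelTrace:
    """State-dependent tri-axial acceleration at ``rate`` Hz.

    Flight windows carry a dominant flapping sinusoid on the dorsoventral
    (z) channel at ``flap_freq`` with small per-window frequency jitter;
    water windows a sub-hertz swell; colony windows only sensor noise
    around 1 g of gravity.
    """
    if rate <= 2 * flap_freq:
        raise ValueError("sampling rate must exceed twice the flap frequency (Nyquist)")
    spw = int(round(states.window * rate))
    nw = len(states)
    n = nw * spw
    t = np.arange(n) / rate
    ax = noise_sd * rng.standard_normal(n)
    ay = noise_sd * rng.standard_normal(n)
    az = 1.0 + noise_sd * rng.standard_normal(n)

    state_per_sample = np.repeat(states.states, spw)
    freqs = flap_freq + _FLAP_JITTER_SD * rng.standard_normal(nw)
    phases = rng.uniform(0, 2 * np.pi, nw)
    fly = state_per_sample == FLIGHT
    if fly.any():
        f_rep = np.repeat(freqs, spw)[fly]
        p_rep = np.repeat(phases, spw)[fly]
        az[fly] += flap_amp * np.sin(2 * np.pi * f_rep * t[fly] + p_rep)
    wet = state_per_sample == BEHAVIOURS.index("water")
    if wet.any():
        az[wet] += swell_amp * np.sin(2 * np.pi * swell_freq * t[wet] + rng.uniform(0, 2 * np.pi))
    return AccelTrace(t0=states.t0, t=t, ax=ax, ay=ay, az=az, rate=rate)


def simulate_gps(
    states: TrueStateSequence,
    colony: tuple,
    trip_range_km: float,
    gps_period: float,
    rng: np.random.Generator,
    flight_speed: float = 10.0,
    jitter_m: float = _COLONY_JITTER_M,
) -> GpsTrack:
    """Central-place track: at-colony fixes jittered around the nest;
    contiguous away-bouts become out-and-back trips along a random
    bearing with a triangular range profile.  Trip extent is
    ``flight_speed`` x half the bout duration, capped at
    ``trip_range_km``, so position is continuous in time and the 3-min
    fix cadence can resolve departures and returns."""
    if gps_period <= 0:
        raise ValueError("gps_period must be positive")
    duration = len(states) * states.window
    t_fix = np.arange(0.0, duration, gps_period)
    widx = np.minimum((t_fix / states.window).astype(int), len(states) - 1)
    away = states.states != COLONY

    # contiguous away-bouts on the window grid
    x = np.zeros_like(t_fix)
    y = np.zeros_like(t_fix)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], away.astype(int), [0]))))
    cap = max(trip_range_km * 1000.0 - 10 * jitter_m, 0.0)
    for ws, we in edges.reshape(-1, 2):
        t_s, t_e = ws * states.window, we * states.window
        dmax = min(cap, flight_speed * (t_e - t_s) / 2.0)
        theta = rng.uniform(0, 2 * np.pi)
        sel = (t_fix >= t_s) & (t_fix < t_e) & away[widx]
        u = (t_fix[sel] - t_s) / (t_e - t_s)
        r = dmax * (1.0 - np.abs(2.0 * u - 1.0))
        x[sel] = r * np.sin(theta)
        y[sel] = r * np.cos(theta)
    x += jitter_m * rng.standard_normal(len(t_fix))
    y += jitter_m * rng.standard_normal(len(t_fix))
    lat, lon = unproject_from_plane(x, y, colony)
    return GpsTrack(t0=states.t0, t=t_fix, lat=lat, lon=lon)


def simulate_physiology(
    stage: str, sex: str, config: ColonyConfig, rng: np.random.Generator
) -> tuple[float, float, tuple]:
    """Draw (mass_pre, mass_post, t3_samples) for one bird.

    T3 samples come from a normal truncated at zero with the configured
    stage mean/sd; masses are sex-specific normals; the post-deployment
    mass adds the configured (default zero) deployment effect.
    """
    mean, sd = config.t3_mean[stage], config.t3_sd[stage]
    if sd == 0:
        t3 = (float(mean), float(mean))
    else:
        a = (0.0 - mean) / sd
        t3 = tuple(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=2, random_state=rng))
    mass_pre = float(rng.normal(config.mass_mean[sex], config.mass_sd[sex]))
    delta = config.mass_change_mean
    if config.mass_change_sd > 0:
        delta += config.mass_change_sd * rng.standard_normal()
    return mass_pre, mass_pre + delta, t3


def _bird_budget(stage_budget: np.ndarray, conc: float, rng) -> np.ndarray:
    """Dirichlet draw around the stage budget; zero components stay zero."""
    alpha = conc * stage_budget
    g = np.array([rng.gamma(a) if a > 0 else 0.0 for a in alpha])
    s = g.sum()
    return g / s if s > 0 else stage_budget


def simulate_bird(
    bird_id: str,
    stage: str,
    config: ColonyConfig,
    root_seed: int,
    duration_days: Optional[float] = None,
    sex: Optional[str] = None,
):
    """Generate one deployment: (BirdRecord, TrueStateSequence, AccelTrace, GpsTrack)."""
    rng = bird_rng(bird_id, root_seed)
    if sex is None:
        sex = "female" if rng.random() < config.female_fraction else "male"
    if duration_days is None:
        lo = config.deployment_days_min - config.deployment_days_mean
        hi = config.deployment_days_max - config.deployment_days_mean
        if hi - lo < 1e-12:
            duration_days = config.deployment_days_min
        else:
            duration_days = float(
                stats.truncnorm.rvs(lo, hi, loc=config.deployment_days_mean,
                                    scale=1.0, random_state=rng)
            )
    duration_s = round(duration_days * 86400 / config.window_s) * config.window_s

    season_start = pd.Timestamp(config.season_start)
    season_end = pd.Timestamp(config.season_end)
    slack_s = max((season_end - season_start).total_seconds() - duration_s, 0.0)
    t0 = season_start + pd.to_timedelta(rng.uniform(0, slack_s), unit="s")
    t0 = t0.floor("s")

    budget = _bird_budget(config.budget(stage), config.budget_concentration, rng)
    seq = simulate_behaviour_sequence(
        budget, duration_s, config.window_s, config.dwell_s, rng, t0=t0
    )
    accel = simulate_accel(
        seq,
        config.accel_rate_hz,
        config.flap_freq_hz,
        rng,
        noise_sd=config.accel_noise_sd_g,
        flap_amp=config.flap_amp_g,
        swell_freq=config.swell_freq_hz,
        swell_amp=config.swell_amp_g,
    )
    gps = simulate_gps(
        seq,
        (config.colony_lat, config.colony_lon),
        config.trip_range_km,
        config.gps_period_s,
        rng,
        flight_speed=config.flight_speed_ms,
    )
    mass_pre, mass_post, t3 = simulate_physiology(stage, sex, config, rng)
    bird = BirdRecord(
        bird_id=bird_id,
        sex=sex,
        stage=stage,
        mass_pre=mass_pre,
        mass_post=mass_post,
        deployment_start=t0,
        deployment_end=t0 + pd.to_timedelta(duration_s, unit="s"),
        t3_samples=t3,
    )
    return bird, seq, accel, gps


_STAGE_PREFIX = {"pre_laying": "PL", "incubation": "IN", "chick_rearing": "CR"}


def simulate_colony(
    config: ColonyConfig,
    seed: Optional[int] = None,
    duration_days: Optional[float] = None,
):
    """Generate the whole colony.

    Returns (birds, deployments) where ``deployments`` maps bird_id to
    (TrueStateSequence, AccelTrace, GpsTrack).
    """
    root = config.seed if seed is None else seed
    birds: list[BirdRecord] = []
    deployments: dict[str, tuple] = {}
    for stage, n in config.n_birds.items():
        for k in range(int(n)):
            bid = f"{_STAGE_PREFIX[stage]}{k + 1:02d}"
            bird, seq, accel, gps = simulate_bird(
                bid, stage, config, root, duration_days=duration_days
            )
            birds.append(bird)
            deployments[bid] = (seq, accel, gps)
    return birds, deployments


def write_deployment(bird: BirdRecord, accel: AccelTrace, gps: GpsTrack, outdir) -> dict:
    """Write one bird's logger files; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "accel": outdir / f"{bird.bird_id}_acc.csv",
        "gps": outdir / f"{bird.bird_id}_gps.csv",
    }
    write_accel(accel, paths["accel"])
    write_gps(gps, paths["gps"])
    return paths
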