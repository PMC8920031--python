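"""Observation streams for behaviour classification.

Raw 25 Hz acceleration and 3-min GPS fixes are reduced to one row per
tumbling analysis window: the dominant wingbeat frequency and its
spectral dominance on the dorsoventral channel, and the great-circle
distance to the colony (dichotomised at 500 m into near/far).
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import AccelTrace, FeatureSeries, GpsTrack

EARTH_RADIUS_M = 6_371_000.0
NEAR_THRESHOLD_M = 500.0  # near: < 500 m, far: >= 500 m
DEFAULT_BAND_HZ = (1.5, 8.0)
DEFAULT_DOMINANCE_MIN = 0.2
MIN_WINDOW_S = 2.0


def haversine_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, float) for v in (lat1, lon1, lat2, lon2))
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _band_peak(power: np.ndarray, freqs: np.ndarray, band) -> tuple[float, float]:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    band_power = power[sel]
    total = band_power.sum()
    if total <= 0:
        return 0.0, 0.0
    i = int(np.argmax(band_power))
    # peak +/- 1 bins: a tone midway between bins leaks into neighbours
    peak = band_power[max(i - 1, 0): i + 2].sum()
    return float(freqs[sel][i]), float(peak / total)


def wingbeat_frequency(
    window: np.ndarray,
    rate: float,
    band=DEFAULT_BAND_HZ,
    dominance_min: float = DEFAULT_DOMINANCE_MIN,
) -> tuple[float, float]:
    """Dominant in-band frequency of one window of the dorsoventral channel.

    The per-window mean (gravity plus posture offset) is removed, a
    Hann-tapered periodogram estimated, and the peak within ``band``
    returned together with its dominance (power in the peak and its two
    neighbouring bins over total in-band power; the neighbours absorb
    spectral leakage of off-bin tones).  Windows whose dominance falls
    below ``dominance_min`` report frequency 0 ("no flapping"); windows
    shorter than 2 s are a missing observation and report NaN.
    """
    x = np.asarray(window, float)
    if not 0 < band[0] < band[1] < rate / 2:
        raise ValueError("band must lie within (0, rate/2)")
    if len(x) < MIN_WINDOW_S * rate:
        return np.nan, np.nan
    x = (x - x.mean()) * np.hanning(len(x))
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    f, dom = _band_peak(power, freqs, band)
    return (f if dom >= dominance_min else 0.0), dom


def _windowed_wingbeat(accel: AccelTrace, window_s: float, band, dominance_min):
    """Batched per-window spectral peak over the whole trace."""
    spw = int(round(window_s * accel.rate))
    nw = len(accel) // spw
    z = accel.az[: nw * spw].reshape(nw, spw)
    z = (z - z.mean(axis=1, keepdims=True)) * np.hanning(spw)
    power = np.abs(np.fft.rfft(z, axis=1)) ** 2
    freqs = np.fft.rfftfreq(spw, d=1.0 / accel.rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    bp = power[:, sel]
    total = bp.sum(axis=1)
    peak_i = np.argmax(bp, axis=1)
    rows = np.arange(nw)
    peak = bp[rows, peak_i].copy()
    peak += np.where(peak_i > 0, bp[rows, np.maximum(peak_i - 1, 0)], 0.0)
    peak += np.where(peak_i < bp.shape[1] - 1,
                     bp[rows, np.minimum(peak_i + 1, bp.shape[1] - 1)], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dom = np.where(total > 0, peak / total, 0.0)
    freq = np.where(dom >= dominance_min, freqs[sel][peak_i], 0.0)
    return nw, freq, dom


def align_gps_to_windows(
    track: GpsTrack, midpoints: np.ndarray, colony: tuple, gps_period: float = 180.0
) -> np.ndarray:
    """Distance to the colony (m) at each window midpoint.

    Positions are linearly interpolated between bracketing fixes in a
    local planar frame centred on the colony; the reported distance is
    the haversine distance of the interpolated position.  Midpoints more
    than one ``gps_period`` outside GPS coverage are NaN (missing).
    """
    from .spaceuse import project_to_plane, unproject_from_plane

    midpoints = np.asarray(midpoints, float)
    out = np.full(len(midpoints), np.nan)
    if len(track) == 0:
        warnings.warn("empty GPS track: all windows missing the distance stream")
        return out
    x, y = project_to_plane(track.lat, track.lon, colony)
    covered = (midpoints >= track.t[0] - gps_period) & (midpoints <= track.t[-1] + gps_period)
    xi = np.interp(midpoints[covered], track.t, x)
    yi = np.interp(midpoints[covered], track.t, y)
    lat_i, lon_i = unproject_from_plane(xi, yi, colony)
    out[covered] = haversine_distance(lat_i, lon_i, colony[0], colony[1])
    return out


def build_features(
    accel: AccelTrace,
    gps: GpsTrack,
    colony: tuple,
    window_s: float = 15.0,
    band=DEFAULT_BAND_HZ,
    dominance_min: float = DEFAULT_DOMINANCE_MIN,
    gps_period: float = 180.0,
) -> FeatureSeries:
    """Tumbling-window observation table for one deployment."""
    if len(accel) == 0:
        raise ValueError("empty acceleration trace")
    nw, freq, dom = _windowed_wingbeat(accel, window_s, band, dominance_min)
    if nw == 0:
        raise ValueError("acceleration trace shorter than one window")
    mid = accel.t[0] + (np.arange(nw) + 0.5) * window_s
    gps_mid = mid + (accel.t0 - gps.t0).total_seconds()
    dist = align_gps_to_windows(gps, gps_mid, colony, gps_period=gps_period)
    if np.isnan(dist).all() and len(gps) > 0:
        raise ValueError("accelerometer and GPS series do not overlap in time")
    return FeatureSeries(
        t0=accel.t0,
        midpoints=mid,
        wingbeat=freq,
        dominance=dom,
        dist_m=dist,
        window=window_s,
    )
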