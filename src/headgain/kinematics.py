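"""Synthetic head-yaw traces and head-movement analysis.

Trace generation emulates the trained back-and-forth sweeps: a triangle wave
between +/- the excursion half-angle, traversed at a per-sweep speed drawn
around the target (lognormal jitter keeps speeds positive), with reversals
rounded off by a short moving average.  Analysis mirrors the offline
treatment of tracker data: Gaussian smoothing, time differentiation, and RMS
speed.

The smoothing filter is specified by its frequency-domain SD in Hz; a
Gaussian with SD ``f_sd`` in the frequency domain is a time-domain Gaussian
kernel with sigma_t = 1/(2*pi*f_sd) (about 19.9 ms for the 8 Hz default),
which passes the trained sweep speeds essentially unattenuated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "HeadTrace",
    "TrajectorySpec",
    "KinematicsSummary",
    "simulate_trajectory",
    "smooth_trace",
    "velocity",
    "rms_speed",
    "summarize",
    "write_trace",
    "read_trace",
]

DEFAULT_FILTER_SD_HZ = 8.0


@dataclass(frozen=True)
class HeadTrace:
    """Uniformly sampled head-yaw trace (degrees) at rate ``fs`` (samples/s)."""

    fs: float
    yaw_deg: np.ndarray

    def __post_init__(self) -> None:
        yaw = np.asarray(self.yaw_deg, dtype=float)
        object.__setattr__(self, "yaw_deg", yaw)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if yaw.ndim != 1 or yaw.size < 2:
            raise ValueError("yaw_deg must be 1-D with length >= 2")
        if not np.all(np.isfinite(yaw)):
            raise ValueError("yaw_deg must be finite")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.yaw_deg.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.yaw_deg.size - 1) / self.fs


@dataclass(frozen=True)
class TrajectorySpec:
    """Back-and-forth sweep protocol.

    target_speed : deg/s, the trained sweep speed.
    excursion_half : deg, sweeps run between -excursion_half and +excursion_half.
    duration : s, total trace length (a 12 s sequence by default).
    speed_jitter_cv : coefficient of variation of the per-sweep speed
        (lognormal, so jittered speeds stay positive).
    turnaround_smoothing : s, moving-average width applied to the raw
        triangle wave so reversals are not instantaneous.
    """

    target_speed: float
    excursion_half: float = 30.0
    duration: float = 12.0
    speed_jitter_cv: float = 0.1
    turnaround_smoothing: float = 0.1
    fs: float = 240.0

    def __post_init__(self) -> None:
        if self.target_speed <= 0 or self.excursion_half <= 0:
            raise ValueError("target_speed and excursion_half must be > 0")
        if self.speed_jitter_cv < 0 or self.turnaround_smoothing < 0:
            raise ValueError("speed_jitter_cv and turnaround_smoothing must be >= 0")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be > 0")

    @property
    def sweep_duration(self) -> float:
        """Seconds per one-way sweep across the full 2*excursion_half arc."""
        return 2 * self.excursion_half / self.target_speed

    @property
    def sweeps_per_sequence(self) -> int:
        return int(round(self.duration / self.sweep_duration))


def simulate_trajectory(spec: TrajectorySpec, seed: int | np.random.Generator = 0) -> HeadTrace:
    """Simulate a back-and-forth yaw trace following ``spec``.

    The yaw starts at -excursion_half and alternates direction each sweep.
    Sweep ``k`` is traversed at speed ``target_speed * jitter_k`` with
    ``jitter_k`` lognormal with unit mean and CV ``speed_jitter_cv``
    (deterministic given the seed).  Sweeps are generated until ``duration``
    is covered — a trace shorter than one sweep simply returns the partial
    sweep — and reversals are finally rounded by a moving average of width
    ``turnaround_smoothing`` seconds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    arc = 2 * spec.excursion_half

    # per-sweep speeds: lognormal with mean target_speed, CV speed_jitter_cv
    def draw_speed() -> float:
        if spec.speed_jitter_cv == 0:
            return spec.target_speed
        sigma2 = np.log1p(spec.speed_jitter_cv**2)
        z = rng.standard_normal()
        return spec.target_speed * np.exp(np.sqrt(sigma2) * z - sigma2 / 2)

    # breakpoints of the piecewise-linear yaw: (time, yaw) at each reversal
    times = [0.0]
    yaws = [-spec.excursion_half]
    direction = 1.0
    while times[-1] < spec.duration:
        s = draw_speed()
        times.append(times[-1] + arc / s)
        yaws.append(yaws[-1] + direction * arc)
        direction = -direction
    yaw = np.interp(t, times, yaws)

    if spec.turnaround_smoothing > 0:
        w = max(1, int(round(spec.turnaround_smoothing * spec.fs)))
        kernel = np.ones(w) / w
        pad = np.concatenate([np.full(w, yaw[0]), yaw, np.full(w, yaw[-1])])
        yaw = np.convolve(pad, kernel, mode="same")[w:-w]
    return HeadTrace(fs=spec.fs, yaw_deg=yaw)


def smooth_trace(trace: HeadTrace, filter_sd_hz: float = DEFAULT_FILTER_SD_HZ) -> HeadTrace:
    """Zero-phase Gaussian smoothing with unit DC gain.

    ``filter_sd_hz`` is the SD of the filter's Gaussian frequency response;
    the equivalent time-domain kernel SD is ``1/(2*pi*filter_sd_hz)`` seconds.
    Short traces are reflect-padded rather than rejected.
    """
    if filter_sd_hz <= 0:
        raise ValueError("filter_sd_hz must be > 0")
    sigma_samples = trace.fs / (2 * np.pi * filter_sd_hz)
    yaw = gaussian_filter1d(trace.yaw_deg, sigma_samples, mode="reflect")
    return HeadTrace(fs=trace.fs, yaw_deg=yaw)


def velocity(trace: HeadTrace) -> np.ndarray:
    """Yaw velocity in deg/s by central differences (one-sided at the edges)."""
    return np.gradient(trace.yaw_deg) * trace.fs


def rms_speed(vel: np.ndarray) -> float:
    """Root-mean-square of a velocity series: sqrt(mean(v^2))."""
    v = np.asarray(vel, dtype=float)
    if v.size == 0:
        raise ValueError("velocity series must be non-empty")
    return float(np.sqrt(np.mean(v * v)))


def summarize(trace: HeadTrace, filter_sd_hz: float = DEFAULT_FILTER_SD_HZ) -> "KinematicsSummary":
    """Smooth, differentiate and summarise a trace as in the offline analysis."""
    vel = velocity(smooth_trace(trace, filter_sd_hz))
    # sweeps counted as sign changes of the (smoothed) velocity, plus one
    sign = np.sign(vel[np.abs(vel) > 1e-9])
    n_sweeps = int(np.count_nonzero(np.diff(sign) != 0) + 1) if sign.size else 0
    return KinematicsSummary(rms_speed=rms_speed(vel), n_sweeps=n_sweeps)


@dataclass(frozen=True)
class KinematicsSummary:
    rms_speed: float
    n_sweeps: int


def write_trace(trace: HeadTrace, path) -> None:
    """Write a head trace as CSV with columns time_s, yaw_deg."""
    pd.DataFrame({"time_s": trace.t, "yaw_deg": trace.yaw_deg}).to_csv(path, index=False)


def read_trace(path, rtol: float = 1e-6) -> HeadTrace:
    """Read a time_s/yaw_deg CSV; fs is inferred and uniformity validated."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=rtol, atol=1e-9):
        raise ValueError("time column is not uniformly sampled")
    return HeadTrace(fs=1.0 / dt[0], yaw_deg=df["yaw_deg"].to_numpy(dtype=float))
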