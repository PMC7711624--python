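"""Seeded synthetic data generators for the three experiment types the
analysis consumes: flow-cell dissolution curves, Franz-cell permeation curves
and mucoadhesion contact-time series.

The generators are phenomenological: they sample the closed-form curves the
downstream fits assume (no hydrodynamics, no diffusion physics) and add
i.i.d. Gaussian noise on the measured signal.  Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .release import MODELS, ReleaseCurve, eval_model
from .permeation import PermeationCurve
from .adhesion import AdhesionSeries

__all__ = [
    "NoiseSpec",
    "ReleaseGenSpec",
    "PermeationGenSpec",
    "gen_release_curve",
    "gen_permeation_curve",
    "gen_adhesion_series",
    "write_curve_csv",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise: standard deviation in the units
    of the signal, plus the RNG seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def sample(self, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.zeros(n)
        return np.random.default_rng(self.seed).normal(0.0, self.sd, n)


@dataclass(frozen=True)
class ReleaseGenSpec:
    """Dissolution-curve generator spec.

    Defaults mirror the flow-cell protocol: 1-mL aliquots collected every
    2 min until the disk is exhausted (64 min plateau).  The default noise sd
    of 1.5% gives a 6-replicate standard error under 1%, the order of the
    error bars such experiments report.
    """

    model: str = "peppas_sahlin"
    params: dict = field(default_factory=lambda: {"k1": -10.912, "k2": 5.571,
                                                  "m": 0.404})
    t_end: float = 64.0
    dt: float = 2.0
    noise: NoiseSpec = NoiseSpec(sd=1.5, seed=0)
    cap_at_100: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.model not in MODELS:
            raise ValueError(f"unknown release model {self.model!r}")
        missing = [p for p in MODELS[self.model].free if p not in self.params]
        if missing:
            raise ValueError(f"{self.model}: missing parameter(s) {missing}")


def gen_release_curve(spec: ReleaseGenSpec) -> ReleaseCurve:
    """Sample a release model on the grid {dt, 2dt, ..., t_end}, add noise,
    optionally clip to [0, 100] (cap_at_100)."""
    n = int(round(spec.t_end / spec.dt))
    t = spec.dt * np.arange(1, n + 1)
    D = eval_model(spec.model, spec.params, t)
    D = D + spec.noise.sample(t.size)
    if spec.cap_at_100:
        D = np.clip(D, 0.0, 100.0)
    return ReleaseCurve(t, D)


@dataclass(frozen=True)
class PermeationGenSpec:
    """Franz-cell permeation generator spec.

    The noiseless curve is zero up to the lag time, linear with slope ``flux``
    up to ``breakdown_h`` (steady state), and thereafter saturates
    exponentially toward an asymptote with time constant ``tau_h``,
    slope-continuous at the breakdown.  Defaults replicate the ex vivo
    buccal-mucosa run: flux 0.237 mg/(cm^2 h), no lag, steady state to 2.5 h,
    hourly sampling over 6 h.  ``breakdown_h`` past ``t_end_h`` means no
    slowdown.  The short default ``tau_h`` encodes a rapid stall of
    permeation once acceptor-side sink conditions are lost; the default noise
    sd (~1.3% of the first hourly sample) matches the precision of a
    six-replicate UV assay and keeps the prefix-window flux estimator on the
    true steady-state window.
    """

    flux: float = 0.237
    lag_h: float = 0.0
    breakdown_h: float = 2.5
    t_end_h: float = 6.0
    dt_h: float = 1.0
    tau_h: float = 0.1
    noise: NoiseSpec = NoiseSpec(sd=0.003, seed=0)

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("flux must be >= 0")
        if self.lag_h < 0 or self.lag_h >= self.breakdown_h:
            raise ValueError("need 0 <= lag_h < breakdown_h")
        if self.dt_h <= 0 or self.t_end_h < self.dt_h:
            raise ValueError("need dt_h > 0 and t_end_h >= dt_h")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be > 0")

    def noiseless(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        q = np.where(t <= self.lag_h, 0.0, self.flux * (t - self.lag_h))
        past = t > self.breakdown_h
        if past.any():
            q_bd = self.flux * (self.breakdown_h - self.lag_h)
            q = np.where(
                past,
                q_bd + self.flux * self.tau_h
                * -np.expm1(-(t - self.breakdown_h) / self.tau_h),
                q,
            )
        return q


def gen_permeation_curve(spec: PermeationGenSpec) -> PermeationCurve:
    """Sample cumulative permeated amount per area on {dt_h, ..., t_end_h}."""
    n = int(round(spec.t_end_h / spec.dt_h))
    t = spec.dt_h * np.arange(1, n + 1)
    q = spec.noiseless(t) + spec.noise.sample(t.size)
    return PermeationCurve(t, q)


def gen_adhesion_series(contact_times, F_max: float, rate: float,
                        noise: NoiseSpec = NoiseSpec()) -> AdhesionSeries:
    """Monotone-plateau adhesion series: force = F_max*(1 - exp(-rate*t)).

    ``contact_times`` in minutes, strictly increasing and positive; ``F_max``
    in newtons, ``rate`` in 1/min.  The corresponding detachment mass in
    grams is back-computed from the (noisy) force.
    """
    t = np.asarray(contact_times, dtype=float)
    if t.size == 0 or np.any(t < 0) or not np.all(np.diff(t) > 0):
        raise ValueError("contact_times must be strictly increasing and "
                         "non-negative")
    if F_max < 0 or rate < 0:
        raise ValueError("F_max and rate must be >= 0")
    force = F_max * -np.expm1(-rate * t)
    force = force + noise.sample(t.size)
    return AdhesionSeries(contact_min=t, force_N=force,
                          mass_g=force * 1000.0 / 9.81)


def write_curve_csv(path, t, values, label: str, spec=None) -> None:
    """Write a two-column ``time,value`` CSV with a one-line comment header
    recording the generator spec (including its seed)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {label}: {spec!r}\n" if spec is not None else f"# {label}\n")
        fh.write("time,value\n")
        for ti, vi in zip(np.asarray(t), np.asarray(values)):
            fh.write(f"{ti:.10g},{vi:.10g}\n")
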