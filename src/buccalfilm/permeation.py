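"""Franz-cell permeation analysis: acceptor-sample bookkeeping and
steady-state flux estimation.

The cell holds mucosa between a donor (the film) and an acceptor compartment;
periodic acceptor samples are withdrawn and replaced with fresh buffer, so
the cumulative permeated amount per unit diffusion area is

    Q_n = (C_n * V_acceptor + V_sample * sum_{i<n} C_i) / A

The steady-state flux Js (mg cm^-2 h^-1) is the slope of Q(t) over the linear
regime, and the lag time its (non-negative) x-intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FranzConfig",
    "PermeationCurve",
    "FluxEstimate",
    "FluxWindowError",
    "corrected_cumulative",
    "estimate_flux",
]


@dataclass(frozen=True)
class FranzConfig:
    """Franz diffusion-cell geometry and sampling volumes.

    Defaults are the vertical cell used for buccal mucosa: 9-mm orifice,
    15-mL acceptor, 0.5-mL samples, 0.636 cm^2 diffusion area.
    """

    acceptor_volume: float = 15.0   # mL
    sample_volume: float = 0.5      # mL
    diffusion_area: float = 0.636   # cm^2
    orifice_diameter: float = 9.0   # mm

    def __post_init__(self) -> None:
        if not 0 <= self.sample_volume < self.acceptor_volume:
            raise ValueError("need 0 <= sample_volume < acceptor_volume")
        if self.diffusion_area <= 0:
            raise ValueError("diffusion_area must be > 0")
        # the stated area should match the orifice within 1%
        geometric = np.pi * (self.orifice_diameter / 20.0) ** 2
        if abs(geometric - self.diffusion_area) > 0.01 * geometric:
            raise ValueError(
                f"diffusion_area {self.diffusion_area} cm^2 inconsistent with "
                f"{self.orifice_diameter} mm orifice ({geometric:.4f} cm^2)")


@dataclass
class PermeationCurve:
    """Cumulative permeated amount per area: t in hours, Q in mg/cm^2."""

    t: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.t.shape != self.Q.shape:
            raise ValueError("t and Q must have equal length")
        if np.any(self.t <= 0) or not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be positive and strictly increasing")

    def __len__(self) -> int:
        return self.t.size


def corrected_cumulative(concentrations, times, cfg: FranzConfig = FranzConfig(),
                         replacement_correction: bool = True) -> PermeationCurve:
    """Convert acceptor concentrations (mg/mL, ordered by sampling time in
    hours) to cumulative permeated amount per area.

    ``replacement_correction`` adds back the drug removed with each prior
    sample; disable it for data already corrected upstream."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    removed = cfg.sample_volume * np.concatenate([[0.0], np.cumsum(c)[:-1]]) \
        if replacement_correction else 0.0
    q = (c * cfg.acceptor_volume + removed) / cfg.diffusion_area
    return PermeationCurve(np.asarray(times, dtype=float), q)


@dataclass
class FluxEstimate:
    """Steady-state flux regression product."""

    Js: float                 # mg cm^-2 h^-1
    lag_h: float              # max(0, x-intercept)
    window: tuple[float, float]
    r_squared: float
    n_points: int
    intercept: float = 0.0    # raw regression intercept (diagnostic)
    origin_anchored: bool = False
    diagnostics: dict = field(default_factory=dict)


class FluxWindowError(RuntimeError):
    """No candidate window met the linearity policy; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def _ols(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, q)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _prefix_candidates(t, q, min_points, r2_threshold):
    out = []
    for end in range(min_points, t.size + 1):
        slope, intercept, r2 = _ols(t[:end], q[:end])
        out.append((end, slope, intercept, r2, r2 >= r2_threshold and slope > 0))
    return out


def estimate_flux(curve: PermeationCurve, window_policy="auto",
                  r2_threshold: float = 0.99, min_points: int = 3,
                  use_origin: str = "fallback") -> FluxEstimate:
    """Estimate the steady-state flux from a cumulative permeation curve.

    ``window_policy='auto'`` selects the longest prefix window (anchored at
    the earliest samples) whose ordinary-least-squares R^2 meets
    ``r2_threshold``.  When no prefix of the samples qualifies -- typical when
    the steady state covers only the first couple of samples -- the physical
    origin (Q(0) = 0, exact by definition of a cumulative amount) is prepended
    and the search repeated (``use_origin='fallback'``; 'always'/'never'
    force either behaviour).  A manual window is given as ``(t_start,
    t_end)`` in hours.

    Negative fitted lag times are reported as 0; the raw intercept is kept in
    the estimate for diagnostics.
    """
    t, q = curve.t, curve.Q
    if window_policy != "auto":
        t0, t1 = window_policy
        mask = (t >= t0) & (t <= t1)
        tw, qw = t[mask], q[mask]
        if tw.size < min_points:
            raise FluxWindowError(
                f"manual window [{t0}, {t1}] holds {tw.size} < {min_points} points",
                {"window": (t0, t1)})
        slope, intercept, r2 = _ols(tw, qw)
        return _package(slope, intercept, r2, tw, origin=False)

    attempts = {}
    orders = {"never": [False], "always": [True], "fallback": [False, True]}
    try:
        with_origin_order = orders[use_origin]
    except KeyError:
        raise ValueError("use_origin must be 'fallback', 'always' or 'never'") \
            from None
    for with_origin in with_origin_order:
        if with_origin and t[0] > 0:
            tt = np.concatenate([[0.0], t])
            qq = np.concatenate([[0.0], q])
        else:
            tt, qq = t, q
        cands = _prefix_candidates(tt, qq, min_points, r2_threshold)
        attempts["origin" if with_origin else "samples"] = [
            {"n": n, "slope": s, "r_squared": r2} for n, s, _, r2, _ in cands]
        passing = [c for c in cands if c[4]]
        if passing:
            end, slope, intercept, r2, _ = max(passing, key=lambda c: c[0])
            return _package(slope, intercept, r2, tt[:end], origin=with_origin,
                            diagnostics=attempts)
    raise FluxWindowError(
        f"no prefix window of >= {min_points} points reached R^2 >= "
        f"{r2_threshold}", attempts)


def _package(slope, intercept, r2, tw, origin, diagnostics=None) -> FluxEstimate:
    if slope < 0:
        raise FluxWindowError("fitted slope is negative; no physical flux",
                              {"slope": slope, "intercept": intercept})
    x_int = -intercept / slope if slope > 0 else 0.0
    return FluxEstimate(Js=float(slope), lag_h=float(max(0.0, x_int)),
                        window=(float(tw[0]), float(tw[-1])),
                        r_squared=float(r2), n_points=int(tw.size),
                        intercept=float(intercept), origin_anchored=origin,
                        diagnostics=diagnostics or {})
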