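"""Mucoadhesion arithmetic: detachment mass to force of adhesion, detachment
force per unit area, and saturating-exponential plateau characterization of
force vs contact time."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "AdhesionSeries",
    "AdhesionSummary",
    "grams_to_newtons",
    "detachment_force",
    "characterize_adhesion",
]

G_STANDARD = 9.81  # m/s^2


@dataclass
class AdhesionSeries:
    """Force of adhesion vs contact time for one film/mucosa pairing."""

    contact_min: np.ndarray
    force_N: np.ndarray
    mass_g: np.ndarray | None = None
    detachment_N_per_m2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contact_min = np.asarray(self.contact_min, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.contact_min.shape != self.force_N.shape:
            raise ValueError("contact_min and force_N must have equal length")
        if not np.all(np.diff(self.contact_min) > 0):
            raise ValueError("contact_min must be strictly increasing")
        if np.any(self.contact_min < 0) or np.any(self.force_N < 0):
            raise ValueError("times and forces must be non-negative")
        for name in ("mass_g", "detachment_N_per_m2"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @classmethod
    def from_masses(cls, contact_min, mass_g, area_cm2: float | None = None
                    ) -> "AdhesionSeries":
        """Build a series from balance readings in grams; with an area the
        detachment force per m^2 is filled in too."""
        force = grams_to_newtons(np.asarray(mass_g, dtype=float))
        det = detachment_force(force, area_cm2) if area_cm2 else None
        return cls(contact_min=contact_min, force_N=force,
                   mass_g=np.asarray(mass_g, dtype=float),
                   detachment_N_per_m2=det)


def grams_to_newtons(mass_g):
    """Force of adhesion (N) from the detachment mass (g): m * g / 1000."""
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g < 0):
        raise ValueError("mass must be >= 0")
    out = mass_g * G_STANDARD / 1000.0
    return float(out) if out.ndim == 0 else out


def detachment_force(force_N, area_cm2: float):
    """Detachment force (N/m^2): force of adhesion per unit film area."""
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    force_N = np.asarray(force_N, dtype=float)
    out = force_N / (area_cm2 * 1e-4)
    return float(out) if out.ndim == 0 else out


@dataclass
class AdhesionSummary:
    """Fit of F(t) = F_max*(1 - exp(-r*t)) plus plateau diagnostics.

    ``plateau_onset_min`` is model-free: the earliest observed contact time
    whose force already reaches ``plateau_frac`` of the final force.  The
    fitted curve's own crossing of ``plateau_frac * F_max`` is kept in
    ``fit_onset_min`` / ``fit_crossing_min``; on strongly sigmoidal data the
    saturating exponential underfits the early rise and those diagnostics
    can disagree with the empirical onset (flagged via ``warnings``)."""

    f_max: float
    rate: float                # 1/min
    plateau_onset_min: float   # empirical, from the observed forces
    fit_onset_min: float       # earliest observed t with fitted F >= frac*F_max
    fit_crossing_min: float    # analytic -ln(1 - plateau_frac)/rate
    plateau_frac: float
    r_squared: float
    monotone: bool
    warnings: list[str] = field(default_factory=list)

    def predict(self, t):
        return self.f_max * -np.expm1(-self.rate * np.asarray(t, dtype=float))


def characterize_adhesion(series: AdhesionSeries, plateau_frac: float = 0.95,
                          monotone_tol: float = 0.0) -> AdhesionSummary:
    """Fit the saturating-exponential adhesion build-up and locate the
    plateau.

    The reported plateau onset is the earliest observed contact time whose
    force reaches ``plateau_frac`` of the final force; the fitted curve's
    own crossing of ``plateau_frac * F_max`` is reported alongside as a
    diagnostic.  A series whose fitted crossing falls beyond the observed
    contact times (e.g. a strictly linear build-up) is flagged: the fit sees
    no plateau.  A non-monotone series (drops larger than ``monotone_tol``)
    is flagged but still fitted.
    """
    if len(series.contact_min) < 4:
        raise ValueError("need >= 4 points to characterize adhesion")
    t, f = series.contact_min, series.force_N
    notes: list[str] = []
    monotone = bool(np.all(np.diff(f) >= -monotone_tol))
    if not monotone:
        notes.append("force series is not monotone beyond tolerance")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)

    fmax0 = float(f.max()) or 1.0
    starts = [(fmax0, 3.0 / t[len(t) // 2]), (1.2 * fmax0, 1.0 / t[-1]),
              (2.0 * fmax0, 0.1 / t[0])]
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    lambda tt, fm, r: fm * -np.expm1(-r * tt), t, f, p0=p0,
                    bounds=([0.0, 1e-9], [10.0 * fmax0, 100.0]), maxfev=20000)
            ssr = float(np.sum((f - popt[0] * -np.expm1(-popt[1] * t)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        raise RuntimeError("adhesion fit failed from every start")
    ssr, (f_max, rate) = best
    sst = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    empirical = t[f >= plateau_frac * f[-1]]
    onset = float(empirical[0]) if empirical.size else float(t[-1])
    t95 = -np.log1p(-plateau_frac) / rate
    reached = t[t >= t95]
    fit_onset = float(reached[0]) if reached.size else float(t95)
    if t95 > t[-1]:
        notes.append(f"fitted curve does not reach {plateau_frac:.0%} of "
                     f"F_max within observed contact times "
                     f"(crossing ~{t95:.0f} min)")
    if r2 < 0.9:
        notes.append(f"poor saturating-exponential fit (R^2 = {r2:.3f})")
    return AdhesionSummary(float(f_max), float(rate), onset, fit_onset,
                           float(t95), plateau_frac, float(r2), monotone,
                           notes)
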