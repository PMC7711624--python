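"""Drug-release kinetics: model evaluation, least-squares fitting, model ranking,
transport-mechanism classification and the Fickian/relaxational decomposition.

The module implements the six closed-form cumulative-release models routinely
used in dissolution analysis of polymeric matrices,

    zero order      D = k*t
    first order     D = 100*(1 - exp(-k*t))
    Higuchi         D = k*t**0.5
    Hopfenberg      D = 100*(1 - (1 - k*t)**n)      (n fixed, n=1 for films)
    power law       D = k*t**n                      (Korsmeyer-Peppas)
    Peppas-Sahlin   D = k1*t**m + k2*t**(2*m)

with D the cumulative percent of the dose released at time t (minutes).  The
Peppas-Sahlin two-term model separates a Fickian diffusional contribution
F = 1/(1 + (k2/k1)*t**m) from a Case-II relaxational/erosional contribution
R = 1 - F; the power-law exponent n classifies the transport regime
(Fickian, anomalous, Case II, Super Case II).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ReleaseCurve",
    "ReleaseModel",
    "FitResult",
    "DecompositionProfile",
    "MechanismCall",
    "MODELS",
    "eval_model",
    "fit_model",
    "rank_models",
    "decompose",
    "classify_mechanism",
    "m_from_aspect_ratio",
    "ASPECT_RATIO_M_TABLE",
]


# --------------------------------------------------------------------------- #
# containers


@dataclass
class ReleaseCurve:
    """Cumulative release time series: t in minutes, D in percent of dose."""

    t: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.t.shape != self.D.shape or self.t.size < 3:
            raise ValueError("t and D must have equal length >= 3")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.t <= 0):
            raise ValueError("t must be positive")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("D must be finite")

    def __len__(self) -> int:
        return self.t.size


def _zero_order(t, k):
    return k * t


def _first_order(t, k):
    # implemented exactly as printed; k is unconstrained in the fit and a
    # negative estimate is reported as returned (flagged downstream)
    return 100.0 * (1.0 - np.exp(-k * t))


def _higuchi(t, k):
    return k * np.sqrt(t)


def _hopfenberg(t, k, n):
    return 100.0 * (1.0 - (1.0 - k * t) ** n)


def _power_law(t, k, n):
    return k * np.power(t, n)


def _peppas_sahlin(t, k1, k2, m):
    tm = np.power(t, m)
    return k1 * tm + k2 * tm * tm


@dataclass(frozen=True)
class ReleaseModel:
    """A named closed-form release model with free and fixed parameters."""

    name: str
    func: Callable
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)

    def with_fixed(self, **fixed) -> "ReleaseModel":
        """Return a copy with additional parameters held fixed (e.g. m for
        Peppas-Sahlin when m comes from the aspect-ratio chart)."""
        free = tuple(p for p in self.free if p not in fixed)
        merged = {**self.fixed, **fixed}
        return ReleaseModel(self.name, self.func, free, merged)

    def with_free(self, *names: str) -> "ReleaseModel":
        """Release previously fixed parameters back into the fit."""
        fixed = {p: v for p, v in self.fixed.items() if p not in names}
        free = tuple(dict.fromkeys([*self.free, *names]))
        return ReleaseModel(self.name, self.func, free, fixed)

    @property
    def all_params(self) -> tuple[str, ...]:
        return tuple([*self.free, *self.fixed])

    def __call__(self, t, params: dict) -> np.ndarray:
        missing = [p for p in self.all_params if p not in {**self.fixed, **params}]
        if missing:
            raise ValueError(f"{self.name}: missing parameter(s) {missing}")
        full = {**self.fixed, **params}
        t = np.asarray(t, dtype=float)
        return np.asarray(self.func(t, *(full[p] for p in self._order())), dtype=float)

    def _order(self) -> tuple[str, ...]:
        import inspect

        return tuple(inspect.signature(self.func).parameters)[1:]


MODELS: dict[str, ReleaseModel] = {
    "zero_order": ReleaseModel("zero_order", _zero_order, ("k",)),
    "first_order": ReleaseModel("first_order", _first_order, ("k",)),
    "higuchi": ReleaseModel("higuchi", _higuchi, ("k",)),
    # n fixed at 1: the dosage form is a film (slab geometry)
    "hopfenberg": ReleaseModel("hopfenberg", _hopfenberg, ("k",), {"n": 1.0}),
    "power_law": ReleaseModel("power_law", _power_law, ("k", "n")),
    "peppas_sahlin": ReleaseModel("peppas_sahlin", _peppas_sahlin, ("k1", "k2", "m")),
}


def _resolve(model: "ReleaseModel | str") -> ReleaseModel:
    if isinstance(model, ReleaseModel):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown release model {model!r}; known: {sorted(MODELS)}"
        ) from None


def eval_model(model: "ReleaseModel | str", params: dict, t) -> np.ndarray:
    """Evaluate a release model at times ``t`` (minutes), returning percent
    released.  ``params`` must supply every free parameter of the model."""
    return _resolve(model)(t, params)


# --------------------------------------------------------------------------- #
# fitting


@dataclass
class FitResult:
    """One fitted model: estimates, standard errors and goodness of fit.

    ``red_chisq`` is the reduced chi-square SSR/(N - p), the convention of the
    dissolution-fitting software this mirrors; ``r_squared`` is 1 - SSR/SST.
    """

    model: str
    params: dict
    stderr: dict
    r_squared: float
    red_chisq: float
    n_points: int
    fit_range: str
    success: bool = True
    message: str = ""
    flags: list[str] = field(default_factory=list)

    def predict(self, t) -> np.ndarray:
        return eval_model(self.model, self.params, t)

    @classmethod
    def failure(cls, model: str, fit_range: str, message: str) -> "FitResult":
        return cls(model, {}, {}, float("nan"), float("nan"), 0, fit_range,
                   success=False, message=message)


def _select_range(curve: ReleaseCurve, fit_range) -> tuple[np.ndarray, np.ndarray, str]:
    """Apply a named fit-range preset or an explicit (tmin, tmax) pair.

    ``to_plateau`` keeps points up to (and including) the first time the curve
    is within 1% of its final value -- the release has effectively plateaued;
    ``first_60pct`` keeps points with D <= 60%, the conventional validity range
    of the power-law family.
    """
    t, D = curve.t, curve.D
    if fit_range in (None, "full"):
        return t, D, "full"
    if fit_range == "to_plateau":
        plateau = D[-1]
        hit = np.nonzero(D >= plateau - 0.01 * abs(plateau))[0]
        end = hit[0] if hit.size else len(D) - 1
        return t[: end + 1], D[: end + 1], "to_plateau"
    if fit_range == "first_60pct":
        mask = D <= 60.0
        return t[mask], D[mask], "first_60pct"
    tmin, tmax = fit_range
    mask = (t >= tmin) & (t <= tmax)
    return t[mask], D[mask], f"[{tmin},{tmax}]"


def _initial_guesses(model: ReleaseModel, t: np.ndarray, D: np.ndarray) -> list[dict]:
    """Heuristic multi-start initial values.

    Power-law family seeds come from a log-log linearization; the two-term
    Peppas-Sahlin model is seeded by variable projection: for each m on a grid
    (k1, k2) solve in closed form, keep the best few m.
    """
    name = model.name
    pos = (t > 0) & (D > 0)
    starts: list[dict] = []
    if name == "zero_order":
        starts = [{"k": float(np.median(D[pos] / t[pos])) if pos.any() else 1.0}]
    elif name == "higuchi":
        starts = [{"k": float(np.median(D[pos] / np.sqrt(t[pos]))) if pos.any() else 1.0}]
    elif name == "first_order":
        frac = np.clip(D / 100.0, None, 0.999)
        ok = frac > 0
        if ok.any():
            k0 = float(np.median(-np.log1p(-frac[ok]) / t[ok]))
        else:
            k0 = 0.02
        starts = [{"k": k0}, {"k": 0.01}, {"k": 0.1}]
    elif name == "hopfenberg":
        n = model.fixed.get("n", 1.0)
        if pos.any():
            inner = np.clip(1.0 - D[pos] / 100.0, 1e-9, None)
            k0 = float(np.median((1.0 - inner ** (1.0 / n)) / t[pos]))
        else:
            k0 = 1.0 / (2.0 * t[-1])
        starts = [{"k": k0}, {"k": 0.5 / t[-1]}]
    elif name == "power_law":
        if pos.sum() >= 2:
            b, a = np.polyfit(np.log(t[pos]), np.log(D[pos]), 1)
            starts.append({"k": float(np.exp(a)), "n": float(b)})
        starts += [{"k": 1.0, "n": 1.0}, {"k": 10.0, "n": 0.5}]
    elif name == "peppas_sahlin":
        if "m" in model.free:
            grid = np.linspace(0.05, 1.5, 59)
        else:
            grid = np.array([model.fixed["m"]])
        scored = []
        for m in grid:
            tm = np.power(t, m)
            X = np.column_stack([tm, tm * tm])
            coef, *_ = np.linalg.lstsq(X, D, rcond=None)
            ssr = float(np.sum((D - X @ coef) ** 2))
            scored.append((ssr, {"k1": float(coef[0]), "k2": float(coef[1]),
                                 "m": float(m)}))
        scored.sort(key=lambda s: s[0])
        starts = [p for _, p in scored[:3]]
    if not starts:
        starts = [{p: 1.0 for p in model.free}]
    return [{p: s[p] for p in model.free if p in s} or {p: 1.0 for p in model.free}
            for s in starts]


def fit_model(curve: ReleaseCurve, model: "ReleaseModel | str",
              fit_range="to_plateau") -> FitResult:
    """Least-squares fit of one release model to a cumulative-release curve.

    Returns a :class:`FitResult`; a fit that fails to converge from every
    start is returned with ``success=False`` and a message, never silent NaNs.
    """
    model = _resolve(model)
    t, D, range_label = _select_range(curve, fit_range)
    p = len(model.free)
    if t.size < p + 1:
        return FitResult.failure(model.name, range_label,
                                 f"needs >= {p + 1} points, got {t.size}")

    def residual_func(tt, *theta):
        return model(tt, dict(zip(model.free, theta)))

    best = None
    errors: list[str] = []
    for start in _initial_guesses(model, t, D):
        p0 = [start[name] for name in model.free]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(residual_func, t, D, p0=p0,
                                                maxfev=20000)
            ssr = float(np.sum((D - residual_func(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        except (RuntimeError, ValueError, TypeError) as exc:  # non-convergence
            errors.append(str(exc))
            continue
    if best is None:
        return FitResult.failure(model.name, range_label,
                                 "no start converged: " + "; ".join(errors[:2]))

    ssr, popt, pcov = best
    sst = float(np.sum((D - D.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    red_chisq = ssr / (t.size - p) if t.size > p else float("nan")
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    params = dict(zip(model.free, map(float, popt)))
    result = FitResult(model.name, params, dict(zip(model.free, map(float, perr))),
                       r2, red_chisq, int(t.size), range_label)
    if model.name == "first_order" and params.get("k", 0.0) < 0:
        result.flags.append("negative first-order rate constant: the printed "
                            "equation then predicts negative release")
    return result


def rank_models(curve: ReleaseCurve, models: Sequence["ReleaseModel | str"] | None = None,
                fit_range="to_plateau") -> list[FitResult]:
    """Fit several models and rank them: descending R-squared, ties broken by
    ascending reduced chi-square.  Individual fit failures are recorded in the
    returned list (at the end), not raised."""
    if models is None:
        models = list(MODELS)
    results = [fit_model(curve, m, fit_range) for m in models]
    ok = [r for r in results if r.success]
    bad = [r for r in results if not r.success]
    ok.sort(key=lambda r: (-r.r_squared, r.red_chisq))
    return ok + bad


# --------------------------------------------------------------------------- #
# mechanism


@dataclass
class DecompositionProfile:
    """Fickian (F) and relaxational (R) fractional contributions over time.

    F = 1/(1 + (k2/k1)*t**m), R = 1 - F, R/F = (k2/k1)*t**m.  With a negative
    fitted k1 the printed formulas can leave [0, 1]; such points are flagged,
    not clipped."""

    t: np.ndarray
    F: np.ndarray
    R: np.ndarray
    R_over_F: np.ndarray
    out_of_range: np.ndarray  # boolean mask where F is not in [0, 1]

    @property
    def any_out_of_range(self) -> bool:
        return bool(self.out_of_range.any())


def decompose(k1: float, k2: float, m: float, times) -> DecompositionProfile:
    """Split release into Fickian and relaxational fractions at each time."""
    if k1 == 0:
        raise ValueError("k1 must be nonzero: F is undefined for k1 = 0")
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    ratio = (k2 / k1) * np.power(t, m)
    F = 1.0 / (1.0 + ratio)
    R = 1.0 - F
    out = (F < 0.0) | (F > 1.0)
    if out.any():
        warnings.warn("Fickian fraction outside [0, 1] at some times "
                      "(negative k1/k2 ratio); values reported as computed",
                      RuntimeWarning, stacklevel=2)
    return DecompositionProfile(t, F, R, ratio, out)


@dataclass(frozen=True)
class MechanismCall:
    n: float
    geometry: str
    mechanism: str


#: (fickian_upper, case_ii_n) breakpoints of the release exponent by geometry
GEOMETRY_THRESHOLDS: dict[str, tuple[float, float]] = {
    "film": (0.5, 1.0),
    "cylinder": (0.45, 0.89),
    "sphere": (0.43, 0.85),
}


def classify_mechanism(n: float, geometry: str = "film",
                       case_ii_tol: float = 0.02) -> MechanismCall:
    """Classify the transport mechanism from the power-law exponent n.

    For a film: n <= 0.5 Fickian; 0.5 < n < 1 anomalous; n = 1 (within
    ``case_ii_tol``) Case II; n > 1 Super Case II.  The boundary n = 0.5 is
    assigned to Fickian by convention."""
    if not np.isfinite(n):
        raise ValueError("n must be finite")
    try:
        fickian_upper, case_ii = GEOMETRY_THRESHOLDS[geometry]
    except KeyError:
        raise ValueError(f"unknown geometry {geometry!r}; "
                         f"known: {sorted(GEOMETRY_THRESHOLDS)}") from None
    if n <= fickian_upper:
        label = "Fickian"
    elif abs(n - case_ii) <= case_ii_tol:
        label = "Case II"
    elif n < case_ii:
        label = "anomalous"
    else:
        label = "Super Case II"
    return MechanismCall(float(n), geometry, label)


# --------------------------------------------------------------------------- #
# pure-Fickian exponent m from disk aspect ratio

#: Approximate piecewise-linear digitization (in log aspect ratio) of the
#: chart giving the pure-Fickian diffusional exponent m of a disk as a
#: function of its aspect ratio 2a/l = diameter/thickness.  Anchored at
#: (13.9, 0.415); m tends to the slab limit 0.5 as the ratio grows without
#: bound (and as the disk degenerates the other way).
ASPECT_RATIO_M_TABLE: tuple[tuple[float, float], ...] = (
    (0.1, 0.500),
    (1.0, 0.457),
    (5.0, 0.432),
    (10.0, 0.420),
    (13.9, 0.415),
    (17.0, 0.414),
    (25.0, 0.420),
    (50.0, 0.440),
    (100.0, 0.462),
    (1000.0, 0.496),
)


def m_from_aspect_ratio(diameter: float, thickness: float,
                        lookup_table: Sequence[tuple[float, float]] | None = None
                        ) -> float:
    """Pure-Fickian exponent m for a disk of given diameter and thickness
    (same units), by interpolation of an aspect-ratio chart.

    The aspect ratio is diameter/thickness; interpolation is linear in
    log(aspect ratio).  Ratios outside the table are clamped with a warning."""
    if thickness <= 0 or diameter <= 0:
        raise ValueError("diameter and thickness must be positive")
    table = sorted(lookup_table if lookup_table is not None else ASPECT_RATIO_M_TABLE)
    ratio = diameter / thickness
    aspects = np.array([a for a, _ in table], dtype=float)
    ms = np.array([m for _, m in table], dtype=float)
    if len(table) == 1:
        warnings.warn("single-entry lookup table: returning its m for any "
                      "aspect ratio", RuntimeWarning, stacklevel=2)
        return float(ms[0])
    if ratio < aspects[0] or ratio > aspects[-1]:
        warnings.warn(f"aspect ratio {ratio:.3g} outside table range "
                      f"[{aspects[0]:g}, {aspects[-1]:g}]; clamped",
                      RuntimeWarning, stacklevel=2)
    return float(np.interp(np.log(ratio), np.log(aspects), ms))
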