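"""Film quality-control calculations: drug loading, dose scaling by area,
UV calibration-curve inversion and replicate uniformity summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilmSpec",
    "CalibrationCurve",
    "drug_loading",
    "dose_from_area",
    "conc_from_absorbance",
    "uniformity_summary",
]


@dataclass(frozen=True)
class FilmSpec:
    """Characterized film geometry and loading.

    Defaults describe the ropinirole-loaded matrix film: an 8.04 cm^2 sheet
    of 1.03 g cut into small disks of 0.6 cm diameter.  The default disk
    area, pi*(0.3 cm)^2 = 0.2827 cm^2, is computed from the diameter; the
    characterization tables round it to 0.282 cm^2, an 0.3% difference kept
    in mind by downstream tolerances.
    """

    total_area: float = 8.04        # cm^2
    total_mass_g: float = 1.03      # g
    thickness_um: float = 793.0     # um
    disk_area: float = 0.2827       # cm^2
    disk_mass_mg: float = 30.94     # mg
    dl_pct: float = 7.40            # % w/w
    disk_dose_mg: float = 2.29      # mg

    def __post_init__(self) -> None:
        if min(self.total_area, self.total_mass_g, self.thickness_um,
               self.disk_area, self.disk_mass_mg) <= 0:
            raise ValueError("film dimensions and masses must be > 0")
        if self.disk_area > self.total_area:
            raise ValueError("disk_area cannot exceed total_area")
        # loading consistency: dose ~ dl_pct * mass / 100 (within ~5%)
        implied = self.dl_pct * self.disk_mass_mg / 100.0
        if self.disk_dose_mg > 0 and abs(implied - self.disk_dose_mg) \
                > 0.05 * self.disk_dose_mg:
            raise ValueError(
                f"disk_dose_mg {self.disk_dose_mg} inconsistent with "
                f"dl_pct * disk_mass ({implied:.3f} mg)")


def drug_loading(drug_mg: float, sample_mg: float) -> float:
    """Drug loading in % w/w: 100 * drug mass / sample mass."""
    if sample_mg <= 0:
        raise ValueError("sample mass must be > 0")
    if drug_mg < 0:
        raise ValueError("drug mass must be >= 0")
    return 100.0 * drug_mg / sample_mg


def dose_from_area(area_cm2: float, film: FilmSpec) -> float:
    """Dose (mg) carried by a piece of film of the given area, scaled
    proportionally from the characterized disk."""
    if area_cm2 < 0:
        raise ValueError("area must be >= 0")
    if area_cm2 > film.total_area:
        raise ValueError(f"area {area_cm2} cm^2 exceeds the film "
                         f"({film.total_area} cm^2)")
    return film.disk_dose_mg * area_cm2 / film.disk_area


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear UV calibration A = slope * c + intercept with its validity
    range in mg/mL.  Defaults: the drug-content assay line."""

    slope: float = 30.81143       # absorbance per mg/mL
    intercept: float = -0.01213   # absorbance
    conc_range: tuple[float, float] = (0.005, 0.100)
    r_squared: float = 0.9999

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.conc_range[0] > self.conc_range[1]:
            raise ValueError("conc_range bounds must be ordered")

    def absorbance(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def in_range(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return (c >= self.conc_range[0]) & (c <= self.conc_range[1])


#: calibration line of the dissolution (release-medium) assay
RELEASE_CALIBRATION = CalibrationCurve(slope=30.92, intercept=-4.93e-3,
                                       conc_range=(0.005, 0.025),
                                       r_squared=0.9996)


def conc_from_absorbance(absorbance, cal: CalibrationCurve = CalibrationCurve()):
    """Invert the calibration line: c = (A - intercept)/slope, in mg/mL.

    Concentrations outside the validated range are returned as computed but
    flagged with a warning."""
    a = np.asarray(absorbance, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("absorbance must be finite")
    c = (a - cal.intercept) / cal.slope
    ok = cal.in_range(c)
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} concentration(s) outside the validated "
            f"range {cal.conc_range} mg/mL", RuntimeWarning, stacklevel=2)
    return float(c) if c.ndim == 0 else c


def uniformity_summary(replicates: dict) -> pd.DataFrame:
    """Mean +/- standard error table for replicate QC measurements.

    ``replicates`` maps quantity name -> sequence of replicate values; the
    summary has columns mean, se (sd/sqrt(n), NaN for a single replicate)
    and n."""
    rows = {}
    for name, values in replicates.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"{name}: no replicates")
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows[name] = {"mean": float(v.mean()), "se": se, "n": int(v.size)}
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "se", "n"]]
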