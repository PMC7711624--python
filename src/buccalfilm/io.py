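"""CSV readers/writers for the study's tabular formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .adhesion import AdhesionSeries
from .permeation import FranzConfig, PermeationCurve, corrected_cumulative
from .release import DecompositionProfile, FitResult, ReleaseCurve

__all__ = [
    "read_release_csv",
    "read_permeation_csv",
    "read_adhesion_csv",
    "fit_results_frame",
    "decomposition_frame",
]


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_release_csv(path) -> ReleaseCurve:
    """Read a ``time_min,released_pct`` (or generic two-column) CSV."""
    df = _read(path)
    t_col = "time_min" if "time_min" in df else df.columns[0]
    d_col = "released_pct" if "released_pct" in df else df.columns[1]
    return ReleaseCurve(df[t_col].to_numpy(), df[d_col].to_numpy())


def read_permeation_csv(path, cfg: FranzConfig = FranzConfig()) -> PermeationCurve:
    """Read a permeation CSV: either cumulative ``time_h,q_mg_per_cm2`` or
    raw acceptor samples ``time_h,conc_mg_per_ml`` (converted with the
    sampling-replacement correction)."""
    df = _read(path)
    t_col = "time_h" if "time_h" in df else df.columns[0]
    if "conc_mg_per_ml" in df:
        return corrected_cumulative(df["conc_mg_per_ml"].to_numpy(),
                                    df[t_col].to_numpy(), cfg)
    q_col = "q_mg_per_cm2" if "q_mg_per_cm2" in df else df.columns[1]
    return PermeationCurve(df[t_col].to_numpy(), df[q_col].to_numpy())


def read_adhesion_csv(path, area_cm2: float | None = None) -> AdhesionSeries:
    """Read ``contact_min,mass_g`` (or ``contact_min,force_N``)."""
    df = _read(path)
    t_col = "contact_min" if "contact_min" in df else df.columns[0]
    if "force_N" in df:
        return AdhesionSeries(df[t_col].to_numpy(), df["force_N"].to_numpy())
    m_col = "mass_g" if "mass_g" in df else df.columns[1]
    return AdhesionSeries.from_masses(df[t_col].to_numpy(),
                                      df[m_col].to_numpy(), area_cm2)


def fit_results_frame(results: list[FitResult]) -> pd.DataFrame:
    """Model-comparison table (one row per fitted model), ready for CSV."""
    rows = []
    for r in results:
        row = {"model": r.model, "r_squared": r.r_squared,
               "red_chisq": r.red_chisq, "n_points": r.n_points,
               "fit_range": r.fit_range, "success": r.success,
               "message": r.message}
        for p, v in r.params.items():
            row[p] = v
            row[f"{p}_se"] = r.stderr.get(p)
        rows.append(row)
    return pd.DataFrame(rows)


def decomposition_frame(prof: DecompositionProfile) -> pd.DataFrame:
    return pd.DataFrame({"time_min": prof.t, "F": prof.F, "R": prof.R,
                         "R_over_F": prof.R_over_F,
                         "out_of_range": prof.out_of_range})


def write_with_comment(df: pd.DataFrame, path, comment: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)
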