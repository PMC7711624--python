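"""Mucoadhesion and film QC: convert the published detachment masses to
forces and per-area detachment forces, characterize the plateau of the
published and synthetic adhesion series, and summarize the film's loading
arithmetic.

Writes results/adhesion_table.csv and results/qc.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from buccalfilm.adhesion import (
    AdhesionSeries,
    characterize_adhesion,
    detachment_force,
    grams_to_newtons,
)
from buccalfilm.config import default_study_config
from buccalfilm.io import write_with_comment
from buccalfilm.qc import FilmSpec, dose_from_area, drug_loading
from buccalfilm.release import m_from_aspect_ratio
from buccalfilm.synthetic import gen_adhesion_series

OUT = Path("results")

# published force-of-adhesion series (N) by contact time (min)
CONTACT_MIN = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0])
FORCE_N = np.array([0.069, 0.128, 0.196, 0.530, 0.844, 0.862])


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = default_study_config(seed)
    film = cfg.film.to_spec()

    mass_g = FORCE_N * 1000.0 / 9.81
    table = pd.DataFrame({
        "contact_min": CONTACT_MIN,
        "mass_g": mass_g,
        "force_N": grams_to_newtons(mass_g),
        "detachment_N_per_m2": detachment_force(grams_to_newtons(mass_g),
                                                film.disk_area),
    })
    write_with_comment(table, OUT / "adhesion_table.csv",
                       f"published forces normalized over {film.disk_area} cm^2")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    summary = characterize_adhesion(AdhesionSeries(CONTACT_MIN, FORCE_N))
    print(f"\npublished series: plateau onset (empirical, 95% of final force) "
          f"= {summary.plateau_onset_min:g} min")
    for w in summary.warnings:
        print(f"  note: {w}")

    synth = gen_adhesion_series(list(cfg.adhesion.contact_times),
                                cfg.adhesion.f_max, cfg.adhesion.rate,
                                cfg.adhesion.noise.to_spec())
    synth_summary = characterize_adhesion(synth)
    print(f"synthetic exponential series: F_max = {synth_summary.f_max:.3f} N, "
          f"rate = {synth_summary.rate:.3f}/min, fitted 95% crossing = "
          f"{synth_summary.fit_crossing_min:.0f} min")

    qc = {
        "drug_loading_pct": drug_loading(film.disk_dose_mg, film.disk_mass_mg),
        "disk_dose_mg": dose_from_area(film.disk_area, film),
        "dose_per_cm2_mg": film.disk_dose_mg / film.disk_area,
        "detachment_force_50min_N_per_m2":
            float(table["detachment_N_per_m2"].iloc[-1]),
        "m_from_aspect_ratio": m_from_aspect_ratio(
            cfg.film.release_disk_diameter_mm, film.thickness_um / 1000.0),
    }
    (OUT / "qc.json").write_text(json.dumps(qc, indent=2) + "\n")
    print("\nQC:", json.dumps(qc, indent=2))


if __name__ == "__main__":
    main()
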