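"""Generate the three synthetic datasets the study analyses: a flow-cell
dissolution curve, a Franz-cell permeation curve and a mucoadhesion
contact-time series, all at the replication defaults with seeded noise.

Writes results/data/{release,permeation,adhesion}.csv.
"""

from pathlib import Path

from buccalfilm.config import default_study_config
from buccalfilm.synthetic import (
    gen_adhesion_series,
    gen_permeation_curve,
    gen_release_curve,
    write_curve_csv,
)

OUT = Path("results/data")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_study_config(seed)

    release = gen_release_curve(cfg.release.to_spec())
    write_curve_csv(OUT / "release.csv", release.t, release.D,
                    "cumulative release (%)", cfg.release.to_spec())
    print(f"release: {len(release)} points every {cfg.release.dt:g} min, "
          f"final {release.D[-1]:.1f}% at {release.t[-1]:g} min")

    permeation = gen_permeation_curve(cfg.permeation.to_spec())
    write_curve_csv(OUT / "permeation.csv", permeation.t, permeation.Q,
                    "cumulative permeation (mg/cm^2)", cfg.permeation.to_spec())
    print(f"permeation: hourly to {permeation.t[-1]:g} h, "
          f"Q(2 h) = {permeation.Q[1]:.3f} mg/cm^2 (steady state), "
          f"Q(6 h) = {permeation.Q[-1]:.3f} (post-breakdown plateau)")

    adhesion = gen_adhesion_series(list(cfg.adhesion.contact_times),
                                   cfg.adhesion.f_max, cfg.adhesion.rate,
                                   cfg.adhesion.noise.to_spec())
    write_curve_csv(OUT / "adhesion.csv", adhesion.contact_min,
                    adhesion.force_N, "force of adhesion (N)")
    print(f"adhesion: {adhesion.contact_min.size} contact times, force "
          f"{adhesion.force_N[0]:.3f} -> {adhesion.force_N[-1]:.3f} N")
    print(f"wrote 3 CSVs to {OUT}/")


if __name__ == "__main__":
    main()
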