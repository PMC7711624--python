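"""Bridge the film's mucosal input to oral prolonged-release dosing at steady
state: compute Ke, Cp_ss, the elimination rate D_E and the absorption rate
D_A for the 4-mg and 8-mg oral references, compare them with the measured
flux, and size the film area that would match each dose.

Writes results/equivalence.json and results/equivalence.txt.
"""

import json
from pathlib import Path

from buccalfilm.config import default_study_config
from buccalfilm.permeation import estimate_flux
from buccalfilm.pipeline import _jsonable
from buccalfilm.pk import equivalence_report
from buccalfilm.synthetic import gen_permeation_curve

OUT = Path("results")


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = default_study_config(seed)
    flux = estimate_flux(gen_permeation_curve(cfg.permeation.to_spec()))
    pk = cfg.pk.to_spec()

    reports = {dose: equivalence_report(pk, dose, flux, cfg.film.disk_area)
               for dose in cfg.pk.oral_doses}
    for dose, rep in reports.items():
        print(rep.render_text())
        print()

    (OUT / "equivalence.json").write_text(json.dumps(
        {f"{dose:g}mg": _jsonable(rep) for dose, rep in reports.items()},
        indent=2) + "\n")
    (OUT / "equivalence.txt").write_text(
        "\n\n".join(rep.render_text() for rep in reports.values()) + "\n")
    print(f"wrote equivalence report to {OUT}/equivalence.[json|txt]")


if __name__ == "__main__":
    main()
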