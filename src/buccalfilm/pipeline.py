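"""End-to-end study orchestration: generate or load the three datasets, fit
and rank the release models, decompose the mechanism, estimate the
steady-state flux, summarize adhesion/QC and emit the film-vs-oral
equivalence report -- deterministically, from one configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__, adhesion, io, permeation, pk, qc, release, synthetic
from .config import StudyConfig

__all__ = ["run_study", "StudyReport"]


@dataclasses.dataclass
class StageResult:
    name: str
    status: str           # "ok" | "skipped" | "failed"
    output: object = None
    message: str = ""


@dataclasses.dataclass
class StudyReport:
    stages: dict
    manifest: dict

    def __getitem__(self, name: str) -> StageResult:
        return self.stages[name]

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.stages.values())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_study(cfg: StudyConfig, write: bool = True) -> StudyReport:
    """Run every stage of the study; stage failures are recorded and do not
    stop stages that don't depend on them.  With ``write``, all tables,
    reports and a manifest land in ``cfg.outdir``."""
    stages: dict[str, StageResult] = {}
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- data ---------------------------------------------------------- #
    release_curve = permeation_curve = adhesion_series = None
    try:
        if cfg.release.path:
            release_curve = io.read_release_csv(cfg.release.path)
        else:
            release_curve = synthetic.gen_release_curve(cfg.release.to_spec())
        stages["release_data"] = StageResult("release_data", "ok")
    except Exception as exc:
        stages["release_data"] = StageResult("release_data", "failed",
                                             message=str(exc))
    try:
        if cfg.permeation.path:
            permeation_curve = io.read_permeation_csv(cfg.permeation.path,
                                                      cfg.franz.to_spec())
        else:
            permeation_curve = synthetic.gen_permeation_curve(
                cfg.permeation.to_spec())
        stages["permeation_data"] = StageResult("permeation_data", "ok")
    except Exception as exc:
        stages["permeation_data"] = StageResult("permeation_data", "failed",
                                                message=str(exc))
    try:
        if cfg.adhesion.path:
            adhesion_series = io.read_adhesion_csv(cfg.adhesion.path,
                                                   cfg.film.disk_area)
        else:
            adhesion_series = synthetic.gen_adhesion_series(
                list(cfg.adhesion.contact_times), cfg.adhesion.f_max,
                cfg.adhesion.rate, cfg.adhesion.noise.to_spec())
            adhesion_series.detachment_N_per_m2 = adhesion.detachment_force(
                adhesion_series.force_N, cfg.film.disk_area)
        stages["adhesion_data"] = StageResult("adhesion_data", "ok")
    except Exception as exc:
        stages["adhesion_data"] = StageResult("adhesion_data", "failed",
                                              message=str(exc))

    # --- release fitting and mechanism --------------------------------- #
    ranked = None
    if not cfg.fit.models:
        stages["release_fits"] = StageResult("release_fits", "skipped",
                                             message="empty model list")
    elif release_curve is None:
        stages["release_fits"] = StageResult("release_fits", "failed",
                                             message="no release data")
    else:
        try:
            ranked = release.rank_models(release_curve, list(cfg.fit.models),
                                         cfg.fit.fit_range)
            stages["release_fits"] = StageResult("release_fits", "ok", ranked)
        except Exception as exc:
            stages["release_fits"] = StageResult("release_fits", "failed",
                                                 message=str(exc))

    if ranked:
        by_name = {r.model: r for r in ranked if r.success}
        if "power_law" in by_name:
            n_hat = by_name["power_law"].params["n"]
            stages["mechanism"] = StageResult(
                "mechanism", "ok",
                release.classify_mechanism(n_hat, cfg.fit.geometry))
        if "peppas_sahlin" in by_name:
            ps = by_name["peppas_sahlin"].params
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prof = release.decompose(ps["k1"], ps["k2"], ps["m"],
                                         release_curve.t)
            stages["decomposition"] = StageResult("decomposition", "ok", prof)

    # --- flux ----------------------------------------------------------- #
    flux = None
    if permeation_curve is not None:
        try:
            flux = permeation.estimate_flux(
                permeation_curve, r2_threshold=cfg.fit.flux_r2_threshold)
            stages["flux"] = StageResult("flux", "ok", flux)
        except Exception as exc:
            stages["flux"] = StageResult("flux", "failed", message=str(exc))
    else:
        stages["flux"] = StageResult("flux", "failed",
                                     message="no permeation data")

    # --- adhesion / QC --------------------------------------------------- #
    if adhesion_series is not None:
        try:
            summary = adhesion.characterize_adhesion(adhesion_series)
            stages["adhesion"] = StageResult("adhesion", "ok", summary)
        except Exception as exc:
            stages["adhesion"] = StageResult("adhesion", "failed",
                                             message=str(exc))
    film = cfg.film.to_spec()
    stages["qc"] = StageResult("qc", "ok", {
        "drug_loading_pct": qc.drug_loading(film.disk_dose_mg,
                                            film.disk_mass_mg),
        "dose_per_cm2_mg": film.disk_dose_mg / film.disk_area,
        "disk_dose_mg": qc.dose_from_area(film.disk_area, film),
        "aspect_ratio": cfg.film.release_disk_diameter_mm
        / (film.thickness_um / 1000.0),
        "m_from_aspect_ratio": release.m_from_aspect_ratio(
            cfg.film.release_disk_diameter_mm, film.thickness_um / 1000.0),
    })

    # --- PK bridge -------------------------------------------------------- #
    pk_params = cfg.pk.to_spec()
    if flux is not None:
        try:
            reports = {dose: pk.equivalence_report(
                pk_params, dose, flux, film.disk_area,
                cfg.pk.area_multiplier) for dose in cfg.pk.oral_doses}
            stages["equivalence"] = StageResult("equivalence", "ok", reports)
        except Exception as exc:
            stages["equivalence"] = StageResult("equivalence", "failed",
                                                message=str(exc))
    else:
        # the PK chain itself does not need flux data
        dose = cfg.pk.oral_doses[0] if cfg.pk.oral_doses else 0.0
        cp = pk.css_for_dose(pk_params, dose)
        de = pk.elimination_rate(cp, pk_params.ke)
        stages["equivalence"] = StageResult(
            "equivalence", "ok",
            {"pk_only": {"dose": dose, "cp_ss": cp, "ke": pk_params.ke,
                         "d_e": de,
                         "d_a": pk.absorption_rate(de, pk_params.v_d)}},
            message="flux unavailable; PK chain only")

    manifest = {
        "package": "buccalfilm",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "stages": {k: s.status for k, s in stages.items()},
    }
    report = StudyReport(stages, manifest)
    if write:
        _write_outputs(report, outdir, release_curve, permeation_curve,
                       adhesion_series)
    return report


def _write_outputs(report, outdir, release_curve, permeation_curve,
                   adhesion_series) -> None:
    import pandas as pd

    stages = report.stages
    if release_curve is not None:
        io.write_with_comment(
            pd.DataFrame({"time_min": release_curve.t,
                          "released_pct": release_curve.D}),
            outdir / "release_curve.csv", "cumulative release (synthetic/loaded)")
    if stages.get("release_fits") and stages["release_fits"].output:
        io.write_with_comment(io.fit_results_frame(stages["release_fits"].output),
                              outdir / "release_fits.csv",
                              "model comparison, ranked by R^2")
    if stages.get("decomposition"):
        io.write_with_comment(io.decomposition_frame(stages["decomposition"].output),
                              outdir / "decomposition.csv",
                              "Fickian/relaxational split of the best "
                              "two-term fit")
    if permeation_curve is not None:
        io.write_with_comment(
            pd.DataFrame({"time_h": permeation_curve.t,
                          "q_mg_per_cm2": permeation_curve.Q}),
            outdir / "permeation_curve.csv", "cumulative permeation")
    for name in ("flux", "adhesion", "qc", "mechanism"):
        if stages.get(name) and stages[name].output is not None:
            (outdir / f"{name}.json").write_text(
                json.dumps(_jsonable(stages[name].output), indent=2))
    if stages.get("equivalence") and stages["equivalence"].output:
        out = stages["equivalence"].output
        (outdir / "equivalence.json").write_text(
            json.dumps({str(k): _jsonable(v) for k, v in out.items()},
                       indent=2))
        text = [v.render_text() for v in out.values()
                if hasattr(v, "render_text")]
        if text:
            (outdir / "equivalence.txt").write_text("\n\n".join(text) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
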