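"""Study configuration: one validated, human-editable document describing
data sources (paths or generator specs), film/cell geometry, PK constants and
fitting options for a full pipeline run."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from . import adhesion, permeation, pk, qc, release, synthetic

__all__ = ["StudyConfig", "default_study_config", "load_config"]


class NoiseSection(BaseModel):
    sd: float = 0.0
    seed: int = 0

    def to_spec(self) -> synthetic.NoiseSpec:
        return synthetic.NoiseSpec(self.sd, self.seed)


class ReleaseSection(BaseModel):
    """Either a CSV path or a generator spec for the dissolution curve."""

    path: Optional[str] = None
    model: str = "peppas_sahlin"
    params: dict = Field(default_factory=lambda: {"k1": -10.912, "k2": 5.571,
                                                  "m": 0.404})
    t_end: float = 64.0
    dt: float = 2.0
    noise: NoiseSection = NoiseSection(sd=1.5)
    cap_at_100: bool = True   # clip to [0, 100] for realism; disable for
                              # parameter-recovery work

    def to_spec(self) -> synthetic.ReleaseGenSpec:
        return synthetic.ReleaseGenSpec(self.model, dict(self.params),
                                        self.t_end, self.dt,
                                        self.noise.to_spec(), self.cap_at_100)


class PermeationSection(BaseModel):
    path: Optional[str] = None
    flux: float = 0.237
    lag_h: float = 0.0
    breakdown_h: float = 2.5
    t_end_h: float = 6.0
    dt_h: float = 1.0
    tau_h: float = 0.1
    noise: NoiseSection = NoiseSection(sd=0.003)

    def to_spec(self) -> synthetic.PermeationGenSpec:
        return synthetic.PermeationGenSpec(self.flux, self.lag_h,
                                           self.breakdown_h, self.t_end_h,
                                           self.dt_h, self.tau_h,
                                           self.noise.to_spec())


class AdhesionSection(BaseModel):
    path: Optional[str] = None
    contact_times: Sequence[float] = (10.0, 15.0, 20.0, 30.0, 40.0, 50.0)
    f_max: float = 0.88
    rate: float = 0.065
    noise: NoiseSection = NoiseSection(sd=0.01)


class FilmSection(BaseModel):
    total_area: float = 8.04
    total_mass_g: float = 1.03
    thickness_um: float = 793.0
    disk_area: float = 0.2827
    disk_mass_mg: float = 30.94
    dl_pct: float = 7.40
    disk_dose_mg: float = 2.29
    disk_diameter_mm: float = 6.0  # small mucoadhesion/permeation disk
    release_disk_diameter_mm: float = 11.0  # flow-cell dissolution disk

    def to_spec(self) -> qc.FilmSpec:
        return qc.FilmSpec(self.total_area, self.total_mass_g,
                           self.thickness_um, self.disk_area,
                           self.disk_mass_mg, self.dl_pct, self.disk_dose_mg)


class FranzSection(BaseModel):
    acceptor_volume: float = 15.0
    sample_volume: float = 0.5
    diffusion_area: float = 0.636
    orifice_diameter: float = 9.0

    def to_spec(self) -> permeation.FranzConfig:
        return permeation.FranzConfig(self.acceptor_volume, self.sample_volume,
                                      self.diffusion_area,
                                      self.orifice_diameter)


class PKSection(BaseModel):
    cp_ss_per_mg: float = 1.0
    t_half: float = 6.0
    v_d_per_kg: float = 7.5
    body_mass: float = 70.0
    exact_ln2: bool = False
    oral_doses: Sequence[float] = (4.0, 8.0)
    area_multiplier: float = 1.0

    def to_spec(self) -> pk.PKParams:
        return pk.PKParams(self.cp_ss_per_mg, self.t_half, self.v_d_per_kg,
                           self.body_mass, self.exact_ln2)


class FitSection(BaseModel):
    models: Sequence[str] = tuple(release.MODELS)
    fit_range: str = "to_plateau"
    geometry: str = "film"
    flux_r2_threshold: float = 0.99


class StudyConfig(BaseModel):
    """Full study description; defaults replicate the published study
    conditions on synthetic data."""

    seed: int = 0
    outdir: str = "results/study"
    release: ReleaseSection = ReleaseSection()
    permeation: PermeationSection = PermeationSection()
    adhesion: AdhesionSection = AdhesionSection()
    film: FilmSection = FilmSection()
    franz: FranzSection = FranzSection()
    pk: PKSection = PKSection()
    fit: FitSection = FitSection()

    @model_validator(mode="after")
    def _paths_exist(self) -> "StudyConfig":
        for section in (self.release, self.permeation, self.adhesion):
            if section.path is not None and not Path(section.path).exists():
                raise ValueError(f"data path does not exist: {section.path}")
        return self

    def with_seed(self, seed: int) -> "StudyConfig":
        """Return a copy with every generator seed derived from ``seed``."""
        cfg = self.model_copy(deep=True)
        cfg.seed = seed
        cfg.release.noise.seed = seed
        cfg.permeation.noise.seed = seed + 1
        cfg.adhesion.noise.seed = seed + 2
        return cfg


def default_study_config(seed: int = 0) -> StudyConfig:
    """The shipped replication configuration: all constants at their
    characterized values, data from the seeded generators."""
    return StudyConfig().with_seed(seed)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig.model_validate(raw)
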