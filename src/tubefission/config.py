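"""Structured run configuration (YAML) and simulation assembly."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dynamics import Simulation, TimeStepper
from .energetics import ElasticParameters
from .fields import AxisymmetricGrid
from .forcing import CoatSet, DynaminCoat

__all__ = ["RunConfig", "load_config"]

_SQRT2 = math.sqrt(2.0)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run.

    The coat list uses per-coat dictionaries with keys ``H_nm``,
    ``center_nm`` and optionally ``F_tau_pN``, ``pitch_nm``, ``N_d``,
    ``R_cut_nm``, ``edge_width_nm``.  ``gamma_N_per_m`` (SI) takes
    precedence over the k_BT/nm^2 value inside ``elastic`` when given.
    """

    grid: dict = field(default_factory=lambda: {
        "L_r_nm": 30.0, "L_z_nm": 360.0, "N_r": 108, "N_z": 1296})
    elastic: dict = field(default_factory=dict)
    gamma_N_per_m: float | None = None
    coats: list = field(default_factory=list)
    stepper: dict = field(default_factory=dict)
    R_in_nm: float | None = None
    max_time: float | None = None
    post_fission_time: float = 0.2
    outdir: str | None = None

    # -- assembly ---------------------------------------------------------
    def build_grid(self) -> AxisymmetricGrid:
        g = self.grid
        return AxisymmetricGrid(L_r=g["L_r_nm"], L_z=g["L_z_nm"],
                                N_r=int(g["N_r"]), N_z=int(g["N_z"]))

    def build_elastic(self) -> ElasticParameters:
        params = ElasticParameters(**self.elastic)
        if self.gamma_N_per_m is not None:
            params = params.with_tension_si(self.gamma_N_per_m)
        return params

    def build_coats(self) -> CoatSet:
        coats = []
        for c in self.coats:
            coats.append(DynaminCoat(
                H=c["H_nm"], z_0=c["center_nm"],
                F_tau=c.get("F_tau_pN", 2.5),
                h_pitch=c.get("pitch_nm", 10.0),
                N_d=int(c.get("N_d", 13)),
                R_cut=c.get("R_cut_nm", 3.0),
                edge_width=c.get("edge_width_nm"),
            ))
        return CoatSet(coats)

    def build_stepper(self) -> TimeStepper:
        return TimeStepper(**self.stepper)

    def validate(self) -> None:
        """Check that every coat sits well inside the domain.

        The coat footprint plus five elastic decay lengths sqrt(2) R_in
        must fit along z, otherwise the periodic boundary contaminates the
        flank response.
        """
        grid = self.build_grid()
        params = self.build_elastic()
        R_in = self.R_in_nm or math.sqrt(params.k_b / (2.0 * params.gamma))
        margin = 5.0 * _SQRT2 * R_in
        for coat in self.build_coats():
            lo, hi = coat.footprint()
            if lo - margin < 0.0 or hi + margin > grid.L_z:
                raise ValueError(
                    f"coat at z={coat.z_0:.0f} nm needs {margin:.0f} nm of clearance "
                    f"on each side; enlarge L_z or recenter the coat"
                )

    def build_simulation(self) -> Simulation:
        self.validate()
        return Simulation(self.build_grid(), self.build_elastic(),
                          coats=self.build_coats(), stepper=self.build_stepper(),
                          R_in=self.R_in_nm)

    # -- (de)serialization ------------------------------------------------
    def to_manifest(self) -> dict:
        params = self.build_elastic()
        manifest = asdict(self)
        manifest["resolved_elastic"] = asdict(params)
        manifest["resolved_R_in_nm"] = self.R_in_nm or math.sqrt(
            params.k_b / (2.0 * params.gamma))
        return manifest

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
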