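"""Physical and computational parameters of the tissue-voxel model.

All lengths are in micrometers, times in seconds, and oxygen partial
pressure in mmHg (the model's concentration unit is identified with mmHg
through the vascular oxygen level ``gamma_max = 60 mmHg``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

# Calibrated nodal uptake conversion (see docs/methods.md, "Uptake scaling").
# Frozen after a one-time bisection on the full pipeline so that tissues with
# 3.5% vascularity / 55% tumor / 30% stromal cellularity stabilize at ~29.9
# mmHg (replicate mean) from a zero initial field with delta_V = delta_T = 1.
UPTAKE_SCALE_CALIBRATED = 4.875


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a 1 mm^2 tissue-voxel simulation.

    The defaults describe a two-dimensional cross-section of a radiology
    voxel populated by immobile vessels (radius ``R_V``), tumor cells
    (``R_T``) and stromal cells (``R_S``), with oxygen entering at
    vessel-covered grid nodes and removed by saturable Michaelis-Menten
    cellular uptake.

    Attributes
    ----------
    R_T, R_S, R_V : float
        Tumor-cell, stromal-cell and vessel radii (um).
    F : float
        Stiffness of the repulsive Hookean contact force (ug / (um s^2)).
    nu : float
        Viscosity of the medium in the overdamped relocation equation
        (ug / (um s)).
    D_gamma : float
        Oxygen diffusion coefficient (um^2/s).
    gamma_max : float
        Intravascular oxygen level (mmHg); also the ceiling a vessel-covered
        node can be driven to at influx rate ``delta_V = 1``.
    kappa_m : float
        Michaelis constant of cellular uptake (mmHg).
    T_max, S_max : float
        Base uptake rates of tumor and stromal cells. The nodal uptake
        coefficient is ``uptake_scale * T_max`` (mmHg/s per covering cell);
        see ``uptake_scale``.
    uptake_scale : float
        Global conversion from the per-cell-volume base uptake rate to a
        per-node volumetric sink (dimensionless). The published rate of
        0.382 is expressed per cell volume in mass units, which does not fix
        the nodal sink strength on a 2-D grid; this single factor was
        calibrated once so that a voxel with 3.5% vascularity, 55% tumor and
        30% stromal cellularity stabilizes at about 29.9 mmHg, and is used
        unchanged everywhere else.
    stromal_node_weight : float
        Relative per-node uptake weight of stromal vs tumor cells (1.0:
        every covering cell contributes equally, as in the model equation).
    vessel_ceiling : bool
        If True (default), vessel-covered nodes are capped at their
        intravascular level ``delta_V * gamma_max`` after each step, so the
        tissue oxygen never exceeds what the vasculature can supply and a
        bounded steady state exists for every composition. If False the
        influx source term acts uncapped.
    dx : float
        Grid spacing (um).
    dt : float
        Time step of the explicit solver (s).
    domain : tuple
        Rectangle (xmin, xmax, ymin, ymax) in um.
    sigma_g : float
        Mass scaling of the concentration unit (g); documentation only.
    """

    R_T: float = 7.5
    R_S: float = 3.75
    R_V: float = 20.0
    F: float = 50.0
    nu: float = 250.0
    D_gamma: float = 100.0
    gamma_max: float = 60.0
    kappa_m: float = 134.0
    T_max: float = 0.382
    S_max: float = 0.382
    uptake_scale: float = UPTAKE_SCALE_CALIBRATED
    stromal_node_weight: float = 1.0
    vessel_ceiling: bool = True
    dx: float = 5.0
    dt: float = 0.05
    domain: tuple[float, float, float, float] = (-500.0, 500.0, -500.0, 500.0)
    sigma_g: float = 0.5e-19

    def __post_init__(self) -> None:
        for name in ("R_T", "R_S", "R_V", "F", "nu", "D_gamma", "gamma_max",
                     "kappa_m", "T_max", "S_max", "uptake_scale", "dx", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        xmin, xmax, ymin, ymax = self.domain
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("domain must be a non-degenerate rectangle")
        if self.cfl > 0.25:
            raise ValueError(
                f"diffusive stability violated: D*dt/dx^2 = {self.cfl:.3g} > 1/4"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def cfl(self) -> float:
        """Diffusive stability number ``D * dt / dx^2`` (must be <= 1/4)."""
        return self.D_gamma * self.dt / self.dx**2

    @property
    def domain_area(self) -> float:
        xmin, xmax, ymin, ymax = self.domain
        return (xmax - xmin) * (ymax - ymin)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Number of nodes along x and y (inclusive of both boundaries)."""
        xmin, xmax, ymin, ymax = self.domain
        nx = int(round((xmax - xmin) / self.dx)) + 1
        ny = int(round((ymax - ymin) / self.dx)) + 1
        return nx, ny

    def node_coords(self):
        """1-D arrays of node x and y coordinates (um)."""
        import numpy as np

        xmin, xmax, ymin, ymax = self.domain
        nx, ny = self.grid_shape
        return (xmin + self.dx * np.arange(nx), ymin + self.dx * np.arange(ny))

    def radius_of(self, kind: str) -> float:
        return {"vessel": self.R_V, "tumor": self.R_T, "stromal": self.R_S}[kind]

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def nominal_area(self, kind: str) -> float:
        return math.pi * self.radius_of(kind) ** 2


def default_params(**overrides) -> ModelParams:
    """Published defaults with the calibrated uptake scale."""
    return ModelParams(**overrides)


@dataclass(frozen=True)
class SearchOptions:
    """Options of the one-dimensional pattern search used per time segment.

    ``initial_mesh`` defaults to 1/4 of the admissible range of the rate
    being fitted (0.25 for influx on [0,1], 12.5 for uptake on [0,50]);
    ``mesh_min`` to range/4096, matching the dyadic granularity of the
    published optimal schedules; ``fit_tol`` is the endpoint tolerance in
    mmHg below which a segment is accepted without further refinement.
    """

    initial_mesh: float | None = None
    mesh_min: float | None = None
    fit_tol: float = 0.01
    max_evals: int = 400

    def resolved(self, lo: float, hi: float) -> tuple[float, float]:
        rng = hi - lo
        mesh0 = self.initial_mesh if self.initial_mesh is not None else rng / 4.0
        mmin = self.mesh_min if self.mesh_min is not None else rng / 4096.0
        return mesh0, mmin


@dataclass
class RunConfig:
    """Serializable provenance record embedded in result files."""

    params: ModelParams = field(default_factory=default_params)
    seed: int = 0
    gof_form: str = "relative"          # "relative" or "mean_square"
    error_norm_sqrt: bool = True        # sqrt in the stabilization error norm
    search: SearchOptions = field(default_factory=SearchOptions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["domain"] = list(self.params.domain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        p = dict(d.pop("params", {}))
        if "domain" in p:
            p["domain"] = tuple(p["domain"])
        s = dict(d.pop("search", {}))
        return cls(params=ModelParams(**p), search=SearchOptions(**s), **d)
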