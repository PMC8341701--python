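"""Oxygen reaction-diffusion on the voxel grid.

The oxygen field gamma(x, t) obeys

    dgamma/dt = sum_i delta_V gamma_max chi_RV(x, V_i)        (vascular influx)
              + D lap gamma                                    (diffusion)
              - sum_j delta_T T_max gamma/(kappa_m+gamma) chi_RT(x, T_j)
              - sum_k       S_max gamma/(kappa_m+gamma) chi_RS(x, S_k)

discretized by forward Euler with a 5-point Laplacian and no-flux (mirror)
boundaries. Element-to-grid coupling uses the indicator chi_R: a node
counts as covered when its Euclidean distance to the element center is
strictly below the interaction radius; covering contributions sum. By
default, vessel-covered nodes are additionally capped at their
intravascular level ``delta_V * gamma_max``, which bounds the field by the
vascular supply and guarantees a steady state for every composition (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import ModelParams, default_params
from .tissue import TissueLayout

__all__ = [
    "IndicatorMasks",
    "OxygenField",
    "StabilizationReport",
    "NoSteadyStateError",
    "DivergenceError",
    "build_indicator_masks",
    "step_oxygen",
    "stabilize",
    "average_po2",
    "simulate_schedule",
    "mass_balance",
    "SEGMENT_BOUNDARIES_MIN",
]

#: Piecewise-constant rate segments of the fluctuation experiments (minutes).
SEGMENT_BOUNDARIES_MIN = (0.0, 4.0, 7.0, 10.0, 13.0, 16.0, 19.0, 22.0, 25.0, 28.0)


class NoSteadyStateError(ValueError):
    """Raised when a layout provably admits no stationary oxygen field."""


class DivergenceError(RuntimeError):
    """Raised when the explicit solver produced non-finite values."""


@dataclass
class IndicatorMasks:
    """Per-node counts of covering vessels / tumor cells / stromal cells."""

    vessel: np.ndarray
    tumor: np.ndarray
    stromal: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel.shape


@dataclass
class OxygenField:
    """Nodal oxygen values (mmHg) on the voxel grid."""

    values: np.ndarray
    params: ModelParams

    @property
    def average(self) -> float:
        return float(self.values.mean())

    def copy(self) -> "OxygenField":
        return OxygenField(self.values.copy(), self.params)


@dataclass
class StabilizationReport:
    iterations: int
    final_error: float
    average_po2: float
    converged: bool
    threshold: float = 1e-10


def build_indicator_masks(layout: TissueLayout,
                          params: ModelParams | None = None) -> IndicatorMasks:
    """Count, for every grid node, the covering elements of each type."""
    params = params or default_params()
    nx, ny = params.grid_shape
    xmin, _, ymin, _ = params.domain
    masks = []
    for pts, R in ((layout.vessels, params.R_V),
                   (layout.tumor_cells, params.R_T),
                   (layout.stromal_cells, params.R_S)):
        counts = np.zeros((nx, ny), dtype=np.int32)
        if len(pts):
            _kernels.add_disk_counts(
                counts, np.ascontiguousarray(pts[:, 0], dtype=float),
                np.ascontiguousarray(pts[:, 1], dtype=float), R,
                xmin, ymin, params.dx)
        masks.append(counts)
    return IndicatorMasks(*masks)


def _rate_arrays(masks: IndicatorMasks, delta_V: float, delta_T: float,
                 params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-node influx (mmHg/s) and uptake prefactor (mmHg/s) arrays."""
    influx = delta_V * params.gamma_max * masks.vessel.astype(float)
    uptake = params.uptake_scale * (
        delta_T * params.T_max * masks.tumor.astype(float)
        + params.stromal_node_weight * params.S_max * masks.stromal.astype(float)
    )
    return influx, uptake


def _check_rates(delta_V: float, delta_T: float) -> None:
    if not 0.0 <= delta_V <= 1.0:
        raise ValueError(f"influx rate {delta_V} outside [0, 1]")
    if not 0.0 <= delta_T <= 50.0:
        raise ValueError(f"uptake rate {delta_T} outside [0, 50]")


def step_oxygen(field: OxygenField, masks: IndicatorMasks, delta_V: float,
                delta_T: float, params: ModelParams | None = None) -> OxygenField:
    """One forward-Euler step (numpy reference implementation).

    The long-running entry points (:func:`stabilize`,
    :func:`simulate_schedule`) use a compiled kernel that must agree with
    this step exactly.
    """
    params = params or field.params or default_params()
    _check_rates(delta_V, delta_T)
    g = field.values
    if not np.all(np.isfinite(g)):
        raise DivergenceError("non-finite oxygen values")
    influx, uptake = _rate_arrays(masks, delta_V, delta_T, params)
    gp = np.pad(g, 1, mode="reflect")
    lap = gp[:-2, 1:-1] + gp[2:, 1:-1] + gp[1:-1, :-2] + gp[1:-1, 2:] - 4.0 * g
    new = g + params.dt * (influx + params.D_gamma / params.dx**2 * lap
                           - uptake * g / (params.kappa_m + g))
    np.maximum(new, 0.0, out=new)
    if params.vessel_ceiling:
        cap = delta_V * params.gamma_max
        vmask = masks.vessel > 0
        new[vmask] = np.minimum(new[vmask], cap)
    if not np.all(np.isfinite(new)):
        raise DivergenceError("oxygen solver diverged")
    return OxygenField(new, params)


def _advance(field: OxygenField, masks: IndicatorMasks, delta_V: float,
             delta_T: float, params: ModelParams, max_steps: int,
             eps_threshold: float, sqrt_norm: bool = True) -> tuple[int, float, int]:
    """Kernel driver; advances ``field.values`` in place."""
    influx, uptake = _rate_arrays(masks, delta_V, delta_T, params)
    alpha = params.D_gamma * params.dt / params.dx**2
    vi, vj = np.nonzero(masks.vessel)
    werr = np.ones_like(field.values)
    if params.vessel_ceiling:
        werr[vi, vj] = 0.0
    steps, eps, status = _kernels.advance_oxygen(
        field.values, influx * params.dt, uptake * params.dt, werr,
        vi.astype(np.int64), vj.astype(np.int64),
        delta_V * params.gamma_max, params.vessel_ceiling, alpha,
        params.kappa_m, max_steps, eps_threshold, sqrt_norm)
    if status == -1:
        raise DivergenceError("oxygen solver diverged")
    return steps, eps, status


def stabilize(layout: TissueLayout, params: ModelParams | None = None,
              init_value: float = 0.0, delta_V: float = 1.0,
              delta_T: float = 1.0, eps_threshold: float = 1e-10,
              max_iter: int = 1_000_000, sqrt_norm: bool = True,
              masks: IndicatorMasks | None = None,
              ) -> tuple[OxygenField, StabilizationReport]:
    """Iterate the explicit solver to the numerically stable distribution.

    Stops when the normalized L2 error between consecutive fields drops to
    ``eps_threshold`` (default 1e-10). ``sqrt_norm`` selects the Euclidean
    norm divided by the node count; ``False`` uses the literal
    sum-of-squares variant. With the vessel ceiling disabled, layouts whose
    saturated uptake capacity cannot absorb the influx admit no steady
    state and are rejected up front.
    """
    params = params or default_params()
    _check_rates(delta_V, delta_T)
    if masks is None:
        masks = build_indicator_masks(layout, params)
    influx, uptake = _rate_arrays(masks, delta_V, delta_T, params)
    if not params.vessel_ceiling and influx.sum() > 0 and \
            influx.sum() >= uptake.sum():
        raise NoSteadyStateError(
            "vascular influx exceeds the saturated uptake capacity; "
            "no stationary field exists without the vessel ceiling")
    nx, ny = params.grid_shape
    field = OxygenField(np.full((nx, ny), float(init_value)), params)
    steps, eps, status = _advance(field, masks, delta_V, delta_T, params,
                                  max_iter, eps_threshold, sqrt_norm)
    report = StabilizationReport(
        iterations=steps, final_error=eps, average_po2=field.average,
        converged=status == 1, threshold=eps_threshold)
    return field, report


def average_po2(field: OxygenField | np.ndarray) -> float:
    """Arithmetic mean over all grid nodes (mmHg)."""
    values = field.values if isinstance(field, OxygenField) else np.asarray(field)
    return float(values.mean())


def simulate_schedule(stable_field: OxygenField, masks: IndicatorMasks,
                      influx_rates=None, uptake_rates=None,
                      params: ModelParams | None = None,
                      boundaries_min=SEGMENT_BOUNDARIES_MIN) -> np.ndarray:
    """Average pO2 at each segment endpoint under piecewise-constant rates.

    Exactly one of ``influx_rates`` / ``uptake_rates`` normally varies; a
    rate left ``None`` is held at 1 throughout. Returns the domain averages
    at t_k = boundaries[1:] (default {4, 7, ..., 28} minutes).
    """
    params = params or stable_field.params or default_params()
    n_seg = len(boundaries_min) - 1
    ones = np.ones(n_seg)
    infl = ones if influx_rates is None else np.asarray(influx_rates, dtype=float)
    upt = ones if uptake_rates is None else np.asarray(uptake_rates, dtype=float)
    if len(infl) != n_seg or len(upt) != n_seg:
        raise ValueError(f"schedules must have {n_seg} rates")
    field = stable_field.copy()
    out = np.empty(n_seg)
    for k in range(n_seg):
        _check_rates(infl[k], upt[k])
        seconds = (boundaries_min[k + 1] - boundaries_min[k]) * 60.0
        n_steps = int(round(seconds / params.dt))
        _advance(field, masks, infl[k], upt[k], params, n_steps, -1.0)
        out[k] = field.average
    return out


def _quadrature_weights(shape: tuple[int, int]) -> np.ndarray:
    """Trapezoidal node weights under which the mirror-boundary Laplacian
    conserves mass exactly (1 interior, 1/2 edges, 1/4 corners)."""
    w = np.ones(shape)
    w[0, :] *= 0.5
    w[-1, :] *= 0.5
    w[:, 0] *= 0.5
    w[:, -1] *= 0.5
    return w


def mass_balance(field: OxygenField, masks: IndicatorMasks, delta_V: float,
                 delta_T: float, params: ModelParams | None = None
                 ) -> tuple[float, float, float]:
    """(effective influx, uptake, relative imbalance), in mmHg um^2 / s.

    Sums are trapezoid-weighted so that diffusion through the no-flux
    boundaries drops out identically; the effective influx includes the
    corrections applied by the vessel ceiling and the zero clip, so at a
    stationary field influx and uptake agree to the stationarity residual.
    """
    params = params or field.params or default_params()
    g = field.values
    influx, uptake_pref = _rate_arrays(masks, delta_V, delta_T, params)
    uptake = uptake_pref * g / (params.kappa_m + g)
    gp = np.pad(g, 1, mode="reflect")
    lap = gp[:-2, 1:-1] + gp[2:, 1:-1] + gp[1:-1, :-2] + gp[1:-1, 2:] - 4.0 * g
    raw = g + params.dt * (influx + params.D_gamma / params.dx**2 * lap - uptake)
    clipped = np.maximum(raw, 0.0)
    if params.vessel_ceiling:
        cap = delta_V * params.gamma_max
        vmask = masks.vessel > 0
        clipped[vmask] = np.minimum(clipped[vmask], cap)
    correction = (clipped - raw) / params.dt
    w = _quadrature_weights(g.shape)
    area = params.dx**2
    total_influx = float(((influx + correction) * w).sum()) * area
    total_uptake = float((uptake * w).sum()) * area
    scale = max(abs(total_influx), abs(total_uptake), 1e-300)
    return total_influx, total_uptake, abs(total_influx - total_uptake) / scale
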