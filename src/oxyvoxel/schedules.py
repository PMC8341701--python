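"""Fitting piecewise-constant influx / uptake schedules to pO2 series.

A measured region-of-interest (ROI) series gives the voxel-average pO2 at
t_k in {4, 7, ..., 28} minutes. Starting from the tissue's stationary
field, either the vascular influx rate delta_V(t) (bounded by [0, 1]) or
the tumor uptake multiplier delta_T(t) (bounded by [0, 50]) is adjusted on
each 3-4 minute segment so that the simulated voxel average at the segment
endpoint matches the measurement. The per-segment rate is found by a
one-dimensional mesh-adaptive pattern search (poll +/- mesh around the
incumbent, double the mesh on success, halve on failure), the direct-search
strategy behind MADS; because the system is causal and each measurement
depends only on the past, the greedy segment-by-segment search solves the
separable L1 matching objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .oxygen import (IndicatorMasks, OxygenField, SEGMENT_BOUNDARIES_MIN,
                     _advance, average_po2)
from .params import ModelParams, SearchOptions, default_params

__all__ = [
    "Schedule",
    "ROISeries",
    "FitResult",
    "RATE_BOUNDS",
    "objective_term",
    "goodness_of_fit",
    "fit_segment",
    "fit_schedule",
]

#: Admissible ranges of the piecewise-constant rates.
RATE_BOUNDS = {"influx": (0.0, 1.0), "uptake": (0.0, 50.0)}


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant rate schedule over the fluctuation segments."""

    kind: str                       # "influx" or "uptake"
    rates: tuple[float, ...]
    boundaries_min: tuple[float, ...] = SEGMENT_BOUNDARIES_MIN

    def __post_init__(self) -> None:
        if self.kind not in RATE_BOUNDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if len(self.rates) != len(self.boundaries_min) - 1:
            raise ValueError("one rate per segment required")
        lo, hi = RATE_BOUNDS[self.kind]
        for r in self.rates:
            if not lo <= r <= hi:
                raise ValueError(f"{self.kind} rate {r} outside [{lo}, {hi}]")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


@dataclass
class ROISeries:
    """Voxel-average pO2 measurements of one region of interest."""

    values: np.ndarray
    times_min: np.ndarray = dfield(
        default_factory=lambda: np.asarray(SEGMENT_BOUNDARIES_MIN[1:]))
    label: str = ""
    anchor_po2: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.values.shape != self.times_min.shape:
            raise ValueError("values and times differ in length")
        if np.any(self.values < 0):
            raise ValueError("pO2 values must be non-negative")
        if self.anchor_po2 is None:
            self.anchor_po2 = float(self.values.max())

    def __len__(self) -> int:
        return len(self.values)

    @property
    def boundaries_min(self) -> tuple[float, ...]:
        return (0.0, *self.times_min.tolist())


def objective_term(gamma_e: float, gamma_c: float) -> float:
    """Absolute mismatch |measured - simulated| of one segment endpoint."""
    return abs(float(gamma_e) - float(gamma_c))


def goodness_of_fit(series_e, series_opt, form: str = "relative") -> float:
    """Normalized discrepancy between measured and simulated series.

    ``relative`` (default): ||E - O||_2 / ||E||_2, a dimensionless relative
    Euclidean error (falls back to the absolute root-mean-square when the
    measured series is identically zero). ``mean_square``: (1/N) sum (E-O)^2
    (mmHg^2), the literal normalized sum of squares.
    """
    e = np.asarray(series_e, dtype=float)
    o = np.asarray(series_opt, dtype=float)
    if e.shape != o.shape:
        raise ValueError("series lengths differ")
    if form == "mean_square":
        return float(np.mean((e - o) ** 2))
    if form != "relative":
        raise ValueError(f"unknown GoF form {form!r}")
    denom = np.linalg.norm(e)
    if denom == 0.0:
        return float(np.sqrt(np.mean((e - o) ** 2)))
    return float(np.linalg.norm(e - o) / denom)


@dataclass
class FitResult:
    """Schedule fitted to one ROI series, with its goodness of fit."""

    schedule: Schedule
    simulated: np.ndarray
    target: np.ndarray
    gof: float
    gof_form: str
    traces: list
    n_evaluations: int

    def summary_rows(self) -> list[dict]:
        rows = []
        b = self.schedule.boundaries_min
        for k, rate in enumerate(self.schedule.rates):
            rows.append({
                "segment": f"{b[k]:g}-{b[k + 1]:g} min",
                "rate": rate,
                "target_mmHg": float(self.target[k]),
                "simulated_mmHg": float(self.simulated[k]),
                "abs_error_mmHg": objective_term(self.target[k], self.simulated[k]),
            })
        return rows


def _segment_steps(boundaries_min, params: ModelParams) -> list[int]:
    return [int(round((boundaries_min[k + 1] - boundaries_min[k]) * 60.0
                      / params.dt))
            for k in range(len(boundaries_min) - 1)]


def fit_segment(current_field: OxygenField, masks: IndicatorMasks,
                n_steps: int, target: float, mode: str,
                params: ModelParams | None = None,
                search_opts: SearchOptions | None = None,
                incumbent: float = 1.0,
                ) -> tuple[float, OxygenField, list]:
    """Fit one segment's rate by 1-D pattern search.

    Starting from ``incumbent`` (the previous segment's accepted rate), the
    search polls ``+/- mesh``, doubling the mesh after an improving poll and
    halving it otherwise, with candidates projected to the rate bounds.
    Stops when the mesh falls below ``mesh_min`` or the endpoint average is
    within ``fit_tol`` mmHg of the target. Returns the accepted rate, the
    field propagated to the segment end under it, and the poll trace.
    """
    params = params or current_field.params or default_params()
    opts = search_opts or SearchOptions()
    lo, hi = RATE_BOUNDS[mode]
    mesh, mesh_min = opts.resolved(lo, hi)
    cache: dict[float, float] = {}
    best_field: dict = {}
    trace: list = []

    def evaluate(rate: float) -> float:
        rate = min(max(rate, lo), hi)
        if rate in cache:
            return cache[rate]
        trial = current_field.copy()
        dv, dt_rate = (rate, 1.0) if mode == "influx" else (1.0, rate)
        try:
            _advance(trial, masks, dv, dt_rate, params, n_steps, -1.0)
            obj = objective_term(target, trial.average)
        except Exception:
            obj = np.inf
        cache[rate] = obj
        if not best_field or obj < best_field["obj"]:
            best_field.update(obj=obj, rate=rate, field=trial)
        trace.append({"rate": rate, "objective": obj, "mesh": mesh})
        return obj

    x = min(max(incumbent, lo), hi)
    f_x = evaluate(x)
    while (len(cache) < opts.max_evals and f_x > opts.fit_tol
           and mesh >= mesh_min):
        improved = False
        for cand in (x + mesh, x - mesh):
            cand = min(max(cand, lo), hi)
            if cand == x:
                continue
            f_c = evaluate(cand)
            if f_c < f_x:
                x, f_x = cand, f_c
                improved = True
                break
        if improved:
            mesh = min(mesh * 2.0, hi - lo)
        else:
            mesh *= 0.5
    if best_field["rate"] != x:  # pragma: no cover - defensive
        x = best_field["rate"]
    return x, best_field["field"], trace


def fit_schedule(stable_field: OxygenField, masks: IndicatorMasks,
                 roi: ROISeries, mode: str,
                 params: ModelParams | None = None,
                 search_opts: SearchOptions | None = None,
                 gof_form: str = "relative") -> FitResult:
    """Fit a full influx or uptake schedule to an ROI series.

    Segments are fitted sequentially in time order: each endpoint depends
    only on the prior state and its own rate, so the greedy per-segment
    search minimizes the separable sum of endpoint mismatches. During
    influx fitting the uptake multiplier stays at 1, and vice versa.
    """
    if mode not in RATE_BOUNDS:
        raise ValueError(f"unknown fit mode {mode!r}")
    params = params or stable_field.params or default_params()
    steps = _segment_steps(roi.boundaries_min, params)
    field = stable_field.copy()
    rates: list[float] = []
    simulated: list[float] = []
    traces: list = []
    n_eval = 0
    incumbent = 1.0
    for k, n_steps in enumerate(steps):
        rate, field, trace = fit_segment(
            field, masks, n_steps, float(roi.values[k]), mode, params,
            search_opts, incumbent)
        rates.append(rate)
        simulated.append(field.average)
        traces.append(trace)
        n_eval += len(trace)
        incumbent = rate
    sim = np.asarray(simulated)
    return FitResult(
        schedule=Schedule(kind=mode, rates=tuple(rates),
                          boundaries_min=tuple(roi.boundaries_min)),
        simulated=sim, target=roi.values.copy(),
        gof=goodness_of_fit(roi.values, sim, gof_form), gof_form=gof_form,
        traces=traces, n_evaluations=n_eval)
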