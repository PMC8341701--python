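"""Random tissue patches: vessels, tumor and stromal cells as hard disks.

A tissue patch realizes target area fractions of vasculature and tumor /
stromal cellularity inside a rectangular voxel cross-section. Element
centers are drawn uniformly at random and overlaps between cells (and
between cells and vessels) are resolved by overdamped relaxation under
repulsive Hookean contact forces. Vessels are immobile and may overlap
each other, mimicking the irregular vessel cross-sections of histology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .params import ModelParams, default_params

__all__ = [
    "TissueComposition",
    "TissueLayout",
    "composition_to_counts",
    "sample_layout",
    "pairwise_repulsion",
    "resolve_overlaps",
    "overlap_report",
]


@dataclass(frozen=True)
class TissueComposition:
    """Target area fractions (percent of the voxel area)."""

    vascular: float
    tumor: float
    stromal: float

    def __post_init__(self) -> None:
        for name in ("vascular", "tumor", "stromal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} fraction must be >= 0")
        if self.total > 100:
            raise ValueError(
                f"fractions sum to {self.total}%, exceeding the voxel area"
            )

    @property
    def total(self) -> float:
        return self.vascular + self.tumor + self.stromal

    def astuple(self) -> tuple[float, float, float]:
        return (self.vascular, self.tumor, self.stromal)


@dataclass
class TissueLayout:
    """Disk centers of one tissue patch (um, in the domain frame).

    ``relaxed`` is set by :func:`resolve_overlaps`; ``jammed`` marks layouts
    whose residual overlaps could not be removed within the iteration
    budget (dense packings above the random disk-packing limit).
    """

    vessels: np.ndarray        # (N_V, 2)
    tumor_cells: np.ndarray    # (N_T, 2)
    stromal_cells: np.ndarray  # (N_S, 2)
    composition: TissueComposition
    seed: int | None = None
    relaxed: bool = False
    jammed: bool = False
    relax_iterations: int = 0
    residual_overlaps: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.vessels), len(self.tumor_cells), len(self.stromal_cells))

    def cells(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        """All mobile cells stacked (tumor first), with their radii."""
        pos = np.vstack([self.tumor_cells, self.stromal_cells])
        rad = np.concatenate([
            np.full(len(self.tumor_cells), params.R_T),
            np.full(len(self.stromal_cells), params.R_S),
        ])
        return pos, rad

    def copy(self) -> "TissueLayout":
        return replace(
            self,
            vessels=self.vessels.copy(),
            tumor_cells=self.tumor_cells.copy(),
            stromal_cells=self.stromal_cells.copy(),
        )


def composition_to_counts(comp: TissueComposition,
                          params: ModelParams | None = None) -> tuple[int, int, int]:
    """Element counts realizing the area fractions with nominal disk areas.

    ``N = round(fraction/100 * area(domain) / (pi R^2))`` per element type.
    Disks may clip the domain boundary; accounting uses the nominal
    (unclipped) area.
    """
    params = params or default_params()
    area = params.domain_area
    out = []
    for frac, kind in ((comp.vascular, "vessel"), (comp.tumor, "tumor"),
                       (comp.stromal, "stromal")):
        n = int(np.rint(frac / 100.0 * area / params.nominal_area(kind)))
        if n < 0:
            raise ValueError("negative element count")
        out.append(n)
    return tuple(out)  # type: ignore[return-value]


def sample_layout(comp: TissueComposition, params: ModelParams | None = None,
                  seed: int | None = None) -> TissueLayout:
    """Draw an unrelaxed layout with i.i.d. uniform centers over the domain."""
    params = params or default_params()
    n_v, n_t, n_s = composition_to_counts(comp, params)
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = params.domain

    def uniform(n: int) -> np.ndarray:
        pts = rng.random((n, 2))
        pts[:, 0] = xmin + pts[:, 0] * (xmax - xmin)
        pts[:, 1] = ymin + pts[:, 1] * (ymax - ymin)
        return pts

    return TissueLayout(
        vessels=uniform(n_v), tumor_cells=uniform(n_t),
        stromal_cells=uniform(n_s), composition=comp, seed=seed,
    )


def pairwise_repulsion(x_i, x_j, r_i: float, r_j: float, stiffness: float,
                       jitter_direction=None) -> np.ndarray:
    """Repulsive Hookean contact force on the element at ``x_i``.

    Zero when the centers are at least ``r_i + r_j`` apart; otherwise of
    magnitude ``stiffness * (r_i + r_j - d)`` directed from ``x_j`` toward
    ``x_i``. Coincident centers repel along ``jitter_direction`` (a unit
    vector; required in that degenerate case).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    dvec = x_i - x_j
    d = float(np.hypot(*dvec))
    rsum = r_i + r_j
    if d >= rsum:
        return np.zeros(2)
    if d < 1e-9:
        if jitter_direction is None:
            raise ValueError("coincident centers need a jitter direction")
        u = np.asarray(jitter_direction, dtype=float)
        return stiffness * rsum * u / np.hypot(*u)
    return stiffness * (rsum - d) * dvec / d


def all_pairs_forces(pos: np.ndarray, rad: np.ndarray, vessels: np.ndarray,
                     r_v: float, stiffness: float,
                     jitter: np.ndarray | None = None) -> np.ndarray:
    """Reference all-pairs force sum (oracle for the binned kernel)."""
    n = len(pos)
    forces = np.zeros((n, 2))
    if jitter is None:
        jitter = np.zeros(n)
    for i in range(n):
        u = np.array([np.cos(jitter[i]), np.sin(jitter[i])])
        for j in range(n):
            if j == i:
                continue
            d = np.hypot(*(pos[i] - pos[j]))
            if d < 1e-9:
                forces[i] += stiffness * (rad[i] + rad[j]) * u
            elif d < rad[i] + rad[j]:
                forces[i] += pairwise_repulsion(pos[i], pos[j], rad[i], rad[j],
                                                stiffness)
        for j in range(len(vessels)):
            d = np.hypot(*(pos[i] - vessels[j]))
            if d < 1e-9:
                forces[i] += stiffness * (rad[i] + r_v) * u
            elif d < rad[i] + r_v:
                forces[i] += pairwise_repulsion(pos[i], vessels[j], rad[i], r_v,
                                                stiffness)
    return forces


def overlap_report(layout: TissueLayout, params: ModelParams | None = None,
                   tol: float = 0.05) -> tuple[int, float]:
    """(count, sum of squared overlap depths) over forbidden pairs.

    Forbidden pairs are cell-cell and cell-vessel; vessel-vessel overlap is
    allowed. A pair overlaps when its center distance is below
    ``R_i + R_j - tol``. The default contact tolerance of 0.05 um (about 1%
    of the stromal radius) absorbs both the depth resolution of the
    relaxation stopping rule and the shallow force-balanced wedge contacts
    (a cell squeezed symmetrically between two obstacles) whose tangential
    escape is asymptotic; such micro-compressions are contacts, not
    overlapping cells.
    """
    params = params or default_params()
    pos, rad = layout.cells(params)
    xmin, xmax, ymin, ymax = params.domain
    cnt, energy = _kernels.count_overlaps_binned(
        np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
        rad, np.ascontiguousarray(layout.vessels[:, 0]),
        np.ascontiguousarray(layout.vessels[:, 1]), params.R_V, tol,
        xmin, xmax, ymin, ymax)
    return int(cnt), float(energy)


def resolve_overlaps(layout: TissueLayout, params: ModelParams | None = None,
                     dt_relax: float = 1.0, tol_disp: float = 1e-3,
                     max_iter: int = 10_000, stall_window: int = 150,
                     stall_rtol: float = 0.98,
                     seed: int | None = None) -> TissueLayout:
    """Relax a layout by explicit integration of the overdamped equations.

    Tumor and stromal cells move with velocity ``F/nu``; vessels never move.
    Iteration stops when the largest per-step displacement falls below
    ``tol_disp`` (um), when ``max_iter`` is reached, or when the
    displacement has plateaued for two consecutive windows (a jammed
    packing: the layout is returned flagged ``jammed`` with its residual
    overlap count, not raised as an error).

    ``seed`` feeds the tie-break directions used for exactly coincident
    centers; it defaults to the layout's own seed.
    """
    params = params or default_params()
    out = layout.copy()
    pos, rad = out.cells(params)
    n_t = len(out.tumor_cells)
    if len(pos) == 0:
        out.relaxed = True
        return out
    rng = np.random.default_rng(layout.seed if seed is None else seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=len(pos))
    px = np.ascontiguousarray(pos[:, 0])
    py = np.ascontiguousarray(pos[:, 1])
    vx = np.ascontiguousarray(out.vessels[:, 0])
    vy = np.ascontiguousarray(out.vessels[:, 1])
    xmin, xmax, ymin, ymax = params.domain
    iters, _, status = _kernels.relax_loop(
        px, py, rad, vx, vy, params.R_V, params.F, params.nu, dt_relax,
        xmin, xmax, ymin, ymax, tol_disp, max_iter, stall_window, stall_rtol,
        np.cos(angles), np.sin(angles))
    out.tumor_cells = np.column_stack([px[:n_t], py[:n_t]])
    out.stromal_cells = np.column_stack([px[n_t:], py[n_t:]])
    out.relaxed = True
    out.relax_iterations = int(iters)
    out.residual_overlaps, _ = overlap_report(out, params)
    out.jammed = status != 1 and out.residual_overlaps > 0
    return out
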