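"""Synthetic ROI-like pO2 series and ground-truth recovery pairs.

The underlying oximetry experiment published only four per-region anchor
values (the initial / maximum voxel-average pO2 of each region of
interest); the full 9-point series exist only as a figure in the cited
experimental study. This module therefore generates synthetic series
anchored at those printed values -- clearly labelled stand-ins, not
digitizations -- plus forward-simulated (schedule, series) pairs that serve
as ground truth for schedule-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oxygen import IndicatorMasks, OxygenField, simulate_schedule
from .params import ModelParams, default_params
from .schedules import ROISeries, Schedule

__all__ = ["ROI_ANCHORS_MMHG", "ROIFixtureSpec", "make_roi_series",
           "forward_series", "random_schedule"]

#: Printed anchor pO2 of the four experimental regions of interest (mmHg).
ROI_ANCHORS_MMHG = {"ROI1": 36.312, "ROI2": 22.89, "ROI3": 13.99, "ROI4": 1.83}

#: Fractions of the fluctuation amplitude subtracted from the anchor at each
#: of the nine sampling times under the ``drop_recover`` style: two large
#: dips with recoveries, emulating the published description of rapid
#: >5-fold swings in the well-oxygenated regions.
_DROP_RECOVER_SHAPE = (0.0, 0.0, 1.0, 0.25, 0.0, 0.0, 0.9, 0.15, 0.0)


@dataclass(frozen=True)
class ROIFixtureSpec:
    """Recipe for one synthetic ROI series."""

    anchor_po2: float
    fluctuation_style: str = "flat"   # flat | drop_recover | oscillate | random_walk
    amplitude: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.anchor_po2 < 0 or self.amplitude < 0:
            raise ValueError("anchor and amplitude must be non-negative")
        styles = ("flat", "drop_recover", "oscillate", "random_walk")
        if self.fluctuation_style not in styles:
            raise ValueError(f"style must be one of {styles}")


def make_roi_series(spec: ROIFixtureSpec, n_points: int = 9) -> ROISeries:
    """Deterministically generate a synthetic 9-point ROI series.

    All values are clipped to [0, anchor + amplitude]; downward styles that
    would cross zero are clipped at zero (recorded in the label).
    """
    a, amp = spec.anchor_po2, spec.amplitude
    times = 4.0 + 3.0 * np.arange(n_points)
    if spec.fluctuation_style == "flat":
        vals = np.full(n_points, a)
    elif spec.fluctuation_style == "drop_recover":
        shape = np.asarray(_DROP_RECOVER_SHAPE[:n_points])
        vals = a - amp * shape
    elif spec.fluctuation_style == "oscillate":
        vals = a - amp * (np.arange(n_points) % 2)
    else:  # random_walk
        rng = np.random.default_rng(spec.seed)
        steps = rng.normal(0.0, amp / 3.0, size=n_points)
        steps[0] = 0.0
        vals = a + np.cumsum(steps)
    clipped = bool(np.any(vals < 0) or np.any(vals > a + amp))
    vals = np.clip(vals, 0.0, a + amp)
    label = spec.label or f"synthetic-{spec.fluctuation_style}"
    if clipped:
        label += "-clipped"
    return ROISeries(values=vals, times_min=times, label=label, anchor_po2=a)


def random_schedule(kind: str, seed: int, n_segments: int = 9,
                    lo: float | None = None, hi: float | None = None) -> Schedule:
    """A random ground-truth schedule with rates uniform in its bounds."""
    from .schedules import RATE_BOUNDS

    b_lo, b_hi = RATE_BOUNDS[kind]
    lo = b_lo if lo is None else lo
    hi = b_hi if hi is None else hi
    rng = np.random.default_rng(seed)
    return Schedule(kind=kind, rates=tuple(rng.uniform(lo, hi, n_segments)))


def forward_series(stable_field: OxygenField, masks: IndicatorMasks,
                   true_schedule: Schedule,
                   params: ModelParams | None = None,
                   label: str = "synthetic-forward",
                   ) -> tuple[ROISeries, Schedule]:
    """Simulate a known schedule forward; ground truth for recovery tests."""
    params = params or stable_field.params or default_params()
    kw = ({"influx_rates": true_schedule.as_array()}
          if true_schedule.kind == "influx"
          else {"uptake_rates": true_schedule.as_array()})
    vals = simulate_schedule(stable_field, masks, params=params,
                             boundaries_min=true_schedule.boundaries_min, **kw)
    series = ROISeries(values=vals,
                       times_min=np.asarray(true_schedule.boundaries_min[1:]),
                       label=label)
    return series, true_schedule
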