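"""Robustness of fitted schedules across morphologically distinct tissues.

A schedule fitted on one tissue is applied verbatim (no re-optimization) to
every representative tissue -- those whose stabilized average pO2 lies
within a tolerance of the measured anchor -- each starting from its own
stationary field. Tissues whose simulated series stays within a
goodness-of-fit threshold of the measured series count as reproducing the
fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryEntry, stabilized_layout
from .oxygen import build_indicator_masks, simulate_schedule
from .params import ModelParams, default_params
from .schedules import ROISeries, Schedule, goodness_of_fit

__all__ = ["RobustnessReport", "evaluate_schedule", "robustness_counts"]


@dataclass
class RobustnessReport:
    roi_label: str
    threshold: float
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_representatives(self) -> int:
        return len(self.records)

    def n_pass(self, kind: str) -> int:
        col = f"gof_{kind}"
        if col not in self.records:
            return 0
        return int((self.records[col] < self.threshold).sum())

    def summary(self) -> dict:
        out = {"roi": self.roi_label, "threshold": self.threshold,
               "n_representatives": self.n_representatives}
        for kind in ("influx", "uptake"):
            if f"gof_{kind}" in self.records:
                out[f"n_pass_{kind}"] = self.n_pass(kind)
        return out


def evaluate_schedule(entry: LibraryEntry, schedule: Schedule, roi: ROISeries,
                      params: ModelParams | None = None,
                      gof_form: str = "relative") -> float:
    """Goodness of fit of a fixed schedule applied to one library tissue.

    The tissue's own stationary field (regenerated from its recorded seed)
    is the initial condition, exactly as during fitting.
    """
    params = params or default_params()
    layout, fld, _ = stabilized_layout(entry.composition, params, entry.seed)
    masks = build_indicator_masks(layout, params)
    kw = ({"influx_rates": schedule.as_array()} if schedule.kind == "influx"
          else {"uptake_rates": schedule.as_array()})
    sim = simulate_schedule(fld, masks, params=params,
                            boundaries_min=roi.boundaries_min, **kw)
    return goodness_of_fit(roi.values, sim, gof_form)


def robustness_counts(representatives: list[LibraryEntry],
                      schedules: dict[str, Schedule] | Schedule,
                      roi: ROISeries, threshold: float = 0.2,
                      params: ModelParams | None = None,
                      gof_form: str = "relative") -> RobustnessReport:
    """Apply schedule(s) to every representative and count threshold passes.

    ``schedules`` may be a single schedule or a mapping with keys "influx"
    and/or "uptake". The per-tissue table records the composition, the
    deviation of the stabilized pO2 from the ROI anchor, and the
    goodness of fit under each schedule (the scatter behind the
    deviation-vs-GoF robustness plots).
    """
    params = params or default_params()
    if isinstance(schedules, Schedule):
        schedules = {schedules.kind: schedules}
    anchor = roi.anchor_po2 if roi.anchor_po2 is not None else roi.values.max()
    rows = []
    for entry in representatives:
        layout, fld, _ = stabilized_layout(entry.composition, params, entry.seed)
        masks = build_indicator_masks(layout, params)
        row = {
            "vascular": entry.composition.vascular,
            "tumor": entry.composition.tumor,
            "stromal": entry.composition.stromal,
            "seed": entry.seed,
            "stabilized_po2": fld.average,
            "deviation_mmHg": fld.average - anchor,
        }
        for kind, sched in schedules.items():
            kw = ({"influx_rates": sched.as_array()} if kind == "influx"
                  else {"uptake_rates": sched.as_array()})
            sim = simulate_schedule(fld, masks, params=params,
                                    boundaries_min=roi.boundaries_min, **kw)
            row[f"gof_{kind}"] = goodness_of_fit(roi.values, sim, gof_form)
        rows.append(row)
    return RobustnessReport(roi_label=roi.label, threshold=threshold,
                            records=pd.DataFrame(rows))
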