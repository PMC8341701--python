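"""Model / results facade over the schedule-fitting pipeline.

`FluctuationModel` packages the full inverse problem -- which
piecewise-constant vascular-influx or tumor-uptake schedule makes a given
tissue's voxel-average pO2 track a measured series -- behind a familiar
``model.fit() -> results`` interface, with the tissue generation and
stabilization handled internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oxygen import OxygenField, build_indicator_masks, stabilize
from .params import ModelParams, SearchOptions, default_params
from .schedules import FitResult, ROISeries, fit_schedule
from .tissue import TissueComposition, TissueLayout, resolve_overlaps, sample_layout

__all__ = ["FluctuationModel", "FluctuationResults"]


class FluctuationModel:
    """Inverse model of short-time pO2 fluctuations in one tissue voxel.

    Parameters
    ----------
    roi : ROISeries
        Measured voxel-average pO2 at the segment endpoints.
    layout : TissueLayout
        Relaxed tissue morphology whose stationary oxygen level matches the
        ROI anchor (see :func:`oxyvoxel.library.find_closest`).
    params : ModelParams, optional
    """

    def __init__(self, roi: ROISeries, layout: TissueLayout,
                 params: ModelParams | None = None):
        self.roi = roi
        self.layout = layout
        self.params = params or default_params()
        self._masks = None
        self._stable: OxygenField | None = None
        self._stable_report = None

    @classmethod
    def from_composition(cls, roi: ROISeries, composition, seed: int = 0,
                         params: ModelParams | None = None) -> "FluctuationModel":
        """Build the tissue from a (vascular, tumor, stromal) composition."""
        params = params or default_params()
        if not isinstance(composition, TissueComposition):
            composition = TissueComposition(*composition)
        layout = resolve_overlaps(sample_layout(composition, params, seed), params)
        return cls(roi, layout, params)

    def _prepare(self) -> None:
        if self._stable is None:
            self._masks = build_indicator_masks(self.layout, self.params)
            self._stable, self._stable_report = stabilize(
                self.layout, self.params, masks=self._masks)

    @property
    def stabilized_po2(self) -> float:
        self._prepare()
        return self._stable.average

    def fit(self, mode: str = "influx",
            search_opts: SearchOptions | None = None,
            gof_form: str = "relative") -> "FluctuationResults":
        """Fit the rate schedule of one mechanism to the ROI series."""
        self._prepare()
        res = fit_schedule(self._stable, self._masks, self.roi, mode,
                           self.params, search_opts, gof_form)
        return FluctuationResults(self, mode, res)


@dataclass
class FluctuationResults:
    """Fitted schedule with diagnostics."""

    model: FluctuationModel
    mode: str
    fit_result: FitResult

    @property
    def schedule(self):
        return self.fit_result.schedule

    @property
    def rates(self) -> np.ndarray:
        return self.fit_result.schedule.as_array()

    @property
    def gof(self) -> float:
        return self.fit_result.gof

    @property
    def simulated(self) -> np.ndarray:
        return self.fit_result.simulated

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fit_result.summary_rows())

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Oxygen fluctuation schedule fit",
            "===============================",
            f"mechanism:        {self.mode} "
            f"({'delta_V in [0,1]' if self.mode == 'influx' else 'delta_T in [0,50]'})",
            f"ROI label:        {self.model.roi.label or '(unnamed)'}",
            f"stabilized pO2:   {self.model.stabilized_po2:.2f} mmHg",
            f"goodness of fit:  {self.gof:.4g} ({self.fit_result.gof_form})",
            f"evaluations:      {self.fit_result.n_evaluations}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs simulated series (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.roi.times_min
        ax.plot(t, self.model.roi.values, "k-o", label="measured")
        ax.plot(t, self.simulated, "b^--", label=f"simulated ({self.mode})")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("average pO2 (mmHg)")
        ax.legend()
        return ax
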