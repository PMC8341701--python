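"""File formats: layouts (CSV), fields (HDF5/CSV), series (CSV), JSON results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .oxygen import OxygenField, StabilizationReport
from .params import ModelParams, default_params
from .schedules import FitResult, ROISeries, Schedule
from .tissue import TissueComposition, TissueLayout

__all__ = [
    "LayoutParseError",
    "write_layout", "read_layout",
    "save_field", "load_field", "export_field_csv",
    "write_roi_series", "read_roi_series",
    "schedule_to_dict", "schedule_from_dict",
    "write_fit_result", "read_schedule",
]

_LAYOUT_COLUMNS = ["type", "x_um", "y_um", "radius_um"]
_KINDS = ("vessel", "tumor", "stromal")


class LayoutParseError(ValueError):
    pass


def write_layout(layout: TissueLayout, path, params: ModelParams | None = None) -> None:
    """CSV with header ``type,x_um,y_um,radius_um``; coordinates to 6 decimals."""
    params = params or default_params()
    rows = []
    for kind, pts in (("vessel", layout.vessels), ("tumor", layout.tumor_cells),
                      ("stromal", layout.stromal_cells)):
        r = params.radius_of(kind)
        for x, y in np.asarray(pts):
            rows.append((kind, f"{x:.6f}", f"{y:.6f}", f"{r:g}"))
    df = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    df.to_csv(path, index=False)


def read_layout(path, params: ModelParams | None = None,
                composition: TissueComposition | None = None) -> TissueLayout:
    """Read a layout CSV; unknown element types are rejected with the line."""
    params = params or default_params()
    try:
        df = pd.read_csv(path, dtype={"type": str})
    except Exception as exc:  # malformed CSV
        raise LayoutParseError(f"{path}: {exc}") from exc
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutParseError(f"{path}: missing columns {missing}")
    bad = df.index[~df["type"].isin(_KINDS)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise LayoutParseError(
            f"{path}: unknown element type {df.loc[bad[0], 'type']!r} "
            f"on line {int(bad[0]) + 2}")
    for col in ("x_um", "y_um", "radius_um"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise LayoutParseError(
                f"{path}: non-numeric values in {col}") from exc
    pts = {k: df.loc[df["type"] == k, ["x_um", "y_um"]].to_numpy(dtype=float)
           for k in _KINDS}
    if composition is None:
        area = params.domain_area
        composition = TissueComposition(*(
            100.0 * len(pts[k]) * params.nominal_area(k) / area for k in _KINDS))
    return TissueLayout(vessels=pts["vessel"], tumor_cells=pts["tumor"],
                        stromal_cells=pts["stromal"], composition=composition,
                        relaxed=True)


def save_field(field: OxygenField, path,
               report: StabilizationReport | None = None) -> None:
    """HDF5 container: 2-D values plus dx / domain / unit metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("po2_mmHg", data=field.values)
        ds.attrs["dx_um"] = field.params.dx
        ds.attrs["domain_um"] = list(field.params.domain)
        ds.attrs["units"] = "mmHg"
        if report is not None:
            for key, val in dataclasses.asdict(report).items():
                ds.attrs[f"stabilization_{key}"] = val


def load_field(path, params: ModelParams | None = None) -> OxygenField:
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["po2_mmHg"]
        values = ds[()]
        dx = float(ds.attrs["dx_um"])
        domain = tuple(float(v) for v in ds.attrs["domain_um"])
    if params is None:
        params = default_params(dx=dx, domain=domain)
    return OxygenField(values, params)


def export_field_csv(field: OxygenField, path) -> None:
    """Plain matrix export (rows = x index, columns = y index)."""
    np.savetxt(path, field.values, delimiter=",")


def write_roi_series(series: ROISeries, path) -> None:
    """CSV ``t_min,po2_mmHg`` with label/anchor metadata in comments."""
    with open(path, "w") as fh:
        fh.write(f"# label: {series.label}\n")
        fh.write(f"# anchor_po2_mmHg: {series.anchor_po2}\n")
        fh.write("t_min,po2_mmHg\n")
        for t, v in zip(series.times_min, series.values):
            fh.write(f"{t:g},{v:.6f}\n")


def read_roi_series(path) -> ROISeries:
    label, anchor = "", None
    with open(path) as fh:
        lines = fh.readlines()
    data = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            if key.strip() == "label":
                label = val.strip()
            elif key.strip() == "anchor_po2_mmHg":
                anchor = float(val)
        elif ln.strip() and not ln.startswith("t_min"):
            t, v = ln.split(",")
            data.append((float(t), float(v)))
    arr = np.asarray(data)
    return ROISeries(values=arr[:, 1], times_min=arr[:, 0], label=label,
                     anchor_po2=anchor)


def schedule_to_dict(schedule: Schedule) -> dict:
    return {"kind": schedule.kind, "boundaries_min": list(schedule.boundaries_min),
            "rates": list(schedule.rates)}


def schedule_from_dict(d: dict) -> Schedule:
    return Schedule(kind=d["kind"], rates=tuple(d["rates"]),
                    boundaries_min=tuple(d.get("boundaries_min",
                                               Schedule.boundaries_min)))


def write_fit_result(result: FitResult, path, extra: dict | None = None) -> None:
    doc = schedule_to_dict(result.schedule)
    doc.update({
        "gof": result.gof,
        "gof_form": result.gof_form,
        "simulated_mmHg": [float(v) for v in result.simulated],
        "target_mmHg": [float(v) for v in result.target],
        "n_evaluations": result.n_evaluations,
    })
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_schedule(path) -> Schedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))
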