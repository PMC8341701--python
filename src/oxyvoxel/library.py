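"""Composition sweep, steady-state library, classification and matching.

The library enumerates tissue compositions (vascularity 0.5-5% in steps of
0.5; tumor cellularity 10-95% and stromal cellularity 5-95% in steps of 5;
total occupancy at most 100%), generates one relaxed morphology per
composition, stabilizes its oxygen field, and records the voxel-average
pO2. Tissues are binned into five oxygenation classes over [0, 60] mmHg
and matched against measured voxel values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .oxygen import build_indicator_masks, stabilize
from .params import ModelParams, default_params
from .tissue import TissueComposition, TissueLayout, resolve_overlaps, sample_layout

__all__ = [
    "LibraryEntry",
    "TissueLibrary",
    "CLASS_EDGES",
    "sweep_compositions",
    "classify",
    "build_library",
    "find_closest",
    "select_representatives",
    "replicate_statistics",
    "stabilized_layout",
]

#: Oxygenation class edges (mmHg): [0,12), [12,24), [24,36), [36,48), [48,60].
CLASS_EDGES = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass
class LibraryEntry:
    composition: TissueComposition
    seed: int
    average_po2: float
    class_index: int
    iterations: int
    converged: bool
    jammed: bool = False
    layout_path: str | None = None

    def row(self) -> dict:
        return {
            "vascular": self.composition.vascular,
            "tumor": self.composition.tumor,
            "stromal": self.composition.stromal,
            "seed": self.seed,
            "avg_po2_mmHg": self.average_po2,
            "class": self.class_index,
            "iterations": self.iterations,
            "converged": self.converged,
            "jammed": self.jammed,
            "layout_path": self.layout_path or "",
        }


@dataclass
class TissueLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    global_seed: int | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def averages(self) -> np.ndarray:
        return np.asarray([e.average_po2 for e in self.entries])

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(len(CLASS_EDGES) - 1, dtype=int)
        for e in self.entries:
            counts[e.class_index] += 1
        return counts


def sweep_compositions() -> list[TissueComposition]:
    """The full constrained sweep, in deterministic lexicographic order."""
    out = []
    for v10 in range(5, 51, 5):          # vascularity in tenths of a percent
        for t in range(10, 96, 5):
            for s in range(5, 96, 5):
                if v10 / 10.0 + t + s <= 100.0:
                    out.append(TissueComposition(v10 / 10.0, float(t), float(s)))
    return out


def classify(average_po2: float) -> int:
    """Oxygenation class of a stabilized average (0..4, 12 mmHg bins).

    Bins are half-open with a closed top bin, so exactly 36.0 mmHg falls in
    class 3 and 60.0 in class 4.
    """
    if not 0.0 <= average_po2 <= CLASS_EDGES[-1]:
        raise ValueError(f"average pO2 {average_po2} outside [0, 60] mmHg")
    idx = int(average_po2 // 12.0)
    return min(idx, len(CLASS_EDGES) - 2)


def composition_seed(global_seed: int, index: int) -> int:
    """Independent per-composition seed derived from (global seed, index)."""
    ss = np.random.SeedSequence([int(global_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stabilized_layout(comp: TissueComposition, params: ModelParams,
                      seed: int) -> tuple[TissueLayout, "object", "object"]:
    """Sample, relax and stabilize one tissue; returns (layout, field, report)."""
    layout = resolve_overlaps(sample_layout(comp, params, seed), params)
    fld, report = stabilize(layout, params)
    return layout, fld, report


def build_library(compositions=None, params: ModelParams | None = None,
                  seed: int = 0, checkpoint: str | Path | None = None,
                  progress: bool = False) -> TissueLibrary:
    """Stabilize one tissue per composition; reproducible from ``seed``.

    With ``checkpoint`` set, finished entries are appended to a CSV index
    and a partial build resumes from it. Non-converged entries are flagged
    and retained.
    """
    params = params or default_params()
    compositions = compositions if compositions is not None else sweep_compositions()
    done: dict[tuple, LibraryEntry] = {}
    path = Path(checkpoint) if checkpoint else None
    fields = ["vascular", "tumor", "stromal", "seed", "avg_po2_mmHg", "class",
              "iterations", "converged", "jammed", "layout_path"]
    if path and path.exists():
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                comp = TissueComposition(float(row["vascular"]),
                                         float(row["tumor"]),
                                         float(row["stromal"]))
                done[comp.astuple()] = LibraryEntry(
                    comp, int(row["seed"]), float(row["avg_po2_mmHg"]),
                    int(row["class"]), int(row["iterations"]),
                    row["converged"] == "True", row["jammed"] == "True",
                    row["layout_path"] or None)
    writer = None
    fh = None
    if path:
        new = not path.exists()
        fh = open(path, "a", newline="")
        writer = csv.DictWriter(fh, fieldnames=fields)
        if new:
            writer.writeheader()
    lib = TissueLibrary(global_seed=seed)
    try:
        iterator = enumerate(compositions)
        if progress:
            try:
                from tqdm import tqdm  # optional nicety
                iterator = tqdm(list(iterator), desc="library")
            except ImportError:
                pass
        for i, comp in iterator:
            if comp.astuple() in done:
                lib.entries.append(done[comp.astuple()])
                continue
            child = composition_seed(seed, i)
            layout, fld, report = stabilized_layout(comp, params, child)
            entry = LibraryEntry(
                composition=comp, seed=child,
                average_po2=report.average_po2,
                class_index=classify(min(report.average_po2, CLASS_EDGES[-1])),
                iterations=report.iterations, converged=report.converged,
                jammed=layout.jammed)
            lib.entries.append(entry)
            if writer:
                writer.writerow(entry.row())
                fh.flush()
    finally:
        if fh:
            fh.close()
    return lib


def find_closest(library: TissueLibrary, target_po2: float) -> LibraryEntry:
    """Entry whose stabilized average is nearest the target (ties: first)."""
    if not library.entries:
        raise ValueError("empty library")
    dist = np.abs(library.averages() - target_po2)
    return library.entries[int(np.argmin(dist))]


def select_representatives(library: TissueLibrary, target_po2: float,
                           tol: float = 3.5) -> list[LibraryEntry]:
    """All entries with stabilized average within ``tol`` mmHg of the target."""
    return [e for e in library.entries
            if abs(e.average_po2 - target_po2) <= tol]


def replicate_statistics(comp: TissueComposition, n: int = 25,
                         params: ModelParams | None = None, seed: int = 0,
                         ) -> tuple[float, float, np.ndarray]:
    """Mean and sample SD of stabilized averages over ``n`` morphologies.

    The ``n`` tissues share the composition but have independent random
    layouts (seeds spawned from ``seed``).
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    params = params or default_params()
    vals = np.empty(n)
    for rep in range(n):
        child = composition_seed(seed, rep)
        _, _, report = stabilized_layout(comp, params, child)
        if not report.converged:
            raise RuntimeError(f"replicate {rep} did not converge")
        vals[rep] = report.average_po2
    return float(vals.mean()), float(vals.std(ddof=1)), vals
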