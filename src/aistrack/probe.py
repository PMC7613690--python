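"""HD-MEA probe geometry.

Default layout follows a CMOS high-density array: a 30 x 30 electrode grid at
17.5 um pitch with 9.3 x 5.45 um rectangular electrodes, of which the central
12 x 12 block is used for footprint analysis.  Electrodes are treated as
points at their centers for the forward model (pitch >> electrode size).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_ROWS = 30
DEFAULT_COLS = 30
DEFAULT_PITCH_UM = 17.5
DEFAULT_ELECTRODE_W_UM = 9.3
DEFAULT_ELECTRODE_H_UM = 5.45
ANALYSIS_BLOCK = 12


@dataclass
class Probe:
    n_rows: int
    n_cols: int
    pitch: float
    electrode_w: float
    electrode_h: float
    centers: np.ndarray  # (n, 3) um, z = 0 plane
    analysis_block: np.ndarray  # electrode indices of the central 12 x 12

    @property
    def n_electrodes(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch": self.pitch,
            "electrode_w": self.electrode_w,
            "electrode_h": self.electrode_h,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def export_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "z"])
            for i, c in enumerate(self.centers):
                w.writerow([i, c[0], c[1], c[2]])


def build_probe(
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    pitch: float = DEFAULT_PITCH_UM,
    w: float = DEFAULT_ELECTRODE_W_UM,
    h: float = DEFAULT_ELECTRODE_H_UM,
    block: int = ANALYSIS_BLOCK,
) -> Probe:
    """Build a planar electrode lattice centered on the origin (z = 0).

    Electrode index = row * cols + col, row-major.  The analysis block is the
    central ``block x block`` sub-grid; when the grid size minus the block is
    odd, the block shifts toward lower indices.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if rows < block or cols < block:
        raise ValueError(f"grid must be at least {block} x {block}")
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    ys = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys)  # row-major: y varies along rows
    centers = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(rows * cols)])

    r0 = (rows - block) // 2
    c0 = (cols - block) // 2
    rr, cc = np.meshgrid(np.arange(r0, r0 + block), np.arange(c0, c0 + block), indexing="ij")
    analysis = (rr * cols + cc).ravel()
    return Probe(rows, cols, pitch, w, h, centers, analysis)


def load_probe_json(path) -> Probe:
    with open(path) as fh:
        d = json.load(fh)
    return build_probe(d["n_rows"], d["n_cols"], d["pitch"], d["electrode_w"], d["electrode_h"])


def nearest_electrode(probe: Probe, p) -> int:
    """Index of the electrode center closest to point ``p``; ties -> lowest index."""
    p = np.asarray(p, dtype=float)
    d2 = np.sum((probe.centers - p) ** 2, axis=1)
    # round distances to break numeric near-ties deterministically toward low ids
    d2 = np.round(d2, 9)
    return int(np.argmin(d2))
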