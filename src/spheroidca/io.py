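"""Exporters: cross-sections, trajectories and run metadata."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .config import ScenarioConfig
from .lattice import CellGrid
from .oxygen import OxygenField

__all__ = ["export_cross_section", "write_run_metadata"]

_QUANTITIES = ("OCCUPANCY", "PHASE", "FATE", "PO2")


def _plane(arr: np.ndarray, axis: int, index: int) -> np.ndarray:
    if not 0 <= index < arr.shape[axis]:
        raise ValueError(f"plane index {index} out of bounds for axis {axis}")
    return np.take(arr, index, axis=axis)


def export_cross_section(
    grid: CellGrid,
    field: Optional[OxygenField],
    axis: int,
    index: int,
    what: str,
    path,
) -> Path:
    """Write one lattice plane as a CSV matrix plus a PNG rendering.

    ``what`` selects the per-voxel quantity: OCCUPANCY (0/1), PHASE (cycle
    stage code, -1 empty), FATE (treatment label, -1 empty) or PO2 (mmHg,
    requires ``field``).  ``path`` is the stem; ``.csv`` and ``.png`` are
    appended.  Returns the CSV path.
    """
    what = what.upper()
    if what not in _QUANTITIES:
        raise ValueError(f"what must be one of {_QUANTITIES}")
    if what == "OCCUPANCY":
        data = _plane(grid.occupied.astype(np.int8), axis, index)
    elif what == "PHASE":
        data = _plane(grid.phase, axis, index)
    elif what == "FATE":
        fate = np.where(grid.occupied, grid.fate, -1)
        data = _plane(fate.astype(np.int8), axis, index)
    else:
        if field is None:
            raise ValueError("PO2 export requires an oxygen field")
        data = _plane(field.values, axis, index)
    stem = Path(path)
    csv_path = stem.with_suffix(".csv")
    fmt = "%.6g" if what == "PO2" else "%d"
    np.savetxt(csv_path, data, delimiter=",", fmt=fmt)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(data.T, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, label=what.lower())
    ax.set_title(f"{what} (axis {axis}, index {index})")
    fig.savefig(stem.with_suffix(".png"), dpi=120, bbox_inches="tight")
    plt.close(fig)
    return csv_path


def write_run_metadata(cfg: ScenarioConfig, seed: int, outdir) -> Path:
    """Dump the resolved config, seed and version so a run can be reproduced."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": seed,
        "config": cfg.model_dump(mode="json"),
        "non_paper_defaults": cfg.log_non_paper_defaults(),
    }
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2))
    return path
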