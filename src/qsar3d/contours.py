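"""StDev*Coeff contour fields and OpenDX export.

The contour quantity at each lattice point is the product of the
descriptor column's standard deviation and its PLS coefficient — the map
of where field variation drives predicted activity.  Favored/disfavored
iso-levels are chosen as contribution-mass percentiles of the signed
distribution (by default the surfaces enclose 80% of the positive and 20%
of the negative contribution mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import FieldGrid
from .pls import PLSQSARResults

__all__ = ["ContourField", "stdev_coeff_fields", "contribution_level",
           "write_opendx", "top_points"]


@dataclass
class ContourField:
    name: str
    grid: FieldGrid
    values: np.ndarray              # flat, z-fastest; filtered columns = 0
    level_favored: float | None    # iso-value for the favored surface
    level_disfavored: float | None

    def reshaped(self) -> np.ndarray:
        return self.values.reshape(self.grid.dims)


def contribution_level(values: np.ndarray, mass_fraction: float,
                       positive: bool = True) -> float | None:
    """Iso-value such that points beyond it hold ``mass_fraction`` of the
    total positive (or negative) contribution mass."""
    vals = values[values > 0] if positive else -values[values < 0]
    if vals.size == 0:
        return None
    vals = np.sort(vals)[::-1]
    cum = np.cumsum(vals)
    idx = int(np.searchsorted(cum, mass_fraction * cum[-1]))
    level = vals[min(idx, len(vals) - 1)]
    return float(level if positive else -level)


def stdev_coeff_fields(results: PLSQSARResults, grid: FieldGrid,
                       favored_mass: float = 0.80,
                       disfavored_mass: float = 0.20
                       ) -> dict[str, ContourField]:
    """One StDev*Coeff field per lattice-based descriptor block."""
    if results.model.columns is None:
        raise ValueError("model was built without column metadata")
    sigma = results.model.exog.std(axis=0, ddof=1)
    fields: dict[str, np.ndarray] = {}
    for j, info in enumerate(results.model.columns):
        if info.lattice_index < 0:
            continue  # whole-molecule columns (clogp) have no lattice home
        arr = fields.setdefault(info.field, np.zeros(grid.n_points))
        arr[info.lattice_index] = sigma[j] * results.params[j]
    out = {}
    for name, vals in fields.items():
        out[name] = ContourField(
            name, grid, vals,
            contribution_level(vals, favored_mass, positive=True),
            contribution_level(vals, disfavored_mass, positive=False),
        )
    return out


def write_opendx(field: ContourField, path: str | Path) -> None:
    """Write the field as an OpenDX scalar grid (z-fastest, matching the
    internal lattice order)."""
    g = field.grid
    nx, ny, nz = g.dims
    ox, oy, oz = g.origin
    s = g.spacing
    lines = [
        f"# qsar3d StDev*Coeff field: {field.name}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {g.n_points} data follows",
    ]
    vals = field.values
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def top_points(field: ContourField, k: int = 10) -> pd.DataFrame:
    """Top-k favored and disfavored lattice points with coordinates."""
    order = np.argsort(field.values)
    rows = []
    for kind, idxs in (("favored", order[::-1][:k]), ("disfavored", order[:k])):
        for i in idxs:
            if (kind == "favored" and field.values[i] <= 0) or \
               (kind == "disfavored" and field.values[i] >= 0):
                continue
            x, y, z = field.grid.point(int(i))
            rows.append({"kind": kind, "lattice_index": int(i),
                         "x": x, "y": y, "z": z,
                         "stdev_coeff": field.values[i]})
    return pd.DataFrame(rows)
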