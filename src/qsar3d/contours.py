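"""STDEV*COEFF contour maps from a fitted field-PLS model.

Each lattice node's value is the product of the training-column standard
deviation and the PLS regression coefficient at that node (response
units), mapped back through the column filter so dropped columns carry 0.
Large positive values mark regions where adding field intensity (bulk,
charge, ...) raises predicted activity; large negative values where it
lowers it.  Iso-levels are set at percentiles of the nonzero value
distribution (the conventional "favoured/disfavoured percent
contribution" display); rendering itself is left to standard volumetric
viewers via OpenDX export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import FieldBlock, GridSpec
from .pls import PLSFitResults

__all__ = [
    "ContourMap",
    "stdev_coeff_map",
    "contour_levels",
    "export_map",
    "read_dx",
]


@dataclass
class ContourMap:
    field: str
    grid: GridSpec
    values: np.ndarray  # per node, response units; filtered nodes are 0
    favored_level: float | None = None
    disfavored_level: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.grid.n_points:
            raise ValueError("value count does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contour values must be finite")


def stdev_coeff_map(
    results: PLSFitResults, block: FieldBlock
) -> dict[str, ContourMap]:
    """One STDEV*COEFF map per field of the fitted block."""
    if block.matrix.shape[1] != results.coefficients.size:
        raise ValueError("field block does not match the fitted model's column space")
    state = results.state
    sd_full = np.zeros(state.n_columns)
    sd_full[state.mask] = state.col_sd
    node_values = sd_full * results.coefficients  # filtered columns -> 0

    maps: dict[str, ContourMap] = {}
    for name in block.fields:
        sl = block.field_slice(name)
        maps[name] = ContourMap(field=name, grid=block.grid, values=node_values[sl])
    return maps


def contour_levels(
    cmap: ContourMap, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Percentile iso-levels of the nonzero node-value distribution."""
    nz = cmap.values[cmap.values != 0]
    if nz.size == 0:
        raise ValueError("all-zero contour map has no levels")
    favored = float(np.percentile(nz, favored_pct))
    disfavored = float(np.percentile(nz, disfavored_pct))
    cmap.favored_level, cmap.disfavored_level = favored, disfavored
    return favored, disfavored


def export_map(cmap: ContourMap, path: str | Path) -> Path:
    """Write the map as an OpenDX regular-grid scalar file.

    Data items follow the grid's x-fastest node order; two exports of the
    same map are byte-identical.
    """
    path = Path(path)
    g = cmap.grid
    n = g.n_points
    nx, ny, nz = g.dims
    # OpenDX enumerates the last counting index fastest; emit values in
    # (x slowest .. z fastest) order so re-import in x-fastest order is exact.
    vals = cmap.values.reshape((nz, ny, nx)).transpose(2, 1, 0).ravel()
    lines = [
        f"# STDEV*COEFF map, field: {cmap.field}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}",
        f"delta {g.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {g.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {g.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    for i in range(0, n, 3):
        lines.append(" ".join(f"{v:.10e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dx(path: str | Path) -> ContourMap:
    """Read an OpenDX regular-grid scalar file written by :func:`export_map`."""
    text = Path(path).read_text().splitlines()
    dims = origin = None
    spacing = None
    data: list[float] = []
    in_data = False
    n_items = 0
    deltas = []
    for line in text:
        s = line.strip()
        if s.startswith("#") or not s:
            continue
        if s.startswith("object 1"):
            dims = tuple(int(x) for x in s.split("counts")[1].split())
        elif s.startswith("origin"):
            origin = tuple(float(x) for x in s.split()[1:4])
        elif s.startswith("delta"):
            deltas.append([float(x) for x in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
        elif in_data and len(data) < n_items:
            data.extend(float(x) for x in s.split())
    if dims is None or origin is None or not deltas:
        raise ValueError(f"{path}: not a recognisable OpenDX grid file")
    spacing = deltas[0][0]
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    nx, ny, nz = dims
    vals = np.array(data[: nx * ny * nz]).reshape((nx, ny, nz)).transpose(2, 1, 0).ravel()
    return ContourMap(field=Path(path).stem, grid=grid, values=vals)
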