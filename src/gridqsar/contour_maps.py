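"""Favored/disfavored contour regions from sd*coefficient lattices, with
OpenDX export for molecular viewers.

Color labels follow the usual display convention per field kind
(steric green/yellow, electrostatic blue/red, donor cyan/purple); they are
metadata only — no rendering here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import GridSpec

__all__ = ["ContourSet", "extract_contours", "export_dx", "read_dx",
           "contour_table", "write_pymol_script", "FIELD_COLORS"]

FIELD_COLORS = {
    "comfa_S": ("green", "yellow"),
    "comfa_E": ("blue", "red"),
    "comsia_S": ("green", "yellow"),
    "comsia_E": ("blue", "red"),
    "comsia_H": ("yellow", "white"),
    "comsia_D": ("cyan", "purple"),
    "comsia_A": ("magenta", "red"),
}


@dataclass
class ContourSet:
    """Voxel membership of favored / disfavored regions for one field."""

    kind: str
    fav_pct: float
    disfav_pct: float
    favored_idx: np.ndarray  # (m, 3) lattice ijk
    disfavored_idx: np.ndarray
    favored_coords: np.ndarray  # (m, 3) Angstrom
    disfavored_coords: np.ndarray
    favored_values: np.ndarray
    disfavored_values: np.ndarray
    colors: tuple[str, str] = ("green", "yellow")

    def __post_init__(self) -> None:
        if not (0 < self.fav_pct < 100 and 0 < self.disfav_pct < 100):
            raise ValueError("percentile thresholds must lie in (0, 100)")


def _voxel_coords(grid: GridSpec, ijk: np.ndarray) -> np.ndarray:
    if len(ijk) == 0:
        return np.zeros((0, 3))
    return np.asarray(grid.origin) + grid.spacing * ijk


def extract_contours(
    values: np.ndarray,
    grid: GridSpec,
    fav_pct: float = 80.0,
    disfav_pct: float = 20.0,
    kind: str = "comfa_S",
    *,
    mode: str = "percentile",
    fav_level: float | None = None,
    disfav_level: float | None = None,
) -> ContourSet:
    """Threshold an (nx, ny, nz) lattice into favored/disfavored voxel sets.

    In ``percentile`` mode voxels strictly above the ``fav_pct`` percentile
    of the value distribution are favored and those strictly below
    ``disfav_pct`` disfavored. ``absolute`` mode thresholds at the given
    levels instead. A constant lattice yields empty sets with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.counts):
        raise ValueError("values shape does not match the grid")
    if values.size == 0:
        raise ValueError("empty grid")
    flat = values.ravel()
    if np.ptp(flat) == 0:
        warnings.warn("constant lattice: no contours extracted", stacklevel=2)
        empty = np.zeros((0, 3), dtype=int)
        return ContourSet(kind, fav_pct, disfav_pct, empty, empty,
                          np.zeros((0, 3)), np.zeros((0, 3)),
                          np.zeros(0), np.zeros(0),
                          FIELD_COLORS.get(kind, ("green", "yellow")))
    if mode == "percentile":
        hi = np.percentile(flat, fav_pct)
        lo = np.percentile(flat, disfav_pct)
    elif mode == "absolute":
        if fav_level is None or disfav_level is None:
            raise ValueError("absolute mode needs fav_level and disfav_level")
        hi, lo = fav_level, disfav_level
    else:
        raise ValueError(f"unknown contour mode {mode!r}")
    fav = np.argwhere(values > hi)
    dis = np.argwhere(values < lo)
    return ContourSet(
        kind=kind,
        fav_pct=fav_pct,
        disfav_pct=disfav_pct,
        favored_idx=fav,
        disfavored_idx=dis,
        favored_coords=_voxel_coords(grid, fav),
        disfavored_coords=_voxel_coords(grid, dis),
        favored_values=values[tuple(fav.T)] if len(fav) else np.zeros(0),
        disfavored_values=values[tuple(dis.T)] if len(dis) else np.zeros(0),
        colors=FIELD_COLORS.get(kind, ("green", "yellow")),
    )


def contour_table(contours: ContourSet) -> pd.DataFrame:
    """Flat voxel listing (region, ijk, xyz, value), favored first."""
    rows = []
    for region, idx, coords, vals in (
        ("favored", contours.favored_idx, contours.favored_coords, contours.favored_values),
        ("disfavored", contours.disfavored_idx, contours.disfavored_coords,
         contours.disfavored_values),
    ):
        for (i, j, k), (x, y, z), v in zip(idx, coords, vals):
            rows.append({"field": contours.kind, "region": region,
                         "ix": int(i), "iy": int(j), "iz": int(k),
                         "x": x, "y": y, "z": z, "value": v})
    return pd.DataFrame(
        rows, columns=["field", "region", "ix", "iy", "iz", "x", "y", "z", "value"]
    )


# ---------------------------------------------------------------------------
# OpenDX scalar-field export (z-fastest data order, per the DX convention)


def export_dx(values: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write an (nx, ny, nz) lattice as an OpenDX scalar field file."""
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.counts):
        raise ValueError("values shape does not match the grid")
    nx, ny, nz = grid.counts
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.ravel(order="C")  # z fastest for shape (nx, ny, nz)
    for start in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.8e}" for v in flat[start : start + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX scalar field written by :func:`export_dx`."""
    counts = origin = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("object 1"):
            counts = tuple(int(v) for v in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(v) for v in line.split()[1:4])
        elif line.startswith("delta"):
            vals = [float(v) for v in line.split()[1:4]]
            deltas.append(max(vals))
        elif line.startswith("object 3"):
            n_items = int(line.split()[-3])
        elif n_items is not None and len(data) < n_items and line[0] in "0123456789-+.":
            data.extend(float(v) for v in line.split())
    if counts is None or origin is None or n_items is None:
        raise ValueError(f"{path} is not a recognizable DX scalar field")
    if len(data) != n_items:
        raise ValueError(f"{path}: expected {n_items} data items, found {len(data)}")
    if len(set(np.round(deltas, 9))) != 1:
        raise ValueError(f"{path}: anisotropic spacing unsupported")
    grid = GridSpec(origin=origin, spacing=deltas[0], counts=counts)
    return np.array(data).reshape(counts, order="C"), grid


def write_pymol_script(
    dx_files: dict[str, tuple[str, str]], path: str | Path, level: float = 0.005
) -> None:
    """Emit a PyMOL command script loading DX maps as colored isomeshes.

    ``dx_files`` maps field kind -> (favored dx path, disfavored dx path).
    """
    lines = []
    for kind, (fav_path, dis_path) in dx_files.items():
        fav_color, dis_color = FIELD_COLORS.get(kind, ("green", "yellow"))
        safe = kind.replace(":", "_")
        lines += [
            f"load {fav_path}, map_{safe}_fav",
            f"isomesh mesh_{safe}_fav, map_{safe}_fav, {level}",
            f"color {fav_color}, mesh_{safe}_fav",
            f"load {dis_path}, map_{safe}_dis",
            f"isomesh mesh_{safe}_dis, map_{safe}_dis, {-level}",
            f"color {dis_color}, mesh_{safe}_dis",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
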