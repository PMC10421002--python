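"""The 1-km² landscape grid: per-cell carbon, landscape totals, class maps.

Each grid cell covers one square kilometre and carries an ecozone label plus
an integer-m² area allocation per forest type (the stated bookkeeping
precision of the land-use database is 1 m²).  Carbon density C_A of a forest
type depends on the cell's ecozone through the stem-volume equation, so the
per-cell computation dispatches on ecozone before multiplying by the occupied
area.

Totals are accumulated with :func:`math.fsum` over the per-(cell, type)
contributions, so summing cells-then-types and types-then-cells give the same
grand total bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .carbon import CarbonResult, type_carbon
from .typology import (ECOZONES, ForestTypeRegistry, SpeciesTable, StandParams,
                       TypologyError)

M2_PER_CELL = 1_000_000
M2_PER_HA = 10_000.0


class GridError(ValueError):
    """Raised on malformed grids or land-use inputs."""


@dataclass
class GridCell:
    cell_id: str
    row: int
    col: int
    ecozone: str
    allocations: dict[str, int] = field(default_factory=dict)  # m² per type

    def __post_init__(self) -> None:
        if self.ecozone not in ECOZONES:
            raise GridError(f"cell {self.cell_id}: unknown ecozone {self.ecozone!r}")
        total = 0
        for ft, a in self.allocations.items():
            if a < 0:
                raise GridError(f"cell {self.cell_id}: negative area for {ft}")
            total += a
        if total > M2_PER_CELL:
            raise GridError(
                f"cell {self.cell_id}: allocations sum to {total} m² > 1 km²")

    @property
    def forest_area_m2(self) -> int:
        return sum(self.allocations.values())


@dataclass
class Landscape:
    """A rectangular grid of 1-km cells, row-major from the northwest corner.

    Cells absent from ``cells`` are no-data (sea, or outside the study
    region).  ``x_origin``/``y_origin`` locate the lower-left corner of the
    grid in map units (metres)."""

    nrows: int
    ncols: int
    cells: list[GridCell]
    x_origin: float = 0.0
    y_origin: float = 0.0
    cellsize: float = 1000.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise GridError(f"invalid grid dimensions {self.nrows}x{self.ncols}")
        seen: set[str] = set()
        for c in self.cells:
            if c.cell_id in seen:
                raise GridError(f"duplicate cell id {c.cell_id!r}")
            seen.add(c.cell_id)
            if not (0 <= c.row < self.nrows and 0 <= c.col < self.ncols):
                raise GridError(f"cell {c.cell_id}: indices ({c.row}, {c.col}) "
                                f"outside {self.nrows}x{self.ncols}")

    def area_by_type_ecozone(self) -> dict[tuple[str, str], int]:
        """Total allocated area in m² per (forest type, ecozone)."""
        acc: dict[tuple[str, str], int] = {}
        for cell in self.cells:
            for ft, a in cell.allocations.items():
                key = (ft, cell.ecozone)
                acc[key] = acc.get(key, 0) + a
        return acc


# ---------------------------------------------------------------------------
# Land-use CSV (long format)
# ---------------------------------------------------------------------------

def write_landuse(landscape: Landscape, path: str | Path) -> None:
    """Write ``landuse.csv``: one row per (cell, forest type) allocation.

    A leading comment line records the grid header so the exact dimensions
    (including empty border rows) survive the round trip."""
    lines = [
        f"# nrows={landscape.nrows} ncols={landscape.ncols} "
        f"cellsize={landscape.cellsize!r} x_origin={landscape.x_origin!r} "
        f"y_origin={landscape.y_origin!r}\n",
        "cell_id,row,col,ecozone,forest_type,area_m2\n",
    ]
    for cell in landscape.cells:
        if cell.allocations:
            for ft, a in cell.allocations.items():
                lines.append(
                    f"{cell.cell_id},{cell.row},{cell.col},{cell.ecozone},{ft},{a}\n")
        else:
            lines.append(f"{cell.cell_id},{cell.row},{cell.col},{cell.ecozone},,0\n")
    Path(path).write_text("".join(lines))


def read_landuse(path: str | Path,
                 registry: ForestTypeRegistry | None = None) -> Landscape:
    """Read a long-format land-use CSV into a :class:`Landscape`.

    If ``registry`` is given, allocations to unknown forest types are
    rejected.  Grid dimensions come from the header comment when present,
    otherwise from the maximum row/col indices."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            k, _, v = tok.partition("=")
            header[k] = float(v)
    df = pd.read_csv(path, comment="#",
                     dtype={"cell_id": str, "forest_type": str})
    cells: dict[str, GridCell] = {}
    for row in df.itertuples(index=False):
        cell = cells.get(row.cell_id)
        if cell is None:
            cell = GridCell(cell_id=row.cell_id, row=int(row.row),
                            col=int(row.col), ecozone=row.ecozone)
            cells[row.cell_id] = cell
        ft = row.forest_type
        if isinstance(ft, str) and ft:
            if registry is not None and ft not in registry:
                raise GridError(f"cell {row.cell_id}: unknown forest type {ft!r}")
            cell.allocations[ft] = cell.allocations.get(ft, 0) + int(row.area_m2)
    nrows = int(header.get("nrows", df["row"].max() + 1))
    ncols = int(header.get("ncols", df["col"].max() + 1))
    return Landscape(
        nrows=nrows, ncols=ncols, cells=list(cells.values()),
        x_origin=header.get("x_origin", 0.0),
        y_origin=header.get("y_origin", 0.0),
        cellsize=header.get("cellsize", 1000.0),
    )


# ---------------------------------------------------------------------------
# Per-cell computation and combination
# ---------------------------------------------------------------------------

def cell_carbon(cell: GridCell, registry: ForestTypeRegistry,
                species: SpeciesTable, stands: Mapping[str, StandParams],
                *, out_of_range: str = "warn") -> list[CarbonResult]:
    """Carbon storage of every forest type allocated in one cell."""
    results = []
    for ft_abbr, area_m2 in cell.allocations.items():
        ft = registry[ft_abbr]
        try:
            stand = stands[ft_abbr]
        except KeyError:
            raise TypologyError(f"no stand parameters for {ft_abbr!r}") from None
        results.append(type_carbon(ft, stand, species, cell.ecozone,
                                   area_m2 / M2_PER_HA,
                                   out_of_range=out_of_range))
    return results


@dataclass
class LandscapeCarbon:
    """Carbon storage of a whole landscape.

    ``per_type`` has one row per (forest type, ecozone) with columns
    forest_type, ecozone, area_ha, v_stand, c_a, c_t.  ``cell_totals`` is a
    (nrows, ncols) array of t C per cell with NaN for no-data cells.
    """

    per_type: pd.DataFrame
    cell_totals: np.ndarray
    landscape: Landscape

    @property
    def total_c_tonnes(self) -> float:
        return float(self.per_type["c_t"].sum())

    def per_type_totals(self) -> pd.DataFrame:
        """Collapse ecozones: one row per forest type (area-weighted)."""
        g = self.per_type.groupby("forest_type", as_index=False).agg(
            area_ha=("area_ha", "sum"), c_t=("c_t", "sum"),
            v_total=("v_total", "sum"))
        g["c_a"] = np.where(g["area_ha"] > 0, g["c_t"] / g["area_ha"], 0.0)
        g["v_stand"] = np.where(g["area_ha"] > 0, g["v_total"] / g["area_ha"], 0.0)
        return g


def estimate_landscape(landscape: Landscape, registry: ForestTypeRegistry,
                       species: SpeciesTable, stands: Mapping[str, StandParams],
                       *, out_of_range: str = "warn") -> LandscapeCarbon:
    """Compute per-cell carbon across the landscape and combine.

    C_A of each (forest type, ecozone) pair is evaluated once and reused for
    every cell, which makes the per-cell pass a pure area multiplication and
    keeps cells-then-types and types-then-cells aggregation consistent.
    """
    densities: dict[tuple[str, str], CarbonResult] = {}

    def density(ft_abbr: str, ecozone: str) -> CarbonResult:
        key = (ft_abbr, ecozone)
        if key not in densities:
            ft = registry[ft_abbr]
            try:
                stand = stands[ft_abbr]
            except KeyError:
                raise TypologyError(f"no stand parameters for {ft_abbr!r}") from None
            densities[key] = type_carbon(ft, stand, species, ecozone, 1.0,
                                         out_of_range=out_of_range)
        return densities[key]

    # per-(cell, type) contributions in t C; summed with fsum either way
    contributions: dict[tuple[str, str], list[float]] = {}
    cell_totals = np.full((landscape.nrows, landscape.ncols), np.nan)
    for cell in landscape.cells:
        parts = []
        for ft_abbr, area_m2 in cell.allocations.items():
            d = density(ft_abbr, cell.ecozone)
            c = d.c_per_area * (area_m2 / M2_PER_HA)
            parts.append(c)
            contributions.setdefault((ft_abbr, cell.ecozone), []).append(c)
        cell_totals[cell.row, cell.col] = math.fsum(parts)

    areas = landscape.area_by_type_ecozone()
    rows = []
    for (ft_abbr, ecozone), parts in sorted(contributions.items()):
        d = density(ft_abbr, ecozone)
        area_ha = areas[(ft_abbr, ecozone)] / M2_PER_HA
        rows.append({
            "forest_type": ft_abbr,
            "ecozone": ecozone,
            "area_ha": area_ha,
            "v_stand": d.v_stand,
            "v_total": d.v_stand * area_ha,
            "c_a": d.c_per_area,
            "c_t": math.fsum(parts),
        })
    per_type = pd.DataFrame(
        rows, columns=["forest_type", "ecozone", "area_ha", "v_stand",
                       "v_total", "c_a", "c_t"])
    return LandscapeCarbon(per_type=per_type, cell_totals=cell_totals,
                           landscape=landscape)


def combine(results: LandscapeCarbon) -> tuple[pd.DataFrame, np.ndarray]:
    """Landscape marginals: per-type totals and the per-cell total map."""
    return results.per_type_totals(), results.cell_totals


# ---------------------------------------------------------------------------
# Class maps and ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def classify_map(values: np.ndarray, breaks: Sequence[float]) -> np.ndarray:
    """Bin a value raster into integer classes by strictly increasing breaks.

    Intervals are left-open/right-closed: class ``k`` (k >= 1) means
    ``breaks[k-1] < v <= breaks[k]``; class 0 is ``v <= breaks[0]`` and class
    ``len(breaks)`` is ``v > breaks[-1]``.  No-data (NaN) cells map to -1.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or len(breaks) < 2 or np.any(np.diff(breaks) <= 0):
        raise GridError("class breaks must be strictly increasing, length >= 2")
    values = np.asarray(values, dtype=float)
    classes = np.searchsorted(breaks, values, side="left").astype(int)
    classes[np.isnan(values)] = -1
    return classes


def write_ascii_grid(array: np.ndarray, path: str | Path, *,
                     x_origin: float = 0.0, y_origin: float = 0.0,
                     cellsize: float = 1000.0,
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (.asc).

    Values are serialized with ``repr`` so a read-back reproduces every float
    bit-exactly; NaN cells become the nodata value."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise GridError("raster must be 2-D")
    nrows, ncols = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x_origin!r}\n")
        fh.write(f"yllcorner {y_origin!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for r in range(nrows):
            fh.write(" ".join(
                repr(nodata) if np.isnan(v) else repr(float(v))
                for v in array[r]) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0]] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    array = np.array(rows, dtype=float)
    nodata = header.get("NODATA_value")
    if nodata is not None:
        array[array == nodata] = np.nan
    return array, header


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
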