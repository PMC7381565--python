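"""Post-glacial climate-change predictors from gridded climate fields.

Derives the four historical variables — temperature and precipitation
anomaly (present minus Last Glacial Maximum, ~21 kyr BP) and the velocity
of temperature/precipitation change — from co-registered current and LGM
rasters.  Velocity divides the temporal gradient (the anomaly) by the local
spatial gradient of the current field, giving the distance (km) over which
an organism must shift to keep its climate constant.

Rasters are plain-text ESRI ASCII grids.  A grid is "north-up": row 0 is
the northernmost row, and ``origin`` is the lower-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClimateGrid",
    "HistoricalVariables",
    "read_ascii_grid",
    "write_ascii_grid",
    "multi_model_mean",
    "anomaly",
    "spatial_gradient",
    "change_velocity",
    "derive_historical",
]

#: km per degree of latitude (spherical earth, mean radius)
KM_PER_DEGREE = 111.32

#: years since the Last Glacial Maximum, for optional per-year velocity scaling
YEARS_SINCE_LGM = 21_000.0


class RegistrationError(ValueError):
    """Grids disagree in shape, cell size or origin."""


@dataclass
class ClimateGrid:
    """One climate variable on a regular grid for one epoch.

    ``cell_units`` records whether ``cellsize``/``origin`` are kilometres
    (projected, x/y) or degrees (geographic, lon/lat).  Degree grids get a
    cos(latitude) correction on east-west spans when physical distance is
    needed.
    """

    values: np.ndarray  # (nrows, ncols), row 0 = north
    cellsize: float
    origin: tuple[float, float]  # lower-left corner (x, y)
    nodata: float = -9999.0
    epoch: str = "current"  # "current" | "lgm"
    variable: str = "MAT"  # "MAT" | "MAP"
    cell_units: str = "km"  # "km" | "deg"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise ValueError("grid must be 2-D with at least 3 rows and 3 columns")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("grid contains non-finite non-nodata values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata

    def row_center_y(self, row: int) -> float:
        """y (or latitude) of the centre of array row ``row`` (row 0 = north)."""
        nrows = self.values.shape[0]
        return self.origin[1] + (nrows - row - 0.5) * self.cellsize

    def cell_spans_km(self, row: int) -> tuple[float, float]:
        """Physical (east-west, north-south) span of one cell in km at ``row``."""
        if self.cell_units == "km":
            return self.cellsize, self.cellsize
        lat = self.row_center_y(row)
        return (
            self.cellsize * KM_PER_DEGREE * math.cos(math.radians(lat)),
            self.cellsize * KM_PER_DEGREE,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); raises if outside."""
        nrows, ncols = self.values.shape
        col = int(math.floor((x - self.origin[0]) / self.cellsize))
        row_from_s = int(math.floor((y - self.origin[1]) / self.cellsize))
        row = nrows - 1 - row_from_s
        if not (0 <= col < ncols and 0 <= row < nrows):
            raise LookupError(f"point ({x}, {y}) falls outside the grid extent")
        return row, col

    def like(self, values: np.ndarray, **overrides) -> "ClimateGrid":
        """New grid sharing this grid's georeference."""
        kw = dict(
            cellsize=self.cellsize,
            origin=self.origin,
            nodata=self.nodata,
            epoch=self.epoch,
            variable=self.variable,
            cell_units=self.cell_units,
        )
        kw.update(overrides)
        return ClimateGrid(values, **kw)


def _check_registered(grids) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise RegistrationError(f"grid shapes differ: {g.shape} vs {ref.shape}")
        if not math.isclose(g.cellsize, ref.cellsize, rel_tol=1e-12):
            raise RegistrationError("grid cell sizes differ")
        if not (
            math.isclose(g.origin[0], ref.origin[0], abs_tol=1e-9)
            and math.isclose(g.origin[1], ref.origin[1], abs_tol=1e-9)
        ):
            raise RegistrationError("grid origins differ")
        if g.cell_units != ref.cell_units:
            raise RegistrationError("grid cell units differ")


def read_ascii_grid(path, **meta) -> ClimateGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data block does not match declared nrows/ncols")
    return ClimateGrid(
        values,
        cellsize=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", -9999.0),
        **meta,
    )


def write_ascii_grid(grid: ClimateGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(grid.origin[0])!r}\n")
        fh.write(f"yllcorner {float(grid.origin[1])!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def multi_model_mean(grids: list[ClimateGrid]) -> ClimateGrid:
    """Cell-wise mean over paleoclimate model outputs (e.g. CCSM and MIROC).

    A cell is nodata in the output iff it is nodata in any input.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to average")
    _check_registered(grids)
    stack = np.stack([g.values for g in grids])
    valid = np.stack([g.mask() for g in grids]).all(axis=0)
    out = np.where(valid, stack.mean(axis=0), grids[0].nodata)
    return grids[0].like(out)


def anomaly(current: ClimateGrid, past: ClimateGrid) -> ClimateGrid:
    """Temporal climate anomaly: current minus past, cell-wise."""
    _check_registered([current, past])
    valid = current.mask() & past.mask()
    out = np.where(valid, current.values - past.values, current.nodata)
    return current.like(out, epoch="anomaly")


def spatial_gradient(grid: ClimateGrid) -> ClimateGrid:
    """Magnitude of the local spatial climate gradient, in variable units per km.

    Central differences over the four rook neighbours:
    ``sqrt(((E-W)/(2 dx))^2 + ((N-S)/(2 dy))^2)``.  Edge cells, and cells
    with any nodata neighbour, are nodata.
    """
    v = grid.values
    m = grid.mask()
    nrows, ncols = v.shape
    out = np.full_like(v, grid.nodata)
    # per-row dx handles the cos(latitude) correction on degree grids
    for r in range(1, nrows - 1):
        dx, dy = grid.cell_spans_km(r)
        ok = m[r, 1:-1] & m[r, :-2] & m[r, 2:] & m[r - 1, 1:-1] & m[r + 1, 1:-1]
        gx = (v[r, 2:] - v[r, :-2]) / (2.0 * dx)
        # row r-1 is north of row r
        gy = (v[r - 1, 1:-1] - v[r + 1, 1:-1]) / (2.0 * dy)
        out[r, 1:-1] = np.where(ok, np.hypot(gx, gy), grid.nodata)
    return grid.like(out, epoch="gradient")


def change_velocity(anom: ClimateGrid, grad: ClimateGrid, floor: float = 1e-6) -> ClimateGrid:
    """Climate-change velocity |anomaly| / max(gradient, floor), in km.

    The gradient floor keeps velocity finite on locally flat terrain, where
    the ratio is otherwise unbounded.
    """
    if floor <= 0:
        raise ValueError("gradient floor must be positive")
    _check_registered([anom, grad])
    valid = anom.mask() & grad.mask()
    denom = np.maximum(grad.values, floor)
    out = np.where(valid, np.abs(anom.values) / denom, anom.nodata)
    return anom.like(out, epoch="velocity")


@dataclass
class HistoricalVariables:
    """The four historical predictors at one site."""

    site: str
    TA: float  # temperature anomaly, degC (signed)
    PA: float  # precipitation anomaly, mm (signed)
    raw_TCV: float  # temperature change velocity, km
    raw_PCV: float  # precipitation change velocity, km
    TCV: float  # log10(raw_TCV + offset)
    PCV: float  # log10(raw_PCV + offset)
    meta: dict = field(default_factory=dict)


def derive_historical(
    current_T: ClimateGrid,
    lgm_T: ClimateGrid,
    current_P: ClimateGrid,
    lgm_P: ClimateGrid,
    sites,
    *,
    gradient_floor: float = 1e-6,
    log_offset: float = 0.0,
    per_year: bool = False,
    signed_anomaly: bool = True,
) -> list[HistoricalVariables]:
    """Full historical-variable chain: anomaly, gradient, velocity, extraction.

    Parameters
    ----------
    sites
        Iterable of ``(site_id, x, y)`` with coordinates in the grids' units.
    gradient_floor
        Minimum spatial gradient (variable units / km) used in the velocity
        denominator.
    log_offset
        Pseudo-offset added before the base-10 log transform of velocities;
        with the default 0, a non-positive raw velocity raises.
    per_year
        If True, divide the temporal gradient by the years elapsed since the
        LGM, yielding velocity in km/yr instead of total km displacement.
    signed_anomaly
        Report TA/PA signed (default) or as magnitudes; the velocity always
        uses the magnitude.
    """
    _check_registered([current_T, lgm_T, current_P, lgm_P])
    anom_T = anomaly(current_T, lgm_T)
    anom_P = anomaly(current_P, lgm_P)
    scale = 1.0 / YEARS_SINCE_LGM if per_year else 1.0
    vel_T = change_velocity(anom_T, spatial_gradient(current_T), gradient_floor)
    vel_P = change_velocity(anom_P, spatial_gradient(current_P), gradient_floor)

    meta = {
        "log_base": 10,
        "log_offset": log_offset,
        "gradient_floor": gradient_floor,
        "per_year": per_year,
        "signed_anomaly": signed_anomaly,
    }
    out = []
    for site_id, x, y in sites:
        try:
            r, c = current_T.cell_index(x, y)
        except LookupError as err:
            raise LookupError(f"site {site_id!r}: {err}") from None
        vals = {}
        for name, g in (("TA", anom_T), ("PA", anom_P), ("TCV", vel_T), ("PCV", vel_P)):
            v = g.values[r, c]
            if v == g.nodata:
                raise ValueError(f"site {site_id!r} falls on a nodata cell for {name}")
            vals[name] = float(v)
        ta, pa = vals["TA"], vals["PA"]
        if not signed_anomaly:
            ta, pa = abs(ta), abs(pa)
        raw_tcv = vals["TCV"] * scale
        raw_pcv = vals["PCV"] * scale
        logged = []
        for raw in (raw_tcv, raw_pcv):
            if raw + log_offset <= 0:
                raise ValueError(
                    f"site {site_id!r}: raw velocity {raw} with offset {log_offset} "
                    "is not positive; set a positive log_offset"
                )
            logged.append(math.log10(raw + log_offset))
        out.append(
            HistoricalVariables(str(site_id), ta, pa, raw_tcv, raw_pcv, *logged, meta=dict(meta))
        )
    return out
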