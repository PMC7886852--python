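"""Construction-land suitability: multi-factor weighted raster overlay.

The support end of the land-resource indicator is the area suitable for
construction, obtained by weighted scoring of graded factor layers (land
cover, fracture zone, mean gradient, soil property, ...) on a common grid:

    C_i = 0                    if any factor grades cell i as 0 (forbidden)
    C_i = sum_j W_j * C_ij     otherwise

with weights summing to one.  Scores are cut into four classes (forbidden /
limited / less-suitable / suitable) by two ascending thresholds; the
less-suitable and suitable area together count as suitable construction
land.  Grades conventionally lie on {0, 1, 3, 5}; both the grade scale and
the thresholds are configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

NODATA_DEFAULT = -9999.0
WEIGHT_SUM_TOL = 1e-9
DEFAULT_THRESHOLDS = (2.0, 4.0)


class SuitabilityClass(enum.IntEnum):
    FORBIDDEN = 0
    LIMITED = 1
    LESS_SUITABLE = 2
    SUITABLE = 3

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", "-")


@dataclass
class FactorLayer:
    """One graded factor raster with its overlay weight.

    Grid values are grade scores >= 0 (0 = forbidden veto); cells equal to
    ``nodata`` are outside the analysis mask.  All layers of one analysis
    must share shape, cell size and no-data mask.
    """

    name: str
    weight: float
    grid: np.ndarray
    cellsize: float = 1.0
    nodata: float = NODATA_DEFAULT
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValidationError(f"layer {self.name!r}: grid must be 2-D")
        if not (0 < self.weight <= 1):
            raise ValidationError(
                f"layer {self.name!r}: weight must lie in (0, 1], got {self.weight}"
            )
        valid = self.grid != self.nodata
        vals = self.grid[valid]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValidationError(
                f"layer {self.name!r}: grades must be finite and >= 0"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.grid != self.nodata


@dataclass
class SuitabilityGrid:
    """Comprehensive suitability scores, optional classes and cell area."""

    scores: np.ndarray
    cell_area: float
    nodata: float = NODATA_DEFAULT
    classes: np.ndarray | None = field(default=None)

    @property
    def mask(self) -> np.ndarray:
        return self.scores != self.nodata


def score_cells(layers: list[FactorLayer]) -> SuitabilityGrid:
    """Weighted overlay of factor layers into a comprehensive score grid.

    A zero grade in any layer vetoes the cell (score 0, forbidden);
    otherwise the score is the weighted sum of grades.  No-data cells stay
    no-data.  Weights must sum to 1 within 1e-9.
    """
    if not layers:
        raise ValidationError("at least one factor layer is required")
    wsum = sum(l.weight for l in layers)
    if abs(wsum - 1.0) > WEIGHT_SUM_TOL:
        raise ValidationError(
            f"layer weights must sum to 1 (got {wsum!r}); check land_suitability.weights"
        )
    shape = layers[0].grid.shape
    nodata = layers[0].nodata
    mask = layers[0].mask
    for l in layers[1:]:
        if l.grid.shape != shape:
            raise ValidationError(
                f"layer {l.name!r} shape {l.grid.shape} does not match {shape}"
            )
        if not np.array_equal(l.mask, mask):
            raise ValidationError(f"layer {l.name!r} no-data mask differs")

    scores = np.zeros(shape, dtype=float)
    for l in layers:
        scores += l.weight * np.where(mask, l.grid, 0.0)
    veto = np.zeros(shape, dtype=bool)
    for l in layers:
        veto |= mask & (l.grid == 0)
    scores[veto] = 0.0
    scores[~mask] = nodata
    cell_area = layers[0].cellsize ** 2
    return SuitabilityGrid(scores=scores, cell_area=cell_area, nodata=nodata)


def classify_suitability(
    grid: SuitabilityGrid, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> SuitabilityGrid:
    """Cut scores into the four suitability classes.

    score = 0 -> forbidden; (0, t1) -> limited; [t1, t2) -> less-suitable;
    >= t2 -> suitable.  Returns the grid with ``classes`` filled in
    (no-data cells carry -1).
    """
    t1, t2 = thresholds
    if not (0 < t1 < t2):
        raise ValidationError(
            f"thresholds must be ascending positive reals, got ({t1}, {t2})"
        )
    mask = grid.mask
    s = grid.scores
    classes = np.full(s.shape, -1, dtype=int)
    classes[mask & (s == 0)] = SuitabilityClass.FORBIDDEN
    classes[mask & (s > 0) & (s < t1)] = SuitabilityClass.LIMITED
    classes[mask & (s >= t1) & (s < t2)] = SuitabilityClass.LESS_SUITABLE
    classes[mask & (s >= t2)] = SuitabilityClass.SUITABLE
    grid.classes = classes
    return grid


def suitable_area(grid: SuitabilityGrid) -> float:
    """Area (m^2) of less-suitable plus suitable cells.

    This is the support value for the land-resource indicator (the pressure
    end being the developed land area).
    """
    if grid.classes is None:
        raise ValidationError("grid must be classified before area accounting")
    n = int(
        np.count_nonzero(
            (grid.classes == SuitabilityClass.LESS_SUITABLE)
            | (grid.classes == SuitabilityClass.SUITABLE)
        )
    )
    return n * grid.cell_area


def class_areas(grid: SuitabilityGrid) -> dict[str, float]:
    """Area (m^2) per suitability class."""
    if grid.classes is None:
        raise ValidationError("grid must be classified before area accounting")
    return {
        c.label: int(np.count_nonzero(grid.classes == c)) * grid.cell_area
        for c in SuitabilityClass
    }


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid (.asc); returns (array, header dict).

    Header keys: ncols, nrows, xllcorner, yllcorner, cellsize,
    nodata_value.  Row-major, origin upper-left.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    header.setdefault("nodata_value", NODATA_DEFAULT)
    for missing in ("ncols", "nrows", "cellsize"):
        if missing not in header:
            raise ValidationError(f"{path}: ASCII grid header missing {missing!r}")
    for line in lines[i:]:
        if line.strip():
            rows.append([float(x) for x in line.split()])
    arr = np.array(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"{path}: grid body shape {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return arr, header


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = NODATA_DEFAULT,
) -> None:
    """Write an ESRI ASCII grid; values are written with shortest
    round-tripping float representation, so read-back is bit-exact."""
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    with Path(path).open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_factor_layer(path: str | Path, name: str, weight: float) -> FactorLayer:
    """Read a factor layer from an .asc file."""
    grid, header = read_ascii_grid(path)
    return FactorLayer(
        name=name,
        weight=weight,
        grid=grid,
        cellsize=header["cellsize"],
        nodata=header["nodata_value"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )
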