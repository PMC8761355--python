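"""Categorical landscape rasters and covariate extraction.

The movement probability of the model is driven by the landscape category
(tree, pavement, grass, building) at the starting position of each step.
This module provides a synthetic patchy-raster generator (standing in for
classified satellite imagery), point-in-cell category lookup, and the
one-hot design rows fed to the probit link.

Cells are indexed row-major from the lower-left corner; y increases
northward. Cell membership uses the half-open convention
``[x0, x0 + cell_size) x [y0, y0 + cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CATEGORIES",
    "CategoricalRaster",
    "generate_synthetic_raster",
    "feature_at",
    "design_row",
    "design_matrix",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Fixed category ordering used everywhere (design rows, raster codes 1-4).
CATEGORIES = ("tree", "pavement", "grass", "building")
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class CategoricalRaster:
    """Gridded landscape of the four feature categories.

    ``codes`` holds integer codes 1..4 (order of :data:`CATEGORIES`) with
    row 0 the southernmost row. ``origin`` is the (x, y) of the lower-left
    corner in metres; ``cell_size`` the square cell edge in metres (the
    source imagery analog is 0.7 m).
    """

    origin: tuple[float, float]
    cell_size: float
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")
        if codes.ndim != 2 or codes.size == 0:
            raise ValueError("codes must be a nonempty 2-D grid")
        if codes.min() < 1 or codes.max() > len(CATEGORIES):
            raise ValueError("category codes must lie in 1..4 (no NoData)")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def category_fractions(self) -> dict[str, float]:
        counts = np.bincount(self.codes.ravel(), minlength=len(CATEGORIES) + 1)
        return {c: counts[i + 1] / self.codes.size for i, c in enumerate(CATEGORIES)}


def generate_synthetic_raster(
    n_cols: int,
    n_rows: int,
    cell_size: float = 0.7,
    proportions: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    n_patches: int | None = None,
) -> CategoricalRaster:
    """Generate a patchy categorical raster with target category fractions.

    The grid is partitioned into nearest-seed (Voronoi) patches; seed points
    receive categories by largest-remainder quota on ``proportions``, so
    realized fractions concentrate tightly around the request (within a few
    percentage points for grids of 100x100 and up). Landscape features come
    out as contiguous patches of roughly equal expected size, mimicking the
    blocky urban mosaics of classified imagery rather than salt-and-pepper
    noise.

    Deterministic given ``seed``.
    """
    if n_cols <= 0 or n_rows <= 0:
        raise ValueError("raster must have positive dimensions")
    if proportions is None:
        proportions = {c: 0.25 for c in CATEGORIES}
    props = np.array([float(proportions.get(c, 0.0)) for c in CATEGORIES])
    if np.any(props < 0) or not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must be nonnegative and sum to 1")
    props = props / props.sum()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if n_patches is None:
        n_patches = int(np.clip((n_cols * n_rows) // 100, 16, 512))
    # Largest-remainder quota: patch counts proportional to the request.
    quota = props * n_patches
    counts = np.floor(quota).astype(int)
    rem = n_patches - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1

    seed_codes = np.repeat(np.arange(1, len(CATEGORIES) + 1), counts)
    rng.shuffle(seed_codes)
    seed_xy = rng.uniform(0.0, 1.0, size=(n_patches, 2)) * [n_cols, n_rows]

    jj, ii = np.meshgrid(np.arange(n_cols) + 0.5, np.arange(n_rows) + 0.5)
    cells = np.column_stack([jj.ravel(), ii.ravel()])
    # Nearest-seed assignment, chunked to bound memory on big grids.
    codes = np.empty(cells.shape[0], dtype=int)
    chunk = 65536
    for s in range(0, cells.shape[0], chunk):
        d2 = (
            (cells[s : s + chunk, None, 0] - seed_xy[None, :, 0]) ** 2
            + (cells[s : s + chunk, None, 1] - seed_xy[None, :, 1]) ** 2
        )
        codes[s : s + chunk] = seed_codes[np.argmin(d2, axis=1)]
    grid = codes.reshape(n_rows, n_cols)

    # Degenerate proportions (e.g. a single category) must be honored even
    # when quota rounding assigned zero seeds to a requested category.
    present = np.unique(grid)
    for ci, p in enumerate(props):
        if p > 0.999999 and not np.array_equal(present, [ci + 1]):
            grid = np.full((n_rows, n_cols), ci + 1)
    return CategoricalRaster(origin=origin, cell_size=cell_size, codes=grid)


def _cell_indices(raster: CategoricalRaster, position: np.ndarray) -> tuple[int, int]:
    x, y = float(position[0]), float(position[1])
    x0, y0, x1, y1 = raster.extent
    if not (x0 <= x < x1) or not (y0 <= y < y1):
        raise ValueError(
            f"position ({x}, {y}) outside raster extent "
            f"[{x0}, {x1}) x [{y0}, {y1})"
        )
    col = int(np.floor((x - x0) / raster.cell_size))
    row = int(np.floor((y - y0) / raster.cell_size))
    return row, col


def feature_at(raster: CategoricalRaster, position) -> str:
    """Landscape category of the cell containing ``position``.

    Uses the half-open cell convention, so a point on a shared edge belongs
    to the higher-index (north/east) cell.
    """
    row, col = _cell_indices(raster, np.asarray(position, dtype=float))
    return CATEGORIES[raster.codes[row, col] - 1]


def design_row(category: str) -> np.ndarray:
    """One-hot (cell-means) indicator row for a category, fixed order
    (tree, pavement, grass, building)."""
    try:
        idx = _CAT_INDEX[category]
    except KeyError:
        raise ValueError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        ) from None
    row = np.zeros(len(CATEGORIES))
    row[idx] = 1.0
    return row


def design_matrix(raster: CategoricalRaster, traj) -> np.ndarray:
    """Design rows for a trajectory's likelihood-eligible steps.

    The step from ``s_{t-1}`` to ``s_t`` uses the category at the starting
    position ``s_{t-1}``; with the eligible displacement at array index k,
    that starting position is ``positions[k]``.
    """
    disp = traj.displacements()
    rows = [design_row(feature_at(raster, traj.positions[k])) for k in disp.eligible]
    if not rows:
        return np.zeros((0, len(CATEGORIES)))
    return np.asarray(rows)


def write_ascii_grid(raster: CategoricalRaster, path) -> None:
    """Write the raster as an ESRI ASCII grid (codes 1-4; see
    :data:`CATEGORIES` for the legend)."""
    x0, y0 = raster.origin
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value -9999\n"
    )
    # ESRI grids store the top (northernmost) row first.
    body = "\n".join(
        " ".join(str(v) for v in row) for row in raster.codes[::-1]
    )
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def read_ascii_grid(path) -> CategoricalRaster:
    """Read an ESRI ASCII grid of category codes 1-4. NoData cells are
    rejected: the model needs a category under every position."""
    with open(path) as fh:
        header: dict[str, float] = {}
        rows: list[list[int]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(v) for v in parts])
    codes = np.asarray(rows[::-1], dtype=int)
    nodata = int(header.get("nodata_value", -9999))
    if np.any(codes == nodata):
        raise ValueError("raster contains NoData cells; a full categorical cover is required")
    return CategoricalRaster(
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        cell_size=header["cellsize"],
        codes=codes,
    )
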