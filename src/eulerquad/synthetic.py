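"""Synthetic binary-image generators with known Euler numbers.

Three families cover the experimental designs the algorithms are validated
on:

* :func:`noise_image` — i.i.d. Bernoulli pixels at a given foreground
  density, emulating uniform-random-noise images thresholded at densities
  spanning 0..1.  Noise images have complicated component geometry and
  connectivity and are the stress test for cross-algorithm agreement.
* :func:`pattern_image` — deterministic tilings of the four named
  specialized families (checkerboard-, sawtooth-, stair- and
  honeycomb-like connected components), each returned together with its
  Euler number in closed form from the tile counts.
* :func:`shape_image` — blob/ring fixtures whose Euler number is known by
  construction (components minus holes by design).

All generators are deterministic given their parameters (and seed).
"""

from __future__ import annotations

import numpy as np

from .image import BinaryImage

__all__ = [
    "noise_image",
    "pattern_image",
    "shape_image",
    "beside",
    "PATTERN_KINDS",
    "SHAPE_KINDS",
]

PATTERN_KINDS = ("checkerboard", "sawtooth", "stair", "honeycomb")
SHAPE_KINDS = ("blob", "ring", "nested_rings", "disjoint_rings")


def noise_image(height: int, width: int, density: float, seed: int) -> BinaryImage:
    """Bernoulli noise: each pixel independently foreground with
    probability ``density``.

    Density 0 yields all-background and density 1 all-foreground exactly.
    Reproducible given ``(seed, shape, density)``.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    if height < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    rng = np.random.default_rng(seed)
    grid = rng.random((height, width)) < density
    return BinaryImage(grid.astype(np.uint8))


# ---------------------------------------------------------------------------
# Specialized tilings
# ---------------------------------------------------------------------------


def _parity_counts(n: int) -> tuple[int, int]:
    """(odd, even) counts among the integers 1..n."""
    return (n + 1) // 2, n // 2


def _checkerboard(height: int, width: int) -> tuple[np.ndarray, int]:
    rr, cc = np.indices((height, width))
    grid = ((rr + cc) % 2 == 0).astype(np.uint8)
    if height == 0 or width == 0:
        return grid, 0
    if height == 1 or width == 1:
        # a line of isolated foreground cells; no enclosed background
        return grid, (max(height, width) + 1) // 2
    # all foreground cells are diagonally 8-connected: one component.
    # Every interior odd-parity cell is a 4-isolated background pixel
    # surrounded by foreground, i.e. one hole.
    odd_r, even_r = _parity_counts(height - 2)
    odd_c, even_c = _parity_counts(width - 2)
    holes = odd_r * even_c + even_r * odd_c
    return grid, 1 - holes


def _sawtooth(height: int, width: int, period: int = 4) -> tuple[np.ndarray, int]:
    if height < 1 or width < 1:
        raise ValueError("sawtooth needs positive dimensions")
    cols = np.arange(width)
    tooth = np.minimum(1 + cols % period, height)  # ramp profile, >= 1
    rr = np.arange(height)[:, None]
    grid = (rr >= height - tooth[None, :]).astype(np.uint8)
    # every column is a contiguous bottom-anchored run sharing the base
    # row: one simply connected component
    return grid, 1


def _stair(height: int, width: int, step: int = 2) -> tuple[np.ndarray, int]:
    if height < 1 or width < 1:
        raise ValueError("stair needs positive dimensions")
    cols = np.arange(width)
    rise = np.minimum(1 + cols // step, height)
    rr = np.arange(height)[:, None]
    grid = (rr >= height - rise[None, :]).astype(np.uint8)
    return grid, 1


def _honeycomb(height: int, width: int, cell: int = 4) -> tuple[np.ndarray, int]:
    """Offset-cell lattice: full-width horizontal walls every ``cell`` rows,
    vertical walls shifted by half a cell on alternate rows (brick/comb
    offset).  Each fully walled cell encloses one hole; edge half-cells of
    shifted rows open to the border and do not."""
    if cell < 2:
        raise ValueError("cell size must be at least 2")
    n_rows = (height - 1) // cell
    n_cols = (width - 1) // cell
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"canvas {height}x{width} too small for any {cell}x{cell} cell"
        )
    lat = np.zeros((n_rows * cell + 1, n_cols * cell + 1), dtype=np.uint8)
    lat[::cell, :] = 1
    for i in range(n_rows):
        offset = cell // 2 if i % 2 else 0
        cols = np.arange(offset, lat.shape[1], cell)
        lat[i * cell : (i + 1) * cell + 1, cols] = 1
    grid = np.zeros((height, width), dtype=np.uint8)
    grid[: lat.shape[0], : lat.shape[1]] = lat
    # one connected lattice; complete cells per row: n_cols on aligned
    # rows, n_cols - 1 on shifted rows
    k = sum(n_cols if i % 2 == 0 else n_cols - 1 for i in range(n_rows))
    return grid, 1 - k


def pattern_image(kind: str, height: int, width: int, **kwargs) -> tuple[BinaryImage, int]:
    """Deterministic tiling of one of the four specialized families.

    Returns ``(image, E)`` with the Euler number computed in closed form
    from the tile counts.  ``kwargs`` forward kind-specific geometry
    (``period`` for sawtooth, ``step`` for stair, ``cell`` for honeycomb).
    """
    builders = {
        "checkerboard": _checkerboard,
        "sawtooth": _sawtooth,
        "stair": _stair,
        "honeycomb": _honeycomb,
    }
    if kind not in builders:
        raise ValueError(f"unknown pattern kind {kind!r}; expected one of {PATTERN_KINDS}")
    if height < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    grid, euler = builders[kind](height, width, **kwargs)
    return BinaryImage(grid), euler


# ---------------------------------------------------------------------------
# Shape fixtures with Euler number known by construction
# ---------------------------------------------------------------------------


def _draw_ring(grid: np.ndarray, top: int, left: int, size: int) -> None:
    """Square annulus of thickness 1 with outer side ``size`` (>= 3)."""
    grid[top : top + size, left : left + size] = 1
    grid[top + 1 : top + size - 1, left + 1 : left + size - 1] = 0


def shape_image(kind: str, **params) -> tuple[BinaryImage, int]:
    """Fixture shapes with ground-truth Euler number by construction.

    Kinds
    -----
    blob : filled rectangle; ``height``/``width`` canvas (default 9);
        one simply connected component, E = 1.
    ring : one square annulus; canvas >= 5 in each dimension, E = 0.
    nested_rings : ``depth`` concentric annuli separated by one
        background pixel; each contributes a component and a hole, E = 0.
    disjoint_rings : ``count`` annuli side by side, E = 0.

    Every shape keeps at least one background pixel of margin to the
    canvas edge and to other shapes; a canvas too small to honor that is
    a parameter error.
    """
    if kind == "blob":
        h = params.get("height", 9)
        w = params.get("width", 9)
        if h < 3 or w < 3:
            raise ValueError("blob canvas must be at least 3x3")
        grid = np.zeros((h, w), dtype=np.uint8)
        grid[1 : h - 1, 1 : w - 1] = 1
        return BinaryImage(grid), 1
    if kind == "ring":
        h = params.get("height", 9)
        w = params.get("width", 9)
        if h < 5 or w < 5:
            raise ValueError("ring canvas must be at least 5x5")
        grid = np.zeros((h, w), dtype=np.uint8)
        grid[1 : h - 1, 1 : w - 1] = 1
        grid[2 : h - 2, 2 : w - 2] = 0
        return BinaryImage(grid), 0
    if kind == "nested_rings":
        depth = params.get("depth", 2)
        if depth < 1:
            raise ValueError("depth must be at least 1")
        side = 4 * depth + 1
        grid = np.zeros((side, side), dtype=np.uint8)
        for i in range(depth):
            offset = 1 + 2 * i
            _draw_ring(grid, offset, offset, side - 2 * offset)
        # depth components, depth enclosed background regions
        return BinaryImage(grid), 0
    if kind == "disjoint_rings":
        count = params.get("count", 2)
        if count < 1:
            raise ValueError("count must be at least 1")
        grid = np.zeros((5, 4 * count + 1), dtype=np.uint8)
        for i in range(count):
            _draw_ring(grid, 1, 1 + 4 * i, 3)
        return BinaryImage(grid), 0
    raise ValueError(f"unknown shape kind {kind!r}; expected one of {SHAPE_KINDS}")


def beside(left: BinaryImage, right: BinaryImage, gap: int = 1) -> BinaryImage:
    """Place two images side by side separated by ``gap`` all-background
    columns (top-aligned).  With ``gap >= 1`` the Euler number of the
    composite is the sum of the parts'."""
    if gap < 1:
        raise ValueError("gap must be at least 1")
    h = max(left.height, right.height)
    grid = np.zeros((h, left.width + gap + right.width), dtype=np.uint8)
    grid[: left.height, : left.width] = left.pixels
    grid[: right.height, left.width + gap :] = right.pixels
    return BinaryImage(grid)
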