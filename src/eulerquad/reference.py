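"""Conventional Euler number algorithms: GRAY, I-GRAY, RUN, HCS-style labeling.

These serve as cross-validation references and as instrumented baselines for
pixel-access accounting:

* GRAY counts three bit-quad pattern families over every 2x2 window,
  reading all four cells each time (4 reads per window);
  ``E = (N1 - N2 - 2*N3) / 4``.
* I-GRAY computes the identical census but carries the previous window's
  right column as the current left column, reading exactly 2 new cells per
  window.
* RUN counts maximal horizontal foreground runs R and 8-adjacent
  neighboring-run pairs O between consecutive rows; ``E = R - O``.
* HCS computes the definition directly, ``E = C - H``, by labeling
  8-connected foreground components and 4-connected background holes with
  a two-pass raster union-find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import BinaryImage

__all__ = [
    "GrayCounts",
    "Run",
    "RunSummary",
    "TopoSummary",
    "euler_gray",
    "euler_igray",
    "extract_runs",
    "count_neighboring_runs",
    "run_summary",
    "euler_run",
    "euler_hcs",
]


# ---------------------------------------------------------------------------
# GRAY and I-GRAY
# ---------------------------------------------------------------------------


@dataclass
class GrayCounts:
    """Bit-quad census of the GRAY family.

    ``n1``: windows with exactly one foreground cell (P1);
    ``n2``: exactly three (P2);
    ``n3``: the two diagonal two-foreground configurations (P3).
    """

    n1: int = 0
    n2: int = 0
    n3: int = 0
    reads: int = 0
    windows: int = 0

    @property
    def euler(self) -> int:
        num = self.n1 - self.n2 - 2 * self.n3
        assert num % 4 == 0, "GRAY census invariant violated"
        return num // 4


def _classify_gray(counts: GrayCounts, u: int, x: int, v: int, y: int) -> None:
    total = u + x + v + y
    if total == 1:
        counts.n1 += 1
    elif total == 3:
        counts.n2 += 1
    elif total == 2 and ((u and y) or (x and v)):
        counts.n3 += 1


def euler_gray(img: BinaryImage) -> tuple[GrayCounts, int]:
    """GRAY census reading all four cells of every padded window."""
    counts = GrayCounts()
    get = img.get
    for r in range(img.height + 1):
        for c in range(img.width + 1):
            u = get(r - 1, c - 1)
            x = get(r - 1, c)
            v = get(r, c - 1)
            y = get(r, c)
            counts.reads += 4
            counts.windows += 1
            _classify_gray(counts, u, x, v, y)
    return counts, counts.euler


def euler_igray(img: BinaryImage) -> tuple[GrayCounts, int]:
    """Same census as GRAY with exactly 2 reads per window.

    The left column (U, V) of each window is the right column (X, Y) of
    its predecessor; the first window of a row starts from the virtual
    left-border column, a known constant needing no read.
    """
    counts = GrayCounts()
    get = img.get
    for r in range(img.height + 1):
        left_u, left_v = 0, 0  # virtual border column
        for c in range(img.width + 1):
            x = get(r - 1, c)
            y = get(r, c)
            counts.reads += 2
            counts.windows += 1
            _classify_gray(counts, left_u, x, left_v, y)
            left_u, left_v = x, y
    return counts, counts.euler


# ---------------------------------------------------------------------------
# RUN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Run:
    """A maximal horizontal sequence of foreground pixels in one row;
    ``end`` is inclusive."""

    row: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("run start must not exceed end")


@dataclass(frozen=True)
class RunSummary:
    r: int  # total runs
    o: int  # neighboring-run pairs

    @property
    def euler(self) -> int:
        return self.r - self.o


def extract_runs(img: BinaryImage) -> list[Run]:
    """All maximal foreground runs in row-major order."""
    runs: list[Run] = []
    for r in range(img.height):
        row = img.pixels[r]
        # transitions of the 0-padded row mark run boundaries
        boundary = np.flatnonzero(np.diff(np.pad(row, 1).astype(np.int8)))
        for start, stop in zip(boundary[::2], boundary[1::2]):
            runs.append(Run(r, int(start), int(stop) - 1))
    return runs


def count_neighboring_runs(runs: list[Run]) -> int:
    """Neighboring-run pairs: runs in vertically adjacent rows with at
    least one 8-adjacent pixel pair, i.e. column intervals
    ``[start-1, end+1]`` and ``[start, end]`` overlapping.  Each pair is
    counted once regardless of how many pixels touch."""
    by_row: dict[int, list[Run]] = {}
    for run in runs:
        by_row.setdefault(run.row, []).append(run)
    pairs = 0
    for row, upper in by_row.items():
        lower = by_row.get(row + 1)
        if not lower:
            continue
        for r1 in upper:
            for r2 in lower:
                if max(r1.start - 1, r2.start) <= min(r1.end + 1, r2.end):
                    pairs += 1
    return pairs


def run_summary(img: BinaryImage) -> RunSummary:
    runs = extract_runs(img)
    return RunSummary(len(runs), count_neighboring_runs(runs))


def euler_run(img: BinaryImage) -> int:
    """Euler number from runs: ``E = R - O``."""
    return run_summary(img).euler


# ---------------------------------------------------------------------------
# HCS-style labeling (E = C - H by direct component/hole counting)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopoSummary:
    """Component count C (8-connected foreground), hole count H
    (4-connected background not reaching the border), and E = C - H."""

    c: int
    h: int

    @property
    def euler(self) -> int:
        return self.c - self.h


_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1))
_OFFSETS_4 = ((-1, 0), (0, -1))


def _count_components(mask: np.ndarray, connectivity: int) -> int:
    """Two-pass raster-scan union-find component count over a boolean mask."""
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int64)
    parent = [0]  # parent[i] for provisional label i; label 0 unused

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neighbor_labels = [
                labels[r + dr, c + dc]
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w and labels[r + dr, c + dc]
            ]
            if not neighbor_labels:
                parent.append(len(parent))
                labels[r, c] = len(parent) - 1
            else:
                roots = {find(l) for l in neighbor_labels}
                keep = min(roots)
                labels[r, c] = keep
                for root in roots:
                    parent[root] = keep
    return len({find(l) for l in range(1, len(parent))})


def euler_hcs(img: BinaryImage) -> TopoSummary:
    """Label components and holes; ``E = C - H``.

    Holes are 4-connected background regions not 4-connected to the
    virtual border; labeling the background of the one-pixel-padded grid
    makes the outside exactly one component, so ``H = components - 1``.
    """
    fg = img.pixels.astype(bool)
    c = _count_components(fg, 8)
    bg = ~np.pad(img.pixels, 1).astype(bool)
    h = _count_components(bg, 4) - 1
    return TopoSummary(c, h)
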