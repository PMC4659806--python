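"""Square-graph formulation of the Euler number: ``E = v - e + s``.

The square graph of a binary image takes every foreground pixel as a
vertex and joins two vertices by an edge iff the pixels are 8-neighbors,
except that when both diagonals of a 2x2 all-foreground block would cross,
only one (the main diagonal, representative to up-left) is kept.  By
Euler's planar formula ``v - e + r = C + 1`` where r counts bounded and
unbounded faces; splitting ``r = H + s + 1`` into holes, basic
right-angled-triangle faces and the outer face gives

    E = C - H = v - e + s.

All three counts are accumulated incrementally per bit-quad (2x2 window of
the virtually padded grid), so no explicit graph is ever built: each window
adds the vertex for its representative pixel, the edges from the
representative to its left/up/up-left neighbors (plus the anti-diagonal
edge of the window where the rules call for it), and the triangle faces
completed inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import BinaryImage
from .two_pattern import BitQuad

__all__ = [
    "GraphSummary",
    "bitquad_increments",
    "count_vertices",
    "count_edges",
    "count_faces",
    "square_graph_summary",
    "euler_graph",
]


@dataclass(frozen=True)
class GraphSummary:
    """Vertex, edge and basic-triangle-face counts of the square graph."""

    v: int
    e: int
    s: int

    @property
    def euler(self) -> int:
        return self.v - self.e + self.s

    def square_count(self, holes: int) -> int:
        """Total face count ``r = H + s + 1`` given the hole count H
        (the +1 is the unbounded outer face)."""
        return holes + self.s + 1


def bitquad_increments(q: BitQuad) -> tuple[int, int, int]:
    """Per-window increments ``(dv, de, ds)`` of vertices, edges, faces.

    Edge rules for the window ``[U X; V Y]`` (Y the representative):

    * Y = 0: only the anti-diagonal V—X edge can be new; count it iff
      V = X = 1.
    * Y = 1 with V = X = 1, U = 0: three new edges (Y—V, Y—X and the
      anti-diagonal V—X).
    * Y = 1 otherwise: one edge from Y to each foreground pixel among
      V, X, U.  In the all-foreground window this counts the main
      diagonal Y—U and drops the crossing anti-diagonal.

    Faces: +2 if all four cells are foreground, +1 if exactly three.
    """
    dv = q.y
    if q.y == 0:
        de = 1 if (q.v == 1 and q.x == 1) else 0
    elif q.v == 1 and q.x == 1 and q.u == 0:
        de = 3
    else:
        de = q.u + q.v + q.x
    total = q.u + q.v + q.x + q.y
    ds = 2 if total == 4 else (1 if total == 3 else 0)
    return dv, de, ds


def _window_cells(img: BinaryImage):
    """(U, X, V, Y) cell arrays for all (N+1) x (M+1) padded windows."""
    p = np.pad(img.pixels, 1).astype(np.int64)
    return p[:-1, :-1], p[:-1, 1:], p[1:, :-1], p[1:, 1:]


def count_vertices(img: BinaryImage) -> int:
    """Vertices of the square graph = foreground pixel count."""
    return img.count_foreground()


def count_edges(img: BinaryImage) -> int:
    """Edges of the square graph, accumulated per bit-quad."""
    u, x, v, y = _window_cells(img)
    three_way = (y == 1) & (v == 1) & (x == 1) & (u == 0)
    e = np.where(
        y == 0,
        (v == 1) & (x == 1),
        np.where(three_way, 3, u + v + x),
    )
    return int(e.sum())


def count_faces(img: BinaryImage) -> int:
    """Basic right-angled-triangle faces: 2 per all-foreground window,
    1 per three-foreground window."""
    u, x, v, y = _window_cells(img)
    total = u + x + v + y
    return int(2 * (total == 4).sum() + (total == 3).sum())


def square_graph_summary(img: BinaryImage) -> GraphSummary:
    return GraphSummary(count_vertices(img), count_edges(img), count_faces(img))


def euler_graph(img: BinaryImage) -> int:
    """Euler number via the square graph: ``v - e + s``."""
    return square_graph_summary(img).euler
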