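# Methods

## Model and conventions

A binary image is an N-row × M-column grid of {0,1} values; 1 is
foreground (object), 0 background. Foreground connectivity is 8,
background/hole connectivity is 4 — the only pairing under which a thin
diagonal foreground line both connects its own pixels and separates the
background consistently. The Euler number is `E = C − H`: 8-connected
foreground components minus 4-connected background regions not reaching
the image exterior.

**Virtual border.** Every scanner operates on the virtually padded grid:
the accessor returns 0 outside the stored extent, and bit-quad scans
visit all (N+1) × (M+1) windows whose representative pixel ranges over
rows 0..N and columns 0..M. This generalizes the common assumption that
the border of an image is background — real segmentation masks touch the
edge, and padding virtually (not in storage) keeps them correct without
changing results on images that already satisfy the assumption.
Coordinates are 0-based `(row, col)`, row 0 at top; the raster scan runs
left-to-right then top-to-bottom.

## The two-pattern scan

Each window `[U X; V Y]` (Y the representative pixel at `(row, col)`, U,
X, V its up-left, up and left neighbors) is classified against two
patterns:

* Q2: `U=V=X=0, Y=1` → `W2 += 1`
* Qc: `U=0, V=X=1`, Y irrelevant → `Wc += 1`

and `E = W2 − Wc`. The correctness of that identity is established by
the square-graph module (below): per-window increments of vertices,
edges and faces give `ΔE = Δv − Δe + Δs`, which is +1 exactly on Q2, −1
exactly on Qc and 0 on the other fourteen patterns — the test suite
checks this exhaustively.

The scan checks cells in the order U → V → X → Y and keeps two pieces of
state along a row:

* **Carried values.** Moving one column right, the new (U, V) is the old
  (X, Y). Whenever the previous window read its X and Y (i.e. it had
  X = 0), the current window starts with U and V known and unread. The
  two reachable carried states are S1 (U=0, V=0) and S2 (U=0, V=1).
* **Skip.** If the current window has X = 1 (read directly, or implied
  by counting Qc), the next window's U is 1, so it can be neither Q2 nor
  Qc and is skipped with zero reads.

Row boundaries: state resets at each row start (the first window of a
row reads its U and V fresh; virtual cells count as inspections), and a
skip pending at a row end is discarded. Skips never cross rows — the
wrap-around window would have a different, unknown U. Discarding is
conservative and cannot miscount: it only ever causes a window to be
examined rather than skipped.

**Read counter contract.** `reads` increments once per individual cell
inspection, including virtual border cells; carried values are never
re-counted. Under this contract GRAY costs exactly 4 reads per window
and I-GRAY exactly 2, so the three instrumented scanners are directly
comparable.

**Orientation groups.** Because E is rotation-invariant, the same scan
applied to the image rotated clockwise by 1, 2 or 3 quarter turns
(groups b, c, d; group a is unrotated) counts rotated pattern pairs and
returns the same E. This is realized literally as scan-after-rotate; the
four groups are property-tested to agree everywhere.

## Access-count model

Classifying the 16 patterns by what the scan must inspect:

| class | condition | patterns | expected reads |
|-------|-----------|----------|----------------|
| R1 | U = 1 | 8 | 1 |
| R2 | U = 0, X = 1 | 4 | 3 amortized over the guaranteed skipped successor → 1.5 |
| R3 | U = 0, X = 0 | 4 | 2 if the predecessor was R3 (carry), else 4 → 2·(4/16) + 4·(12/16) = 3.5 |

Assuming all 16 patterns equiprobable, the probability that an R3 window
follows another R3 is 4/16 = 1/4, and the uniform average is
`(1×8 + 1.5×4 + 3.5×4)/16 = 1.75` reads per bit-quad. The model is
derived at run time by enumerating patterns, not stored as constants.
It is an idealization: real images are not pattern-equiprobable, so the
measured reads-per-window of the instrumented scan varies with content
(≈1 on dense foreground, ≈2 on empty images), bounded by 4.

## Square-graph formulation

Vertices are foreground pixels; edges join 8-neighbors except that when
both diagonals of an all-foreground 2×2 block would cross, only the main
diagonal (representative to up-left) is kept — the formulation only
requires *some* consistent resolution, and this one follows from the
per-window edge rules: in the all-foreground window the representative
contributes edges to each of its three foreground predecessors (main
diagonal included) and the anti-diagonal is never added. Faces are the
basic right-angled triangles: 2 per all-foreground window, 1 per
three-foreground window. Then `E = v − e + s`, and Euler's planar
formula `v − e + (H + s + 1) = C + 1` ties the counts to the labeling
oracle's C and H (property-tested). Counting is incremental per window;
an explicit graph is built only in tests (networkx) as the independent
cross-check of the edge counter.

## Reference algorithms

* **GRAY**: census of three pattern families per window — exactly one
  foreground cell (P1), exactly three (P2), the two diagonal pairs (P3);
  `E = (N1 − N2 − 2N3)/4`. The numerator is divisible by 4 on every
  image (property-tested). 4 reads per window.
* **I-GRAY**: identical census; the previous window's right column is
  carried as the current left column (row starts carry the virtual
  border column, a known constant), so exactly 2 reads per window.
* **RUN**: maximal horizontal foreground runs R and neighboring-run
  pairs O — runs in vertically adjacent rows whose column intervals
  `[start−1, end+1]` and `[start, end]` overlap (8-adjacency). Pairs are
  counted once regardless of how many pixels touch. `E = R − O`.
* **HCS-style labeling**: `E = C − H` directly, via a two-pass raster
  union-find over foreground (8-connectivity) and over the
  background of the one-pixel-padded grid (4-connectivity; the padding
  ring makes the outside exactly one component, so `H = components − 1`).
  Only the input/output contract (C, H, E) is normative here; the
  original single-scan equivalent-label-set bookkeeping is an
  implementation detail of its authors and is not reproduced.

## Oracle

`euler_oracle` computes `E = C − H` from `scipy.ndimage.label` with the
appropriate structuring elements. It shares no code with any scanner —
that independence is what makes the cross-algorithm equivalence tests
meaningful. The oracle itself is validated against hand-derivable
fixtures (rings, nested rings, checkerboards) and its own invariances
(rotation, background-margin padding).

## Synthetic data

* **Noise images** — i.i.d. Bernoulli pixels at densities spanning 0..1
  (the density sweep defaults to 41 values 0, 0.025, …, 1.0). Noise
  masks have complicated component geometry and connectivity and are the
  stress test for agreement; they emulate thresholded uniform-noise
  images. Default sweep size 128×128 keeps the full CLI sweep in
  seconds; tests use smaller sizes (≤64) so the whole suite runs in well
  under a minute.
* **Specialized tilings** with closed-form Euler numbers:
  checkerboard (parity board; one diagonally connected component, one
  hole per interior odd-parity cell, so `E = 1 − holes`, which is
  negative for boards with interior cells), sawtooth and stair
  (bottom-anchored column profiles; simply connected, E = 1), honeycomb
  (offset-cell wall lattice; `E = 1 − k` with k the number of fully
  walled cells — aligned cell-rows contribute `n_cols`, shifted rows
  `n_cols − 1` because their edge half-cells open to the border). The
  tilings are representatives of the named families, with unit cells
  chosen here; every declared E is asserted equal to the oracle's.
* **Shape fixtures** — blob (E = 1), ring, nested and disjoint rings
  (E = 0: every ring contributes one component and one hole, at any
  nesting depth). A `beside` composer places images with a background
  gap for additivity tests.

What passing on synthetic data does *not* show: Bernoulli noise has no
spatial correlation, and the tilings are exactly periodic; real
segmentation masks (cells, text, textures) sit between these extremes.
Since every algorithm here is exact — no approximation anywhere — the
synthetic families are chosen to exercise all 16 bit-quad patterns and
both connectivity regimes densely, which they do; agreement transfers to
any 0/1 mask.

## Numerical and degenerate-input choices

* Everything is integer arithmetic; there are no tolerances.
* The empty image (0 rows or columns) is legal everywhere and has E = 0.
* Binarization of grayscale input is strict (`intensity > threshold`,
  default 0); PBM 1-bits are foreground regardless of threshold.
* A Q2/Qc tie is impossible (Q2 needs V = X = 0, Qc needs V = X = 1) and
  is asserted, not handled.
* PBM writing uses ASCII P1 by default (diff-friendly), packed P4 on
  request; both round-trip bit-exactly.

## Limitations

* 2-D, single-class binary masks only: no 3-D volumes, no multi-label
  images, no per-component Euler numbers.
* 8-connectivity for foreground only; no 4-connectivity variant of the
  two-pattern scan or of the square graph.
* Pixel-access counts, not wall-clock time, are the complexity metric:
  the Python implementations are instrumented references, not optimized
  kernels, and timing them would measure the interpreter.
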