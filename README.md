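# eulerquad

Euler number computation for 2-D binary images by bit-quad pattern
counting — with a two-pattern raster scan as the core algorithm,
conventional reference algorithms for cross-validation, pixel-access
instrumentation, a labeling oracle, and synthetic image generators.

## The problem

The Euler number (Euler characteristic) of a binary image,

```
E = C − H
```

— connected components minus holes — is a topological invariant widely
used in cell-image analysis, document processing, object recognition and
robot vision: it is unchanged when objects are stretched, flexed or
rotated. Throughout this package foreground connectivity is 8 (pixels
touching horizontally, vertically or diagonally) and hole connectivity
is 4, the standard pairing that keeps foreground and background
topologically consistent.

## The core algorithm

Write each 2×2 window (*bit-quad*) of the image, scanned left-to-right
and top-to-bottom, as

```
U X      U = p(x−1, y−1)   X = p(x, y−1)
V Y      V = p(x−1, y)     Y = p(x, y)   (the representative pixel)
```

Building the *square graph* of the image — foreground pixels as vertices,
edges between 8-neighbors with crossing diagonals resolved to one — and
applying Euler's planar formula `v − e + r = C + 1` with `r = H + s + 1`
(holes + basic triangular faces + outer face) gives

```
E = C − H = v − e + s.
```

Accumulating `v`, `e`, `s` per bit-quad and tabulating the increment
`ΔE = Δv − Δe + Δs` over all 16 patterns shows that only two patterns
change E:

* **Q2** `(U,V,X,Y) = (0,0,0,1)` — isolated representative pixel, ΔE = +1;
* **Qc** `U = 0, V = X = 1`, Y free — ΔE = −1 (the Karnaugh merge of two
  patterns).

So `E = W2 − Wc`, two tallies from one raster scan. Checking pixels in
the order U → V → X → Y with a two-state machine (`S1`: V = 0, `S2`:
V = 1, both with U = 0) lets the scan reuse the previous window's (X, Y)
as the current (U, V) and *skip* the successor of any window with X = 1
(its U is then known to be 1). Under equiprobable patterns the expected
cost is

```
(1 × 8 + 1.5 × 4 + 3.5 × 4) / 16 = 1.75 pixel reads per bit-quad,
```

versus 4 for the classic bit-quad census (GRAY) and 2 for its
column-carrying refinement (I-GRAY) — all three of which are implemented
here with honest per-inspection read counters, alongside the run-based
(`E = R − O`) and labeling-based (`E = C − H`) algorithms.

## Worked example

Generate a 16×16 noise image at density 0.4 (seed 0) and compute its
Euler number with the two-pattern scan:

```
$ eulerquad gen noise noise.pbm --height 16 --width 16 --density 0.4
wrote 16x16 noise image to noise.pbm
$ eulerquad compute noise.pbm --algorithm two_pattern
image: noise.pbm
algorithm: two_pattern
E: 11
W2: 34
Wc: 23
group: a
reads: 506
bitquads_processed: 224
```

The scan found 34 Q2 windows and 23 Qc windows, so `E = 34 − 23 = 11`:
this mask has eleven more 8-connected components than enclosed holes.
It inspected 506 pixel cells over the 17×17 = 289 windows of the padded
grid (65 windows were skipped for free) — about 1.75 reads per window.

Comparing all algorithms over a density sweep (any Euler disagreement
would exit nonzero):

```
$ eulerquad compare --size 32 --densities 0,0.25,0.5,0.75,1 --seed 3
case          E    two_pattern  gray  igray  agree
noise d=0     0    2.0606       4.0   2.0    True
noise d=0.25  74   1.8182       4.0   2.0    True
noise d=0.5   -54  1.5344       4.0   2.0    True
noise d=0.75  -87  1.3287       4.0   2.0    True
noise d=1     1    1.0615       4.0   2.0    True
```

The read columns are measured reads per bit-quad: GRAY is exactly 4,
I-GRAY exactly 2, and the two-pattern scan varies with content between
about 1 (dense foreground) and about 2 (empty), always below GRAY.

## Library surface

```python
from eulerquad import (
    BinaryImage, load_image, save_pbm,        # masks, PBM/PNG/TIFF I/O
    euler_two_pattern, scan_two_pattern,      # the two-pattern scan
    access_model,                             # analytic read accounting
    euler_graph, square_graph_summary,        # E = v − e + s
    euler_gray, euler_igray,                  # bit-quad census references
    euler_run, euler_hcs,                     # run-based and labeling-based
    euler_oracle,                             # ground truth via scipy labeling
    noise_image, pattern_image, shape_image,  # synthetic fixtures
)
```

See `docs/methods.md` for the model details, conventions and limitations.
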