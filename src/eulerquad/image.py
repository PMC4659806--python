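"""Binary image container, virtual background border, rotation, and file I/O.

A :class:`BinaryImage` is a 2-D grid of 0/1 values (0 = background,
1 = foreground/object), addressed as ``(row, col)`` with row 0 at the top.
Every scanner in this package operates on the *virtually padded* grid: the
accessor :meth:`BinaryImage.get` returns 0 for any coordinate outside the
stored extent, so masks whose foreground touches the image edge are handled
without copying or imposing a background-border requirement on user data.

Supported file formats: PBM (P1 ASCII and P4 binary) read/write bit-exact,
with the PBM convention that a 1-bit is foreground; PNG and TIFF read-only,
binarized as ``intensity > threshold``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BinaryImage",
    "UnsupportedImageError",
    "load_image",
    "save_pbm",
]


class UnsupportedImageError(ValueError):
    """Raised for image files this package cannot interpret as a 2-D binary mask."""


class BinaryImage:
    """An immutable 2-D binary mask with a virtual background border.

    Parameters
    ----------
    pixels : array-like
        2-D array of 0/1 values (any integer or boolean dtype). The empty
        image (zero rows and/or zero columns) is legal.
    """

    __slots__ = ("pixels",)

    def __init__(self, pixels) -> None:
        arr = np.asarray(pixels, dtype=np.uint8)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D grid, got {arr.ndim}-D")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("pixel values must be exactly 0 or 1")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("BinaryImage is immutable")

    @property
    def height(self) -> int:
        """Number of rows (N)."""
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        """Number of columns (M)."""
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def get(self, row: int, col: int) -> int:
        """Pixel value at ``(row, col)``; 0 anywhere outside the stored extent.

        Never raises: the image is conceptually embedded in an infinite
        background plane.
        """
        if 0 <= row < self.pixels.shape[0] and 0 <= col < self.pixels.shape[1]:
            return int(self.pixels[row, col])
        return 0

    def count_foreground(self) -> int:
        """Number of foreground (1) pixels."""
        return int(self.pixels.sum())

    def rotate90(self, quarter_turns: int = 1) -> "BinaryImage":
        """Rotate clockwise by ``quarter_turns`` quarter turns.

        Dimensions swap for odd turns; the foreground pixel count (and the
        Euler number, a topological invariant) are preserved.
        """
        k = int(quarter_turns) % 4
        # np.rot90 rotates counter-clockwise for positive k
        return BinaryImage(np.rot90(self.pixels, -k))

    def padded(self, margin: int = 1) -> "BinaryImage":
        """A copy with an explicit all-background margin on every side."""
        if margin < 0:
            raise ValueError("margin must be non-negative")
        return BinaryImage(np.pad(self.pixels, margin))

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )

    def __hash__(self):
        return hash((self.pixels.shape, self.pixels.tobytes()))

    def __repr__(self) -> str:
        return f"BinaryImage({self.height}x{self.width}, fg={self.count_foreground()})"


# ---------------------------------------------------------------------------
# PBM codec (P1 ASCII / P4 packed).  1-bit = foreground per the PBM standard.
# ---------------------------------------------------------------------------

_TOKEN = re.compile(rb"(?:\s|#[^\n\r]*)*([0-9]+|P[14])")


def _pbm_header(data: bytes) -> tuple[bytes, int, int, int]:
    """Parse magic, width, height; return them plus the offset past the header."""
    pos = 0
    fields: list[bytes] = []
    while len(fields) < 3:
        m = _TOKEN.match(data, pos)
        if not m:
            raise UnsupportedImageError("truncated or malformed PBM header")
        fields.append(m.group(1))
        pos = m.end()
    magic = fields[0]
    if magic not in (b"P1", b"P4"):
        raise UnsupportedImageError(f"not a PBM file (magic {magic!r})")
    width, height = int(fields[1]), int(fields[2])
    return magic, width, height, pos


def _read_pbm(data: bytes) -> np.ndarray:
    magic, width, height, pos = _pbm_header(data)
    if magic == b"P1":
        bits = re.sub(rb"#[^\n\r]*", b"", data[pos:])
        bits = re.sub(rb"\s", b"", bits)
        if len(bits) < width * height:
            raise UnsupportedImageError("P1 raster shorter than width*height")
        arr = np.frombuffer(bits[: width * height], dtype=np.uint8) - ord("0")
        if arr.size and arr.max() > 1:
            raise UnsupportedImageError("P1 raster contains characters other than 0/1")
        return arr.reshape(height, width)
    # P4: exactly one whitespace byte after the header, then packed rows
    pos += 1
    row_bytes = (width + 7) // 8
    raw = data[pos : pos + row_bytes * height]
    if len(raw) < row_bytes * height:
        raise UnsupportedImageError("P4 raster truncated")
    rows = np.frombuffer(raw, dtype=np.uint8).reshape(height, row_bytes)
    return np.unpackbits(rows, axis=1)[:, :width] if width else np.zeros((height, 0), np.uint8)


def save_pbm(img: BinaryImage, path, *, binary: bool = False) -> None:
    """Write ``img`` as PBM: ASCII P1 by default, packed P4 if ``binary``."""
    path = Path(path)
    h, w = img.shape
    if binary:
        packed = (
            np.packbits(img.pixels, axis=1)
            if w
            else np.zeros((h, 0), np.uint8)
        )
        path.write_bytes(b"P4\n%d %d\n" % (w, h) + packed.tobytes())
        return
    lines = ["P1", f"{w} {h}"]
    for row in img.pixels:
        text = "".join("1" if p else "0" for p in row)
        # keep lines within the PBM 70-character limit
        lines.extend(text[i : i + 64] for i in range(0, len(text), 64))
    path.write_text("\n".join(lines) + "\n")


def load_image(path, threshold: int = 0) -> BinaryImage:
    """Load a mask from PBM (P1/P4), PNG or TIFF.

    PBM 1-bits map directly to foreground (``threshold`` is ignored).
    Grayscale/RGB rasters are binarized as ``intensity > threshold``
    (strict; default threshold 0, so any nonzero pixel is foreground).

    Raises
    ------
    UnsupportedImageError
        For multi-frame or non-2-D images, or malformed PBM data.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    data = path.read_bytes()
    if data[:2] in (b"P1", b"P4"):
        return BinaryImage(_read_pbm(data))
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise UnsupportedImageError("multi-frame images are not supported")
            gray = im.convert("L")
            arr = np.asarray(gray)
    except UnsupportedImageError:
        raise
    except Exception as exc:  # Pillow raises various per-format errors
        raise UnsupportedImageError(f"cannot read {path.name}: {exc}") from exc
    if arr.ndim != 2:
        raise UnsupportedImageError("only 2-D single-channel rasters are supported")
    return BinaryImage((arr > threshold).astype(np.uint8))
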