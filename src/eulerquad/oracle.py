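"""Ground-truth Euler number by definition, via scipy.ndimage labeling.

This module is the independent referee for every scan algorithm in the
package: it computes ``E = C - H`` directly from connected-component
labelings (8-connectivity for foreground, 4-connectivity for background
holes) and deliberately shares no code with the raster scanners.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import BinaryImage

__all__ = ["label_components", "euler_oracle"]

_STRUCTURE = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_components(
    img: BinaryImage, connectivity: int = 8, target: str = "foreground"
) -> tuple[np.ndarray, int]:
    """Label connected regions of the foreground or the background.

    Returns ``(labels, count)`` with labels the same shape as the image.
    For the background, the image is conceptually embedded in an infinite
    background plane: every background region 4- (or 8-) connected to the
    border belongs to the outside and is labeled 0, and ``count`` is the
    number of *enclosed* regions (holes, for 4-connectivity).
    """
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE[connectivity]
    if target == "foreground":
        labels, count = ndimage.label(img.pixels, structure)
        return labels, int(count)
    if target != "background":
        raise ValueError("target must be 'foreground' or 'background'")
    padded = np.pad(img.pixels, 1)
    lab, count = ndimage.label(padded == 0, structure)
    outside = lab[0, 0]  # the padded ring is one background component
    inner = lab[1:-1, 1:-1].copy()
    enclosed_ids = [i for i in range(1, count + 1) if i != outside]
    remap = np.zeros(count + 1, dtype=np.int64)
    for new, old in enumerate(enclosed_ids, start=1):
        remap[old] = new
    return remap[inner], len(enclosed_ids)


def euler_oracle(img: BinaryImage) -> int:
    """``E = C - H``: 8-connected foreground components minus 4-connected
    holes, by exhaustive labeling."""
    _, c = label_components(img, 8, "foreground")
    _, h = label_components(img, 4, "background")
    return c - h
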