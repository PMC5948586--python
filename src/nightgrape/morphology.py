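"""Morphological cleanup of the raw segmentation.

The raw level-set mask may contain several connected regions (multiple
clusters, speckle) and interior holes (specular spots on berries).  The
cleanup keeps the largest connected region, fills its holes, then applies
an opening followed by a closing with a disk structuring element, which
also strips thin appendages such as the stem so the fruit rectangle is
computed on the cluster alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening

from .levelset import BinaryMask
from .preprocessing import InvalidInputError


@dataclass(frozen=True)
class MorphParams:
    open_radius: int = 3
    close_radius: int = 3
    connectivity: int = 8  # foreground; background flood uses the 4-dual

    def __post_init__(self) -> None:
        if self.open_radius < 1 or self.close_radius < 1:
            raise InvalidInputError("structuring-element radii must be >= 1")
        if self.connectivity not in (4, 8):
            raise InvalidInputError("connectivity must be 4 or 8")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def keep_largest(mask: BinaryMask) -> BinaryMask:
    """Retain only the connected component of maximal pixel count."""
    labels, n = ndimage.label(mask.labels, structure=_structure(mask.connectivity))
    if n <= 1:
        return BinaryMask(mask.labels.copy(), mask.connectivity)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return BinaryMask(labels == sizes.argmax(), mask.connectivity)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not connected to the image border.

    The background flood uses 4-connectivity, the dual of the 8-connected
    foreground.
    """
    filled = ndimage.binary_fill_holes(mask.labels, structure=_structure(4))
    return BinaryMask(filled, mask.connectivity)


def open_close(mask: BinaryMask, params: MorphParams | None = None) -> BinaryMask:
    """Opening then closing with disk structuring elements."""
    params = params or MorphParams()
    out = opening(mask.labels, disk(params.open_radius))
    out = closing(out, disk(params.close_radius))
    return BinaryMask(out, mask.connectivity)


def clean_mask(mask: BinaryMask, params: MorphParams | None = None) -> BinaryMask:
    """Full cleanup: largest region, hole fill, then open/close.

    The result has at most one connected component; opening can split or
    empty a region, so the largest-region step is repeated at the end to
    restore that guarantee.
    """
    params = params or MorphParams()
    out = keep_largest(mask)
    out = fill_holes(out)
    out = open_close(out, params)
    return keep_largest(out)
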