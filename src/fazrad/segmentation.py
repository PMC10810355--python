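"""Pluggable FAZ segmentation: contract, conformance checks, reference impl.

Production FAZ segmentation is a learned model (e.g. an nnU-Net trained on
public OCTA scan/mask pairs); that model is deliberately not part of this
package.  What is defined here is the slot it plugs into: any object with a
``segment(image) -> FazMask`` method satisfying the contract below can feed
the radiomics pipeline.

The bundled :class:`ReferenceSegmenter` is a classical intensity-threshold
segmenter — the FAZ is the dark avascular region at the centre of the
en-face angiogram — adequate for synthetic images and as a smoke-test
stand-in, not a clinical tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .geometry import FazMask, preprocess_mask

__all__ = [
    "OctaImage",
    "Segmenter",
    "SegmentationError",
    "ReferenceSegmenter",
    "check_segmenter_contract",
]


class SegmentationError(RuntimeError):
    """Raised when no central avascular region can be found."""


@dataclass
class OctaImage:
    """En-face OCTA grayscale image with a physical pixel scale."""

    pixels: np.ndarray  # intensities in [0, 1]
    pixel_size_mm: tuple[float, float]
    id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if not np.isfinite(p).all():
            raise ValueError("image intensities must be finite")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = p
        ph, pw = (float(v) for v in self.pixel_size_mm)
        if ph <= 0 or pw <= 0:
            raise ValueError("pixel size must be positive")
        self.pixel_size_mm = (ph, pw)


@runtime_checkable
class Segmenter(Protocol):
    """Contract: deterministic ``image -> FazMask`` of the same shape."""

    def segment(self, image: OctaImage) -> FazMask: ...


@dataclass
class ReferenceSegmenter:
    """Percentile threshold + central connected component.

    The threshold is the given intensity percentile of the central window
    (a ``center_window`` fraction of each image side).  Pixels strictly
    darker than the threshold are candidates; after a small binary closing
    the connected component containing (or nearest to) the image centre is
    kept and its holes filled.
    """

    percentile: float = 10.0
    center_window: float = 0.5
    closing_radius: int = 2

    def segment(self, image: OctaImage) -> FazMask:
        h, w = image.pixels.shape
        mh = int(round(h * (1 - self.center_window) / 2))
        mw = int(round(w * (1 - self.center_window) / 2))
        window = image.pixels[mh : h - mh, mw : w - mw]
        threshold = np.percentile(window, self.percentile)
        candidates = image.pixels < threshold
        if not candidates.any():
            raise SegmentationError("no pixels below the intensity threshold")
        if self.closing_radius > 0:
            candidates = ndimage.binary_closing(
                candidates, structure=morphology.disk(self.closing_radius)
            )
        labels = measure.label(candidates, connectivity=2)
        centre = ((h - 1) / 2.0, (w - 1) / 2.0)
        centre_label = labels[int(round(centre[0])), int(round(centre[1]))]
        if centre_label == 0:
            # nearest foreground component to the image centre
            rows, cols = np.nonzero(labels)
            if rows.size == 0:
                raise SegmentationError("no connected dark component found")
            d2 = (rows - centre[0]) ** 2 + (cols - centre[1]) ** 2
            centre_label = labels[rows[d2.argmin()], cols[d2.argmin()]]
        grid = ndimage.binary_fill_holes(labels == centre_label).astype(np.uint8)
        if grid.sum() == 0:
            raise SegmentationError("central dark component is empty")
        return FazMask(grid, image.pixel_size_mm, id=image.id)


def check_segmenter_contract(
    segmenter: Segmenter, image: OctaImage
) -> FazMask:
    """Run a segmenter and verify the output contract.

    Checks: same shape as the input, binary, deterministic across reruns,
    and invariant under :func:`~fazrad.geometry.preprocess_mask` (single
    8-connected component, no holes).  Returns the validated mask; raises
    ``AssertionError`` on contract violations, so the same routine can be
    pointed at any third-party segmenter plugin.
    """
    mask = segmenter.segment(image)
    assert mask.grid.shape == image.pixels.shape, "mask shape differs from image"
    assert set(np.unique(mask.grid)) <= {0, 1}, "mask is not binary"
    again = segmenter.segment(image)
    assert np.array_equal(mask.grid, again.grid), "segmenter is not deterministic"
    cleaned = preprocess_mask(mask)
    assert np.array_equal(mask.grid, cleaned.grid), (
        "mask is not a single hole-free component"
    )
    return mask
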