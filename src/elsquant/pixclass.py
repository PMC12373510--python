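"""Global-threshold pixel classification and mask clean-up.

Pixels are classified as positive for a marker by a single global intensity
threshold per channel — the same rule used when a trained operator assigns a
per-channel cut-off to a whole acquisition batch.  An automatic Otsu fallback
is provided for unattended runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from .imgio import MultiplexImage

__all__ = ["ThresholdSpec", "global_threshold", "auto_threshold", "clean_mask"]


@dataclass(frozen=True)
class ThresholdSpec:
    """A per-channel global threshold.

    ``method="manual"`` requires an explicit ``threshold``; ``method="otsu"``
    derives it from the channel histogram and ignores any supplied value.
    ``comparison`` sets the boundary semantics; the default is inclusive.
    """

    channel: str
    threshold: float | None = None
    comparison: str = ">="
    method: str = "manual"

    def __post_init__(self) -> None:
        if self.comparison not in (">=", ">"):
            raise ValueError("comparison must be '>=' or '>'")
        if self.method not in ("manual", "otsu"):
            raise ValueError("method must be 'manual' or 'otsu'")
        if self.method == "manual" and self.threshold is None:
            raise ValueError("manual thresholding requires an explicit threshold")


def auto_threshold(image: MultiplexImage, channel: str, nbins: int = 256) -> float:
    """Otsu's threshold for one channel: the cut maximizing between-class
    variance over the intensity histogram.

    Raises
    ------
    ValueError
        If the channel is constant (no separable classes).
    """
    data = image.channel(channel)
    if np.ptp(data) == 0:
        raise ValueError(
            f"channel {channel!r} is constant; Otsu thresholding is undefined"
        )
    return float(threshold_otsu(np.asarray(data, dtype=float), nbins=nbins))


def global_threshold(image: MultiplexImage, spec: ThresholdSpec) -> np.ndarray:
    """Binary mask of pixels whose intensity satisfies the spec's comparison
    against its (manual or Otsu) threshold."""
    data = image.channel(spec.channel)
    if spec.method == "otsu":
        thr = auto_threshold(image, spec.channel)
    else:
        thr = float(spec.threshold)
    return data >= thr if spec.comparison == ">=" else data > thr


def clean_mask(
    mask: np.ndarray,
    min_object_area_um2: float = 0.0,
    fill_holes: bool = False,
    pixel_size_um: float = 1.0,
    connectivity: int = 8,
) -> np.ndarray:
    """Remove connected components smaller than ``min_object_area_um2`` and
    optionally fill fully enclosed holes.  Idempotent; with
    ``fill_holes=False`` the output is a subset of the input."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    out = mask.copy()
    if min_object_area_um2 > 0:
        lab, n = _label(out, connectivity=1 if connectivity == 4 else 2, return_num=True)
        if n:
            sizes = np.bincount(lab.ravel())
            min_px = min_object_area_um2 / pixel_size_um**2
            small = np.nonzero(sizes < min_px)[0]
            small = small[small > 0]
            if small.size:
                out[np.isin(lab, small)] = False
    if fill_holes:
        out = ndi.binary_fill_holes(out)
    return out
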