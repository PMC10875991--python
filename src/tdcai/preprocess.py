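"""Skull and extracranial-tissue removal on registered 4D CTP series.

Bone is far denser than any soft tissue or contrast-enhanced vessel, so a
simple HU threshold (default 155 HU) on the first frame isolates the skull.
Everything outside the largest cavity enclosed by the skull mask is treated
as extracranial and blanked to an air sentinel; in-brain voxels pass through
untouched.  The mask is 3D and applied uniformly to every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTPSeries

__all__ = ["SkullMask", "compute_skull_mask", "strip_skull", "BACKGROUND_HU"]

BACKGROUND_HU = -1024.0  # air; outside any vessel-threshold range


@dataclass
class SkullMask:
    mask: np.ndarray  # 3D boolean
    threshold_hu: float = 155.0


def compute_skull_mask(series: CTPSeries, threshold_hu: float = 155.0) -> SkullMask:
    """Threshold the first frame at >= ``threshold_hu`` (inclusive).

    The first frame is the registration benchmark, acquired before contrast
    arrival, so only bone exceeds the threshold there.
    """
    frame0 = series.values[0]
    if not np.all(np.isfinite(frame0)):
        raise ValueError("series contains non-finite voxels")
    return SkullMask(mask=frame0 >= threshold_hu, threshold_hu=float(threshold_hu))


def strip_skull(series: CTPSeries, skull: SkullMask, dilate_mm: float = 0.0) -> CTPSeries:
    """Blank skull and extracranial voxels to the air sentinel in every frame.

    The brain region is the largest connected component of the mask's
    complement that does not touch the volume border (i.e. the cavity the
    skull encloses).  If no enclosed cavity exists (no shell in the image),
    all non-skull voxels are kept, so an empty mask is the identity.
    """
    mask = skull.mask
    if mask.shape != series.shape:
        raise ValueError(f"mask shape {mask.shape} does not match series grid {series.shape}")
    if dilate_mm > 0:
        it = max(1, int(round(dilate_mm / min(series.spacing))))
        mask = ndimage.binary_dilation(mask, iterations=it)

    if not mask.any():
        return CTPSeries(values=series.values.copy(), times=series.times.copy(),
                         spacing=series.spacing, origin=series.origin)

    keep = _brain_region(mask)
    values = np.where(keep[None], series.values, np.float32(BACKGROUND_HU)).astype(series.values.dtype)
    return CTPSeries(values=values, times=series.times.copy(),
                     spacing=series.spacing, origin=series.origin)


def _brain_region(mask: np.ndarray) -> np.ndarray:
    """Largest complement component fully enclosed by the mask; all non-mask
    voxels when nothing is enclosed."""
    comp = ~mask
    labels, n = ndimage.label(comp)
    if n == 0:
        return np.zeros_like(mask)
    border = np.zeros_like(mask)
    border[0] = border[-1] = True
    border[:, 0] = border[:, -1] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border & comp])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[touching] = 0
    if counts.max() == 0:
        return comp  # no enclosed cavity: keep everything that is not skull
    return labels == int(np.argmax(counts))
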