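"""Cell footprint segmentation and edge protrusion/retraction velocity.

The edge velocity at a boundary point is the change in the signed distance
transform between consecutive frames (positive inside the cell), divided by
the frame interval: a uniformly advancing front therefore reads positive
(protrusion), a retracting one negative.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = ["EdgeSeries", "segment_cell", "edge_velocity", "distance_to_edge",
           "signed_distance"]


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance (px) to the mask's boundary pixels: positive inside
    the mask, negative outside, exactly 0 on boundary pixels themselves."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return -ndimage.distance_transform_edt(~mask)
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    d = ndimage.distance_transform_edt(~boundary)
    return np.where(mask, d, -d)


def segment_cell(frame: np.ndarray, min_fraction: float = 0.01) -> np.ndarray:
    """Segment the cell footprint: Otsu on log intensity, fill holes, keep
    the largest connected component."""
    frame = np.asarray(frame, dtype=float)
    shifted = frame - frame.min() + 1.0
    logim = np.log(shifted)
    if logim.max() - logim.min() < 1e-12:
        raise ValueError("uniform frame: no cell foreground found")
    thr = threshold_otsu(logim)
    mask = logim > thr
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no cell foreground found")
    sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if mask.sum() < min_fraction * mask.size:
        raise ValueError("foreground below minimum cell fraction")
    return mask


class EdgeSeries:
    """Per-frame cell masks, boundaries, and boundary-point normal velocity.

    Also serves as the edge-geometry provider for feature extraction:
    ``distance_um`` is the signed distance (µm, positive inside) from a pixel
    position to the cell edge and ``local_velocity_um_min`` the edge normal
    velocity at the boundary point nearest to the query position.
    """

    def __init__(self, masks: np.ndarray, pixel_size_um: float,
                 frame_interval_s: float):
        self.masks = np.asarray(masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (T, H, W) stack")
        self.pixel_size_um = pixel_size_um
        self.frame_interval_s = frame_interval_s
        self._sdist = np.stack([signed_distance(m) for m in self.masks])
        # velocity field per frame pair, µm/min, sampled on the pixel grid
        self._vel = (np.diff(self._sdist, axis=0) * pixel_size_um
                     * 60.0 / frame_interval_s)
        self.boundaries = [
            measure.find_contours(m.astype(float), 0.5)[0]
            if m.any() and not m.all() else np.zeros((0, 2))
            for m in self.masks
        ]

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    def velocity_at_boundary(self, frame: int) -> np.ndarray:
        """Normal velocity (µm/min) sampled at the boundary points of ``frame``."""
        b = self.boundaries[frame]
        if len(b) == 0:
            return np.zeros(0)
        t = min(frame, self._vel.shape[0] - 1)
        r = np.clip(np.round(b[:, 0]).astype(int), 0, self._vel.shape[1] - 1)
        c = np.clip(np.round(b[:, 1]).astype(int), 0, self._vel.shape[2] - 1)
        return self._vel[t, r, c]

    def distance_um(self, x: float, y: float, frame: int) -> float:
        r = int(np.clip(round(y), 0, self._sdist.shape[1] - 1))
        c = int(np.clip(round(x), 0, self._sdist.shape[2] - 1))
        return float(self._sdist[frame, r, c] * self.pixel_size_um)

    def local_velocity_um_min(self, x: float, y: float, frame: int) -> float:
        b = self.boundaries[frame]
        if len(b) == 0:
            return 0.0
        d2 = (b[:, 0] - y) ** 2 + (b[:, 1] - x) ** 2
        i = int(np.argmin(d2))
        t = min(frame, self._vel.shape[0] - 1)
        r = int(np.clip(round(b[i, 0]), 0, self._vel.shape[1] - 1))
        c = int(np.clip(round(b[i, 1]), 0, self._vel.shape[2] - 1))
        return float(self._vel[t, r, c])


def edge_velocity(masks: np.ndarray, pixel_size_um: float,
                  frame_interval_s: float) -> EdgeSeries:
    """Build an :class:`EdgeSeries` from a (T, H, W) mask stack (T >= 2)."""
    masks = np.asarray(masks, dtype=bool)
    if masks.shape[0] < 2:
        raise ValueError("edge velocity needs at least 2 frames")
    return EdgeSeries(masks, pixel_size_um, frame_interval_s)


def distance_to_edge(position_px: tuple[float, float], mask: np.ndarray,
                     pixel_size_um: float) -> float:
    """Signed distance (µm) from a pixel position to the mask edge;
    positive inside the cell, negative outside."""
    sd = signed_distance(mask)
    x, y = position_px
    r = int(np.clip(round(y), 0, mask.shape[0] - 1))
    c = int(np.clip(round(x), 0, mask.shape[1] - 1))
    return float(sd[r, c] * pixel_size_um)
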