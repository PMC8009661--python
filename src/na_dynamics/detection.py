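"""Point-source detection of nascent adhesions and FC/FA segmentation.

Diffraction-limited adhesions are detected as point sources: the frame is
filtered with a Laplacian-of-Gaussian at the PSF scale, local maxima above a
robust noise threshold become candidates, and each candidate is fit with an
isotropic 2D Gaussian (fixed sd = PSF sd by default; free-sd mode for PSF
validation).  Fits whose amplitude is not significant against the local
residual noise at level ``alpha`` are rejected.

Larger adhesions are segmented by thresholding the denoised,
background-subtracted frame at the mean of Otsu's and Rosin's (triangle)
thresholds; components larger than the minimum area are classified focal
contact (FC) or focal adhesion (FA) by the major-axis length of the fitted
ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, threshold_triangle

from .config import ImagingConfig

__all__ = ["PointDetection", "SegmentedAdhesion", "detect_point_sources",
           "segment_adhesions", "adhesion_densities", "fit_gaussian_spot"]


@dataclass
class PointDetection:
    """A single accepted point-source fit."""

    frame: int
    x: float
    y: float
    amplitude: float      # background-subtracted Gaussian amplitude, AU
    background: float     # local background level, AU
    sigma: float          # fitted (or fixed) Gaussian sd, px
    p_value: float        # amplitude significance (smaller = stronger)


@dataclass
class SegmentedAdhesion:
    """A segmented focal contact (FC) or focal adhesion (FA)."""

    frame: int
    mask: np.ndarray
    area_um2: float
    length_um: float      # major axis of the fitted ellipse
    kind: str             # "FC" or "FA"
    centroid: tuple[float, float]  # (x, y) px


def _gaussian2d(params, xx, yy, fixed_sigma):
    if fixed_sigma is None:
        a, x0, y0, s, b = params
    else:
        a, x0, y0, b = params
        s = fixed_sigma
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s * s)) + b


def fit_gaussian_spot(window: np.ndarray, x0: float, y0: float,
                      sigma: float, free_sigma: bool = False):
    """Least-squares isotropic Gaussian fit on a local window.

    Returns (amplitude, x, y, sigma, background, residual_sd) with positions
    in window coordinates.
    """
    win = np.asarray(window, dtype=float)
    yy, xx = np.mgrid[0:win.shape[0], 0:win.shape[1]]
    b0 = float(np.percentile(win, 20))
    a0 = max(float(win.max() - b0), 1e-6)
    if free_sigma:
        p0 = [a0, x0, y0, sigma, b0]
        fixed = None
        lb = [0.0, 0.0, 0.0, 0.3, -np.inf]
        ub = [np.inf, win.shape[1] - 1.0, win.shape[0] - 1.0, 20.0, np.inf]
    else:
        p0 = [a0, x0, y0, b0]
        fixed = sigma
        lb = [0.0, 0.0, 0.0, -np.inf]
        ub = [np.inf, win.shape[1] - 1.0, win.shape[0] - 1.0, np.inf]
    res = optimize.least_squares(
        lambda p: (_gaussian2d(p, xx, yy, fixed) - win).ravel(),
        p0, bounds=(lb, ub), method="trf", max_nfev=200)
    p = res.x
    if free_sigma:
        a, xf, yf, sf, b = p
    else:
        a, xf, yf, b = p
        sf = sigma
    resid = _gaussian2d(p, xx, yy, fixed) - win
    dof = max(win.size - len(p), 1)
    resid_sd = float(np.sqrt((resid ** 2).sum() / dof))
    return float(a), float(xf), float(yf), float(sf), float(b), resid_sd


def detect_point_sources(frame: np.ndarray, sigma_px: float = 2.1,
                         alpha: float = 0.05, frame_index: int = 0,
                         free_sigma: bool = False,
                         threshold_k: float = 5.0) -> list[PointDetection]:
    """LoG filtering + local maxima + Gaussian fitting of point sources.

    The candidate threshold is ``threshold_k`` robust noise sd of the LoG
    response (MAD-based).  The amplitude of each fit is tested against its
    standard error from the local residual noise; candidates with
    one-sided p >= ``alpha`` are rejected.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or not np.isfinite(img).all():
        raise ValueError("frame must be a finite 2D image")
    response = -ndimage.gaussian_laplace(img, sigma_px) * sigma_px ** 2
    med = np.median(response)
    noise_sd = 1.4826 * np.median(np.abs(response - med))
    if noise_sd == 0:
        noise_sd = response.std()
    if noise_sd == 0:
        return []
    thr = med + threshold_k * noise_sd
    coords = peak_local_max(response, min_distance=max(int(sigma_px), 1),
                            threshold_abs=thr, exclude_border=False)
    half = max(int(np.ceil(4 * sigma_px)), 3)
    detections: list[PointDetection] = []
    # effective dof of the amplitude estimate in a Gaussian LSQ fit
    for r, c in coords:
        r0, r1 = max(r - half, 0), min(r + half + 1, img.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, img.shape[1])
        win = img[r0:r1, c0:c1]
        if win.shape[0] < 5 or win.shape[1] < 5:
            continue
        a, xf, yf, sf, b, resid_sd = fit_gaussian_spot(
            win, c - c0, r - r0, sigma_px, free_sigma=free_sigma)
        # SE of the amplitude for an isotropic Gaussian model:
        # var(a) ≈ resid_sd² / Σ(g − ḡ)², g the unit-amplitude profile
        yy, xx = np.mgrid[0:win.shape[0], 0:win.shape[1]]
        g = np.exp(-((xx - xf) ** 2 + (yy - yf) ** 2) / (2 * sf * sf))
        denom = ((g - g.mean()) ** 2).sum()
        se = resid_sd / np.sqrt(max(denom, 1e-12))
        z = a / max(se, 1e-12)
        p = float(stats.norm.sf(z))
        if a <= 0 or p >= alpha:
            continue
        detections.append(PointDetection(frame_index, c0 + xf, r0 + yf,
                                         a, b, sf, p))
    return detections


def _rosin_threshold(img: np.ndarray) -> float:
    # Rosin's unimodal corner threshold; the triangle construction is the
    # standard library form of it.
    return float(threshold_triangle(img))


def preprocess_frame(frame: np.ndarray, noise_sigma_px: float = 1.0,
                     background_radius_px: int = 10) -> np.ndarray:
    """Noise removal (Gaussian blur) + background subtraction (morphological
    opening with a disk)."""
    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), noise_sigma_px)
    footprint = morphology.disk(background_radius_px)
    background = morphology.opening(img, footprint)
    return img - background


def segment_adhesions(frame: np.ndarray, config: ImagingConfig,
                      frame_index: int = 0, combine: str = "mean",
                      preprocessed: bool = False) -> list[SegmentedAdhesion]:
    """Segment FCs/FAs with a combined Otsu/Rosin threshold.

    ``combine`` selects how the two thresholds merge: "mean" (default),
    "min", or "max".  Components with area above the configured minimum are
    kept; each is labelled FA if its ellipse major axis exceeds the FA length
    threshold, else FC.
    """
    img = np.asarray(frame, dtype=float)
    if not preprocessed:
        img = preprocess_frame(img)
    if img.max() - img.min() < 1e-12:
        return []
    t_otsu = float(threshold_otsu(img))
    t_rosin = _rosin_threshold(img)
    thr = {"mean": 0.5 * (t_otsu + t_rosin),
           "min": min(t_otsu, t_rosin),
           "max": max(t_otsu, t_rosin)}[combine]
    binary = img > thr
    labels = measure.label(binary)
    px_area = config.pixel_size_um ** 2
    out: list[SegmentedAdhesion] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 <= config.fc_min_area_um2:
            continue
        length_um = region.axis_major_length * config.pixel_size_um
        kind = "FA" if length_um > config.fa_min_length_um else "FC"
        mask = labels == region.label
        cy, cx = region.centroid
        out.append(SegmentedAdhesion(frame_index, mask, float(area_um2),
                                     float(length_um), kind, (cx, cy)))
    return out


def adhesion_densities(detections: list[PointDetection],
                       segments: list[SegmentedAdhesion],
                       cell_mask: np.ndarray,
                       pixel_size_um: float):
    """NA/FA densities (per µm² of cell area) and FA area/length arrays."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    area_um2 = cell_mask.sum() * pixel_size_um ** 2
    if area_um2 == 0:
        raise ValueError("empty cell mask")
    fa = [s for s in segments if s.kind == "FA"]
    na_density = len(detections) / area_um2
    fa_density = len(fa) / area_um2
    fa_areas = np.array([s.area_um2 for s in fa])
    fa_lengths = np.array([s.length_um for s in fa])
    return na_density, fa_density, fa_areas, fa_lengths
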