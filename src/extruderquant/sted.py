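"""STED super-resolution spot analysis.

Segmentation of single-molecule-scale spots inside a nuclear mask
(Gaussian blur, Otsu threshold within the mask, erosion/size
filtering/dilation, watershed splitting of clusters on local maxima),
per-spot intensity statistics, spot densities and labeling efficiency,
Pearson colocalization of two channels, and dimer-fraction inference from
spot-intensity distributions via a fixed-means two-component mixture
(monomers at the reference median mu, dimers at 2*mu).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import grey_erosion, grey_dilation
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, erosion, remove_small_objects
from skimage.segmentation import watershed


@dataclass
class SegmentationParams:
    blur_sigma: float = 1.0
    min_size: int = 4            # px, after erosion
    erosion_radius: int = 1
    peak_min_distance: int = 4
    threshold: float | None = None   # fixed common threshold; None = per-image Otsu

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0 or self.min_size <= 0 or self.erosion_radius <= 0 \
                or self.peak_min_distance <= 0:
            raise ValueError("segmentation parameters must be positive")


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int
    ok: bool = True


@dataclass
class DimerFit:
    dimer_fraction: float
    median_ratio: float
    monomer_mean: float
    sigma: float
    n_iter: int


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Estimate and remove a smooth background by greyscale opening.

    The background envelope is a flat opening (erosion then dilation) with
    a separable square structuring element of half-width ``radius``, the
    morphological analogue of rolling-ball subtraction.
    """
    size = 2 * radius + 1
    background = grey_dilation(grey_erosion(image, size=(size, size)),
                               size=(size, size))
    return image - background


def segment_spots(image: np.ndarray, nuclear_mask: np.ndarray,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment fluorescent spots inside the nuclear mask.

    Pipeline: mild Gaussian blur -> Otsu threshold computed within the mask
    (or a supplied common threshold) -> binary erosion and removal of
    objects below ``min_size`` -> dilation -> cluster splitting by local
    maxima and watershed.  Per-spot statistics (intensity-weighted
    centroid, area, mean intensity) come from the ORIGINAL image, which is
    expected to be background-subtracted (see :func:`subtract_background`).

    Returns a spot table with columns row, col, area, mean_intensity,
    max_intensity, label.
    """
    if params is None:
        params = SegmentationParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    mask = np.asarray(nuclear_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nuclear mask")

    blurred = gaussian(image, sigma=params.blur_sigma, preserve_range=True)
    vals = blurred[mask]
    if np.ptp(vals) == 0:
        return _empty_spot_table()
    thr = params.threshold if params.threshold is not None else threshold_otsu(vals)
    binary = (blurred > thr) & mask
    selem = disk(params.erosion_radius)
    binary = erosion(binary, selem)
    binary = remove_small_objects(binary, max_size=params.min_size - 1)
    binary = dilation(binary, selem) & mask
    if not binary.any():
        return _empty_spot_table()

    coarse = label(binary)
    peaks = peak_local_max(blurred, labels=coarse,
                           min_distance=params.peak_min_distance,
                           exclude_border=False)
    markers = np.zeros_like(coarse)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        labels = coarse
    else:
        labels = watershed(-blurred, markers=markers, mask=binary)

    rows = []
    for prop in regionprops(labels, intensity_image=image):
        r, c = prop.centroid_weighted
        rows.append({
            "row": float(r), "col": float(c),
            "area": int(prop.area),
            "mean_intensity": float(prop.intensity_mean),
            "max_intensity": float(prop.intensity_max),
            "label": int(prop.label),
        })
    return pd.DataFrame(rows) if rows else _empty_spot_table()


def _empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "col", "area", "mean_intensity",
                                 "max_intensity", "label"])


def pearson_colocalization(image_a: np.ndarray, image_b: np.ndarray,
                           nuclear_mask: np.ndarray) -> ColocResult:
    """Pearson correlation of two channels over masked pixels."""
    a, b = np.asarray(image_a, float), np.asarray(image_b, float)
    if a.shape != b.shape:
        raise ValueError("channel images must have identical shapes")
    mask = np.asarray(nuclear_mask, dtype=bool)
    if mask.shape != a.shape or not mask.any():
        raise ValueError("mask must match the images and be nonempty")
    va, vb = a[mask], b[mask]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return ColocResult(pearson_r=np.nan, n_pixels=int(mask.sum()), ok=False)
    r = float(np.corrcoef(va, vb)[0, 1])
    return ColocResult(pearson_r=r, n_pixels=int(mask.sum()))


def spot_density(table: pd.DataFrame, mask_area_um2: float,
                 z_depth_um: float = 0.5) -> float:
    """Detected spots per um^3 assuming an optical-section depth (0.5 um)."""
    if mask_area_um2 <= 0 or z_depth_um <= 0:
        raise ValueError("area and z-depth must be positive")
    return len(table) / (mask_area_um2 * z_depth_um)


def labeling_efficiency(observed_density: float, expected_density: float) -> float:
    """Ratio of observed spot density to the density expected from copy numbers."""
    if expected_density <= 0:
        raise ValueError("expected density must be positive")
    if observed_density < 0:
        raise ValueError("observed density must be nonnegative")
    ratio = observed_density / expected_density
    if ratio > 1:
        import warnings
        warnings.warn("observed density exceeds expectation (efficiency > 1)")
    return ratio


def dimer_fraction(intensities, monomer_reference, max_iter: int = 200,
                   tol: float = 1e-8) -> DimerFit:
    """Dimer fraction from spot intensities against a monomer reference.

    Fits a two-component Gaussian mixture with means fixed at mu and 2*mu
    (mu = median of the reference distribution) and a shared variance
    estimated robustly from the reference; only the mixing weight is free
    and is estimated by expectation-maximization.  Also reports the
    median intensity ratio test/reference.
    """
    x = np.asarray(intensities, dtype=float)
    ref = np.asarray(monomer_reference, dtype=float)
    if x.size < 30 or ref.size < 30:
        raise ValueError("need at least 30 spots in each distribution")
    mu = float(np.median(ref))
    if mu <= 0:
        raise ValueError("degenerate reference (non-positive median)")
    sigma = 1.4826 * float(np.median(np.abs(ref - mu)))
    if sigma <= 0:
        sigma = max(np.std(ref), 1e-12)
    ratio = float(np.median(x)) / mu

    w = 0.5
    log_norm = -0.5 * np.log(2 * np.pi * sigma**2)
    ll1 = log_norm - 0.5 * ((x - mu) / sigma) ** 2
    ll2 = log_norm - 0.5 * ((x - 2 * mu) / sigma) ** 2
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        num = w * np.exp(ll2 - np.maximum(ll1, ll2))
        den = (1 - w) * np.exp(ll1 - np.maximum(ll1, ll2)) + num
        resp = num / den
        w_new = float(np.mean(resp))
        if abs(w_new - w) < tol:
            w = w_new
            break
        w = w_new
    return DimerFit(dimer_fraction=w, median_ratio=ratio, monomer_mean=mu,
                    sigma=sigma, n_iter=n_iter)
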