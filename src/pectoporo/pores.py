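"""Pore quantification from electron micrographs.

Pipeline mirroring standard SEM cell-wall porosimetry: crop a calibrated
region of interest, threshold into pore / non-pore phases, clean the mask
with erode/dilate morphology, label connected components, convert pixel
areas to nm², filter to the 5–300 nm² analysis window, bin into the
15-nm²-wide histogram over 5–305 nm², and estimate the areal porosity

    phi = <A_p> * N_p / A_s

(mean pore area times pore count over sample area, identically the total
pore area fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, erosion

from .quench import ConfigurationError, DomainError


class ThresholdingError(ValueError):
    """Automatic thresholding is impossible (e.g. constant image)."""


@dataclass
class CalibratedImage:
    """Grayscale micrograph with a physical pixel size.

    ``roi_nm`` is an optional (width, height) rectangle in nm, cropped from
    the image centre before any analysis.
    """

    pixels: np.ndarray
    nm_per_px: float
    roi_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DomainError("pixels must be a non-empty 2-D array")
        if self.nm_per_px <= 0:
            raise DomainError("nm_per_px must be positive")
        if self.roi_nm is not None:
            w_px = int(round(self.roi_nm[0] / self.nm_per_px))
            h_px = int(round(self.roi_nm[1] / self.nm_per_px))
            if w_px > self.pixels.shape[1] or h_px > self.pixels.shape[0]:
                raise DomainError("ROI does not fit within the image")

    def roi_view(self) -> np.ndarray:
        """The analysis region: the centred ROI crop, or the whole image."""
        if self.roi_nm is None:
            return self.pixels
        w_px = int(round(self.roi_nm[0] / self.nm_per_px))
        h_px = int(round(self.roi_nm[1] / self.nm_per_px))
        r0 = (self.pixels.shape[0] - h_px) // 2
        c0 = (self.pixels.shape[1] - w_px) // 2
        return self.pixels[r0:r0 + h_px, c0:c0 + w_px]

    @property
    def sample_area_nm2(self) -> float:
        return float(self.roi_view().size) * self.nm_per_px ** 2


@dataclass
class PoreRecord:
    label_id: int
    pixel_count: int
    area_nm2: float
    centroid: tuple[float, float]  # (row, col) in ROI pixel coordinates


@dataclass
class PoreSizeDistribution:
    bin_edges: np.ndarray     # nm², length n_bins + 1
    counts: np.ndarray        # per-bin pore counts
    frequencies: np.ndarray   # counts normalised to 1 (zeros if no pores)


@dataclass
class PorositySummary:
    mean_pore_area_nm2: float
    n_pores: int
    sample_area_nm2: float
    phi: float


# --------------------------------------------------------------------------


def threshold_pores(
    image: CalibratedImage,
    method: str = "otsu",
    manual_level: float | None = None,
    dark_pores: bool = True,
) -> np.ndarray:
    """Segment the (ROI-cropped) image into pore / non-pore pixels.

    ``method="otsu"`` picks a global level automatically; ``method="manual"``
    uses ``manual_level``.  With ``dark_pores`` (the default for
    secondary-electron micrographs) pixels strictly below the level are pore.
    """
    px = image.roi_view()
    if method == "manual":
        if manual_level is None:
            raise ConfigurationError("manual thresholding requires manual_level")
        level = manual_level
    elif method == "otsu":
        if np.ptp(px) == 0:
            raise ThresholdingError("constant image: no automatic threshold exists")
        level = threshold_otsu(px)
    else:
        raise ConfigurationError(f"unknown threshold method {method!r}")
    return px < level if dark_pores else px > level


def morph_filter(
    mask: np.ndarray,
    erode_iters: int = 1,
    dilate_iters: int = 1,
    element: np.ndarray | None = None,
) -> np.ndarray:
    """Erosion(s) then dilation(s); defaults give a 3×3-square opening."""
    if erode_iters < 0 or dilate_iters < 0:
        raise DomainError("iteration counts must be non-negative")
    if element is None:
        element = np.ones((3, 3), dtype=bool)
    out = np.asarray(mask, dtype=bool)
    for _ in range(erode_iters):
        out = erosion(out, element)
    for _ in range(dilate_iters):
        out = dilation(out, element)
    return out.astype(bool)


def label_pores(
    mask: np.ndarray,
    image: CalibratedImage,
    connectivity: int = 2,
) -> list[PoreRecord]:
    """Connected components of the mask as calibrated pore records.

    ``connectivity=2`` (8-neighbour, the default) merges diagonally touching
    pixels; ``connectivity=1`` is the 4-neighbour alternative.
    """
    labelled = cc_label(np.asarray(mask, dtype=bool), connectivity=connectivity)
    scale = image.nm_per_px ** 2
    return [
        PoreRecord(
            label_id=int(rp.label),
            pixel_count=int(rp.area),
            area_nm2=float(rp.area) * scale,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        )
        for rp in regionprops(labelled)
    ]


def filter_pores(
    records: list[PoreRecord],
    min_nm2: float = 5.0,
    max_nm2: float = 300.0,
) -> list[PoreRecord]:
    """Keep pores with area in the inclusive window [min_nm2, max_nm2]."""
    if min_nm2 > max_nm2:
        raise ConfigurationError("min_nm2 must not exceed max_nm2")
    return [r for r in records if min_nm2 <= r.area_nm2 <= max_nm2]


def size_histogram(
    records: list[PoreRecord],
    bin_width: float = 15.0,
    lo: float = 5.0,
    hi: float = 305.0,
) -> PoreSizeDistribution:
    """Bin pore areas into [lo, lo+w), ..., [hi-w, hi] (last bin closed)."""
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ConfigurationError("(hi - lo) must be an integer multiple of bin_width")
    edges = lo + bin_width * np.arange(int(round(n_bins)) + 1)
    areas = np.array([r.area_nm2 for r in records], dtype=float)
    counts, _ = np.histogram(areas, bins=edges)
    total = counts.sum()
    freqs = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return PoreSizeDistribution(edges, counts, freqs)


def porosity_estimate(
    records: list[PoreRecord],
    sample_area_nm2: float,
) -> PorositySummary:
    """Areal porosity ``phi = <A_p> * N_p / A_s`` (zero when no pores)."""
    if sample_area_nm2 <= 0:
        raise DomainError("sample area must be positive")
    n = len(records)
    total = float(sum(r.area_nm2 for r in records))
    mean_area = total / n if n else 0.0
    return PorositySummary(mean_area, n, sample_area_nm2, total / sample_area_nm2)


@dataclass
class DistributionComparison:
    """Per-bin frequency differences (b − a) and the unique sign crossover."""

    bin_edges: np.ndarray
    differences: np.ndarray
    crossover_nm2: float | None  # edge where the sign of the difference flips


def compare_distributions(
    dist_a: PoreSizeDistribution,
    dist_b: PoreSizeDistribution,
) -> DistributionComparison:
    """Contrast two pore-size distributions on identical binning.

    Reports ``freq_b - freq_a`` per bin and, when the sign pattern of the
    nonzero differences flips exactly once along the area axis, the bin edge
    at which it flips (e.g. the ~70 nm² boundary separating a small-pore-rich
    from a large-pore-rich genotype).
    """
    if dist_a.bin_edges.shape != dist_b.bin_edges.shape or not np.allclose(
        dist_a.bin_edges, dist_b.bin_edges
    ):
        raise ConfigurationError("distributions must share identical binning")
    diff = dist_b.frequencies - dist_a.frequencies
    signs = np.sign(diff)
    nz = np.nonzero(signs)[0]
    crossover = None
    if nz.size:
        flips = [
            (nz[k], nz[k + 1])
            for k in range(nz.size - 1)
            if signs[nz[k]] != signs[nz[k + 1]]
        ]
        if len(flips) == 1:
            # edge between the last bin of one sign and the first of the other
            crossover = float(dist_a.bin_edges[flips[0][0] + 1])
    return DistributionComparison(dist_a.bin_edges.copy(), diff, crossover)


def analyze_image(
    image: CalibratedImage,
    threshold_method: str = "otsu",
    manual_level: float | None = None,
    dark_pores: bool = True,
    erode_iters: int = 1,
    dilate_iters: int = 1,
    min_nm2: float = 5.0,
    max_nm2: float = 300.0,
    connectivity: int = 2,
) -> tuple[list[PoreRecord], PoreSizeDistribution, PorositySummary]:
    """Threshold → morphology → label → filter → histogram → porosity."""
    mask = threshold_pores(image, threshold_method, manual_level, dark_pores)
    mask = morph_filter(mask, erode_iters, dilate_iters)
    records = filter_pores(label_pores(mask, image, connectivity), min_nm2, max_nm2)
    dist = size_histogram(records)
    summary = porosity_estimate(records, image.sample_area_nm2)
    return records, dist, summary
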