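"""Nuclei segmentation and per-cell Voronoi tessellation.

The nuclei channel is turned into labelled nuclei by the fixed pipeline
Gaussian blur -> threshold -> binarise -> fill holes -> distance-transform
watershed -> small-object removal, and the full image is then partitioned
into one Voronoi region per nucleus *component* (each pixel goes to the
nucleus whose nearest pixel is closest in Euclidean distance, ties broken
toward the smaller label). Regions cutting the image border and regions
whose GFP-foreground coverage is too low are excluded before any aggregate
calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .errors import SegmentationError
from .images import ChannelImage

__all__ = [
    "SegmentationParams",
    "LabelMap",
    "CellRegionSet",
    "segment_nuclei",
    "voronoi_regions",
    "exclude_background_and_edge",
]

# 8-connectivity for component labelling (design: components 8-conn,
# watershed ridges 4-conn)
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation stage.

    ``min_contrast`` guards Otsu thresholding on signal-free channels: if the
    foreground/background mean-intensity separation after blurring falls
    below it, the channel is treated as empty instead of thresholding noise.
    """

    nuclei_blur_sigma: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5
    min_nucleus_area: int = 30
    background_coverage_min: float = 0.2
    gfp_foreground_method: str = "otsu"  # "otsu" | "fixed"
    gfp_fixed_threshold: float = 0.1
    min_contrast: float = 0.02

    def __post_init__(self):
        if self.nuclei_blur_sigma < 0:
            raise ValueError("nuclei_blur_sigma must be >= 0")
        if not (0.0 <= self.background_coverage_min <= 1.0):
            raise ValueError("background_coverage_min must lie in [0, 1]")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.gfp_foreground_method not in ("otsu", "fixed"):
            raise ValueError("gfp_foreground_method must be 'otsu' or 'fixed'")
        if self.min_nucleus_area < 1:
            raise ValueError("min_nucleus_area must be >= 1")


@dataclass
class LabelMap:
    """Integer label image; 0 is background, labels run 1..n_labels."""

    labels: np.ndarray
    n_labels: int

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMap":
        relab, _, _ = relabel_sequential(labels)
        return cls(labels=relab.astype(np.int32), n_labels=int(relab.max()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CellRegionSet:
    """Voronoi partition of a field with per-region exclusion flags.

    ``analyzable``, ``excluded_edge`` and ``excluded_background`` are
    disjoint and together cover all region labels; edge exclusion takes
    precedence over background exclusion.
    """

    region_labels: LabelMap
    excluded_edge: set[int]
    excluded_background: set[int]
    analyzable: set[int]
    nucleus_of_region: dict[int, int]

    @property
    def n_regions(self) -> int:
        return self.region_labels.n_labels


def _threshold(img: np.ndarray, method: str, fixed: float, min_contrast: float) -> np.ndarray:
    """Binary foreground mask with an empty-channel guard for Otsu."""
    if method == "fixed":
        return img > fixed
    if img.max() - img.min() < 1e-9:
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    fg = img > t
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=bool)
    if img[fg].mean() - img[~fg].mean() < min_contrast:
        return np.zeros(img.shape, dtype=bool)
    return fg


def _gfp_foreground(blurred: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """GFP foreground (cell-covered) mask for background removal.

    Automatic mode uses the *lowest* threshold of a 3-class Otsu: the GFP
    channel has up to three intensity populations (background, dim filament
    texture, bright puncta), and a plain 2-class Otsu can land between
    filaments and puncta, wrongly flagging whole cells as background. The
    lowest 3-class cut separates background from cell interiors regardless
    of how many puncta are present; images with fewer than three intensity
    populations fall back to the 2-class threshold.
    """
    if params.gfp_foreground_method == "fixed":
        return blurred > params.gfp_fixed_threshold
    if blurred.max() - blurred.min() < 1e-9:
        return np.zeros(blurred.shape, dtype=bool)
    try:
        t = float(threshold_multiotsu(blurred, classes=3)[0])
    except ValueError:
        t = float(threshold_otsu(blurred))
    fg = blurred > t
    if not fg.any() or fg.all():
        return np.zeros(blurred.shape, dtype=bool)
    if blurred[fg].mean() - blurred[~fg].mean() < params.min_contrast:
        return np.zeros(blurred.shape, dtype=bool)
    return fg


def segment_nuclei(nuclei: ChannelImage, params: SegmentationParams) -> LabelMap:
    """Segment nuclei from the nuclei channel.

    Pipeline (fixed order): Gaussian blur, threshold (Otsu or fixed),
    binarise, fill holes, distance-transform watershed to split touching
    nuclei, drop components below ``min_nucleus_area``, relabel 1..n.
    A blank channel yields a valid empty map (``n_labels = 0``).
    """
    img = ndi.gaussian_filter(nuclei.pixels, sigma=params.nuclei_blur_sigma, mode="reflect")
    binary = _threshold(img, params.threshold_method, params.fixed_threshold, params.min_contrast)
    if not binary.any():
        return LabelMap(np.zeros(nuclei.shape, dtype=np.int32), 0)
    binary = ndi.binary_fill_holes(binary)

    distance = ndi.distance_transform_edt(binary)
    smoothed = ndi.gaussian_filter(distance, sigma=1.0, mode="reflect")
    min_dist = max(3, int(round(math.sqrt(params.min_nucleus_area / math.pi))))
    coords = peak_local_max(smoothed, min_distance=min_dist, labels=ndi.label(binary, _STRUCT8)[0])
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return LabelMap(np.zeros(nuclei.shape, dtype=np.int32), 0)
    labels = watershed(-smoothed, markers, mask=binary, connectivity=1)

    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < params.min_nucleus_area)
    labels[np.isin(labels, small[small > 0])] = 0
    return LabelMap.from_labels(labels)


def voronoi_regions(nuclei_labels: LabelMap) -> LabelMap:
    """Assign every pixel to the nearest nucleus *component*.

    Nearest means minimal Euclidean distance to any pixel of the component
    (distance 0 inside it); exact ties go to the smaller label. Computed as
    one distance transform per label with strictly-less updates in ascending
    label order, which realises the tie-break exactly.
    """
    if nuclei_labels.n_labels == 0:
        raise SegmentationError("no cells segmented: cannot build Voronoi regions")
    labels = nuclei_labels.labels
    h, w = labels.shape
    if nuclei_labels.n_labels == 1:
        return LabelMap(np.ones_like(labels), 1)

    # Any pixel's winning label lies within D_max (the largest distance from
    # any pixel to its nearest nucleus) of that label's bounding box, so each
    # per-label distance transform can be computed on a padded crop without
    # changing the result; ties at equal distance still resolve to the
    # smaller label via the strictly-less update in ascending label order.
    d_global = ndi.distance_transform_edt(labels == 0)
    pad = int(math.ceil(float(d_global.max()))) + 2
    best = np.full(labels.shape, np.inf)
    out = np.zeros(labels.shape, dtype=np.int32)
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        r0 = max(0, sl[0].start - pad)
        r1 = min(h, sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(w, sl[1].stop + pad)
        win = (slice(r0, r1), slice(c0, c1))
        d = ndi.distance_transform_edt(labels[win] != k)
        upd = d < best[win]
        out[win][upd] = k
        best[win][upd] = d[upd]
    return LabelMap(out, nuclei_labels.n_labels)


def exclude_background_and_edge(
    voronoi: LabelMap,
    gfp: ChannelImage,
    params: SegmentationParams,
    nuclei_labels: LabelMap,
) -> CellRegionSet:
    """Flag edge-cutting and background-dominated Voronoi regions.

    A region touching any border pixel is ``excluded_edge``; otherwise, if
    the fraction of its pixels inside the GFP foreground mask (threshold on
    the blurred GFP channel) is below ``background_coverage_min`` it is
    ``excluded_background``. Edge exclusion is evaluated first so the three
    sets stay disjoint.
    """
    if voronoi.shape != gfp.shape:
        raise SegmentationError("voronoi map and gfp channel shapes differ")
    labels = voronoi.labels
    n = voronoi.n_labels

    blurred = ndi.gaussian_filter(gfp.pixels, sigma=params.nuclei_blur_sigma, mode="reflect")
    fg = _gfp_foreground(blurred, params)

    border = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    edge = set(int(x) for x in np.unique(border) if x > 0)

    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    fg_counts = np.bincount(labels.ravel(), weights=fg.ravel().astype(float), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = np.where(counts > 0, fg_counts / counts, 0.0)

    background = {
        k
        for k in range(1, n + 1)
        if k not in edge and coverage[k] < params.background_coverage_min
    }
    analyzable = set(range(1, n + 1)) - edge - background
    return CellRegionSet(
        region_labels=voronoi,
        excluded_edge=edge,
        excluded_background=background,
        analyzable=analyzable,
        nucleus_of_region={k: k for k in range(1, n + 1)},
    )
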