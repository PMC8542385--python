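"""Deterministic synthetic fluorescence imagery with exact ground truth.

Three generators emulate the assay inputs:

* :func:`generate_reporter_field` — a two-channel field ("nuclei" + "gfp") of
  subconfluent GFP–keratin reporter keratinocytes. The GFP channel carries a
  dim band-pass "filament" texture inside each cell footprint plus bright
  circular puncta (keratin aggregates) in a controllable fraction of cells,
  biased toward the cell periphery.
* :func:`generate_fragment_dish` — a bright culture-dish disk containing
  detached monolayer fragments of exactly requested pixel areas, for the
  dispase dissociation assay.
* :func:`generate_viability_field` — a three-channel LIVE/DEAD field
  ("hoechst" all nuclei, "ethd1" dead nuclei co-located with their Hoechst
  blobs, "calcein" live-cell cytoplasm).

All generators are pure functions of their configuration: identical
(config, seed) gives bit-identical images and scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import GenerationError
from .images import ChannelImage, MultiChannelImage

__all__ = [
    "GenerationConfig",
    "SyntheticScene",
    "generate_reporter_field",
    "generate_fragment_dish",
    "generate_viability_field",
    "degrade_focus",
    "match_nuclei_to_scene",
]


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the reporter-field generator.

    Defaults describe one 384×384 px field of a subconfluent reporter
    culture, roughly 80 cells per field, with 75% of cells carrying
    aggregates — the untreated mutant regime in which 70–80% of cells are
    aggregate-positive. Aggregates are rendered as small Gaussian puncta much
    brighter than the filament texture; ``peripheral_bias`` is the
    probability that a punctum is placed in the outer half of the cell
    radius.
    """

    image_height: int = 384
    image_width: int = 384
    n_cells: int = 80
    aggregate_fraction: float = 0.75
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 1.0
    cell_radius_mean: float = 24.0
    aggregates_per_positive_cell: int = 3
    aggregate_radius: float = 2.0
    aggregate_peak_intensity: float = 0.85
    filament_texture_intensity: float = 0.12
    background_level: float = 0.06
    noise_sd: float = 0.01
    peripheral_bias: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.aggregate_fraction <= 1.0):
            raise ValueError("aggregate_fraction must lie in [0, 1]")
        if not (0.0 <= self.peripheral_bias <= 1.0):
            raise ValueError("peripheral_bias must lie in [0, 1]")
        if not (
            self.aggregate_peak_intensity
            > self.filament_texture_intensity
            > self.background_level
        ):
            raise ValueError(
                "require aggregate_peak_intensity > filament_texture_intensity "
                "> background_level"
            )
        for name in ("nucleus_radius_mean", "cell_radius_mean", "aggregate_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.aggregates_per_positive_cell < 1:
            raise ValueError("aggregates_per_positive_cell must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """Exact ground truth for one generated field.

    ``nucleus_label_map`` and ``cell_footprints`` use 0 for background and
    labels 1..n for cells; ``aggregate_coords`` lists
    ``(cell_label, (row, col), radius)`` for every planted punctum.
    """

    nucleus_centres: list[tuple[float, float]]
    nucleus_label_map: np.ndarray
    cell_footprints: np.ndarray
    positive_cells: set[int]
    aggregate_coords: list[tuple[int, tuple[int, int], float]]
    dead_cells: set[int] = field(default_factory=set)
    n_positive_requested: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_centres)

    def to_json_dict(self) -> dict:
        """Compact ground-truth record (no label maps) for sidecar files."""
        return {
            "nucleus_centres": [list(map(float, c)) for c in self.nucleus_centres],
            "positive_cells": sorted(self.positive_cells),
            "aggregate_coords": [
                [int(lab), [int(r), int(c)], float(rad)]
                for lab, (r, c), rad in self.aggregate_coords
            ],
            "dead_cells": sorted(self.dead_cells),
            "n_positive_requested": int(self.n_positive_requested),
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _place_centres(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    min_spacing: float,
    margin: float,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centres at pairwise distance >= min_spacing."""
    if 2 * margin >= min(height, width):
        raise GenerationError("image too small for the requested margin")
    centres: list[tuple[float, float]] = []
    max_tries = 4000 * n
    tries = 0
    sq = min_spacing * min_spacing
    while len(centres) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} nuclei with spacing {min_spacing:.1f}px in a "
                f"{height}x{width} image after {max_tries} tries; "
                "the requested cell density exceeds the placement limit"
            )
        r = rng.uniform(margin, height - 1 - margin)
        c = rng.uniform(margin, width - 1 - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= sq for rr, cc in centres):
            centres.append((r, c))
    return centres


def _disk_label_map(
    shape: tuple[int, int],
    centres: Sequence[tuple[float, float]],
    radii: Sequence[float],
) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for i, ((r, c), rad) in enumerate(zip(centres, radii), start=1):
        r0, r1 = int(max(0, r - rad - 1)), int(min(shape[0], r + rad + 2))
        c0, c1 = int(max(0, c - rad - 1)), int(min(shape[1], c + rad + 2))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= rad * rad
        labels[r0:r1, c0:c1][mask] = i
    return labels


def _voronoi_of_centres(
    shape: tuple[int, int], centres: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Per-pixel index (1-based) of the nearest centre (ground truth only)."""
    from scipy.spatial import cKDTree

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    _, idx = cKDTree(np.asarray(centres)).query(pts)
    return (idx.reshape(shape) + 1).astype(np.int32)


def _bandpass_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Oriented band-pass noise in [-1, 1] standing in for filament texture."""
    noise = rng.standard_normal(shape)
    low = ndi.gaussian_filter(noise, sigma=(1.0, 3.0), mode="reflect")
    band = low - ndi.gaussian_filter(noise, sigma=6.0, mode="reflect")
    peak = np.max(np.abs(band))
    if peak > 0:
        band = band / peak
    return band


def _add_gaussian_blob(
    img: np.ndarray, centre: tuple[float, float], sigma: float, amplitude: float
) -> None:
    """Add amplitude * exp(-d^2 / 2 sigma^2) in place, on a local window."""
    h, w = img.shape
    r, c = centre
    ext = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(r) - ext), min(h, int(r) + ext + 1)
    c0, c1 = max(0, int(c) - ext), min(w, int(c) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma * sigma)
    )


def _sample_aggregate_sites(
    rng: np.random.Generator,
    cfg: GenerationConfig,
    label: int,
    centre: tuple[float, float],
    footprints: np.ndarray,
    taken: list[tuple[int, int]],
    min_sep: float,
) -> list[tuple[int, int]]:
    """Pick punctum centres inside the cell footprint, peripherally biased.

    Sites are drawn uniformly from the eligible footprint pixels: with
    probability ``peripheral_bias`` the radial annulus [0.5, 0.95] of the
    cell radius (so ``peripheral_bias = 1`` puts every punctum in the outer
    half), otherwise [0.25, 0.95]. Sites keep ``min_sep`` from all previously
    placed puncta so planted puncta stay resolvable as separate connected
    components; in footprints too cramped for the full punctum count the
    cell receives fewer puncta (never zero — that raises instead).
    """
    pix = np.argwhere(footprints == label)
    if pix.size == 0:
        raise GenerationError(f"cell {label} has an empty footprint")
    rf = np.hypot(pix[:, 0] - centre[0], pix[:, 1] - centre[1]) / cfg.cell_radius_mean
    sites: list[tuple[int, int]] = []

    def _pool(lo: float, sep: float) -> np.ndarray:
        ok = (rf >= lo) & (rf <= 0.95)
        for tr, tc in taken + sites:
            ok &= (pix[:, 0] - tr) ** 2 + (pix[:, 1] - tc) ** 2 >= sep * sep
        return pix[ok]

    for j in range(cfg.aggregates_per_positive_cell):
        peripheral = rng.random() < cfg.peripheral_bias
        lo = 0.5 if peripheral else 0.25
        pool = _pool(lo, min_sep)
        if pool.size == 0:
            # cramped footprint: relax separation toward the resolvability
            # floor (half-maximum radius of the bump is ~1.18 sigma)
            pool = _pool(lo, 2 * cfg.aggregate_radius + 2)
        if pool.size == 0:
            if j > 0:
                break
            raise GenerationError(
                f"could not place an aggregate inside cell {label}; "
                "footprint too small for the requested punctum spacing"
            )
        r, c = pool[int(rng.integers(pool.shape[0]))]
        sites.append((int(r), int(c)))
    return sites


def generate_reporter_field(
    config: GenerationConfig,
) -> tuple[MultiChannelImage, SyntheticScene]:
    """Generate one two-channel reporter field with ground truth.

    Returns a :class:`MultiChannelImage` with channels ``"nuclei"`` and
    ``"gfp"`` plus a :class:`SyntheticScene`. The number of aggregate-positive
    cells is ``round-half-up(aggregate_fraction * n_cells)`` and is recorded
    in the scene.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height, cfg.image_width
    shape = (h, w)

    min_spacing = 2 * cfg.nucleus_radius_mean + 8
    margin = cfg.nucleus_radius_mean + 4
    centres = _place_centres(rng, cfg.n_cells, h, w, min_spacing, margin)

    lo = max(2.0, cfg.nucleus_radius_mean - 2.5 * cfg.nucleus_radius_sd)
    hi = cfg.nucleus_radius_mean + 2.5 * cfg.nucleus_radius_sd
    radii = np.clip(
        rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd, cfg.n_cells), lo, hi
    )
    nucleus_labels = _disk_label_map(shape, centres, radii)

    vor = _voronoi_of_centres(shape, centres)
    rr, cc = np.mgrid[0:h, 0:w]
    footprints = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(centres, start=1):
        inside = (vor == i) & (
            (rr - r) ** 2 + (cc - c) ** 2 <= cfg.cell_radius_mean**2
        )
        footprints[inside] = i

    n_pos = _round_half_up(cfg.aggregate_fraction * cfg.n_cells)
    order = rng.permutation(cfg.n_cells) + 1
    positive = set(int(x) for x in order[:n_pos])

    # keep puncta separable: half-max radius of the Gaussian bump is ~1.18 sigma
    min_sep = 4 * cfg.aggregate_radius + 3
    aggregate_coords: list[tuple[int, tuple[int, int], float]] = []
    taken: list[tuple[int, int]] = []
    for lab in sorted(positive):
        sites = _sample_aggregate_sites(
            rng, cfg, lab, centres[lab - 1], footprints, taken, min_sep
        )
        for s in sites:
            aggregate_coords.append((lab, s, cfg.aggregate_radius))
            taken.append(s)

    # --- nuclei channel: soft disks + noise
    nuclei = np.full(shape, 0.04)
    hard = np.where(nucleus_labels > 0, 0.8, 0.0)
    nuclei += ndi.gaussian_filter(hard, sigma=1.2, mode="reflect")
    nuclei += rng.normal(0.0, cfg.noise_sd, shape)
    nuclei = np.clip(nuclei, 0.0, 1.0)

    # --- gfp channel: background + filament texture in footprints + puncta
    gfp = np.full(shape, cfg.background_level)
    texture = _bandpass_texture(rng, shape)
    fill = cfg.filament_texture_intensity * (0.7 + 0.3 * texture)
    gfp += np.where(footprints > 0, fill, 0.0)
    amp = cfg.aggregate_peak_intensity - cfg.background_level
    for _lab, (r, c), rad in aggregate_coords:
        _add_gaussian_blob(gfp, (float(r), float(c)), rad, amp)
    gfp += rng.normal(0.0, cfg.noise_sd, shape)
    gfp = np.clip(gfp, 0.0, 1.0)

    image = MultiChannelImage(
        {
            "nuclei": ChannelImage(nuclei, name="nuclei"),
            "gfp": ChannelImage(gfp, name="gfp"),
        },
        provenance={"generator": "reporter_field", "config": cfg.__dict__.copy()},
    )
    scene = SyntheticScene(
        nucleus_centres=centres,
        nucleus_label_map=nucleus_labels,
        cell_footprints=footprints,
        positive_cells=positive,
        aggregate_coords=aggregate_coords,
        n_positive_requested=n_pos,
    )
    return image, scene


# ---------------------------------------------------------------------------
# fragment dish


def _grow_fragment(rng: np.random.Generator, area: int) -> np.ndarray:
    """Grow a connected blob of exactly ``area`` pixels (Eden-model growth)."""
    side = int(3 * math.sqrt(area)) + 5
    grid = np.zeros((side, side), dtype=bool)
    mid = side // 2
    grid[mid, mid] = True
    frontier = {(mid + dr, mid + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))}
    count = 1
    while count < area:
        idx = rng.integers(len(frontier))
        pick = sorted(frontier)[idx]
        frontier.discard(pick)
        r, c = pick
        if grid[r, c]:
            continue
        grid[r, c] = True
        count += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 < nr < side - 1 and 0 < nc < side - 1 and not grid[nr, nc]:
                frontier.add((nr, nc))
    rows = np.any(grid, axis=1)
    cols = np.any(grid, axis=0)
    return grid[rows][:, cols]


def generate_fragment_dish(
    areas: Sequence[int],
    dish_radius: float = 220.0,
    seed: int = 0,
) -> tuple[ChannelImage, np.ndarray]:
    """Generate a dish image with fragments of exactly the requested areas.

    Returns the image and a ground-truth label map in which fragment ``i``
    (1-based, in input order) occupies exactly ``areas[i-1]`` pixels.
    Fragments are mutually separated by at least 2 px and lie fully inside
    the dish disk.
    """
    rng = np.random.default_rng(seed)
    pad = 24
    side = int(2 * (dish_radius + pad))
    shape = (side, side)
    centre = (side - 1) / 2.0
    rr, cc = np.mgrid[0:side, 0:side]
    dish_mask = (rr - centre) ** 2 + (cc - centre) ** 2 <= dish_radius**2

    dish_area = int(dish_mask.sum())
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    order = sorted(range(len(areas)), key=lambda i: -areas[i])
    for i in order:
        area = int(areas[i])
        if area < 1:
            raise GenerationError("fragment areas must be >= 1 pixel")
        if area > 0.5 * dish_area:
            raise GenerationError(
                f"fragment of {area}px does not fit in a dish of {dish_area}px"
            )
        blob = _grow_fragment(rng, area)
        bh, bw = blob.shape
        placed = False
        for _try in range(2000):
            r0 = int(rng.integers(0, side - bh))
            c0 = int(rng.integers(0, side - bw))
            window_dish = dish_mask[r0 : r0 + bh, c0 : c0 + bw]
            if not np.all(window_dish[blob]):
                continue
            # demand 2-px clearance around the blob against prior fragments
            r0c, r1c = max(0, r0 - 2), min(side, r0 + bh + 2)
            c0c, c1c = max(0, c0 - 2), min(side, c0 + bw + 2)
            if occupied[r0c:r1c, c0c:c1c].any():
                grown = np.zeros((r1c - r0c, c1c - c0c), dtype=bool)
                grown[r0 - r0c : r0 - r0c + bh, c0 - c0c : c0 - c0c + bw] = blob
                grown = ndi.binary_dilation(grown, iterations=2)
                if (grown & occupied[r0c:r1c, c0c:c1c]).any():
                    continue
            labels[r0 : r0 + bh, c0 : c0 + bw][blob] = i + 1
            occupied[r0 : r0 + bh, c0 : c0 + bw] |= blob
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place fragment of {area}px inside the dish without contact"
            )

    img = np.full(shape, 0.05)
    img[dish_mask] = 0.35
    img[labels > 0] = 0.9
    img += rng.normal(0.0, 0.01, shape)
    img = np.clip(img, 0.0, 1.0)
    return ChannelImage(img, name="dish"), labels


# ---------------------------------------------------------------------------
# viability field


def generate_viability_field(
    n_cells: int,
    n_dead: int,
    seed: int = 0,
) -> tuple[MultiChannelImage, SyntheticScene]:
    """Generate a three-channel LIVE/DEAD field.

    Channels: ``"hoechst"`` (all nuclei), ``"ethd1"`` (dead nuclei,
    co-located with their Hoechst blobs), ``"calcein"`` (live-cell
    cytoplasm). ``scene.dead_cells`` has exactly ``n_dead`` labels.
    """
    if n_dead > n_cells:
        raise GenerationError(f"n_dead ({n_dead}) exceeds n_cells ({n_cells})")
    rng = np.random.default_rng(seed)
    side = max(192, int(math.ceil(math.sqrt(max(n_cells, 1) * 950))))
    shape = (side, side)
    nucleus_r = 5.5
    cyto_r = 13.0

    centres = _place_centres(rng, n_cells, side, side, 2 * nucleus_r + 8, nucleus_r + 4)
    radii = [nucleus_r] * n_cells
    nucleus_labels = _disk_label_map(shape, centres, radii)
    dead = set(int(x) for x in (rng.permutation(n_cells) + 1)[:n_dead])

    vor = _voronoi_of_centres(shape, centres) if n_cells else np.zeros(shape, np.int32)
    rr, cc = np.mgrid[0:side, 0:side]
    footprints = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(centres, start=1):
        inside = (vor == i) & ((rr - r) ** 2 + (cc - c) ** 2 <= cyto_r**2)
        footprints[inside] = i

    def _render_nuclei(label_set: set[int] | None) -> np.ndarray:
        img = np.full(shape, 0.04)
        if label_set is None:
            mask = nucleus_labels > 0
        else:
            mask = np.isin(nucleus_labels, sorted(label_set)) if label_set else np.zeros(shape, bool)
        img += ndi.gaussian_filter(np.where(mask, 0.8, 0.0), sigma=1.2, mode="reflect")
        img += rng.normal(0.0, 0.01, shape)
        return np.clip(img, 0.0, 1.0)

    hoechst = _render_nuclei(None)
    ethd1 = _render_nuclei(dead)
    live = set(range(1, n_cells + 1)) - dead
    calcein = np.full(shape, 0.04)
    if live:
        body = np.isin(footprints, sorted(live))
        calcein += ndi.gaussian_filter(np.where(body, 0.55, 0.0), sigma=2.0, mode="reflect")
    calcein += rng.normal(0.0, 0.01, shape)
    calcein = np.clip(calcein, 0.0, 1.0)

    image = MultiChannelImage(
        {
            "hoechst": ChannelImage(hoechst, name="hoechst"),
            "ethd1": ChannelImage(ethd1, name="ethd1"),
            "calcein": ChannelImage(calcein, name="calcein"),
        },
        provenance={"generator": "viability_field", "n_cells": n_cells, "n_dead": n_dead},
    )
    scene = SyntheticScene(
        nucleus_centres=centres,
        nucleus_label_map=nucleus_labels,
        cell_footprints=footprints,
        positive_cells=set(),
        aggregate_coords=[],
        dead_cells=dead,
    )
    return image, scene


def degrade_focus(image: ChannelImage, sigma: float) -> ChannelImage:
    """Gaussian-defocus a channel; ``sigma = 0`` returns an identical copy."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ChannelImage(image.pixels.copy(), name=image.name, pixel_size=image.pixel_size)
    blurred = ndi.gaussian_filter(image.pixels, sigma=sigma, mode="reflect")
    return ChannelImage(blurred, name=image.name, pixel_size=image.pixel_size)


def match_nuclei_to_scene(
    nucleus_labels: np.ndarray,
    scene: SyntheticScene,
    max_dist: float = 10.0,
) -> dict[int, int]:
    """Map segmented nucleus labels to ground-truth cell labels.

    Each segmented label is matched to the nearest scene nucleus centre
    within ``max_dist`` px of its centroid; unmatched labels are omitted.
    Used to score per-cell calls against planted ground truth.
    """
    out: dict[int, int] = {}
    if nucleus_labels.max() == 0 or not scene.nucleus_centres:
        return out
    centroids = ndi.center_of_mass(
        np.ones_like(nucleus_labels),
        nucleus_labels,
        index=range(1, int(nucleus_labels.max()) + 1),
    )
    truth = np.asarray(scene.nucleus_centres)
    for lab, (r, c) in enumerate(centroids, start=1):
        d = np.hypot(truth[:, 0] - r, truth[:, 1] - c)
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            out[lab] = j + 1
    return out
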