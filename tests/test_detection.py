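"""DoG enhancement, per-region calling, percent positive, full pipeline."""

import dataclasses
import math

import numpy as np
import pytest

from aggscreen import (
    AggregateParams,
    ChannelImage,
    DetectionError,
    MultiChannelImage,
    SegmentationParams,
    analyze_field,
    call_regions,
    enhance_puncta,
    percent_positive,
)
from aggscreen.detection import resolve_intensity_threshold
from aggscreen.segmentation import CellRegionSet, LabelMap
from aggscreen.synthetic import degrade_focus
from conftest import SMALL
from aggscreen import generate_reporter_field
from oracle_utils import brute_call_regions


def test_enhance_constant_image_gives_zero_response():
    const = ChannelImage(np.full((48, 48), 0.4), "gfp")
    resp = enhance_puncta(const, AggregateParams())
    assert np.max(np.abs(resp)) < 1e-12


def test_enhance_single_bright_pixel_peaks_there_and_matches_convolution():
    px = np.zeros((21, 21))
    px[10, 10] = 1.0
    resp = enhance_puncta(ChannelImage(px, "gfp"), AggregateParams())
    assert np.unravel_index(np.argmax(resp), resp.shape) == (10, 10)

    # direct convolution oracle with the same truncated Gaussian kernels
    def kern(sigma):
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        return k / k.sum()

    def blur(img, sigma):
        k = kern(sigma)
        pad = len(k) // 2
        out = np.empty_like(img)
        # scipy's "reflect" boundary duplicates the edge sample (numpy "symmetric")
        tmp = np.pad(img, ((0, 0), (pad, pad)), mode="symmetric")
        for r in range(img.shape[0]):
            out[r] = np.convolve(tmp[r], k, mode="valid")
        tmp = np.pad(out, ((pad, pad), (0, 0)), mode="symmetric")
        out2 = np.empty_like(img)
        for c in range(img.shape[1]):
            out2[:, c] = np.convolve(tmp[:, c], k, mode="valid")
        return out2

    p = AggregateParams()
    oracle = blur(px, p.dog_sigma_small) - blur(px, p.dog_sigma_large)
    assert np.max(np.abs(resp - oracle)) < 1e-12


def test_punctum_scale_preferred_over_broad_blob():
    """A punctum of roughly sigma_small size out-responds a much broader blob
    of the same peak intensity."""
    rr, cc = np.mgrid[0:64, 0:64]

    def blob(centre, sigma):
        return np.exp(-(((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2) / (2 * sigma**2)))

    p = AggregateParams()
    narrow = 0.8 * blob((32, 32), p.dog_sigma_small)
    broad = 0.8 * blob((32, 32), 4 * p.dog_sigma_large)
    r_narrow = enhance_puncta(ChannelImage(narrow, "gfp"), p).max()
    r_broad = enhance_puncta(ChannelImage(broad, "gfp"), p).max()
    assert r_narrow > r_broad


def test_sigma_order_validated():
    with pytest.raises(ValueError):
        AggregateParams(dog_sigma_small=4.0, dog_sigma_large=2.0)


# -------------------------------------------------------------- call_regions


def _toy_regions(shape=(40, 40)):
    """One interior analyzable region (label 5 at the centre of a 3x3 grid)."""
    labels = np.zeros(shape, np.int32)
    h, w = shape
    for i, r in enumerate((0, h // 3, 2 * h // 3)):
        for j, c in enumerate((0, w // 3, 2 * w // 3)):
            labels[r : r + h // 3 + (h % 3 if i == 2 else 0), c : c + w // 3 + (w % 3 if j == 2 else 0)] = (
                3 * i + j + 1
            )
    labels[labels == 0] = 9
    lm = LabelMap(labels, 9)
    return CellRegionSet(
        region_labels=lm,
        excluded_edge=set(range(1, 10)) - {5},
        excluded_background=set(),
        analyzable={5},
        nucleus_of_region={k: k for k in range(1, 10)},
    )


def test_region_below_threshold_is_negative():
    regions = _toy_regions()
    resp = np.zeros((40, 40))
    calls = call_regions(resp, regions, AggregateParams(intensity_min=0.1))
    assert len(calls) == 1
    assert not calls[0].has_aggregates
    assert calls[0].n_puncta == 0


def test_planted_punctum_is_called():
    regions = _toy_regions()
    resp = np.zeros((40, 40))
    resp[18:21, 18:21] = 0.5  # 9-px component inside region 5
    calls = call_regions(resp, regions, AggregateParams(intensity_min=0.1))
    assert calls[0].has_aggregates and calls[0].n_puncta == 1
    assert calls[0].punctum_areas == [9]
    assert calls[0].peak_response == 0.5


def test_area_window_boundaries_inclusive():
    regions = _toy_regions()
    p = AggregateParams(intensity_min=0.1, punctum_area_min=9, punctum_area_max=9)
    resp = np.zeros((40, 40))
    resp[18:21, 18:21] = 0.5  # area exactly punctum_area_min -> kept
    assert call_regions(resp, regions, p)[0].n_puncta == 1
    resp = np.zeros((40, 40))
    resp[18:21, 18:20] = 0.5
    resp[18:20, 20] = 0.5  # area 8 = min-1 -> rejected
    assert call_regions(resp, regions, p)[0].n_puncta == 0
    p10 = AggregateParams(intensity_min=0.1, punctum_area_min=2, punctum_area_max=8)
    resp = np.zeros((40, 40))
    resp[18:21, 18:21] = 0.5  # area 9 = max+1 -> rejected
    assert call_regions(resp, regions, p10)[0].n_puncta == 0


def test_no_analyzable_regions_raises():
    regions = _toy_regions()
    regions.analyzable = set()
    with pytest.raises(DetectionError, match="nothing to call"):
        call_regions(np.zeros((40, 40)), regions, AggregateParams(intensity_min=0.1))


def test_call_regions_matches_brute_force_oracle(small_field):
    from aggscreen import exclude_background_and_edge, segment_nuclei, voronoi_regions

    img, _ = small_field
    seg = SegmentationParams()
    lm = segment_nuclei(img["nuclei"], seg)
    vor = voronoi_regions(lm)
    regions = exclude_background_and_edge(vor, img["gfp"], seg, lm)
    p = AggregateParams()
    resp = enhance_puncta(img["gfp"], p)
    thr = resolve_intensity_threshold(resp, p)
    calls = call_regions(resp, regions, p)
    oracle = brute_call_regions(
        resp, vor.labels, regions.analyzable, thr, p.punctum_area_min, p.punctum_area_max
    )
    assert {c.region_label: c.n_puncta for c in calls} == oracle


def test_monotone_in_intensity_and_area_thresholds(small_field):
    img, _ = small_field
    resp = enhance_puncta(img["gfp"], AggregateParams())
    from aggscreen import exclude_background_and_edge, segment_nuclei, voronoi_regions

    seg = SegmentationParams()
    lm = segment_nuclei(img["nuclei"], seg)
    regions = exclude_background_and_edge(voronoi_regions(lm), img["gfp"], seg, lm)

    def n_pos(**kw):
        p = AggregateParams(**kw)
        return sum(c.has_aggregates for c in call_regions(resp, regions, p))

    by_intensity = [n_pos(intensity_min=t) for t in (0.05, 0.1, 0.2, 0.4, 0.8)]
    assert all(a >= b for a, b in zip(by_intensity, by_intensity[1:]))
    by_area = [n_pos(intensity_min=0.1, punctum_area_min=m) for m in (1, 4, 16, 64)]
    assert all(a >= b for a, b in zip(by_area, by_area[1:]))


# ---------------------------------------------------------- percent_positive


@pytest.mark.parametrize("n_pos,n_tot,expected", [(3, 4, 75.0), (0, 10, 0.0), (7, 28, 25.0)])
def test_percent_positive_formula(n_pos, n_tot, expected):
    assert percent_positive(n_pos, n_tot) == expected


def test_percent_positive_undefined_for_zero_total():
    with pytest.raises(DetectionError):
        percent_positive(0, 0)
    with pytest.raises(ValueError):
        percent_positive(5, 4)


# ------------------------------------------------------------- analyze_field


def test_analyze_field_zero_fraction_reports_zero_percent():
    img, _ = generate_reporter_field(dataclasses.replace(SMALL, aggregate_fraction=0.0))
    res = analyze_field(img)
    assert not res.rejected
    assert res.percent_positive == 0.0
    assert res.n_positive == 0
    assert res.n_positive + res.n_negative == res.n_regions_total


def test_analyze_field_recovers_planted_fraction(default_field):
    img, _ = default_field  # 75% planted
    res = analyze_field(img)
    assert res.percent_positive == pytest.approx(75.0, abs=10.0)


def test_analyze_field_rejects_blurred_field(default_field):
    img, _ = default_field
    blurred = MultiChannelImage(
        {"nuclei": degrade_focus(img["nuclei"], 6), "gfp": degrade_focus(img["gfp"], 6)}
    )
    res = analyze_field(blurred)
    assert res.rejected
    assert res.percent_positive is None
    assert res.calls == []


def test_analyze_field_deterministic(small_field):
    img, _ = small_field
    a = analyze_field(img)
    b = analyze_field(img)
    assert a.to_dict() == b.to_dict()


def test_analyze_field_requires_channels(small_field):
    img, _ = small_field
    with pytest.raises(DetectionError, match="channel"):
        analyze_field(MultiChannelImage({"gfp": img["gfp"]}))


def test_conservation_of_region_counts(small_field):
    img, _ = small_field
    res = analyze_field(img)
    assert res.n_positive + res.n_negative == res.n_regions_total
    assert res.n_regions_total == len(res.calls)
    assert res.percent_positive == pytest.approx(
        100.0 * res.n_positive / res.n_regions_total
    )
    assert math.isfinite(res.qc.metric)
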