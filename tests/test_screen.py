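"""Well summaries, baseline normalisation, hit calling, dose response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggscreen import (
    FieldResult,
    PlateLayout,
    ScreenError,
    WellInfo,
    WellSummary,
    call_hits,
    dose_response,
    plate_heatmap,
    summarize_wells,
)
from aggscreen.images import FocusReport
from aggscreen.screen import all_well_ids
from oracle_utils import brute_spearman


def _field(percent, accepted=True):
    qc = FocusReport(metric=0.02 if accepted else 0.001, threshold=0.016, accepted=accepted)
    if not accepted:
        return FieldResult(0, 0, 0, None, [], qc)
    n = 20
    pos = round(n * percent / 100)
    return FieldResult(n, pos, n - pos, 100.0 * pos / n, [], qc)


def _layout(roles):
    return PlateLayout({w: WellInfo(role=r) for w, r in roles.items()})


def test_summary_single_field_sd_zero():
    layout = _layout({"A01": "test"})
    (s,) = summarize_wells({"A01": [_field(50.0)]}, layout)
    assert s.mean_percent_positive == 50.0
    assert s.sd_percent_positive == 0.0
    assert s.n_fields == 1


def test_summary_mean_over_fields():
    layout = _layout({"A01": "test"})
    (s,) = summarize_wells({"A01": [_field(50.0), _field(70.0)]}, layout)
    assert s.mean_percent_positive == 60.0
    assert s.sd_percent_positive == pytest.approx(np.std([50, 70], ddof=1))


def test_summary_all_rejected_flagged_and_excluded_from_baseline():
    layout = _layout({"A01": "negative_control", "B01": "negative_control", "C01": "test"})
    results = {
        "A01": [_field(0, accepted=False)],
        "B01": [_field(80.0)],
        "C01": [_field(40.0)],
    }
    summaries = summarize_wells(results, layout)
    flagged = next(s for s in summaries if s.well == "A01")
    assert flagged.all_rejected and flagged.mean_percent_positive is None
    res = call_hits(summaries, layout)
    assert res.dmso_baseline == 80.0  # only B01 contributes


def test_summary_unknown_well_errors():
    layout = _layout({"A01": "test"})
    with pytest.raises(ScreenError, match="Z99|B02"):
        summarize_wells({"B02": [_field(10.0)]}, layout)


def test_invalid_well_ids_rejected():
    with pytest.raises(ScreenError, match="invalid well"):
        _layout({"Z99": "test"})


# ----------------------------------------------------------------- call_hits


def _screen(baseline, test_means, cutoff=0.25):
    roles = {"A01": "negative_control"}
    wells = {}
    summaries = [WellSummary("A01", 2, baseline, 1.0, 0)]
    test_ids = [w for w in all_well_ids() if w != "A01"]
    for w, m in zip(test_ids, test_means):
        roles[w] = "test"
        summaries.append(WellSummary(w, 2, m, 1.0, 0))
        wells[w] = m
    return call_hits(summaries, _layout(roles), cutoff=cutoff), wells


def test_hit_boundary_inclusive_at_25_percent_reduction():
    res, wells = _screen(80.0, [60.0, 79.0, 90.0])
    w60, w79, w90 = wells  # insertion order follows the means
    assert res.dmso_baseline == 80.0
    assert res.reductions[w60] == pytest.approx(0.25)
    assert w60 in res.hits  # exactly 25% reduction is a hit ("at least")
    assert res.reductions[w79] == pytest.approx(0.0125)
    assert w79 not in res.hits
    assert res.reductions[w90] == pytest.approx(-0.125)  # aggregate increase
    assert w90 not in res.hits


def test_positive_controls_reported_but_never_hits():
    layout = _layout({"A01": "negative_control", "A12": "positive_control"})
    summaries = [WellSummary("A01", 1, 80.0, 0.0, 0), WellSummary("A12", 1, 8.0, 0.0, 0)]
    res = call_hits(summaries, layout)
    assert res.reductions["A12"] == pytest.approx(0.9)
    assert res.hits == set()


def test_zero_baseline_errors():
    layout = _layout({"A01": "negative_control", "B01": "test"})
    summaries = [WellSummary("A01", 1, 0.0, 0.0, 0), WellSummary("B01", 1, 0.0, 0.0, 0)]
    with pytest.raises(ScreenError, match="baseline"):
        call_hits(summaries, layout)


def test_no_negative_controls_errors():
    layout = _layout({"B01": "test"})
    with pytest.raises(ScreenError, match="negative-control"):
        call_hits([WellSummary("B01", 1, 50.0, 0.0, 0)], layout)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    means=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=20),
    cut1=st.floats(0.0, 1.0),
    cut2=st.floats(0.0, 1.0),
)
def test_hit_set_monotone_in_cutoff(means, cut1, cut2):
    lo, hi = sorted((cut1, cut2))
    res_lo, _ = _screen(80.0, means, cutoff=lo)
    res_hi, _ = _screen(80.0, means, cutoff=hi)
    assert res_hi.hits <= res_lo.hits
    for red in res_lo.reductions.values():
        assert red <= 1.0


def test_reductions_invariant_to_field_order():
    layout = _layout({"A01": "negative_control", "B01": "test"})
    f1, f2 = _field(30.0), _field(50.0)
    a = summarize_wells({"A01": [_field(80.0)], "B01": [f1, f2]}, layout)
    b = summarize_wells({"A01": [_field(80.0)], "B01": [f2, f1]}, layout)
    ra = call_hits(a, layout).reductions["B01"]
    rb = call_hits(b, layout).reductions["B01"]
    assert ra == rb


# ------------------------------------------------------------- dose_response


def test_dose_response_strictly_decreasing():
    s = dose_response([(1, 70.0), (3, 50.0), (10, 20.0)])
    assert s.monotone_decreasing
    assert s.trend_statistic == pytest.approx(-1.0)


def test_dose_response_flat_series_is_monotone_with_zero_trend():
    s = dose_response([(1, 50.0), (3, 50.0), (10, 50.0)])
    assert s.monotone_decreasing  # non-strict convention
    assert s.trend_statistic == 0.0


def test_dose_response_non_monotone_matches_rank_oracle():
    pts = [(1, 40.0), (3, 60.0), (10, 20.0)]
    s = dose_response(pts)
    assert not s.monotone_decreasing
    oracle = brute_spearman([p[0] for p in pts], [p[1] for p in pts])
    assert s.trend_statistic == pytest.approx(oracle)


def test_dose_response_averages_duplicates_and_requires_three_points():
    s = dose_response([(1, 60.0), (1, 40.0), (3, 30.0), (10, 10.0)])
    assert s.points[0] == (1.0, 50.0)
    with pytest.raises(ScreenError, match="3 distinct"):
        dose_response([(1, 50.0), (3, 40.0)])


# ------------------------------------------------------------- plate_heatmap


def _full_plate_result(missing=()):
    wells = {}
    summaries = []
    for w in all_well_ids():
        role = "negative_control" if w.endswith("01") else "test"
        wells[w] = WellInfo(role=role)
        if w in missing:
            continue
        summaries.append(WellSummary(w, 2, 55.0 if role == "test" else 75.0, 2.0, 0))
    layout = PlateLayout(wells)
    return call_hits(summaries, layout)


def test_plate_heatmap_full_plate_and_csv_twin(tmp_path):
    res = _full_plate_result()
    png, csv = plate_heatmap(res, str(tmp_path / "plate.png"))
    assert (tmp_path / "plate.png").exists()
    df = pd.read_csv(csv)
    assert len(df) == 96
    # CSV twin reproduces the summary table exactly
    ref = res.to_dataframe()
    assert df["well"].tolist() == ref["well"].tolist()
    assert df["role"].tolist() == ref["role"].tolist()
    assert df["hit"].astype(bool).tolist() == ref["hit"].tolist()
    for col in ("n_fields", "mean_percent_positive", "sd_percent_positive", "reduction"):
        assert np.allclose(
            df[col].astype(float), ref[col].astype(float), atol=1e-12, equal_nan=True
        )


def test_plate_heatmap_missing_well_renders_na(tmp_path):
    res = _full_plate_result(missing=("D07",))
    _, csv = plate_heatmap(res, str(tmp_path / "plate.png"))
    df = pd.read_csv(csv)
    assert len(df) == 95
    assert "D07" not in set(df["well"])
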