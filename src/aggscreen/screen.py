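"""Plate-level screen logic: well summaries, DMSO-normalised reductions,
hit calling, dose-response refinement and the colour-coded plate map.

A well is a hit when its aggregate-positive percentage is reduced, relative
to the negative-control (DMSO) baseline, by at least the cut-off fraction
(default 0.25, boundary inclusive). Positive-control wells are reported but
never enter the baseline or the hit set.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import FieldResult
from .errors import ScreenError

__all__ = [
    "ROLES",
    "WellInfo",
    "PlateLayout",
    "WellSummary",
    "ScreenResult",
    "DoseResponseSeries",
    "summarize_wells",
    "call_hits",
    "dose_response",
    "plate_heatmap",
    "all_well_ids",
]

ROLES = ("negative_control", "positive_control", "test")
_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")
_ROWS = "ABCDEFGH"


def all_well_ids() -> list[str]:
    """The 96 well ids of an 8x12 plate, row-major (A01..H12)."""
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, 13)]


@dataclass(frozen=True)
class WellInfo:
    role: str
    compound: str = ""
    concentration_uM: float = float("nan")
    replicate: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ScreenError(f"unknown well role {self.role!r}; expected one of {ROLES}")


@dataclass
class PlateLayout:
    """Mapping of 96-well ids to treatment roles and compounds."""

    wells: dict[str, WellInfo]

    def __post_init__(self):
        bad = [w for w in self.wells if not _WELL_RE.match(w)]
        if bad:
            raise ScreenError(f"invalid well ids for an 8x12 plate: {bad}")

    @classmethod
    def from_csv(cls, path: str) -> "PlateLayout":
        df = pd.read_csv(path, dtype={"well": str})
        required = {"well", "role"}
        if not required.issubset(df.columns):
            raise ScreenError(f"layout CSV needs columns {sorted(required)}, has {list(df.columns)}")
        wells = {}
        for _, row in df.iterrows():
            conc = row.get("concentration_uM", float("nan"))
            wells[row["well"]] = WellInfo(
                role=row["role"],
                compound=str(row.get("compound", "") or ""),
                concentration_uM=float(conc) if pd.notna(conc) else float("nan"),
                replicate=str(row.get("replicate", "") or ""),
            )
        return cls(wells)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            [
                {
                    "well": w,
                    "role": i.role,
                    "compound": i.compound,
                    "concentration_uM": i.concentration_uM,
                    "replicate": i.replicate,
                }
                for w, i in sorted(self.wells.items())
            ]
        ).to_csv(path, index=False)

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, i in self.wells.items() if i.role == role)


@dataclass
class WellSummary:
    """Per-well aggregation over QC-accepted fields."""

    well: str
    n_fields: int
    mean_percent_positive: float | None
    sd_percent_positive: float
    n_fields_rejected: int

    @property
    def all_rejected(self) -> bool:
        return self.n_fields == 0


@dataclass
class ScreenResult:
    """Complete outcome of one plate analysis."""

    layout: PlateLayout
    summaries: dict[str, WellSummary]
    dmso_baseline: float
    reductions: dict[str, float]
    hits: set[str]
    cutoff: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w in sorted(self.summaries):
            s = self.summaries[w]
            info = self.layout.wells[w]
            rows.append(
                {
                    "well": w,
                    "role": info.role,
                    "compound": info.compound,
                    "concentration_uM": info.concentration_uM,
                    "n_fields": s.n_fields,
                    "n_fields_rejected": s.n_fields_rejected,
                    "mean_percent_positive": s.mean_percent_positive,
                    "sd_percent_positive": s.sd_percent_positive,
                    "reduction": self.reductions.get(w, float("nan")),
                    "hit": w in self.hits,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str) -> None:
        payload = {
            "dmso_baseline": self.dmso_baseline,
            "cutoff": self.cutoff,
            "hits": sorted(self.hits),
            "reductions": {k: self.reductions[k] for k in sorted(self.reductions)},
            "wells": {
                w: {
                    "n_fields": s.n_fields,
                    "mean_percent_positive": s.mean_percent_positive,
                    "sd_percent_positive": s.sd_percent_positive,
                    "n_fields_rejected": s.n_fields_rejected,
                }
                for w, s in sorted(self.summaries.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class DoseResponseSeries:
    compound: str
    points: list[tuple[float, float]]  # (concentration uM, mean percent positive)
    monotone_decreasing: bool
    trend_statistic: float


def summarize_wells(
    field_results: Mapping[str, Sequence[FieldResult]],
    layout: PlateLayout,
) -> list[WellSummary]:
    """Per-well mean/sd of percent positive over QC-accepted fields.

    A well with every field rejected is flagged (``n_fields = 0``,
    ``mean_percent_positive = None``) and later excluded from the baseline.
    With a single accepted field the sd is 0 by convention.
    """
    out = []
    for well in sorted(field_results):
        if well not in layout.wells:
            raise ScreenError(f"well {well!r} absent from the plate layout")
        results = field_results[well]
        accepted = [r.percent_positive for r in results if not r.rejected]
        n_rej = sum(1 for r in results if r.rejected)
        if accepted:
            mean = float(np.mean(accepted))
            sd = float(np.std(accepted, ddof=1)) if len(accepted) > 1 else 0.0
            out.append(WellSummary(well, len(accepted), mean, sd, n_rej))
        else:
            out.append(WellSummary(well, 0, None, 0.0, n_rej))
    return out


def call_hits(
    summaries: Iterable[WellSummary],
    layout: PlateLayout,
    cutoff: float = 0.25,
) -> ScreenResult:
    """Hit calling against the DMSO baseline.

    ``baseline`` is the unweighted mean over usable negative-control wells;
    each test well's reduction is ``(baseline - well_mean) / baseline``; a
    test well is a hit when its reduction is at least ``cutoff`` (inclusive).
    Positive controls get reductions for reporting but never become hits.
    """
    summap = {s.well: s for s in summaries}
    negatives = [
        summap[w]
        for w in layout.wells_with_role("negative_control")
        if w in summap and not summap[w].all_rejected
    ]
    if not negatives:
        raise ScreenError("no usable negative-control wells: cannot establish baseline")
    baseline = float(np.mean([s.mean_percent_positive for s in negatives]))
    if baseline == 0:
        raise ScreenError("DMSO baseline is 0%: reduction undefined")

    reductions: dict[str, float] = {}
    hits: set[str] = set()
    for w, s in summap.items():
        if s.all_rejected:
            continue
        role = layout.wells[w].role
        if role == "negative_control":
            continue
        red = (baseline - s.mean_percent_positive) / baseline
        reductions[w] = red
        if role == "test" and red >= cutoff:
            hits.add(w)
    return ScreenResult(layout, summap, baseline, reductions, hits, cutoff)


def dose_response(
    points: Sequence[tuple[float, float]],
    compound: str = "",
) -> DoseResponseSeries:
    """Dose-trend summary for a secondary-screen compound.

    Duplicate concentrations are averaged first; at least 3 distinct
    concentrations are required. ``monotone_decreasing`` is non-strict;
    ``trend_statistic`` is the Spearman rank correlation between
    concentration and percent positive (negative = reduction with dose), 0
    when the percentages are constant.
    """
    if not points:
        raise ScreenError("dose_response requires data points")
    df = pd.DataFrame(points, columns=["conc", "pct"]).groupby("conc", as_index=False).mean()
    if len(df) < 3:
        raise ScreenError("dose_response requires >= 3 distinct concentrations")
    df = df.sort_values("conc").reset_index(drop=True)
    diffs = np.diff(df["pct"].to_numpy())
    monotone = bool(np.all(diffs <= 0))
    if np.allclose(df["pct"], df["pct"].iloc[0]):
        trend = 0.0
    else:
        trend = float(stats.spearmanr(df["conc"], df["pct"]).statistic)
        if math.isnan(trend):
            trend = 0.0
    return DoseResponseSeries(
        compound=compound,
        points=[(float(c), float(p)) for c, p in df.itertuples(index=False)],
        monotone_decreasing=monotone,
        trend_statistic=trend,
    )


def plate_heatmap(result: ScreenResult, path: str) -> tuple[str, str]:
    """Write the 8x12 colour-coded plate map (PNG) and its CSV twin.

    Cells are coloured by mean percent positive; hit wells are outlined;
    wells absent from the summaries render as explicit NA. The CSV twin is
    the full summary table so the plate map is always re-derivable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    grid = np.full((8, 12), np.nan)
    for w, s in result.summaries.items():
        if s.mean_percent_positive is None:
            continue
        r = _ROWS.index(w[0])
        c = int(w[1:]) - 1
        grid[r, c] = s.mean_percent_positive

    fig, ax = plt.subplots(figsize=(9, 6))
    masked = np.ma.masked_invalid(grid)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=100)
    for w in sorted(result.hits):
        r = _ROWS.index(w[0])
        c = int(w[1:]) - 1
        ax.add_patch(
            patches.Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False, edgecolor="red", lw=2)
        )
    nan_rc = np.argwhere(np.isnan(grid))
    for r, c in nan_rc:
        ax.text(c, r, "NA", ha="center", va="center", fontsize=7, color="0.3")
    ax.set_xticks(range(12), [f"{c:02d}" for c in range(1, 13)])
    ax.set_yticks(range(8), list(_ROWS))
    ax.set_title(f"% aggregate-positive cells (baseline {result.dmso_baseline:.1f}%, "
                 f"hits outlined, cutoff {result.cutoff:.0%})")
    fig.colorbar(im, ax=ax, label="% positive")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    csv_path = path.rsplit(".", 1)[0] + ".csv"
    result.to_dataframe().to_csv(csv_path, index=False)
    return path, csv_path
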