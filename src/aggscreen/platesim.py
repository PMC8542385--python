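"""Simulated 96-well screening plates with designed active wells.

This harness generates a full plate of reporter fields well by well, runs
the per-field analysis immediately (so at most one field is held in memory),
and returns the screen result together with the designed ground truth — the
tool's own benchmark for end-to-end hit recovery.

Plate design: column 01 holds the eight DMSO negative controls at the
untreated aggregate fraction (0.75); two positive-control wells (A12, B12)
emulate wild-type reporter cells at fraction 0.10; ``n_active`` randomly
chosen test wells get strong-responder fractions in the treated regime
(0.10-0.20); all remaining test wells draw fractions uniformly from
0.70-0.80.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import (
    DEFAULT_QC_THRESHOLD,
    AggregateParams,
    FieldResult,
    analyze_field,
)
from .screen import PlateLayout, ScreenResult, WellInfo, all_well_ids, call_hits, summarize_wells
from .segmentation import SegmentationParams
from .synthetic import GenerationConfig, generate_reporter_field

__all__ = ["PlateDesign", "design_plate", "simulate_plate_results", "run_simulated_screen"]

NEGATIVE_FRACTION = 0.75
POSITIVE_CONTROL_FRACTION = 0.10
ACTIVE_FRACTIONS = (0.10, 0.125, 0.15, 0.175, 0.20)


@dataclass
class PlateDesign:
    layout: PlateLayout
    well_fractions: dict[str, float]
    active_wells: set[str]


def design_plate(seed: int, n_active: int = 5) -> PlateDesign:
    """Draw a plate design: layout, per-well aggregate fractions, actives."""
    rng = np.random.default_rng(seed)
    wells: dict[str, WellInfo] = {}
    fractions: dict[str, float] = {}
    negatives = [f"{r}01" for r in "ABCDEFGH"]
    positives = ["A12", "B12"]
    test_wells = [w for w in all_well_ids() if w not in negatives + positives]

    active = sorted(rng.choice(test_wells, size=n_active, replace=False).tolist())
    for w in negatives:
        wells[w] = WellInfo(role="negative_control", compound="DMSO")
        fractions[w] = NEGATIVE_FRACTION
    for w in positives:
        wells[w] = WellInfo(role="positive_control", compound="WT")
        fractions[w] = POSITIVE_CONTROL_FRACTION
    for i, w in enumerate(test_wells):
        wells[w] = WellInfo(role="test", compound=f"CPD-{i + 1:03d}", concentration_uM=1.0)
        if w in active:
            fractions[w] = ACTIVE_FRACTIONS[active.index(w) % len(ACTIVE_FRACTIONS)]
        else:
            fractions[w] = float(rng.uniform(0.70, 0.80))
    return PlateDesign(PlateLayout(wells), fractions, set(active))


def simulate_plate_results(
    design: PlateDesign,
    seed: int,
    n_fields_per_well: int = 2,
    base_config: GenerationConfig | None = None,
    seg: SegmentationParams | None = None,
    agg: AggregateParams | None = None,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> dict[str, list[FieldResult]]:
    """Generate and analyse every field of a designed plate, streaming."""
    base = base_config or GenerationConfig()
    rng = np.random.default_rng(seed)
    results: dict[str, list[FieldResult]] = {}
    for well in sorted(design.layout.wells):
        frac = design.well_fractions[well]
        per_well = []
        for _ in range(n_fields_per_well):
            cfg = replace(base, aggregate_fraction=frac, seed=int(rng.integers(2**31)))
            image, _scene = generate_reporter_field(cfg)
            per_well.append(analyze_field(image, seg, agg, qc_threshold))
        results[well] = per_well
    return results


def run_simulated_screen(
    seed: int,
    n_active: int = 5,
    n_fields_per_well: int = 2,
    cutoff: float = 0.25,
    base_config: GenerationConfig | None = None,
) -> tuple[ScreenResult, PlateDesign]:
    """One full simulated screen: design, image, analyse, call hits."""
    design = design_plate(seed, n_active=n_active)
    field_results = simulate_plate_results(
        design, seed=seed + 1, n_fields_per_well=n_fields_per_well, base_config=base_config
    )
    summaries = summarize_wells(field_results, design.layout)
    result = call_hits(summaries, design.layout, cutoff=cutoff)
    return result, design
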