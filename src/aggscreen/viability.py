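"""LIVE/DEAD viability counting.

Total nuclei are counted on the Hoechst channel and dead nuclei on the
EthD-1 channel with the same nuclei segmentation; live cells are derived by
subtraction (live = total - dead). The two channels are counted
independently — no colocalisation matching is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DetectionError
from .images import ChannelImage, MultiChannelImage
from .segmentation import SegmentationParams, segment_nuclei

__all__ = ["ViabilityResult", "count_nuclei", "viability"]


@dataclass
class ViabilityResult:
    n_total: int
    n_dead: int
    n_live: int
    percent_dead: float
    inconsistent: bool = False


def count_nuclei(channel: ChannelImage, seg: SegmentationParams | None = None) -> int:
    """Number of segmented nuclei in one channel (0 for a blank channel)."""
    seg = seg or SegmentationParams()
    return segment_nuclei(channel, seg).n_labels


def viability(
    field: MultiChannelImage, seg: SegmentationParams | None = None
) -> ViabilityResult:
    """LIVE/DEAD readout for one field.

    Requires channels ``"hoechst"`` and ``"ethd1"``. If segmentation yields
    more dead than total nuclei the live count is clamped to 0 and the result
    flagged inconsistent.
    """
    seg = seg or SegmentationParams()
    for required in ("hoechst", "ethd1"):
        if required not in field.channels:
            raise DetectionError(f"viability field lacks channel {required!r}")
    n_total = count_nuclei(field["hoechst"], seg)
    n_dead = count_nuclei(field["ethd1"], seg)
    inconsistent = n_dead > n_total
    n_live = max(0, n_total - n_dead)
    percent_dead = 100.0 * n_dead / n_total if n_total > 0 else 0.0
    return ViabilityResult(n_total, n_dead, n_live, percent_dead, inconsistent)
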