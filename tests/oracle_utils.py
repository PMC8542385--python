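"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the optimised code paths (scipy labelling, distance
transforms) so they can certify the pipeline's results on small inputs.
"""

from __future__ import annotations

import numpy as np


def brute_voronoi(labels: np.ndarray) -> np.ndarray:
    """Nearest-component assignment by exhaustive per-pixel search.

    Minimal Euclidean distance to any pixel of each component; exact ties go
    to the smaller label.
    """
    h, w = labels.shape
    n = int(labels.max())
    pix = {k: np.argwhere(labels == k) for k in range(1, n + 1)}
    out = np.zeros_like(labels)
    for r in range(h):
        for c in range(w):
            best = np.inf
            best_label = 0
            for k in range(1, n + 1):
                if pix[k].size == 0:
                    continue
                d = np.min((pix[k][:, 0] - r) ** 2 + (pix[k][:, 1] - c) ** 2)
                if d < best:  # strict: ties stay with the smaller label
                    best = d
                    best_label = k
            out[r, c] = best_label
    return out


def brute_connected_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling by flood fill."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            stack = [(r0, c0)]
            labels[r0, c0] = current
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not labels[nr, nc]:
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels, current


def brute_call_regions(
    response: np.ndarray,
    region_labels: np.ndarray,
    analyzable: set[int],
    threshold: float,
    area_min: int,
    area_max: int,
) -> dict[int, int]:
    """Per-region punctum counts by flood fill, no optimised labelling.

    Components of ``response >= threshold`` with area in the inclusive
    window, each assigned to the region of its maximum-response pixel
    (first-occurrence tie-break in scan order, matching ``np.argmax``).
    """
    mask = response >= threshold
    comp, n = brute_connected_components(mask)
    counts = {k: 0 for k in analyzable}
    for idx in range(1, n + 1):
        coords = np.argwhere(comp == idx)
        area = coords.shape[0]
        if not (area_min <= area <= area_max):
            continue
        vals = response[coords[:, 0], coords[:, 1]]
        r, c = coords[int(np.argmax(vals))]
        region = int(region_labels[r, c])
        if region in counts:
            counts[region] += 1
    return counts


def brute_spearman(x, y) -> float:
    """Spearman rank correlation from first principles (average ranks)."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        rk = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            rk[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return rk

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else 0.0
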