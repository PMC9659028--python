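"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities from first
principles (pair counting, threshold enumeration, breadth-first flood
fill, raw image moments) so they share no code with the implementation
they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------


def brute_auc(scores, positive) -> float:
    """All-pairs Mann–Whitney count (ties half)."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def froc_oracle(slides, fp_rates=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0)) -> float:
    """Exhaustive threshold enumeration of the FROC score.

    ``slides`` is a list of dicts with keys ``positive`` (bool),
    ``lesions`` (list of hit scores or None) and ``fps`` (list of
    false-positive point scores).  For every candidate threshold (every
    distinct score, plus one above all scores) sensitivity and the
    false-positive rate on metastasis-free slides are counted directly;
    the score averages, over the target rates, the best sensitivity
    whose FP rate does not exceed the target.
    """
    n_lesions = sum(len(s["lesions"]) for s in slides)
    neg = [s for s in slides if not s["positive"]]
    all_scores = sorted(
        {sc for s in slides for sc in s["lesions"] if sc is not None}
        | {sc for s in neg for sc in s["fps"]}
    )
    candidates = all_scores + [max(all_scores, default=0.0) + 1.0]
    points = []
    for th in candidates:
        hits = sum(
            1 for s in slides for sc in s["lesions"]
            if sc is not None and sc >= th
        )
        fps = sum(1 for s in neg for sc in s["fps"] if sc >= th)
        points.append((fps / len(neg), hits / n_lesions))
    sens_at = []
    for rate in fp_rates:
        ok = [sens for fp, sens in points if fp <= rate + 1e-12]
        sens_at.append(max(ok, default=0.0))
    return float(np.mean(sens_at))


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by breadth-first search."""
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    h, w = binary.shape
    for i in range(h):
        for j in range(w):
            if not binary[i, j] or seen[i, j]:
                continue
            comp = set()
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            components.append(comp)
    return components


def moment_major_axis_px(pixels) -> float:
    """Major axis of the moment-matched ellipse, from raw coordinates."""
    coords = np.asarray(sorted(pixels), dtype=np.float64)
    mu = coords - coords.mean(axis=0)
    cov = mu.T @ mu / len(coords)
    eigvals = np.linalg.eigvalsh(cov)
    return float(4.0 * np.sqrt(max(eigvals.max(), 0.0)))


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-negative / ten-positive cohort with imperfect scores."""
    from lymphmet.synthetic import CohortSpec, HeatmapSpec, simulate_slides

    spec = CohortSpec(
        dataset_name="fix", n_negative=10, n_positive=10, seed=21,
        slide_extent_mm=(8.0, 8.0), raster_spacing_um=16.0,
        macro_diameter_mm=(2.5, 3.5),
    )
    hspec = HeatmapSpec(fp_blob_rate=1.0, seed=22)
    return list(simulate_slides(spec, hspec))
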