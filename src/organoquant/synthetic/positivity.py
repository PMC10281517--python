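"""Synthetic proliferation-marker scenes (EdU / KI67-style nuclear positivity).

A set fraction of nuclei carries marker signal above background; the exact
positive count is round(n * fraction) with half rounded away from zero, so
scoring has a countable target.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["generate_positivity_scene", "round_half_away"]

DYE_LEVEL = 3000.0
MARKER_LEVEL = 1500.0
MARKER_BACKGROUND = 50.0


def round_half_away(x: float) -> int:
    """Round half away from zero (ties like 2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def generate_positivity_scene(
    n_cells: int,
    positive_fraction: float,
    seed: int = 0,
    nucleus_radius_px: float = 5.0,
    noise_sd: float = 0.0,
):
    """Nucleus-dye and marker images with known positive labels.

    Returns
    -------
    dye : (Y, X) float image, all nuclei bright
    marker : (Y, X) float image, positive nuclei bright on low background
    truth : DataFrame (cell_id, row, col, radius_px, positive)
    """
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError(f"positive_fraction must be in [0, 1], got {positive_fraction}")
    rng = np.random.default_rng(seed)

    pitch = 2 * nucleus_radius_px + 6.0
    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    margin = nucleus_radius_px + 4.0
    shape = (
        int(np.ceil(2 * margin + (nrows - 1) * pitch)),
        int(np.ceil(2 * margin + (ncols - 1) * pitch)),
    )
    centers = []
    for k in range(n_cells):
        i, j = divmod(k, ncols)
        centers.append(
            (
                margin + i * pitch + rng.uniform(-2.0, 2.0),
                margin + j * pitch + rng.uniform(-2.0, 2.0),
            )
        )

    n_pos = round_half_away(n_cells * positive_fraction)
    positive = np.zeros(n_cells, dtype=bool)
    positive[rng.choice(n_cells, size=n_pos, replace=False)] = True

    dye = np.zeros(shape, dtype=float)
    marker = np.full(shape, MARKER_BACKGROUND, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    rows = []
    for k, (r0, c0) in enumerate(centers):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= nucleus_radius_px**2
        dye[disk] = DYE_LEVEL
        if positive[k]:
            marker[disk] = MARKER_LEVEL
        rows.append(
            {
                "cell_id": k,
                "row": float(r0),
                "col": float(c0),
                "radius_px": float(nucleus_radius_px),
                "positive": bool(positive[k]),
            }
        )
    if noise_sd > 0:
        dye = np.clip(dye * (1 + noise_sd * rng.standard_normal(shape)), 0, None)
        marker = np.clip(marker * (1 + noise_sd * rng.standard_normal(shape)), 0, None)
    return dye, marker, pd.DataFrame(rows)
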