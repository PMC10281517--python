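"""Synthetic organoid silhouettes: near-spherical versus budding (lobed).

Spherical organoids rasterise to a disk (solidity close to 1); budding
organoids are a union of a central disk and peripheral lobes whose necks
create convex deficiencies, pushing solidity well below the spherical
regime.  True pixel areas are recorded for area-measurement tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_silhouette"]


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_silhouette(kind: str, size: float = 100.0, n_lobes: int = 3, seed: int = 0):
    """Binary organoid mask plus ground truth.

    Parameters
    ----------
    kind : {"spherical", "budding"}
    size : characteristic radius in pixels (>= 10)
    n_lobes : number of buds (budding only, >= 2)
    seed : RNG seed (lobe sizes/angles)

    Returns
    -------
    mask : (Y, X) bool array; pixel-centre rasterisation
    truth : dict with keys kind, area_px, n_lobes
    """
    if size < 10:
        raise ValueError(f"size must be at least a 10 px radius, got {size}")
    if kind not in ("spherical", "budding"):
        raise ValueError(f"kind must be 'spherical' or 'budding', got {kind!r}")
    rng = np.random.default_rng(seed)

    if kind == "spherical":
        half = int(np.ceil(size)) + 4
        shape = (2 * half + 1, 2 * half + 1)
        mask = _disk(shape, (half, half), size)
        return mask, {"kind": kind, "area_px": int(mask.sum()), "n_lobes": 0}

    if n_lobes < 2:
        raise ValueError(f"budding silhouettes need n_lobes >= 2, got {n_lobes}")
    core_r = 0.55 * size
    lobe_dist = 0.75 * size
    extent = lobe_dist + 0.65 * size
    half = int(np.ceil(extent)) + 4
    shape = (2 * half + 1, 2 * half + 1)
    mask = _disk(shape, (half, half), core_r)
    base = rng.uniform(0, 2 * np.pi)
    for i in range(n_lobes):
        phi = base + 2 * np.pi * i / n_lobes + rng.uniform(-0.15, 0.15)
        lobe_r = size * rng.uniform(0.35, 0.45)
        center = (half + lobe_dist * np.cos(phi), half + lobe_dist * np.sin(phi))
        mask |= _disk(shape, center, lobe_r)
    return mask, {"kind": kind, "area_px": int(mask.sum()), "n_lobes": int(n_lobes)}
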