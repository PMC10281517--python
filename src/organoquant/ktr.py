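"""KTR cytoplasm/nucleus ratio quantitation.

Turns segmented reporter movies into normalised per-cell and per-organoid
C/N ratio traces.  The per-cell ratio is the mean cytoplasmic (ring)
intensity divided by the mean nuclear intensity; every ratio in a movie is
then expressed as a percentage of the cohort mean at the first time point,
so the cohort mean at T0 is exactly 100%.  Per-organoid traces are the
arithmetic mean across scored cells per time point with a t-distribution
95% confidence band, and the T0-versus-Tk comparison across replicate
organoids uses one-way ANOVA on the replicate means.

Cells with a nuclear mean below a small fraction of the channel's dynamic
range are excluded (division guard).  Frames are analysed independently by
default — sufficient for cohort means; a greedy nearest-neighbour centroid
matcher provides per-cell identity over time when individual traces are
wanted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segmentation import (
    LabelMap,
    SegmentationParams,
    label_table,
    ring_compartments,
    segment_nuclei,
    select_plane_indices,
)
from .stats import TestResult, one_way_anova

logger = logging.getLogger(__name__)

__all__ = [
    "cn_ratio",
    "measure_cells",
    "normalize_to_t0",
    "match_cells_across_time",
    "aggregate_per_organoid",
    "anova_t0_vs_t",
    "analyze_movie",
]

#: nuclear means below this fraction of the channel dynamic range are excluded
MIN_NUCLEAR_FRACTION = 0.01


def cn_ratio(cyto_mean, nuclear_mean, eps: float = 0.0):
    """Cytoplasm/nucleus ratio: mean cytoplasmic / mean nuclear intensity.

    Scalar or array; entries with nuclear mean <= ``eps`` come back NaN
    (callers flag and exclude them).
    """
    cyto = np.asarray(cyto_mean, dtype=float)
    nuc = np.asarray(nuclear_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nuc > eps, cyto / np.where(nuc > eps, nuc, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def measure_cells(
    reporter: np.ndarray,
    nuclei: LabelMap,
    rings: LabelMap,
    time_min: float = 0.0,
    z: int = 0,
    organoid: int = 0,
    min_nuclear_fraction: float = MIN_NUCLEAR_FRACTION,
) -> pd.DataFrame:
    """Per-cell record table for one plane.

    Columns: cell_id, organoid, time_min, z, nuclear_mean, cyto_mean,
    nuclear_area_px, ring_area_px, ratio, excluded.  Cells without any ring
    pixels or with a nuclear mean under the division guard are flagged
    ``excluded`` and get NaN ratios.
    """
    nuc_tab = label_table(reporter, nuclei).rename(
        columns={"mean": "nuclear_mean", "area_px": "nuclear_area_px"}
    )
    ring_tab = label_table(reporter, rings).rename(
        columns={"mean": "cyto_mean", "area_px": "ring_area_px"}
    )[["label", "cyto_mean", "ring_area_px"]]
    df = nuc_tab.merge(ring_tab, on="label", how="left")
    df["ring_area_px"] = pd.to_numeric(df["ring_area_px"], errors="coerce").fillna(0).astype(int)
    eps = min_nuclear_fraction * float(np.max(reporter)) if df.shape[0] else 0.0
    df["ratio"] = cn_ratio(df["cyto_mean"], df["nuclear_mean"], eps=eps)
    df["excluded"] = df["ratio"].isna() | (df["ring_area_px"] == 0)
    df.loc[df["excluded"], "ratio"] = np.nan
    n_excl = int(df["excluded"].sum())
    if n_excl:
        logger.info("measure_cells: excluded %d/%d cells (division guard or no ring)",
                    n_excl, len(df))
    df = df.rename(columns={"label": "cell_id"})
    df.insert(1, "organoid", organoid)
    df.insert(2, "time_min", float(time_min))
    df.insert(3, "z", int(z))
    return df


def _valid_rows(df: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in df.columns:
        return df[~df["excluded"].astype(bool)]
    return df


def normalize_to_t0(records: pd.DataFrame, by=("organoid",), movie: str = "") -> pd.DataFrame:
    """Normalise ratios to the cohort mean at the first time point (as 100%).

    Every measurement in a cohort (grouping keys ``by``, pooled across z
    planes and cells) is divided by the mean ratio over all scored cells at
    T0 and multiplied by 100, so the cohort mean at T0 is exactly 100%.
    A missing or zero T0 mean is a hard error naming the movie.
    """
    df = records.copy()
    keys = [k for k in by if k in df.columns]
    groups = df.groupby(keys, sort=True) if keys else [((), df)]
    out = []
    for name, grp in groups:
        v = _valid_rows(grp).dropna(subset=["ratio"])
        t0 = grp["time_min"].min()  # the movie's first time point
        t0_vals = v.loc[v["time_min"] == t0, "ratio"]
        if t0_vals.empty or t0_vals.mean() == 0 or not np.isfinite(t0_vals.mean()):
            raise ValueError(
                f"cannot normalise movie {movie!r} cohort {name!r}: "
                "no valid cells (or zero mean ratio) at the first time point"
            )
        g = grp.copy()
        g["ratio_pct"] = g["ratio"] / t0_vals.mean() * 100.0
        out.append(g)
    return pd.concat(out, ignore_index=True)


def match_cells_across_time(tables: pd.DataFrame, max_displacement: float = 10.0) -> pd.DataFrame:
    """Greedy nearest-neighbour identity assignment across frames.

    ``tables`` needs columns time_min, cell_id, centroid_row, centroid_col.
    Frame-to-frame pairs are matched in order of increasing distance (ties
    by smaller previous then current label); pairs farther apart than
    ``max_displacement`` px stay unmatched and start new track ids.  Returns
    the table with a ``track_id`` column.
    """
    df = tables.sort_values(["time_min", "cell_id"]).copy()
    df["track_id"] = -1
    times = sorted(df["time_min"].unique())
    next_id = 0
    prev_idx: dict[int, int] = {}  # cell label in previous frame -> track id
    for ti, t in enumerate(times):
        frame = df[df["time_min"] == t]
        if ti == 0:
            for i in frame.index:
                df.at[i, "track_id"] = next_id
                prev_idx[df.at[i, "cell_id"]] = next_id
                next_id += 1
            prev_frame = frame
            continue
        pairs = []
        for i in prev_frame.index:
            for j in frame.index:
                d = np.hypot(
                    df.at[i, "centroid_row"] - df.at[j, "centroid_row"],
                    df.at[i, "centroid_col"] - df.at[j, "centroid_col"],
                )
                if d <= max_displacement:
                    pairs.append((d, df.at[i, "cell_id"], df.at[j, "cell_id"], i, j))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_prev, used_cur = set(), set()
        new_idx: dict[int, int] = {}
        for d, lp, lc, i, j in pairs:
            if i in used_prev or j in used_cur:
                continue
            used_prev.add(i)
            used_cur.add(j)
            tid = prev_idx[lp]
            df.at[j, "track_id"] = tid
            new_idx[lc] = tid
        for j in frame.index:
            if j not in used_cur:
                df.at[j, "track_id"] = next_id
                new_idx[df.at[j, "cell_id"]] = next_id
                next_id += 1
        prev_idx = new_idx
        prev_frame = frame
    return df


def aggregate_per_organoid(traces: pd.DataFrame, value: str = "ratio_pct") -> pd.DataFrame:
    """Mean trace per organoid per time with a 95% t-confidence band.

    CI half-width = t(0.975, n-1) * sd / sqrt(n); with a single cell the CI
    is reported missing (NaN), never zero.
    """
    valid = _valid_rows(traces)
    rows = []
    for (org, t), grp in valid.groupby(["organoid", "time_min"]):
        vals = grp[value].dropna().to_numpy()
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        if n > 1:
            half = float(sps.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n))
        else:
            half = np.nan
        rows.append(
            {
                "organoid": org,
                "time_min": float(t),
                value: mean,
                "n": n,
                "ci_lo": mean - half,
                "ci_hi": mean + half,
            }
        )
    return pd.DataFrame(rows).sort_values(["organoid", "time_min"]).reset_index(drop=True)


def anova_t0_vs_t(replicate_means: pd.DataFrame, t_target: float,
                  value: str = "ratio_pct") -> TestResult:
    """One-way ANOVA comparing replicate means at T0 against a target time.

    ``replicate_means`` holds one row per organoid replicate per time
    (columns organoid, time_min, and the value column).  Requires at least
    two replicates per group.
    """
    t0 = replicate_means["time_min"].min()
    g0 = replicate_means.loc[replicate_means["time_min"] == t0, value].dropna().to_numpy()
    g1 = replicate_means.loc[replicate_means["time_min"] == t_target, value].dropna().to_numpy()
    if g0.size < 2 or g1.size < 2:
        raise ValueError(
            f"ANOVA needs >= 2 replicates per group; got {g0.size} at T0 and "
            f"{g1.size} at t={t_target}"
        )
    return one_way_anova(g0, g1)


def analyze_movie(
    stack: np.ndarray,
    frame_interval_min: float = 10.0,
    nuclear_channel: int = 0,
    reporter_channel: int = 1,
    params: SegmentationParams | None = None,
    n_planes: int | None = None,
    z_indices=None,
    organoid: int = 0,
) -> pd.DataFrame:
    """End-to-end per-cell measurement of a (T, Z, C, Y, X) reporter movie.

    Segments nuclei on the dye channel per frame and z plane, builds the
    ring cytoplasm, measures the reporter channel and normalises to T0.
    z planes are analysed independently and pooled at the cohort level.
    """
    if params is None:
        params = SegmentationParams()
    if stack.ndim != 5:
        raise ValueError(f"expected (T, Z, C, Y, X), got shape {stack.shape}")
    n_t, n_z = stack.shape[:2]
    if z_indices is not None or n_planes is not None:
        z_sel = select_plane_indices(n_z, n_planes or 0, indices=z_indices)
    else:
        z_sel = list(range(n_z))
    frames = []
    for t in range(n_t):
        for z in z_sel:
            dye = stack[t, z, nuclear_channel]
            rep = stack[t, z, reporter_channel]
            nuclei = segment_nuclei(dye, params)
            nuc_measure, rings = ring_compartments(nuclei, params)
            frames.append(
                measure_cells(rep, nuc_measure, rings, time_min=t * frame_interval_min,
                              z=z, organoid=organoid)
            )
    records = pd.concat(frames, ignore_index=True)
    return normalize_to_t0(records)
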