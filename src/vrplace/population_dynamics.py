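"""Population-vector correlations and lap-wise field dynamics.

Population vectors (PVs) are the cellwise mean rates at one position bin over
a short lap window; correlating PV sets between lap intervals tracks how the
population code evolves across a session.  Field dynamics quantify lap-by-lap
changes of individual fields: in/out-of-field ratio, center-of-mass offsets
and above-threshold field size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vrplace.preprocessing import BinnedActivity
from vrplace.tuning import PccResult, PlaceField, TuningConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PvCorrelation",
    "pv_matrix",
    "pv_timecourse",
    "group_activity",
    "in_out_ratio",
    "com_shift",
    "field_size_by_lap",
    "circular_com_cm",
]

MIN_FINITE_DIAG = 50  # finite diagonal bins required to report diag_mean


@dataclass
class PvCorrelation:
    matrix: np.ndarray      # bins x bins Pearson correlations
    diag_mean: float
    lap_window: int


def _pv_set(binned: BinnedActivity, laps: np.ndarray | None) -> np.ndarray:
    """bins x cells mean-rate PVs over a lap window."""
    return np.nan_to_num(binned.lap_average(laps), nan=0.0)


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of a with each row of b; NaN for zero variance."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a @ b.T) / np.outer(sa, sb)
    c[sa == 0, :] = np.nan
    c[:, sb == 0] = np.nan
    return c


def pv_matrix(
    binned_ref: BinnedActivity,
    binned_other: BinnedActivity,
    laps_ref: np.ndarray | None = None,
    laps_other: np.ndarray | None = None,
    lap_window: int = 3,
) -> PvCorrelation:
    """Correlate PVs of one lap interval against PVs of another, bin by bin."""
    if binned_ref.n_cells != binned_other.n_cells:
        raise ValueError("PV sets must share the cell dimension")
    if binned_ref.n_bins != binned_other.n_bins:
        raise ValueError("PV sets must share the bin count")
    m = _corr_rows(_pv_set(binned_ref, laps_ref), _pv_set(binned_other, laps_other))
    diag = np.diag(m)
    finite = np.isfinite(diag)
    diag_mean = float(diag[finite].mean()) if finite.sum() >= MIN_FINITE_DIAG else np.nan
    return PvCorrelation(matrix=m, diag_mean=diag_mean, lap_window=lap_window)


def pv_timecourse(
    binned_fam: BinnedActivity,
    binned_nov: BinnedActivity,
    lap_window: int = 3,
    offset_laps: int = 7,
) -> dict[str, pd.DataFrame]:
    """The three diagonal-mean timecourses across the teleportation.

    Variant C: final-3 familiar laps vs every non-overlapping 3-lap interval
    (familiar then novel).  Variant D: novel laps 13-15 vs all earlier
    non-overlapping novel intervals.  Variant E: each novel interval vs the
    interval starting ``offset_laps`` laps later (e.g. laps 1-3 with 8-10).
    """
    Mf, Mn = binned_fam.n_laps, binned_nov.n_laps
    out: dict[str, pd.DataFrame] = {}

    def intervals(m: int) -> list[np.ndarray]:
        return [np.arange(s, s + lap_window) for s in range(0, m - lap_window + 1, lap_window)]

    # variant C
    if Mf >= lap_window:
        ref = np.arange(Mf - lap_window, Mf)
        rows = []
        for iv in intervals(Mf):
            r = pv_matrix(binned_fam, binned_fam, ref, iv, lap_window).diag_mean
            rows.append({"env": "familiar", "lap_start": int(iv[0]), "diag_mean": r})
        for iv in intervals(Mn):
            r = pv_matrix(binned_fam, binned_nov, ref, iv, lap_window).diag_mean
            rows.append({"env": "novel", "lap_start": int(iv[0]), "diag_mean": r})
        out["C"] = pd.DataFrame(rows)
    else:
        logger.info("variant C skipped: fewer than %d familiar laps", lap_window)

    # variant D
    if Mn >= 15:
        ref = np.arange(12, 15)
        rows = [
            {"lap_start": int(iv[0]), "diag_mean": pv_matrix(binned_nov, binned_nov, ref, iv, lap_window).diag_mean}
            for iv in intervals(12)
        ]
        out["D"] = pd.DataFrame(rows)
    else:
        logger.info("variant D skipped: fewer than 15 novel laps")

    # variant E
    rows = []
    for iv in intervals(Mn):
        later = iv + offset_laps
        if later[-1] >= Mn:
            break
        rows.append(
            {
                "lap_start": int(iv[0]),
                "diag_mean": pv_matrix(binned_nov, binned_nov, iv, later, lap_window).diag_mean,
            }
        )
    if rows:
        out["E"] = pd.DataFrame(rows)
    else:
        logger.info("variant E skipped: not enough novel laps for a %d-lap offset", offset_laps)
    return out


# ---------------------------------------------------------------------------
# lap-wise group activity
# ---------------------------------------------------------------------------

def _lap_means(binned: BinnedActivity) -> np.ndarray:
    """Occupancy-weighted mean activity per lap per cell (laps x cells)."""
    occ = binned.occupancy[:, :, None]
    num = (np.nan_to_num(binned.rate, nan=0.0) * occ).sum(axis=1)
    den = binned.occupancy.sum(axis=1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def group_activity(
    binned_fam: BinnedActivity,
    binned_nov: BinnedActivity,
    pcc_fam: list[PccResult],
    pcc_nov: list[PccResult],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Lap-wise z-scored mean activity for familiar-only / both / novel-only PCC groups.

    Per cell, lap-mean activity across the whole session (familiar then novel
    laps) is z-scored over laps, then averaged within each group.  Also reports
    each group's raw percent drop from familiar-lap mean to novel-lap mean.
    """
    fam = {r.cell for r in pcc_fam if r.is_pcc}
    nov = {r.cell for r in pcc_nov if r.is_pcc}
    groups = {
        "familiar_only": sorted(fam - nov),
        "both": sorted(fam & nov),
        "novel_only": sorted(nov - fam),
    }
    lm = np.vstack([_lap_means(binned_fam), _lap_means(binned_nov)])  # laps x cells
    mu = np.nanmean(lm, axis=0, keepdims=True)
    sd = np.nanstd(lm, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (lm - mu) / sd
    Mf = binned_fam.n_laps
    lap_col = np.arange(lm.shape[0])
    rows = []
    drops: dict[str, float] = {}
    for name, cells in groups.items():
        if not cells:
            drops[name] = np.nan
            continue
        series = np.nanmean(z[:, cells], axis=1)
        for l, v in zip(lap_col, series):
            rows.append(
                {
                    "group": name,
                    "lap": int(l),
                    "env": "familiar" if l < Mf else "novel",
                    "z_activity": float(v),
                }
            )
        raw = np.nanmean(lm[:, cells], axis=1)
        fam_mean, nov_mean = np.nanmean(raw[:Mf]), np.nanmean(raw[Mf:])
        drops[name] = float(100.0 * (fam_mean - nov_mean) / fam_mean) if fam_mean else np.nan
    return pd.DataFrame(rows), drops


def in_out_ratio(
    binned: BinnedActivity,
    peak_bins: np.ndarray | None = None,
    window_cm: float = 30.0,
) -> pd.DataFrame:
    """Per-lap ratio of in-field to out-of-field mean activity, averaged over cells.

    The in-field window is the ``window_cm`` circular region centered on each
    cell's lap-averaged peak bin (all cells, not only PCCs).
    """
    N = binned.n_bins
    if peak_bins is None:
        avg = np.nan_to_num(binned.lap_average(), nan=0.0)
        peak_bins = np.argmax(avg, axis=0)
    centers = np.arange(N)
    half_bins = window_cm / 2.0 / binned.bin_size
    d = np.abs(centers[None, :] - np.asarray(peak_bins)[:, None])
    d = np.minimum(d, N - d)
    in_mask = d <= half_bins  # cells x bins
    rows = []
    for lap in range(binned.n_laps):
        r = binned.rate[lap]  # bins x cells
        ratios = []
        for c in range(binned.n_cells):
            inside = r[in_mask[c], c]
            outside = r[~in_mask[c], c]
            with np.errstate(invalid="ignore"):
                mi, mo = np.nanmean(inside), np.nanmean(outside)
            if np.isfinite(mi) and np.isfinite(mo) and mo > 0:
                ratios.append(mi / mo)
        rows.append(
            {
                "lap": lap,
                "ratio": float(np.mean(ratios)) if ratios else np.nan,
                "n_cells": len(ratios),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# field-resolved dynamics
# ---------------------------------------------------------------------------

def circular_com_cm(bins: np.ndarray, weights: np.ndarray, n_bins: int, bin_size: float) -> float:
    """Weighted circular center of mass of a set of bins, in cm (vector-mean angle)."""
    w = np.nan_to_num(np.asarray(weights, dtype=float), nan=0.0)
    if w.sum() <= 0:
        return np.nan
    theta = 2 * np.pi * (np.asarray(bins) + 0.5) / n_bins
    ang = np.arctan2((w * np.sin(theta)).sum(), (w * np.cos(theta)).sum()) % (2 * np.pi)
    return float(ang / (2 * np.pi) * n_bins * bin_size)


def _signed_circ_diff_cm(a: float, b: float, track_length: float) -> float:
    """Signed circular difference a - b in (-L/2, L/2]."""
    d = (a - b) % track_length
    if d > track_length / 2:
        d -= track_length
    return float(d)


def com_shift(
    binned: BinnedActivity,
    fields: list[PlaceField],
    cfg: TuningConfig | None = None,
) -> pd.DataFrame:
    """Per-field per-active-lap COM offsets (cm), aligned to each field's onset lap.

    The offset is the lap COM minus the field's mean COM (circular, weighted
    by binned activity inside the field boundary); laps without
    above-threshold in-field activity are excluded, not zero-filled.
    """
    N = binned.n_bins
    L = N * binned.bin_size
    rows = []
    for fid, f in enumerate(fields):
        mean_map = np.nanmean(binned.rate[:, f.bins, f.cell], axis=0)
        com_mean = circular_com_cm(f.bins, mean_map, N, binned.bin_size)
        for lap in f.active_laps:
            w = binned.rate[lap, f.bins, f.cell]
            com_lap = circular_com_cm(f.bins, w, N, binned.bin_size)
            if not np.isfinite(com_lap):
                continue
            rows.append(
                {
                    "field": fid,
                    "cell": f.cell,
                    "lap": int(lap),
                    "laps_since_onset": int(lap - f.onset_lap),
                    "com_offset_cm": _signed_circ_diff_cm(com_lap, com_mean, L),
                }
            )
    return pd.DataFrame(rows)


def com_shift_population_mean(table: pd.DataFrame) -> pd.Series:
    """Mean COM offset per laps-since-onset across fields."""
    return table.groupby("laps_since_onset")["com_offset_cm"].mean()


def field_size_by_lap(
    binned: BinnedActivity,
    fields: list[PlaceField],
) -> pd.DataFrame:
    """Above-threshold bin count inside each field's fixed boundary, per active lap.

    The threshold is the cell's 50th percentile of activity over all bins and
    laps; counts are normalized by the field's across-lap mean count.
    """
    rows = []
    for fid, f in enumerate(fields):
        cell_rate = binned.rate[:, :, f.cell]
        vals = cell_rate[np.isfinite(cell_rate)]
        if vals.size == 0:
            continue
        thr = float(np.percentile(vals, 50))
        counts = []
        for lap in f.active_laps:
            infield = cell_rate[lap, f.bins]
            counts.append(int(np.nansum(infield > thr)))
        mean_count = np.mean(counts) if counts else np.nan
        for lap, cnt in zip(f.active_laps, counts):
            rows.append(
                {
                    "field": fid,
                    "cell": f.cell,
                    "lap": int(lap),
                    "laps_since_onset": int(lap - f.onset_lap),
                    "size_bins": cnt,
                    "size_norm": cnt / mean_count if mean_count else np.nan,
                }
            )
    return pd.DataFrame(rows)
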