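"""Global-remapping statistics across environments and rate-remapping variance.

Global remapping is probed by (a) the correlation of single-field locations
across environments and (b) the observed vs expected (product of proportions)
overlap of tuned-cell sets.  Rate remapping under object destabilization is
probed by the across-lap standard deviation of each tuned cell's lap-peak
activity, with running speed at the peak as a control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vrplace.decoding import circular_distance_cm
from vrplace.preprocessing import BinnedActivity
from vrplace.session_io import EnvironmentSpec
from vrplace.tuning import PccResult, circular_smooth

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapStats",
    "field_location_correlation",
    "overlap_vs_expected",
    "lap_peak_variability",
    "speed_at_peak_variability",
]


@dataclass
class OverlapStats:
    p_fam: float
    p_nov: float
    p_both_observed: float
    p_both_expected: float
    difference: float


def field_location_correlation(
    pcc_fam: list[PccResult],
    pcc_nov: list[PccResult],
    exclude_tunnel: bool = False,
    n_bins: int = 100,
    tunnel_margin_bins: int = 5,
    circular: bool = False,
):
    """Pearson r between familiar and novel peak bins of single-field cells.

    Restricted to cells with exactly one field in each environment.  With
    ``exclude_tunnel``, cells whose peak falls within ``tunnel_margin_bins``
    of the beginning or end of the track in either environment are removed.
    ``circular=True`` uses a circular-circular correlation instead.
    Returns ``(r, n, p)``; r and p are NaN when n < 3.
    """
    fam = {r.cell: r.fields[0].peak_bin for r in pcc_fam if len(r.fields) == 1}
    nov = {r.cell: r.fields[0].peak_bin for r in pcc_nov if len(r.fields) == 1}
    cells = sorted(set(fam) & set(nov))
    x = np.array([fam[c] for c in cells], dtype=float)
    y = np.array([nov[c] for c in cells], dtype=float)
    if exclude_tunnel:
        near = (
            (x < tunnel_margin_bins)
            | (x >= n_bins - tunnel_margin_bins)
            | (y < tunnel_margin_bins)
            | (y >= n_bins - tunnel_margin_bins)
        )
        x, y = x[~near], y[~near]
    n = len(x)
    if n < 3:
        return np.nan, n, np.nan
    if circular:
        r = _circ_corr(2 * np.pi * x / n_bins, 2 * np.pi * y / n_bins)
        return float(r), n, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), n, float(p)


def _circ_corr(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation."""
    a = alpha - stats.circmean(alpha)
    b = beta - stats.circmean(beta)
    num = np.sum(np.sin(a) * np.sin(b))
    den = np.sqrt(np.sum(np.sin(a) ** 2) * np.sum(np.sin(b) ** 2))
    return num / den if den > 0 else np.nan


def overlap_vs_expected(
    sessions: list[tuple[list[PccResult], list[PccResult]]],
) -> tuple[pd.DataFrame, float, float]:
    """Observed vs expected (p_fam * p_nov) joint PCC proportions per session.

    Returns the per-session table, plus the t statistic and p value of a
    one-sample t-test of the observed-minus-expected differences against 0.
    Sessions with zero cells are excluded.
    """
    rows = []
    for i, (pcc_fam, pcc_nov) in enumerate(sessions):
        n = len(pcc_fam)
        if n == 0 or len(pcc_nov) != n:
            logger.info("session %d excluded from overlap stats (cell sets unusable)", i)
            continue
        fam = np.array([r.is_pcc for r in pcc_fam])
        nov = np.array([r.is_pcc for r in pcc_nov])
        s = OverlapStats(
            p_fam=float(fam.mean()),
            p_nov=float(nov.mean()),
            p_both_observed=float((fam & nov).mean()),
            p_both_expected=float(fam.mean() * nov.mean()),
            difference=float((fam & nov).mean() - fam.mean() * nov.mean()),
        )
        rows.append({"session": i, **s.__dict__})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        t, p = stats.ttest_1samp(table["difference"], 0.0)
        return table, float(t), float(p)
    return table, np.nan, np.nan


# ---------------------------------------------------------------------------
# rate-remapping variance
# ---------------------------------------------------------------------------

def _zscore_session(rate: np.ndarray) -> np.ndarray:
    """Z-score each cell's laps x bins activity over the whole session."""
    flat = rate.reshape(-1, rate.shape[2])
    mu = np.nanmean(flat, axis=0)
    sd = np.nanstd(flat, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rate - mu) / sd


def _lap_peaks(z: np.ndarray, smooth_bins: int = 5):
    """Per lap per cell: peak value and bin of the circularly smoothed z trace."""
    M, N, C = z.shape
    peaks = np.full((M, C), np.nan)
    peak_bins = np.full((M, C), -1, dtype=int)
    for c in range(C):
        for lap in range(M):
            trace = z[lap, :, c]
            finite = np.isfinite(trace)
            if finite.sum() < N // 2:
                continue
            sm = circular_smooth(np.where(finite, trace, np.nanmean(trace[finite])), smooth_bins)
            peak_bins[lap, c] = int(np.argmax(sm))
            peaks[lap, c] = float(sm[peak_bins[lap, c]])
    return peaks, peak_bins


def lap_peak_variability(
    binned: BinnedActivity,
    pcc: list[PccResult],
    epochs: np.ndarray,
    env: EnvironmentSpec,
    smooth_bins: int = 5,
    min_laps_per_epoch: int = 3,
    peak_stability_cm: float | None = None,
) -> pd.DataFrame:
    """Across-lap SD of lap-peak activity per tuned cell, split by epoch and zone.

    Activity is z-scored over the whole session first; each lap's trace is
    convolved with a ``smooth_bins`` Hanning window and its free-location peak
    extracted.  A cell's zone is the zone of its across-lap mean peak.  With
    ``peak_stability_cm`` set, only cells whose mean peak moved less than that
    circular distance between the two epochs are kept (in-field-mean variant).
    Returns one row per cell x epoch with ``sd_lap_peak``.
    """
    epochs = np.asarray(epochs)
    if len(epochs) != binned.n_laps:
        raise ValueError("epochs must label every lap")
    z = _zscore_session(binned.rate)
    peaks, peak_bins = _lap_peaks(z, smooth_bins)
    tuned = [r.cell for r in pcc if r.is_pcc]
    labels = pd.unique(epochs)
    rows = []
    for c in tuned:
        valid = np.isfinite(peaks[:, c])
        if valid.sum() == 0:
            continue
        mean_peak_bin = int(
            np.round(
                circular_com_bin(peak_bins[valid, c], binned.n_bins)
            )
        ) % binned.n_bins
        zone = env.zone_of_bin(mean_peak_bin)
        if peak_stability_cm is not None and len(labels) == 2:
            mb = []
            for lab in labels:
                sel = valid & (epochs == lab)
                if sel.sum() == 0:
                    mb.append(np.nan)
                else:
                    mb.append(circular_com_bin(peak_bins[sel, c], binned.n_bins))
            if not all(np.isfinite(mb)):
                continue
            moved = circular_distance_cm(
                mb[0] * binned.bin_size, mb[1] * binned.bin_size, env.track_length
            )
            if moved >= peak_stability_cm:
                continue
        for lab in labels:
            sel = valid & (epochs == lab)
            if sel.sum() < min_laps_per_epoch:
                continue
            rows.append(
                {
                    "cell": c,
                    "epoch": lab,
                    "zone": zone,
                    "sd_lap_peak": float(np.std(peaks[sel, c], ddof=1)),
                    "n_laps": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def circular_com_bin(bins: np.ndarray, n_bins: int) -> float:
    """Unweighted circular mean of bin indices."""
    theta = 2 * np.pi * np.asarray(bins, dtype=float) / n_bins
    ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) % (2 * np.pi)
    return float(ang / (2 * np.pi) * n_bins)


def speed_at_peak_variability(
    binned: BinnedActivity,
    velocity_binned: np.ndarray,
    pcc: list[PccResult],
    epochs: np.ndarray,
    env: EnvironmentSpec,
    smooth_bins: int = 5,
    min_laps_per_epoch: int = 3,
) -> pd.DataFrame:
    """Across-lap SD of running speed at each tuned cell's lap-peak bin.

    ``velocity_binned`` is a laps x bins occupancy-normalized speed map; the
    speed for a cell and lap is the lap's mean speed in that lap's activity
    peak bin.  Output mirrors :func:`lap_peak_variability` (zone x epoch rows).
    """
    epochs = np.asarray(epochs)
    z = _zscore_session(binned.rate)
    peaks, peak_bins = _lap_peaks(z, smooth_bins)
    tuned = [r.cell for r in pcc if r.is_pcc]
    labels = pd.unique(epochs)
    rows = []
    for c in tuned:
        valid = np.isfinite(peaks[:, c])
        if valid.sum() == 0:
            continue
        mean_peak_bin = int(np.round(circular_com_bin(peak_bins[valid, c], binned.n_bins))) % binned.n_bins
        zone = env.zone_of_bin(mean_peak_bin)
        speeds = np.full(binned.n_laps, np.nan)
        for lap in np.nonzero(valid)[0]:
            speeds[lap] = velocity_binned[lap, peak_bins[lap, c]]
        for lab in labels:
            sel = valid & (epochs == lab) & np.isfinite(speeds)
            if sel.sum() < min_laps_per_epoch:
                continue
            rows.append(
                {
                    "cell": c,
                    "epoch": lab,
                    "zone": zone,
                    "sd_speed_at_peak": float(np.std(speeds[sel], ddof=1)),
                    "n_laps": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def zone_epoch_means(table: pd.DataFrame, value: str) -> pd.DataFrame:
    """Session-level zone x epoch means of a per-cell variability column."""
    return table.groupby(["zone", "epoch"], dropna=False)[value].mean().reset_index()
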