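"""Bayesian position decoding with leave-one-lap-out cross-validation.

The decoder assumes Poisson emissions: the log-posterior over position bins in
a time window is ``sum_i n_i log f_i(x) - T sum_i f_i(x)`` plus a uniform
log-prior, where f_i(x) are Gaussian-smoothed training ratemaps, n_i the
summed events of cell i in the window and T the retained window duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from vrplace.preprocessing import BinnedActivity, PreprocessConfig, bin_activity, get_signal
from vrplace.session_io import EnvironmentSpec, SessionRecording

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderConfig",
    "DecoderOutput",
    "decode_loocv",
    "error_exceedance_by_lap",
    "best_laps_error",
    "circular_distance_cm",
]


@dataclass
class DecoderConfig:
    tau: float = 3.0                   # decoding window, seconds
    ratemap_smooth_sigma: float = 2.0  # bins, circular Gaussian
    error_threshold: float = 20.0      # cm, for exceedance summaries
    rate_floor_events: float = 0.01    # floor = rate_floor_events / tau
    circular_error: bool = True
    min_window_frac: float = 0.5       # discard truncated windows shorter than this

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.ratemap_smooth_sigma < 0:
            raise ValueError("ratemap_smooth_sigma must be nonnegative")


@dataclass
class DecoderOutput:
    windows: pd.DataFrame       # lap, t_mid, duration_s, decoded_bin, true_bin, error_cm
    per_lap: pd.DataFrame       # lap, mean_error_cm, frac_above_threshold, n_windows
    mean_error_cm: float
    best5_error_cm: float
    track_length: float
    n_bins: int


def circular_distance_cm(a_cm, b_cm, track_length: float) -> np.ndarray:
    """min(d, L - d) between positions in cm on a circular track."""
    d = np.abs(np.asarray(a_cm, dtype=float) - np.asarray(b_cm, dtype=float)) % track_length
    return np.minimum(d, track_length - d)


def window_posterior(fmap: np.ndarray, n: np.ndarray, duration_s: float) -> np.ndarray:
    """Normalized Poisson posterior over bins for one window.

    ``fmap`` is bins x cells (already floored), ``n`` the per-cell event sums
    and ``duration_s`` the retained window duration.  Uniform prior.
    """
    logpost = np.log(fmap) @ n - duration_s * fmap.sum(axis=1) - np.log(fmap.shape[0])
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def _training_ratemaps(binned: BinnedActivity, exclude_row: int | None, sigma: float) -> np.ndarray:
    """Occupancy-weighted mean rate per bin over all laps except ``exclude_row``."""
    rows = np.arange(binned.n_laps)
    if exclude_row is not None:
        rows = rows[rows != exclude_row]
    occ = binned.occupancy[rows]                      # laps x bins
    num = np.nan_to_num(binned.rate[rows], nan=0.0) * occ[:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        fmap = num.sum(axis=0) / occ.sum(axis=0)[:, None]
    fmap = np.nan_to_num(fmap, nan=0.0)               # bins x cells
    if sigma > 0:
        fmap = gaussian_filter1d(fmap, sigma=sigma, axis=0, mode="wrap")
    return fmap


def _iter_windows(idx: np.ndarray, times: np.ndarray, dt: np.ndarray, tau: float, min_frac: float):
    """Chunk retained sample indices of one lap into non-overlapping tau windows."""
    if idx.size == 0:
        return
    start = 0
    t0 = times[idx[0]]
    for k in range(1, idx.size + 1):
        if k == idx.size or times[idx[k]] - t0 >= tau:
            sel = idx[start:k]
            dur = float(dt[sel].sum())
            if dur >= min_frac * tau and k > start:
                yield sel, dur
            if k < idx.size:
                start = k
                t0 = times[idx[k]]


def decode_loocv(
    rec: SessionRecording,
    env: EnvironmentSpec,
    cfg: DecoderConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    signal: np.ndarray | None = None,
    binned: BinnedActivity | None = None,
    loocv: bool = True,
) -> DecoderOutput:
    """Decode position from population activity, leaving out the decoded lap.

    Training ratemaps come from the velocity-gated binned (deconvolved) signal
    of every other lap; test windows are non-overlapping ``tau``-length chunks
    of retained samples, truncated at lap boundaries.  ``loocv=False`` trains
    on all laps (sanity baseline).
    """
    cfg = cfg or DecoderConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    if signal is None:
        signal = get_signal(rec, "deconv", pre_cfg)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if binned is None:
        binned = bin_activity(rec, env, pre_cfg, signal_kind="deconv", signal=signal)
    if binned.n_laps < 3:
        raise ValueError("decoding requires at least 3 laps")

    times = rec.sample_times
    dt = np.empty(rec.n_samples)
    diffs = np.diff(times)
    dt[:-1] = diffs
    dt[-1] = diffs[-1] if diffs.size else 1.0 / rec.frame_rate_hz
    retained = rec.env_mask(env.name) & (rec.velocity >= pre_cfg.speed_floor)
    floor = cfg.rate_floor_events / cfg.tau
    centers = (np.arange(env.n_bins) + 0.5) * env.bin_size

    rows = []
    for row, lap in enumerate(binned.lap_ids):
        lap_idx = np.nonzero(retained & (rec.lap_index == lap))[0]
        fmap = np.maximum(
            _training_ratemaps(binned, row if loocv else None, cfg.ratemap_smooth_sigma), floor
        )
        n_win = 0
        for sel, dur in _iter_windows(lap_idx, times, dt, cfg.tau, cfg.min_window_frac):
            n = signal[:, sel].sum(axis=1)         # events per cell
            post = window_posterior(fmap, n, dur)
            decoded = int(np.argmax(post))
            mid = sel[len(sel) // 2]
            true_pos = rec.position[mid]
            if cfg.circular_error:
                err = float(circular_distance_cm(centers[decoded], true_pos, env.track_length))
            else:
                err = float(abs(centers[decoded] - true_pos))
            rows.append(
                {
                    "lap": int(lap),
                    "t_mid": float(times[mid]),
                    "duration_s": dur,
                    "decoded_bin": decoded,
                    "true_bin": int(env.position_to_bin(true_pos)),
                    "error_cm": err,
                }
            )
            n_win += 1
        if n_win == 0:
            logger.info("lap %d too short for a single decoding window; excluded", lap)

    windows = pd.DataFrame(rows)
    if windows.empty:
        raise ValueError("no decodable windows in environment " + env.name)
    per_lap = (
        windows.groupby("lap")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_error_cm": g["error_cm"].mean(),
                    "frac_above_threshold": float(
                        (g["duration_s"] * (g["error_cm"] > cfg.error_threshold)).sum()
                        / g["duration_s"].sum()
                    ),
                    "n_windows": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    mean_err = float(windows["error_cm"].mean())
    return DecoderOutput(
        windows=windows,
        per_lap=per_lap,
        mean_error_cm=mean_err,
        best5_error_cm=best_laps_error_from_series(per_lap["mean_error_cm"].to_numpy(), 5),
        track_length=env.track_length,
        n_bins=env.n_bins,
    )


def error_exceedance_by_lap(out: DecoderOutput, threshold: float | None = None) -> pd.Series:
    """Time-weighted fraction of each lap's decoded windows with error above threshold."""
    if threshold is None:
        frac = out.per_lap.set_index("lap")["frac_above_threshold"]
        return frac
    w = out.windows
    grp = w.groupby("lap").apply(
        lambda g: float(
            (g["duration_s"] * (g["error_cm"] > threshold)).sum() / g["duration_s"].sum()
        ),
        include_groups=False,
    )
    grp.name = "frac_above_threshold"
    return grp


def best_laps_error_from_series(per_lap_errors: np.ndarray, k: int = 5) -> float:
    errs = np.sort(np.asarray(per_lap_errors, dtype=float))
    if len(errs) < k:
        logger.info("only %d laps (< k=%d); using all laps", len(errs), k)
        k = len(errs)
    return float(errs[:k].mean())


def best_laps_error(out: DecoderOutput, k: int = 5) -> float:
    """Mean error over the k laps with the lowest per-lap mean error."""
    return best_laps_error_from_series(out.per_lap["mean_error_cm"].to_numpy(), k)
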