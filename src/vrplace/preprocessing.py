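"""Neuropil-corrected dF/F with a running-minimum baseline, and velocity-gated
occupancy-normalized position binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vrplace.session_io import EnvironmentSpec, SessionRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "BinnedActivity",
    "compute_dff",
    "bin_activity",
    "bin_velocity",
    "get_signal",
    "deconv_fallback",
]


@dataclass
class PreprocessConfig:
    """Parameters of the dF/F baseline and of position binning.

    ``t1`` is the running-average smoothing window, ``t2`` the trailing-minimum
    window used for the baseline; samples slower than ``speed_floor`` are
    dropped before binning.
    """

    neuropil_coeff: float = 0.7
    t1: float = 1.0
    t2: float = 15.0
    speed_floor: float = 1.0
    n_bins: int = 100
    centered_t1: bool = True

    def __post_init__(self):
        if not 0.0 <= self.neuropil_coeff <= 1.0:
            raise ValueError("neuropil_coeff must be in [0, 1]")
        if self.t1 > self.t2:
            raise ValueError("t1 must not exceed t2")
        if self.speed_floor < 0:
            raise ValueError("speed_floor must be nonnegative")


@dataclass
class BinnedActivity:
    """Occupancy-normalized rate tensor for one environment.

    ``rate`` is laps x bins x cells (NaN where the lap/bin was never occupied
    at or above the speed floor); ``occupancy`` is laps x bins in seconds and
    ``p_i`` the occupancy probability per bin.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    p_i: np.ndarray
    bin_size: float
    signal_kind: str
    environment: str = ""
    lap_ids: np.ndarray | None = None

    @property
    def n_laps(self) -> int:
        return self.rate.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rate.shape[1]

    @property
    def n_cells(self) -> int:
        return self.rate.shape[2]

    def lap_average(self, laps: np.ndarray | None = None) -> np.ndarray:
        """Mean rate over (a subset of) laps, bins x cells; NaN-aware."""
        r = self.rate if laps is None else self.rate[laps]
        with np.errstate(invalid="ignore"):
            return np.nanmean(r, axis=0)

    def select_laps(self, laps) -> "BinnedActivity":
        laps = np.asarray(laps)
        occ = self.occupancy[laps]
        tot = occ.sum()
        return BinnedActivity(
            rate=self.rate[laps],
            occupancy=occ,
            p_i=occ.sum(axis=0) / tot if tot > 0 else np.zeros(self.n_bins),
            bin_size=self.bin_size,
            signal_kind=self.signal_kind,
            environment=self.environment,
            lap_ids=self.lap_ids[laps] if self.lap_ids is not None else laps,
        )


def compute_dff(
    fluo_soma: np.ndarray,
    fluo_neuropil: np.ndarray | None,
    cfg: PreprocessConfig,
    frame_rate_hz: float,
) -> np.ndarray:
    """Compute dF/F0 from soma and surround traces.

    The corrected trace ``F = soma - c * neuropil`` is smoothed with a running
    mean over ``t1``; the baseline ``F0(t)`` is the minimum of the smoothed
    trace over the trailing window ``(t - t2, t]``; dF/F = (F - F0)/F0 with F0
    floored at a small scale-free epsilon.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    soma = np.atleast_2d(np.asarray(fluo_soma, dtype=float))
    if fluo_neuropil is not None:
        f = soma - cfg.neuropil_coeff * np.atleast_2d(np.asarray(fluo_neuropil, dtype=float))
    else:
        f = soma.copy()
    w1 = max(int(round(cfg.t1 * frame_rate_hz)), 1)
    w2 = int(round(cfg.t2 * frame_rate_hz))
    if w2 < 1:
        raise ValueError(f"t2={cfg.t2}s is shorter than one frame at {frame_rate_hz} Hz")

    df = pd.DataFrame(f.T)  # samples x cells
    smoothed = df.rolling(w1, center=cfg.centered_t1, min_periods=1).mean()
    f0 = smoothed.rolling(w2, min_periods=1).min().to_numpy().T

    # scale-free guard against division by a near-zero baseline
    scale = np.nanpercentile(np.abs(f), 95)
    eps = 1e-6 * scale if scale > 0 else 1e-6
    flagged = (f0 <= eps).any(axis=1)
    if flagged.any():
        logger.warning("nonpositive dF/F baseline floored for %d cell(s)", int(flagged.sum()))
    # numerator keeps the raw baseline so a flat-at-floor trace yields dff == 0
    return (f - f0) / np.maximum(f0, eps)


def deconv_fallback(dff: np.ndarray) -> np.ndarray:
    """Positive part of the dF/F first difference; stand-in for deconvolved events."""
    d = np.diff(dff, axis=-1, prepend=dff[..., :1])
    return np.maximum(d, 0.0)


def get_signal(rec: SessionRecording, signal_kind: str, cfg: PreprocessConfig | None = None):
    """Return the cells x samples matrix for ``signal_kind`` ('dff' or 'deconv').

    Computes dF/F from raw fluorescence when needed; substitutes the positive
    dF/F first difference (logged) when 'deconv' is requested but absent.
    """
    cfg = cfg or PreprocessConfig()
    if signal_kind == "dff":
        if rec.dff is not None:
            return rec.dff
        return compute_dff(rec.fluo_soma, rec.fluo_neuropil, cfg, rec.frame_rate_hz)
    if signal_kind == "deconv":
        if rec.deconv is not None:
            return rec.deconv
        logger.warning("deconv channel absent; falling back to positive dF/F first difference")
        return deconv_fallback(get_signal(rec, "dff", cfg))
    raise ValueError(f"unknown signal_kind {signal_kind!r}")


def _bin_accumulate(
    rec: SessionRecording,
    env: EnvironmentSpec,
    cfg: PreprocessConfig,
    signal: np.ndarray,
):
    """Shared accumulation: per-(lap,bin) signal*dt sums and dt sums."""
    mask = rec.env_mask(env.name) & (rec.velocity >= cfg.speed_floor)
    dt_all = np.empty(rec.n_samples)
    diffs = np.diff(rec.sample_times)
    dt_all[:-1] = diffs
    dt_all[-1] = diffs[-1] if diffs.size else 1.0 / rec.frame_rate_hz

    idx = np.nonzero(mask)[0]
    laps_present = np.unique(rec.lap_index[rec.env_mask(env.name)])
    lap_lookup = {int(l): i for i, l in enumerate(laps_present)}
    M, N = len(laps_present), env.n_bins

    bins = env.position_to_bin(rec.position[idx])
    lap_rows = np.array([lap_lookup[int(l)] for l in rec.lap_index[idx]], dtype=int)
    dt = dt_all[idx]

    flat = lap_rows * N + bins
    occ = np.bincount(flat, weights=dt, minlength=M * N).reshape(M, N)
    C = signal.shape[0]
    num = np.empty((M, N, C))
    for c in range(C):
        num[:, :, c] = np.bincount(flat, weights=signal[c, idx] * dt, minlength=M * N).reshape(M, N)
    return num, occ, laps_present


def bin_activity(
    rec: SessionRecording,
    env: EnvironmentSpec,
    cfg: PreprocessConfig | None = None,
    signal_kind: str = "dff",
    signal: np.ndarray | None = None,
) -> BinnedActivity:
    """Velocity-gated, occupancy-normalized laps x bins x cells rate tensor.

    Samples with velocity below ``cfg.speed_floor`` are excluded from both the
    numerator and the occupancy; per-(lap, bin) rate = sum(signal*dt)/sum(dt)
    over retained samples.  Entries with zero occupancy are NaN.
    """
    cfg = cfg or PreprocessConfig()
    if signal is None:
        signal = get_signal(rec, signal_kind, cfg)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    num, occ, laps_present = _bin_accumulate(rec, env, cfg, signal)

    empty = occ.sum(axis=1) == 0
    if empty.any():
        logger.info("%d lap(s) with no retained samples in %s", int(empty.sum()), env.name)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = num / occ[:, :, None]
    rate[occ == 0] = np.nan
    tot = occ.sum()
    p_i = occ.sum(axis=0) / tot if tot > 0 else np.zeros(env.n_bins)
    return BinnedActivity(
        rate=rate,
        occupancy=occ,
        p_i=p_i,
        bin_size=env.bin_size,
        signal_kind=signal_kind,
        environment=env.name,
        lap_ids=laps_present,
    )


def bin_velocity(
    rec: SessionRecording, env: EnvironmentSpec, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Occupancy-normalized laps x bins running speed (same gating as activity)."""
    binned = bin_activity(rec, env, cfg, signal_kind="velocity", signal=rec.velocity[None, :])
    return binned.rate[:, :, 0]
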