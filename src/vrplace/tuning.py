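"""Position-correlated cell classification, spatial information and sparsity.

A cell is a position-correlated cell (PCC) if it has at least one place field
passing a three-step criterion: (1) candidate peaks on the smoothed
lap-averaged trace with boundary growth, (2) lap-wise reliability of in-field
activity, (3) field-size bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vrplace.preprocessing import BinnedActivity
from vrplace.session_io import EnvironmentSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TuningConfig",
    "PlaceField",
    "PccResult",
    "detect_fields",
    "classify_pcc",
    "spatial_information",
    "sparsity",
    "order_by_peak",
    "circular_smooth",
    "circular_local_maxima",
]


@dataclass
class TuningConfig:
    peak_factor: float = 3.5        # candidate peaks > factor * trace median
    baseline_factor: float = 3.5    # lap reliability: in-field peak > factor * baseline
    reliability_frac: float = 1 / 3  # fraction of laps required (vs. 5, whichever greater)
    min_reliable_laps: int = 5
    min_size_cm: float = 20.0
    max_size_cm: float = 150.0
    smooth_bins: int = 5
    trough_frac: float = 0.7
    min_laps: int = 5
    percentiles_on_smoothed: bool = True


@dataclass
class PlaceField:
    """One detected place field with circular boundaries."""

    cell: int
    environment: str
    peak_bin: int
    boundary: tuple[int, int]           # circular inclusive interval [start, end]
    bins: np.ndarray                    # bin indices inside the boundary
    size_cm: float
    active_laps: np.ndarray             # lap rows with above-threshold in-field peaks
    onset_lap: int
    peak_rate: float


@dataclass
class PccResult:
    cell: int
    is_pcc: bool
    fields: list[PlaceField] = field(default_factory=list)
    si_bits: float = np.nan
    si_shuffle: np.ndarray | None = None
    si_p: float = np.nan
    sparsity: float = np.nan
    zone: str | None = None


# ---------------------------------------------------------------------------
# circular-trace helpers
# ---------------------------------------------------------------------------

def circular_smooth(trace: np.ndarray, window_bins: int = 5) -> np.ndarray:
    """Circular convolution with a normalized Hanning window."""
    kernel = np.hanning(window_bins)
    kernel = kernel / kernel.sum()
    n = len(trace)
    pad = window_bins  # enough context to make the convolution circular
    ext = np.concatenate([trace[-pad:], trace, trace[:pad]])
    sm = np.convolve(ext, kernel, mode="same")
    return sm[pad:pad + n]


def circular_local_maxima(trace: np.ndarray) -> np.ndarray:
    """Bins strictly greater than both circular neighbors; plateaus take the leftmost bin."""
    n = len(trace)
    out = []
    for i in range(n):
        left = trace[(i - 1) % n]
        right = trace[(i + 1) % n]
        if trace[i] > left and trace[i] >= right:
            # walk a plateau to its right edge; accept only if it then drops
            j = i
            while trace[(j + 1) % n] == trace[i] and j < i + n:
                j += 1
            if trace[(j + 1) % n] < trace[i]:
                out.append(i)
    return np.asarray(out, dtype=int)


def _grow_boundary(trace: np.ndarray, peak: int, median: float, trough_frac: float) -> tuple[int, int]:
    """Extend a candidate's boundary from its peak in both circular directions.

    Growth in a direction stops just before the trace drops below the trace
    median, or just before the nearest trough at which the trace has reached
    below ``trough_frac`` of the peak -- whichever comes first.  The stopping
    bin itself is outside the field.
    """
    n = len(trace)
    peak_val = trace[peak]
    edges = []
    for step in (-1, 1):
        last_good = peak
        for k in range(1, n // 2 + 1):
            j = (peak + step * k) % n
            v = trace[j]
            if v < median:
                break
            nxt = trace[(peak + step * (k + 1)) % n]
            prev = trace[(peak + step * (k - 1)) % n]
            if v <= trough_frac * peak_val and v <= prev and v <= nxt:
                break
            last_good = j
        edges.append(last_good)
    return edges[0], edges[1]  # (left edge, right edge)


def _interval_bins(start: int, end: int, n: int) -> np.ndarray:
    """Bins of the circular inclusive interval [start, end]."""
    if start <= end:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, n), np.arange(0, end + 1)])


# ---------------------------------------------------------------------------
# field detection
# ---------------------------------------------------------------------------

def detect_fields(
    binned: BinnedActivity,
    cell: int,
    cfg: TuningConfig | None = None,
) -> list[PlaceField]:
    """Apply the three-step place-field criterion to one cell."""
    cfg = cfg or TuningConfig()
    rate = binned.rate[:, :, cell]
    M, N = rate.shape
    if M < cfg.min_laps:
        logger.info("cell %d: only %d laps (< %d), skipping field detection", cell, M, cfg.min_laps)
        return []
    with np.errstate(invalid="ignore"):
        lap_avg = np.nanmean(rate, axis=0)
    lap_avg = np.nan_to_num(lap_avg, nan=0.0)
    if not np.any(lap_avg > 0):
        return []
    smoothed = circular_smooth(lap_avg, cfg.smooth_bins)
    ref_trace = smoothed if cfg.percentiles_on_smoothed else lap_avg
    trace_median = float(np.median(ref_trace))

    candidates = []
    for p in circular_local_maxima(smoothed):
        if smoothed[p] > cfg.peak_factor * trace_median:
            start, end = _grow_boundary(smoothed, p, trace_median, cfg.trough_frac)
            bins = _interval_bins(start, end, N)
            candidates.append((p, float(smoothed[p]), start, end, bins))

    # merge overlapping candidates, keeping the higher peak
    candidates.sort(key=lambda c: -c[1])
    kept: list[tuple] = []
    taken = np.zeros(N, dtype=bool)
    for cand in candidates:
        if taken[cand[4]].any():
            continue
        taken[cand[4]] = True
        kept.append(cand)

    vals = rate[np.isfinite(rate)]
    baseline = float(np.percentile(vals, 50) - np.percentile(vals, 5)) if vals.size else 0.0
    need = max(math.ceil(cfg.reliability_frac * M), cfg.min_reliable_laps)

    fields = []
    for p, peak_val, start, end, bins in kept:
        infield = rate[:, bins]
        with np.errstate(invalid="ignore"):
            lap_peaks = np.nanmax(np.where(np.isfinite(infield), infield, -np.inf), axis=1)
        active = np.nonzero(lap_peaks > cfg.baseline_factor * baseline)[0]
        if len(active) < need:
            continue
        # size = distance between the two boundary bins
        size_cm = (len(bins) - 1) * binned.bin_size
        if not (cfg.min_size_cm <= size_cm <= cfg.max_size_cm):
            continue
        fields.append(
            PlaceField(
                cell=cell,
                environment=binned.environment,
                peak_bin=int(p),
                boundary=(int(start), int(end)),
                bins=bins,
                size_cm=float(size_cm),
                active_laps=active,
                onset_lap=int(active.min()),
                peak_rate=peak_val,
            )
        )
    fields.sort(key=lambda f: f.peak_bin)
    return fields


# ---------------------------------------------------------------------------
# spatial information and sparsity
# ---------------------------------------------------------------------------

def _si_rate(p_i: np.ndarray, f_i: np.ndarray) -> float:
    f_i = np.nan_to_num(f_i, nan=0.0)
    fbar = float(np.sum(p_i * f_i))
    if fbar <= 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_i * f_i * np.log2(f_i / fbar)
    terms[f_i <= 0] = 0.0
    return float(np.sum(terms))


def spatial_information(
    binned: BinnedActivity,
    cell: int,
    n_shuffles: int = 100,
    seed: int | np.random.Generator | None = None,
    per_event: bool = False,
) -> tuple[float, np.ndarray]:
    """Spatial information of one cell (bits/s by default) plus its shuffle null.

    SI = sum_i p_i f_i log2(f_i / fbar) over bins with f_i > 0, where p_i is
    the occupancy probability and f_i the lap-averaged rate.  The null
    re-computes SI after circularly shifting each lap's binned activity by an
    independent random integer; exactly ``n_shuffles`` values are returned.
    ``per_event=True`` divides by fbar (bits per event).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = binned.rate[:, :, cell]
    M, N = rate.shape
    p_i = binned.p_i
    with np.errstate(invalid="ignore"):
        f_i = np.nanmean(rate, axis=0)
    si = _si_rate(p_i, f_i)
    if per_event:
        fbar = float(np.nansum(p_i * np.nan_to_num(f_i)))
        si = si / fbar if fbar > 0 else 0.0

    shifts = rng.integers(1, N, size=(n_shuffles, M))
    cols = (np.arange(N)[None, None, :] - shifts[:, :, None]) % N
    shifted = rate[np.arange(M)[None, :, None], cols]  # shuffles x laps x bins
    with np.errstate(invalid="ignore"):
        f_sh = np.nanmean(shifted, axis=1)
    null = np.array([_si_rate(p_i, f_sh[s]) for s in range(n_shuffles)])
    if per_event:
        fbars = np.nansum(p_i[None, :] * np.nan_to_num(f_sh), axis=1)
        null = np.divide(null, fbars, out=np.zeros_like(null), where=fbars > 0)
    return si, null


def sparsity(binned: BinnedActivity, cell: int) -> float:
    """Lifetime sparsity (sum p_i f_i)^2 / sum p_i f_i^2; NaN for silent cells."""
    with np.errstate(invalid="ignore"):
        f_i = np.nanmean(binned.rate[:, :, cell], axis=0)
    f_i = np.nan_to_num(f_i, nan=0.0)
    denom = float(np.sum(binned.p_i * f_i**2))
    if denom <= 0:
        return np.nan
    return float(np.sum(binned.p_i * f_i) ** 2 / denom)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def classify_pcc(
    binned: BinnedActivity,
    binned_si: BinnedActivity | None = None,
    env: EnvironmentSpec | None = None,
    cfg: TuningConfig | None = None,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> list[PccResult]:
    """Classify every cell; SI/sparsity use ``binned_si`` (deconvolved) when given."""
    cfg = cfg or TuningConfig()
    rng = np.random.default_rng(seed)
    si_src = binned_si if binned_si is not None else binned
    results = []
    for cell in range(binned.n_cells):
        fields = detect_fields(binned, cell, cfg)
        si, null = spatial_information(si_src, cell, n_shuffles=n_shuffles, seed=rng)
        si_p = float((np.sum(null >= si) + 1) / (len(null) + 1))
        zone = None
        if fields and env is not None:
            zone = env.zone_of_bin(fields[0].peak_bin)
        results.append(
            PccResult(
                cell=cell,
                is_pcc=bool(fields),
                fields=fields,
                si_bits=si,
                si_shuffle=null,
                si_p=si_p,
                sparsity=sparsity(si_src, cell),
                zone=zone,
            )
        )
    return results


def pcc_fraction(results: list[PccResult]) -> float:
    if not results:
        return np.nan
    return float(np.mean([r.is_pcc for r in results]))


def pcc_table(results: list[PccResult], environment: str = "") -> pd.DataFrame:
    """Tidy per-cell table (one row per cell)."""
    rows = []
    for r in results:
        f0 = r.fields[0] if r.fields else None
        rows.append(
            {
                "cell": r.cell,
                "env": environment,
                "is_pcc": r.is_pcc,
                "n_fields": len(r.fields),
                "peak_bin": f0.peak_bin if f0 else np.nan,
                "size_cm": f0.size_cm if f0 else np.nan,
                "si": r.si_bits,
                "si_shuffle_p": r.si_p,
                "sparsity": r.sparsity,
                "zone": r.zone,
            }
        )
    return pd.DataFrame(rows)


def order_by_peak(
    binned: BinnedActivity, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split-half peak ordering for population visualization.

    Peak bins are computed on a random 5 of the final 10 laps; the returned
    matrix (cells x bins) averages the complementary laps; the ordering sorts
    cells by peak bin ascending.  With fewer than 10 laps, odd laps order and
    even laps average (logged deviation).
    """
    rng = np.random.default_rng(seed)
    M = binned.n_laps
    if M >= 10:
        tail = np.arange(M - 10, M)
        pick = rng.choice(tail, size=5, replace=False)
        rest = np.setdiff1d(np.arange(M), pick)
    else:
        logger.info("fewer than 10 laps; ordering on odd laps, averaging on even laps")
        pick = np.arange(1, M, 2)
        rest = np.arange(0, M, 2)
    peak_src = binned.lap_average(np.sort(pick))
    peak_bins = np.nanargmax(np.nan_to_num(peak_src, nan=-np.inf), axis=0)
    order = np.argsort(peak_bins, kind="stable")
    heldout = binned.lap_average(rest).T  # cells x bins
    return order, heldout, peak_bins
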