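"""Object- vs position-reference-frame tuning via aligned windows and shuffles.

Activity is aligned, lap by lap, to a landmark (an object's actual slot, or a
fixed potential slot) over a short window of position bins.  A cell is tuned
to a landmark iff (1) its trial-averaged activity minus SEM exceeds the
97.5th percentile of a random-alignment null at some window bin, and (2) the
trial-and-bin-averaged window activity has a z-score above ``Z_CUTOFF``
against the null's window averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vrplace.preprocessing import BinnedActivity
from vrplace.session_io import EnvironmentSpec

logger = logging.getLogger(__name__)

__all__ = [
    "Z_CUTOFF",
    "ObjectTuningConfig",
    "TuningClassification",
    "align_activity",
    "shuffle_null",
    "landmark_tuned",
    "classify_tuning",
]

# one-sided standard normal 99% quantile (p = 0.01)
Z_CUTOFF = 2.3263


@dataclass
class ObjectTuningConfig:
    window_before: int = 2   # bins before the landmark bin
    window_after: int = 1    # bins after the landmark bin
    n_shuffles: int = 1000
    z_cutoff: float = Z_CUTOFF
    null_percentile: float = 97.5

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window_before, self.window_after + 1)


@dataclass
class TuningClassification:
    cell: int
    tuned_to_position: np.ndarray            # flag per potential slot
    tuned_to_object: np.ndarray | None       # flag per object (None if no object table)
    category: str                            # position | object | both | neither
    z_position: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_object: np.ndarray | None = None
    unclassifiable: bool = False


def align_activity(
    binned: BinnedActivity,
    landmark_bins: np.ndarray,
    cfg: ObjectTuningConfig | None = None,
    env: EnvironmentSpec | None = None,
) -> np.ndarray:
    """Extract the aligned window around a (possibly per-lap) landmark bin.

    ``landmark_bins`` is a scalar or a per-lap array of bin indices.  Returns
    a laps x window-bins x cells stack; alignment wraps circularly.  Landmarks
    inside the tunnel are rejected (objects never occupy the tunnel).
    """
    cfg = cfg or ObjectTuningConfig()
    lb = np.broadcast_to(np.asarray(landmark_bins, dtype=int), (binned.n_laps,))
    if env is not None:
        tunnel = set(env.tunnel_bins or env.default_tunnel_bins())
        bad = [int(b) for b in np.unique(lb) if int(b) in tunnel]
        if bad:
            raise ValueError(f"landmark bin(s) {bad} lie inside the tunnel")
    cols = (lb[:, None] + cfg.offsets[None, :]) % binned.n_bins  # laps x W
    return binned.rate[np.arange(binned.n_laps)[:, None], cols, :]


def shuffle_null(
    binned: BinnedActivity,
    permitted_bins: np.ndarray,
    cfg: ObjectTuningConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Null distribution of aligned-window statistics under random alignment.

    Each draw aligns every lap to an independently random permitted location;
    per draw, the per-window-bin lap means (draws x W x cells) and the
    window-averaged means (draws x cells) are recorded.
    """
    cfg = cfg or ObjectTuningConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    permitted = np.asarray(permitted_bins, dtype=int)
    W = len(cfg.offsets)
    bin_lap_means = np.empty((cfg.n_shuffles, W, binned.n_cells))
    window_means = np.empty((cfg.n_shuffles, binned.n_cells))
    lap_rows = np.arange(binned.n_laps)[:, None]
    for s in range(cfg.n_shuffles):
        lb = rng.choice(permitted, size=binned.n_laps)
        cols = (lb[:, None] + cfg.offsets[None, :]) % binned.n_bins
        aligned = binned.rate[lap_rows, cols, :]  # laps x W x cells
        with np.errstate(invalid="ignore"):
            blm = np.nanmean(aligned, axis=0)
            bin_lap_means[s] = blm
            window_means[s] = np.nanmean(blm, axis=0)
    return {"bin_lap_means": bin_lap_means, "window_means": window_means}


def landmark_tuned(
    aligned: np.ndarray,
    null: dict[str, np.ndarray],
    cfg: ObjectTuningConfig | None = None,
):
    """Apply the double criterion to one landmark's aligned stack, all cells at once.

    Returns ``(tuned, z, pass1, pass2, unclassifiable)`` arrays over cells.
    """
    cfg = cfg or ObjectTuningConfig()
    with np.errstate(invalid="ignore"):
        lap_mean = np.nanmean(aligned, axis=0)                 # W x cells
        n_laps = np.sum(np.isfinite(aligned), axis=0)          # W x cells
        sd = np.nanstd(aligned, axis=0, ddof=1)
        sem = np.where(n_laps > 1, sd / np.sqrt(np.maximum(n_laps, 1)), np.inf)
        pct = np.nanpercentile(null["bin_lap_means"], cfg.null_percentile, axis=0)  # W x cells
        pass1 = np.any(np.nan_to_num(lap_mean, nan=-np.inf) - sem > pct, axis=0)

        obs = np.nanmean(lap_mean, axis=0)                     # cells
        mu = np.nanmean(null["window_means"], axis=0)
        sigma = np.nanstd(null["window_means"], axis=0, ddof=1)
    unclassifiable = ~(sigma > 0)
    z = np.where(unclassifiable, np.nan, (obs - mu) / np.where(sigma > 0, sigma, 1.0))
    pass2 = np.nan_to_num(z, nan=-np.inf) > cfg.z_cutoff
    return pass1 & pass2, z, pass1, pass2, unclassifiable


def classify_tuning(
    binned: BinnedActivity,
    slot_bins: np.ndarray,
    object_bins_per_lap: np.ndarray | None = None,
    cfg: ObjectTuningConfig | None = None,
    seed: int | None = None,
    env: EnvironmentSpec | None = None,
) -> list[TuningClassification]:
    """Classify each cell as position-, object-, both- or neither-tuned.

    ``slot_bins`` are the six potential landmark bins; ``object_bins_per_lap``
    (laps x 4) gives each object's actual bin per lap.  The same per-cell
    random-alignment null is used for every landmark.
    """
    cfg = cfg or ObjectTuningConfig()
    rng = np.random.default_rng(seed)
    slot_bins = np.asarray(slot_bins, dtype=int)
    null = shuffle_null(binned, slot_bins, cfg, rng)

    pos_flags, pos_z = [], []
    for b in slot_bins:
        aligned = align_activity(binned, b, cfg, env)
        tuned, z, *_ , unc = landmark_tuned(aligned, null, cfg)
        pos_flags.append(tuned)
        pos_z.append(z)
    pos_flags = np.array(pos_flags).T       # cells x 6
    pos_z = np.array(pos_z).T

    obj_flags = obj_z = None
    if object_bins_per_lap is not None:
        object_bins_per_lap = np.asarray(object_bins_per_lap, dtype=int)
        flags, zs = [], []
        for j in range(object_bins_per_lap.shape[1]):
            aligned = align_activity(binned, object_bins_per_lap[:, j], cfg, env)
            tuned, z, *_, unc = landmark_tuned(aligned, null, cfg)
            flags.append(tuned)
            zs.append(z)
        obj_flags = np.array(flags).T       # cells x 4
        obj_z = np.array(zs).T

    # a cell is unclassifiable if its null has zero variance
    with np.errstate(invalid="ignore"):
        sigma = np.nanstd(null["window_means"], axis=0, ddof=1)
    unclassifiable = ~(sigma > 0)

    out = []
    for c in range(binned.n_cells):
        p = bool(pos_flags[c].any())
        o = bool(obj_flags[c].any()) if obj_flags is not None else False
        category = {(True, True): "both", (True, False): "position",
                    (False, True): "object", (False, False): "neither"}[(p, o)]
        out.append(
            TuningClassification(
                cell=c,
                tuned_to_position=pos_flags[c],
                tuned_to_object=obj_flags[c] if obj_flags is not None else None,
                category=category if not unclassifiable[c] else "neither",
                z_position=pos_z[c],
                z_object=obj_z[c] if obj_z is not None else None,
                unclassifiable=bool(unclassifiable[c]),
            )
        )
    return out


def tuning_table(classifications: list[TuningClassification]) -> pd.DataFrame:
    rows = []
    for tc in classifications:
        row = {"cell": tc.cell, "category": tc.category, "unclassifiable": tc.unclassifiable}
        for i, f in enumerate(tc.tuned_to_position):
            row[f"slot_{i}"] = bool(f)
            row[f"z_slot_{i}"] = float(tc.z_position[i])
        if tc.tuned_to_object is not None:
            for i, f in enumerate(tc.tuned_to_object):
                row[f"object_{i}"] = bool(f)
                row[f"z_object_{i}"] = float(tc.z_object[i])
        rows.append(row)
    return pd.DataFrame(rows)
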