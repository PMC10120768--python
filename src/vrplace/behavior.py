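"""Lick behavior scored against hidden reward sites.

Licks are binarized per (lap, position bin) so bursts count once.  The five
bins before each reward bin are anticipatory; the reward bin and the four
after it are post-reward and excluded from scoring.  Precision is the ratio
of anticipatory lick-bins to total-minus-post lick-bins; chance is exactly
10/90 = 1/9 on a 100-bin track with two reward sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from vrplace.session_io import EnvironmentSpec, SessionRecording

logger = logging.getLogger(__name__)

__all__ = ["LickSummary", "lick_precision", "precision_from_lick_bins", "lick_bin_matrix"]

N_ANTICIPATORY = 5
N_POST = 5
CHANCE_LEVEL = 10.0 / 90.0


@dataclass
class LickSummary:
    lick_bin_matrix: np.ndarray      # laps x n_bins binary
    anticipatory_count: int
    post_reward_count: int
    total_count: int
    precision: float
    chance_level: float = CHANCE_LEVEL
    alt_precision: float | None = None


def _window_bins(reward_bins, n_bins: int):
    """Anticipatory and post-reward bin sets, wrapping circularly.

    Anticipatory: the ``N_ANTICIPATORY`` bins before each reward bin.  Post:
    the reward bin itself plus the following ``N_POST - 1`` bins.
    """
    ant, post = set(), set()
    for r in reward_bins:
        for k in range(1, N_ANTICIPATORY + 1):
            ant.add((int(r) - k) % n_bins)
        for k in range(N_POST):
            post.add((int(r) + k) % n_bins)
    return np.array(sorted(ant)), np.array(sorted(post))


def lick_bin_matrix(rec: SessionRecording, env: EnvironmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Binary laps x bins matrix of lick occurrence in this environment."""
    mask = rec.env_mask(env.name)
    laps = np.unique(rec.lap_index[mask])
    lap_lookup = {int(l): i for i, l in enumerate(laps)}
    mat = np.zeros((len(laps), env.n_bins), dtype=bool)
    if rec.lick_times.size == 0:
        return mat, laps
    idx = np.searchsorted(rec.sample_times, rec.lick_times)
    idx = np.clip(idx, 0, rec.n_samples - 1)
    for i in idx:
        if not mask[i]:
            continue
        lap = int(rec.lap_index[i])
        if lap in lap_lookup:
            mat[lap_lookup[lap], int(env.position_to_bin(rec.position[i]))] = True
    return mat, laps


def precision_from_lick_bins(
    mat: np.ndarray,
    reward_bins,
    n_bins: int | None = None,
) -> tuple[float, int, int, int]:
    """Precision and counts from a binary laps x bins lick matrix."""
    n_bins = n_bins or mat.shape[1]
    ant_bins, post_bins = _window_bins(reward_bins, n_bins)
    total = int(mat.sum())
    ant = int(mat[:, ant_bins].sum())
    post = int(mat[:, post_bins].sum())
    scored = total - post
    precision = ant / scored if scored > 0 else np.nan
    return precision, ant, post, total


def lick_precision(
    rec: SessionRecording,
    env: EnvironmentSpec,
    alt_reward_bins=None,
) -> LickSummary:
    """Score licking against the environment's reward bins.

    ``alt_reward_bins`` scores the same licks against an alternative reward
    map (e.g. the former environment's reward locations).
    """
    mat, _ = lick_bin_matrix(rec, env)
    precision, ant, post, total = precision_from_lick_bins(mat, env.reward_bins, env.n_bins)
    if not np.isfinite(precision):
        logger.info("no scored lick-bins in %s; precision undefined", env.name)
    alt = None
    if alt_reward_bins is not None:
        alt = precision_from_lick_bins(mat, alt_reward_bins, env.n_bins)[0]
    return LickSummary(
        lick_bin_matrix=mat,
        anticipatory_count=ant,
        post_reward_count=post,
        total_count=total,
        precision=precision,
        alt_precision=alt,
    )
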