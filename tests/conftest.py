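import numpy as np
import pytest

from vrplace.preprocessing import BinnedActivity, PreprocessConfig, bin_activity
from vrplace.synthetic import ScenarioConfig, make_session


def make_binned(rate, bin_size=3.77, occupancy=None, signal_kind="dff", environment="env"):
    """BinnedActivity from a raw laps x bins x cells tensor (uniform occupancy default)."""
    rate = np.asarray(rate, dtype=float)
    if rate.ndim == 2:
        rate = rate[:, :, None]
    M, N, _ = rate.shape
    occ = np.ones((M, N)) if occupancy is None else np.asarray(occupancy, dtype=float)
    tot = occ.sum()
    return BinnedActivity(
        rate=rate,
        occupancy=occ,
        p_i=occ.sum(axis=0) / tot if tot > 0 else np.zeros(N),
        bin_size=bin_size,
        signal_kind=signal_kind,
        environment=environment,
        lap_ids=np.arange(M),
    )


def hann_bump_binned(
    span_bins,
    center=50,
    n_laps=20,
    n_bins=100,
    bin_size=3.77,
    bg=0.2,
    peak=3.0,
    active_laps=None,
    noise=0.0,
    seed=0,
):
    """Deterministic single-field tensor: Hanning bump of exact ``span_bins`` extent."""
    bump = np.zeros(n_bins)
    w = np.hanning(span_bins + 2)[1:-1]
    idx = (np.arange(span_bins) - span_bins // 2 + center) % n_bins
    bump[idx] = peak * w
    rate = np.full((n_laps, n_bins, 1), bg) + bump[None, :, None]
    if active_laps is not None:
        off = np.setdiff1d(np.arange(n_laps), active_laps)
        rate[off] = bg
    if noise > 0:
        rate += np.random.default_rng(seed).uniform(0, noise, rate.shape)
    return make_binned(rate, bin_size)


@pytest.fixture(scope="session")
def teleport_session():
    """Medium teleportation session reused across test modules."""
    cfg = ScenarioConfig(
        seed=11,
        n_cells=60,
        n_laps_familiar=12,
        n_laps_novel=16,
        track_length_familiar=377.0,
        track_length_novel=503.0,
    )
    rec, envs, truth = make_session(cfg)
    return cfg, rec, envs, truth


@pytest.fixture(scope="session")
def teleport_binned(teleport_session):
    """dff- and deconv-binned tensors for both environments of the shared session."""
    cfg, rec, envs, truth = teleport_session
    pre = PreprocessConfig()
    out = {}
    for env in envs:
        out[env.name] = {
            "dff": bin_activity(rec, env, pre, "dff"),
            "deconv": bin_activity(rec, env, pre, "deconv", signal=rec.deconv),
        }
    return out


@pytest.fixture(scope="session")
def shifting_session():
    cfg = ScenarioConfig(
        seed=21,
        scenario="shifting",
        n_cells=40,
        frac_pcc=0.4,
        frac_object=0.2,
        n_laps_main=18,
    )
    rec, envs, truth = make_session(cfg)
    return cfg, rec, envs, truth


@pytest.fixture(scope="session")
def destabilized_session():
    cfg = ScenarioConfig(
        seed=31,
        scenario="destabilized",
        n_cells=50,
        frac_pcc=0.6,
        n_laps_pre=12,
        n_laps_main=14,
        gain_jitter_sd=0.6,
        jitter_zone="B",
        jitter_epochs=("destabilized",),
    )
    rec, envs, truth = make_session(cfg)
    return cfg, rec, envs, truth
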