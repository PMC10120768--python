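import numpy as np
import pytest

from conftest import make_binned
from vrplace.preprocessing import PreprocessConfig, bin_activity, bin_velocity
from vrplace.remapping import (
    field_location_correlation,
    lap_peak_variability,
    overlap_vs_expected,
    speed_at_peak_variability,
    zone_epoch_means,
)
from vrplace.session_io import EnvironmentSpec
from vrplace.tuning import PccResult, PlaceField, classify_pcc


def _single_field_result(cell, peak_bin, env="fam"):
    f = PlaceField(
        cell=cell, environment=env, peak_bin=peak_bin,
        boundary=(peak_bin - 2, peak_bin + 2),
        bins=np.arange(peak_bin - 2, peak_bin + 3) % 100,
        size_cm=20.0, active_laps=np.arange(10), onset_lap=0, peak_rate=1.0,
    )
    return PccResult(cell=cell, is_pcc=True, fields=[f])


def _untuned(cell):
    return PccResult(cell=cell, is_pcc=False, fields=[])


# ---------------------------------------------------------------------------
# field-location correlation
# ---------------------------------------------------------------------------

def test_identical_locations_r_is_one():
    fam = [_single_field_result(c, 10 + 2 * c) for c in range(20)]
    nov = [_single_field_result(c, 10 + 2 * c, env="nov") for c in range(20)]
    r, n, p = field_location_correlation(fam, nov)
    assert r == pytest.approx(1.0)
    assert n == 20


def test_independent_locations_r_near_zero():
    rng = np.random.default_rng(0)
    cells = range(600)
    fam = [_single_field_result(c, int(rng.integers(0, 100))) for c in cells]
    nov = [_single_field_result(c, int(rng.integers(0, 100)), env="nov") for c in cells]
    r, n, p = field_location_correlation(fam, nov)
    assert abs(r) < 0.1
    assert n == 600


def test_tunnel_exclusion_window_is_five_bins():
    fam = [_single_field_result(0, 4), _single_field_result(1, 95),
           _single_field_result(2, 50), _single_field_result(3, 5),
           _single_field_result(4, 94)]
    nov = [_single_field_result(c, 30 + c, env="nov") for c in range(5)]
    r, n, p = field_location_correlation(fam, nov, exclude_tunnel=True)
    # bins 4 (< 5) and 95 (>= 95) are excluded; 5 and 94 are kept
    assert n == 3


def test_too_few_pairs_is_missing():
    fam = [_single_field_result(0, 10), _single_field_result(1, 20)]
    nov = [_single_field_result(0, 30, env="n"), _single_field_result(1, 40, env="n")]
    r, n, p = field_location_correlation(fam, nov)
    assert n == 2 and np.isnan(r)


def test_multi_field_cells_excluded():
    two = _single_field_result(0, 10)
    two.fields = two.fields * 2
    fam = [two, _single_field_result(1, 20), _single_field_result(2, 30),
           _single_field_result(3, 40)]
    nov = [_single_field_result(c, 50 + c, env="n") for c in range(4)]
    r, n, p = field_location_correlation(fam, nov)
    assert n == 3


# ---------------------------------------------------------------------------
# overlap vs expected
# ---------------------------------------------------------------------------

def _session_from_flags(fam_flags, nov_flags):
    fam = [(_single_field_result(c, 10) if f else _untuned(c)) for c, f in enumerate(fam_flags)]
    nov = [(_single_field_result(c, 20, "n") if f else _untuned(c)) for c, f in enumerate(nov_flags)]
    return fam, nov


def test_overlap_zero_when_p_fam_zero():
    fam, nov = _session_from_flags([False] * 50, [True] * 25 + [False] * 25)
    table, t, p = overlap_vs_expected([(fam, nov)])
    row = table.iloc[0]
    assert row.p_fam == 0 and row.p_both_expected == 0 and row.p_both_observed == 0


def test_overlap_product_law_under_independence():
    rng = np.random.default_rng(1)
    sessions = []
    for _ in range(200):
        fam_flags = rng.random(300) < 0.3
        nov_flags = rng.random(300) < 0.2
        sessions.append(_session_from_flags(fam_flags, nov_flags))
    table, t, p = overlap_vs_expected(sessions)
    assert table["p_both_expected"].mean() == pytest.approx(0.06, abs=0.01)
    # calibration: |mean difference| below 2 binomial standard errors
    se = np.sqrt(0.06 * 0.94 / 300) / np.sqrt(200)
    assert abs(table["difference"].mean()) < 2 * se


def test_overlap_recovers_planted_excess():
    rng = np.random.default_rng(2)
    pf, pn, excess = 0.3, 0.2, 0.02
    p_both = pf * pn + excess
    sessions = []
    for _ in range(120):
        u = rng.random(400)
        fam_flags = u < pf
        nov_flags = (u < p_both) | ((u >= pf) & (u < pf + pn - p_both))
        sessions.append(_session_from_flags(fam_flags, nov_flags))
    table, t, p = overlap_vs_expected(sessions)
    assert table["difference"].mean() == pytest.approx(excess, abs=0.01)
    assert p < 0.01


def test_overlap_empty_session_excluded():
    fam, nov = _session_from_flags([True] * 10, [True] * 10)
    table, t, p = overlap_vs_expected([(fam, nov), ([], [])])
    assert len(table) == 1


def test_overlap_expected_is_exact_product():
    fam, nov = _session_from_flags([True] * 30 + [False] * 70,
                                   [True] * 10 + [False] * 90)
    table, _, _ = overlap_vs_expected([(fam, nov)])
    row = table.iloc[0]
    assert row.p_both_expected == row.p_fam * row.p_nov


# ---------------------------------------------------------------------------
# rate-remapping variance
# ---------------------------------------------------------------------------

ENV = EnvironmentSpec(
    "object", 377.0, zone_boundaries={"B": (20, 70), "A": (70, 20)}
)


def _field_pop(rng, n_cells=12, n_laps=20, gain=None):
    """Cells with fields at spread peaks; optional per-lap per-cell gain matrix."""
    rate = np.zeros((n_laps, 100, n_cells))
    peaks = np.linspace(5, 95, n_cells).astype(int)
    for c in range(n_cells):
        d = np.abs(np.arange(100) - peaks[c])
        d = np.minimum(d, 100 - d)
        bump = 3.0 * np.exp(-(d**2) / 8.0)
        g = np.ones(n_laps) if gain is None else gain[:, c]
        rate[:, :, c] = g[:, None] * bump[None, :]
    rate += rng.uniform(0, 0.1, rate.shape)
    return make_binned(rate), peaks


def test_lap_peak_sd_zero_for_identical_laps():
    rate = np.tile(np.random.default_rng(3).random((1, 100, 4)), (12, 1, 1))
    b = make_binned(rate)
    pcc = [_single_field_result(c, 10) for c in range(4)]
    tab = lap_peak_variability(b, pcc, np.array(["all"] * 12), ENV)
    np.testing.assert_allclose(tab["sd_lap_peak"], 0.0, atol=1e-10)


def test_lap_peak_sd_invariant_to_additive_constant():
    rng = np.random.default_rng(4)
    b, peaks = _field_pop(rng)
    pcc = [_single_field_result(c, int(p)) for c, p in enumerate(peaks)]
    epochs = np.array(["pre"] * 10 + ["destab"] * 10)
    t1 = lap_peak_variability(b, pcc, epochs, ENV)
    b2 = make_binned(b.rate + 5.0)
    t2 = lap_peak_variability(b2, pcc, epochs, ENV)
    np.testing.assert_allclose(
        t1["sd_lap_peak"].to_numpy(), t2["sd_lap_peak"].to_numpy(), rtol=1e-8
    )


def test_lap_peak_variability_planted_zone_b_jitter():
    rng = np.random.default_rng(5)
    n_cells, n_laps = 12, 24
    peaks = np.linspace(5, 95, n_cells).astype(int)
    zones = [ENV.zone_of_bin(int(p)) for p in peaks]
    epochs = np.array(["pre"] * 12 + ["destabilized"] * 12)
    gain = np.ones((n_laps, n_cells))
    for c, z in enumerate(zones):
        if z == "B":
            gain[12:, c] = np.maximum(0.05, 1 + 0.8 * rng.standard_normal(12))
    b, _ = _field_pop(rng, n_cells, n_laps, gain)
    pcc = [_single_field_result(c, int(p)) for c, p in enumerate(peaks)]
    tab = lap_peak_variability(b, pcc, epochs, ENV)
    means = zone_epoch_means(tab, "sd_lap_peak").set_index(["zone", "epoch"])["sd_lap_peak"]
    target = means["B", "destabilized"]
    assert target > means["B", "pre"]
    assert target > means["A", "destabilized"]
    assert target > means["A", "pre"]
    # strictly greatest among the four zone x epoch means
    assert target == means.max()


def test_speed_at_peak_sd_zero_for_constant_speed():
    rng = np.random.default_rng(6)
    b, peaks = _field_pop(rng)
    vel = np.full((b.n_laps, 100), 15.0)
    pcc = [_single_field_result(c, int(p)) for c, p in enumerate(peaks)]
    tab = speed_at_peak_variability(b, vel, pcc, np.array(["all"] * b.n_laps), ENV)
    np.testing.assert_allclose(tab["sd_speed_at_peak"], 0.0, atol=1e-10)


def test_speed_at_peak_null_by_construction():
    # speed statistics identical across zones/epochs: no zone or epoch effect
    rng = np.random.default_rng(7)
    b, peaks = _field_pop(rng, n_cells=16, n_laps=24)
    vel = 15.0 + rng.standard_normal((24, 100))
    pcc = [_single_field_result(c, int(p)) for c, p in enumerate(peaks)]
    epochs = np.array(["pre"] * 12 + ["destabilized"] * 12)
    tab = speed_at_peak_variability(b, vel, pcc, epochs, ENV)
    means = zone_epoch_means(tab, "sd_speed_at_peak")["sd_speed_at_peak"]
    assert means.max() - means.min() < 0.5  # all ~1.0, no structured effect


def test_zone_relabeling_equivariance():
    rng = np.random.default_rng(8)
    b, peaks = _field_pop(rng)
    pcc = [_single_field_result(c, int(p)) for c, p in enumerate(peaks)]
    epochs = np.array(["all"] * b.n_laps)
    env_swapped = EnvironmentSpec(
        "object", 377.0, zone_boundaries={"A": (20, 70), "B": (70, 20)}
    )
    t1 = lap_peak_variability(b, pcc, epochs, ENV)
    t2 = lap_peak_variability(b, pcc, epochs, env_swapped)
    swap = {"A": "B", "B": "A"}
    assert list(t2["zone"]) == [swap[z] for z in t1["zone"]]
    np.testing.assert_allclose(t1["sd_lap_peak"], t2["sd_lap_peak"])


def test_destabilized_session_end_to_end(destabilized_session):
    cfg, rec, envs, truth = destabilized_session
    env = envs[0]
    pre = PreprocessConfig()
    b = bin_activity(rec, env, pre, "dff")
    pcc = classify_pcc(b, env=env, seed=0)
    epochs = truth.epochs_by_lap[np.asarray(b.lap_ids, dtype=int)]
    tab = lap_peak_variability(b, pcc, epochs, env)
    means = zone_epoch_means(tab, "sd_lap_peak").set_index(["zone", "epoch"])["sd_lap_peak"]
    assert means["B", "destabilized"] == means.max()
    vel = bin_velocity(rec, env, pre)
    sp = speed_at_peak_variability(b, vel, pcc, epochs, env)
    assert (sp["sd_speed_at_peak"] >= 0).all()
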