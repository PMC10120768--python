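import numpy as np
import pytest

from conftest import hann_bump_binned, make_binned
from vrplace.population_dynamics import (
    circular_com_cm,
    com_shift,
    com_shift_population_mean,
    field_size_by_lap,
    group_activity,
    in_out_ratio,
    pv_matrix,
    pv_timecourse,
)
from vrplace.synthetic import ScenarioConfig, make_session
from vrplace.preprocessing import PreprocessConfig, bin_activity
from vrplace.tuning import classify_pcc, detect_fields


def _random_binned(seed, n_laps=9, n_bins=100, n_cells=40):
    rng = np.random.default_rng(seed)
    return make_binned(rng.random((n_laps, n_bins, n_cells)))


# ---------------------------------------------------------------------------
# PV correlations
# ---------------------------------------------------------------------------

def test_pv_matrix_self_diag_is_one():
    b = _random_binned(0)
    pv = pv_matrix(b, b)
    assert pv.matrix.shape == (100, 100)
    np.testing.assert_allclose(np.diag(pv.matrix), 1.0, atol=1e-10)
    assert pv.diag_mean == pytest.approx(1.0)


def test_pv_matrix_transpose_symmetry():
    a, b = _random_binned(1), _random_binned(2)
    m_ab = pv_matrix(a, b).matrix
    m_ba = pv_matrix(b, a).matrix
    np.testing.assert_allclose(m_ab, m_ba.T, atol=1e-10)


def test_pv_matrix_independent_populations_near_zero():
    a, b = _random_binned(3, n_cells=200), _random_binned(4, n_cells=200)
    assert abs(pv_matrix(a, b).diag_mean) < 0.1


def test_pv_matrix_zero_variance_pv_missing():
    a = _random_binned(5)
    b = _random_binned(6)
    b.rate[:, 7, :] = 2.0  # bin 7 PV has zero variance across cells
    m = pv_matrix(a, b).matrix
    assert np.isnan(m[:, 7]).all()
    assert np.isfinite(m[0, 8])


def test_pv_matrix_requires_matching_dims():
    with pytest.raises(ValueError):
        pv_matrix(_random_binned(0, n_cells=10), _random_binned(1, n_cells=11))


def test_pv_timecourse_stable_population_all_ones():
    rng = np.random.default_rng(7)
    base = rng.random((1, 100, 30))
    fam = make_binned(np.tile(base, (6, 1, 1)))
    nov = make_binned(np.tile(base, (16, 1, 1)))
    tc = pv_timecourse(fam, nov)
    for variant in ("C", "D", "E"):
        assert np.allclose(tc[variant]["diag_mean"].dropna(), 1.0)


def test_pv_timecourse_global_remap_drop():
    rng = np.random.default_rng(8)
    fam_map = rng.random((1, 100, 120))
    nov_map = rng.random((1, 100, 120))  # independent code
    noise = lambda shape: 0.05 * rng.random(shape)
    fam = make_binned(np.tile(fam_map, (6, 1, 1)) + noise((6, 100, 120)))
    nov = make_binned(np.tile(nov_map, (16, 1, 1)) + noise((16, 100, 120)))
    tc = pv_timecourse(fam, nov)["C"]
    pre = tc[tc.env == "familiar"]["diag_mean"]
    post = tc[tc.env == "novel"]["diag_mean"]
    assert (pre >= 0.6).all()
    assert (post.abs() <= 0.1).all()


def test_pv_timecourse_seven_lap_pairing():
    nov = _random_binned(9, n_laps=16)
    fam = _random_binned(10, n_laps=6)
    tc = pv_timecourse(fam, nov)["E"]
    # first pairing is laps 0-2 vs laps 7-9; intervals advance by 3
    assert list(tc["lap_start"]) == [0, 3, 6]


# ---------------------------------------------------------------------------
# group activity
# ---------------------------------------------------------------------------

def _pcc_like(cells, flags):
    from vrplace.tuning import PccResult

    return [PccResult(cell=c, is_pcc=bool(f), fields=[]) for c, f in zip(cells, flags)]


def test_group_activity_stationary_near_zero():
    rng = np.random.default_rng(11)
    fam = make_binned(1.0 + 0.01 * rng.random((10, 50, 20)))
    nov = make_binned(1.0 + 0.01 * rng.random((10, 50, 20)))
    pf = _pcc_like(range(20), [True] * 10 + [False] * 10)
    pn = _pcc_like(range(20), [False] * 5 + [True] * 10 + [False] * 5)
    table, drops = group_activity(fam, nov, pf, pn)
    assert abs(table["z_activity"].mean()) < 0.2


def test_group_activity_recovers_planted_drop():
    # 'both' cells halve their rate in the novel environment
    rng = np.random.default_rng(12)
    n_cells = 30
    fam_rate = 2.0 + 0.05 * rng.random((10, 50, n_cells))
    nov_rate = 2.0 + 0.05 * rng.random((10, 50, n_cells))
    nov_rate[:, :, :10] *= 0.5   # 'both' cells halve
    nov_rate[:, :, 10:20] *= 0.3  # familiar-only cells fall away
    fam_rate[:, :, 20:] *= 0.3    # novel-only cells are quiet pre-switch
    fam, nov = make_binned(fam_rate), make_binned(nov_rate)
    pf = _pcc_like(range(n_cells), [True] * 10 + [True] * 10 + [False] * 10)
    pn = _pcc_like(range(n_cells), [True] * 10 + [False] * 10 + [True] * 10)
    table, drops = group_activity(fam, nov, pf, pn)
    assert drops["both"] == pytest.approx(50.0, abs=3.0)
    # familiar-only group declines after the switch; novel-only rises
    g = table.groupby(["group", "env"])["z_activity"].mean()
    assert g["familiar_only", "familiar"] > g["familiar_only", "novel"]
    assert g["novel_only", "novel"] > g["novel_only", "familiar"]


# ---------------------------------------------------------------------------
# in/out ratio
# ---------------------------------------------------------------------------

def test_in_out_ratio_uniform_is_one():
    b = make_binned(np.full((8, 100, 5), 1.3))
    tab = in_out_ratio(b)
    np.testing.assert_allclose(tab["ratio"], 1.0)


def test_in_out_ratio_window_is_30cm():
    # a field exactly 15 cm from the peak is inside; 16 cm away is outside
    n_bins = 100
    rate = np.ones((5, n_bins, 1))
    rate[:, 50, 0] = 10.0
    b = make_binned(rate, bin_size=3.0)  # 300 cm track; 30 cm window = +/-5 bins
    tab = in_out_ratio(b, peak_bins=np.array([50]), window_cm=30.0)
    in_mean = (10.0 + 10 * 1.0) / 11.0
    out_mean = 1.0
    np.testing.assert_allclose(tab["ratio"], in_mean / out_mean)


def test_in_out_ratio_planted_ramp_increases():
    rate = np.ones((12, 100, 6))
    for lap in range(12):
        rate[lap, 45:55, :] += 0.5 * lap
    tab = in_out_ratio(make_binned(rate))
    slope = np.polyfit(tab["lap"], tab["ratio"], 1)[0]
    assert slope > 0


# ---------------------------------------------------------------------------
# COM shift and field size
# ---------------------------------------------------------------------------

def test_circular_com_at_seam():
    # mass split across bins 99 and 0 -> COM at the seam, not mid-track
    com = circular_com_cm(np.array([99, 0]), np.array([1.0, 1.0]), 100, 3.77)
    d = min(com, 377.0 - com)
    assert d < 3.77


def test_com_shift_symmetric_stable_field_near_zero():
    b = hann_bump_binned(11)
    fields = detect_fields(b, 0)
    tab = com_shift(b, fields)
    assert np.abs(tab["com_offset_cm"]).max() < 1e-9


def test_com_shift_recovers_planted_drift():
    # field center moves -1 cm per lap
    n_laps, n_bins, bs = 18, 100, 3.77
    rate = np.zeros((n_laps, n_bins, 1))
    centers_cm = 200.0 - 1.0 * np.arange(n_laps)
    bins_cm = (np.arange(n_bins) + 0.5) * bs
    for lap in range(n_laps):
        d = np.abs(bins_cm - centers_cm[lap])
        d = np.minimum(d, n_bins * bs - d)
        rate[lap, :, 0] = 3.0 * np.exp(-(d**2) / (2 * 10.0**2))
    # fluctuating background gives the boundary walk a stopping point
    rate += np.random.default_rng(4).uniform(0, 0.2, rate.shape)
    b = make_binned(rate, bin_size=bs)
    fields = detect_fields(b, 0)
    assert len(fields) == 1
    tab = com_shift(b, fields)
    slope = np.polyfit(tab["laps_since_onset"], tab["com_offset_cm"], 1)[0]
    assert slope == pytest.approx(-1.0, rel=0.2)
    series = com_shift_population_mean(tab)
    assert series.iloc[0] > series.iloc[-1]


def test_com_shift_excludes_inactive_laps():
    active = [0, 2, 4, 6, 8, 10, 12, 14]
    b = hann_bump_binned(11, active_laps=active, bg=0.0, noise=0.3, seed=3)
    fields = detect_fields(b, 0)
    assert len(fields) == 1
    tab = com_shift(b, fields)
    assert set(tab["lap"]) == set(fields[0].active_laps)
    assert set(tab["lap"]).issubset(set(active))


def test_field_size_constant_field_is_one():
    b = hann_bump_binned(11)
    fields = detect_fields(b, 0)
    tab = field_size_by_lap(b, fields)
    np.testing.assert_allclose(tab["size_norm"], 1.0)
    assert (tab["size_bins"] <= len(fields[0].bins)).all()


def test_field_size_widening_field_increases():
    n_laps, n_bins = 16, 100
    rate = np.full((n_laps, n_bins, 1), 0.05)
    for lap in range(n_laps):
        half = 2 + lap // 3
        rate[lap, 50 - half: 50 + half + 1, 0] = 3.0
    b = make_binned(rate, bin_size=3.77)
    fields = detect_fields(b, 0)
    assert len(fields) == 1
    tab = field_size_by_lap(b, fields)
    slope = np.polyfit(tab["lap"], tab["size_norm"], 1)[0]
    assert slope > 0


@pytest.mark.parametrize("shift", [9, 51])
def test_com_and_size_rotation_equivariance(shift):
    b = hann_bump_binned(11, bg=0.0, noise=0.2, seed=5)
    rolled = make_binned(np.roll(b.rate, shift, axis=1), bin_size=b.bin_size)
    f0, f1 = detect_fields(b, 0), detect_fields(rolled, 0)
    t0, t1 = com_shift(b, f0), com_shift(rolled, f1)
    np.testing.assert_allclose(
        t0["com_offset_cm"].to_numpy(), t1["com_offset_cm"].to_numpy(), atol=1e-6
    )
    s0, s1 = field_size_by_lap(b, f0), field_size_by_lap(rolled, f1)
    np.testing.assert_allclose(s0["size_bins"].to_numpy(), s1["size_bins"].to_numpy())
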