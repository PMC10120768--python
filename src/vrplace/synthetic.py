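"""Synthetic VR sessions with planted ground truth.

Generates trajectories on circular tracks (with teleportation between a
familiar and a novel environment, or fixed/shifting/destabilized object
configurations), Poisson event trains from planted tuning curves, slow
calcium-like fluorescence with a shared neuropil component, and calibrated
lick behavior.  Every planted parameter is recorded so each analysis stage
can be checked by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vrplace.session_io import EnvironmentSpec, SessionRecording, write_session

__all__ = [
    "ScenarioConfig",
    "FieldTruth",
    "CellTruth",
    "GroundTruth",
    "generate_trajectory",
    "generate_object_table",
    "generate_population",
    "generate_licks",
    "make_session",
    "write_ground_truth",
]

N_OBJECTS = 4
N_SLOTS = 6


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Fully determines one synthetic session (bit-identical under ``seed``)."""

    scenario: str = "teleportation"  # teleportation | fixed | shifting | destabilized
    seed: int = 0
    # geometry
    track_length_familiar: float = 314.0
    track_length_novel: float = 503.0
    track_length_object: float = 377.0
    n_bins: int = 100
    tunnel_length: float = 30.0
    # laps
    n_laps_familiar: int = 12
    n_laps_novel: int = 18
    n_laps_pre: int = 12     # destabilized scenario: laps in the fixed epoch
    n_laps_main: int = 18    # object scenarios: laps in the (shifting/destabilized) epoch
    # trajectory
    frame_rate_hz: float = 7.0
    mean_speed: float = 15.0
    speed_sd: float = 3.0
    speed_tau_s: float = 2.0
    pause_prob_per_lap: float = 0.0
    pause_duration_s: float = 4.0
    # population
    n_cells: int = 80
    frac_pcc: float = 0.5
    frac_object: float = 0.0
    p_field_familiar: float = 1.0   # of PCC cells, probability of a familiar field
    p_field_novel: float = 0.6
    overlap_excess: float = 0.0     # added to the product law for joint allocation
    baseline_rate: float = 0.02     # events/s
    peak_rate: float = 3.0
    field_width_cm: float = 40.0
    onset_lap_max: int = 0          # novel-field onsets drawn from 0..max
    ramp_laps: int = 0              # laps to reach full in-field rate after onset
    com_drift_cm_per_lap: float = 0.0
    gain_jitter_sd: float = 0.0     # lap gain jitter in the jittered epoch/zone
    jitter_zone: str | None = "B"   # zone receiving jitter (object scenarios)
    jitter_epochs: tuple[str, ...] = ("destabilized",)
    rate_ceiling: float = 50.0
    # calcium
    decay_s: float = 1.5
    fluo_gain: float = 1.0
    fluo_offset: float = 100.0
    noise_sd: float = 0.5
    neuropil_sd: float = 2.0
    # behavior
    lick_precision_target: float = 0.4
    lick_rate_uniform: float = 0.05  # per-bin exploratory lick probability

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FieldTruth:
    environment: str
    center_cm: float
    width_cm: float
    peak_rate: float
    onset_lap: int = 0              # lap row within the environment
    com_drift_cm_per_lap: float = 0.0
    ramp_laps: int = 0


@dataclass
class CellTruth:
    cell: int
    kind: str                        # pcc | object_locked | untuned
    fields: list[FieldTruth] = field(default_factory=list)
    object_id: int | None = None
    object_offset_cm: float = 0.0    # distance behind the object
    gain_jitter_sd: float = 0.0
    jitter_epochs: tuple[str, ...] = ()
    zone: str | None = None


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    scenario: str
    epochs_by_lap: np.ndarray                 # epoch label per global lap
    object_table: np.ndarray | None = None    # laps x 4 slot indices
    switch_lap: int | None = None             # first lap of the second env/epoch

    def cells_of_kind(self, kind: str) -> list[int]:
        return [c.cell for c in self.cells if c.kind == kind]

    def cells_with_field_in(self, environment: str) -> list[int]:
        return [
            c.cell for c in self.cells if any(f.environment == environment for f in c.fields)
        ]


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _simulate_block(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    track_length: float,
    n_laps: int,
    lap0: int,
    v0: float,
):
    """One environment block: OU-like speed, integrated position, lap counter."""
    dt = 1.0 / cfg.frame_rate_hz
    theta = 1.0 / cfg.speed_tau_s
    pos, lap, v = 0.0, lap0, v0
    positions, velocities, laps = [], [], []
    pause_left = 0.0
    while lap < lap0 + n_laps:
        v += theta * (cfg.mean_speed - v) * dt + cfg.speed_sd * np.sqrt(2 * theta * dt) * rng.standard_normal()
        v = max(v, 1.5)
        if pause_left > 0:
            v_eff = 0.3  # below the 1 cm/s gate
            pause_left -= dt
        else:
            v_eff = v
            if cfg.pause_prob_per_lap > 0:
                # expected cfg.pause_prob_per_lap pauses per lap
                laps_per_sample = v_eff * dt / track_length
                if rng.random() < cfg.pause_prob_per_lap * laps_per_sample:
                    pause_left = cfg.pause_duration_s
        positions.append(pos)
        velocities.append(v_eff)
        laps.append(lap)
        pos += v_eff * dt
        if pos >= track_length:
            pos -= track_length
            lap += 1
    return (
        np.array(positions),
        np.array(velocities),
        np.array(laps, dtype=int),
        v,
    )


def generate_trajectory(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Times, position, velocity, lap index and environment label per sample."""
    rng = rng or cfg.rng()
    dt = 1.0 / cfg.frame_rate_hz
    blocks = []
    if cfg.scenario == "teleportation":
        blocks = [
            ("familiar", cfg.track_length_familiar, cfg.n_laps_familiar),
            ("novel", cfg.track_length_novel, cfg.n_laps_novel),
        ]
    elif cfg.scenario in ("fixed", "shifting"):
        blocks = [("object", cfg.track_length_object, cfg.n_laps_main)]
    elif cfg.scenario == "destabilized":
        blocks = [("object", cfg.track_length_object, cfg.n_laps_pre + cfg.n_laps_main)]
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")

    pos_l, vel_l, lap_l, env_l = [], [], [], []
    lap0, v0 = 0, cfg.mean_speed
    for name, L, n_laps in blocks:
        p, v, l, v0 = _simulate_block(cfg, rng, L, n_laps, lap0, v0)
        pos_l.append(p)
        vel_l.append(v)
        lap_l.append(l)
        env_l.append(np.full(len(p), name, dtype=object))
        lap0 = l[-1] + 1
    position = np.concatenate(pos_l)
    velocity = np.concatenate(vel_l)
    lap_index = np.concatenate(lap_l)
    env_id = np.concatenate(env_l)
    times = np.arange(len(position)) * dt
    return times, position, velocity, lap_index, env_id


# ---------------------------------------------------------------------------
# objects
# ---------------------------------------------------------------------------

def generate_object_table(
    cfg: ScenarioConfig,
    n_laps: int | None = None,
    rng: np.random.Generator | None = None,
    fixed: bool | None = None,
) -> np.ndarray:
    """Per-lap injective assignment of 4 objects into 6 slots (uniform over 360).

    ``fixed=True`` (or scenario 'fixed') repeats one constant row.
    """
    rng = rng or cfg.rng()
    if n_laps is None:
        n_laps = cfg.n_laps_main
    if fixed is None:
        fixed = cfg.scenario == "fixed"
    if fixed:
        row = np.array([0, 2, 3, 5])
        return np.tile(row, (n_laps, 1))
    return np.array([rng.permutation(N_SLOTS)[:N_OBJECTS] for _ in range(n_laps)])


def object_environment(cfg: ScenarioConfig, n_laps_table: int, table: np.ndarray) -> EnvironmentSpec:
    """377 cm two-zone environment with 6 zone-B slots and the given object table."""
    env = EnvironmentSpec(
        name="object",
        track_length=cfg.track_length_object,
        n_bins=cfg.n_bins,
        reward_bins=(40, 85),
        zone_boundaries={"B": (20, 70), "A": (70, 20)},  # A wraps through the seam/tunnel
        lap_object_table=table,
    )
    env.tunnel_bins = env.default_tunnel_bins(cfg.tunnel_length)
    slot_bins = np.linspace(23, 66, N_SLOTS).round().astype(int)
    env.object_slots = {"B": [float((b + 0.5) * env.bin_size) for b in slot_bins]}
    return env


def slot_bins_of(env: EnvironmentSpec) -> np.ndarray:
    return np.array([int(p / env.bin_size) for p in env.object_slots["B"]])


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _plan_cells(cfg: ScenarioConfig, rng: np.random.Generator, envs: list[EnvironmentSpec],
                epochs_by_lap: np.ndarray) -> list[CellTruth]:
    n_pcc = int(round(cfg.frac_pcc * cfg.n_cells))
    n_obj = int(round(cfg.frac_object * cfg.n_cells))
    kinds = ["pcc"] * n_pcc + ["object_locked"] * n_obj
    kinds += ["untuned"] * (cfg.n_cells - len(kinds))
    by_name = {e.name: e for e in envs}
    cells = []
    for i, kind in enumerate(kinds):
        ct = CellTruth(cell=i, kind=kind)
        if kind == "pcc":
            if cfg.scenario == "teleportation":
                pf, pn = cfg.p_field_familiar, cfg.p_field_novel
                p_both = min(pf, pn, max(0.0, pf * pn + cfg.overlap_excess))
                u = rng.random()
                has_fam = u < p_both or (p_both <= u < pf)
                has_nov = u < p_both or (pf <= u < pf + (pn - p_both))
                if has_fam:
                    L = by_name["familiar"].track_length
                    ct.fields.append(
                        FieldTruth(
                            "familiar",
                            center_cm=rng.uniform(0, L),
                            width_cm=cfg.field_width_cm,
                            peak_rate=cfg.peak_rate,
                            onset_lap=0,
                            com_drift_cm_per_lap=cfg.com_drift_cm_per_lap,
                        )
                    )
                if has_nov:
                    L = by_name["novel"].track_length
                    ct.fields.append(
                        FieldTruth(
                            "novel",
                            center_cm=rng.uniform(0, L),
                            width_cm=cfg.field_width_cm,
                            peak_rate=cfg.peak_rate,
                            onset_lap=int(rng.integers(0, cfg.onset_lap_max + 1)),
                            ramp_laps=cfg.ramp_laps,
                        )
                    )
            else:
                env = by_name["object"]
                center = rng.uniform(0, env.track_length)
                ct.fields.append(
                    FieldTruth(
                        "object",
                        center_cm=center,
                        width_cm=cfg.field_width_cm,
                        peak_rate=cfg.peak_rate,
                        onset_lap=0,
                    )
                )
                ct.zone = env.zone_of_bin(int(center / env.bin_size))
                if cfg.gain_jitter_sd > 0 and (cfg.jitter_zone is None or ct.zone == cfg.jitter_zone):
                    ct.gain_jitter_sd = cfg.gain_jitter_sd
                    ct.jitter_epochs = cfg.jitter_epochs
        elif kind == "object_locked":
            ct.object_id = int(rng.integers(0, N_OBJECTS))
            ct.object_offset_cm = float(rng.uniform(2.0, 8.0))
        cells.append(ct)
    return cells


def generate_population(
    cfg: ScenarioConfig,
    truth: GroundTruth,
    trajectory,
    envs: list[EnvironmentSpec],
    rng: np.random.Generator | None = None,
):
    """Poisson events and GCaMP-like fluorescence from the planted tuning curves.

    Returns ``(rate, deconv, fluo_soma, fluo_neuropil)``; ``deconv`` is the
    noiseless event train (the ground-truth channel).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    times, position, velocity, lap_index, env_id = trajectory
    by_name = {e.name: e for e in envs}
    n_samp = len(times)
    dt = 1.0 / cfg.frame_rate_hz
    rate = np.full((cfg.n_cells, n_samp), cfg.baseline_rate)

    # per-lap gain for each cell (ramp x jitter)
    lap_min = {}
    for env in envs:
        laps = np.unique(lap_index[env_id == env.name])
        lap_min[env.name] = int(laps.min()) if laps.size else 0

    slot_positions = None
    if truth.object_table is not None:
        env = by_name["object"]
        slot_positions = np.asarray(env.object_slots["B"], dtype=float)

    for ct in truth.cells:
        if ct.kind == "pcc":
            for f in ct.fields:
                env = by_name[f.environment]
                mask = env_id == f.environment
                if not mask.any():
                    continue
                lap_rel = lap_index[mask] - lap_min[f.environment]
                gains = _lap_gains(ct, f, lap_rel, truth.epochs_by_lap, lap_index[mask], rng)
                centers = (f.center_cm + f.com_drift_cm_per_lap * np.maximum(lap_rel - f.onset_lap, 0)) % env.track_length
                d = np.abs(position[mask] - centers)
                d = np.minimum(d, env.track_length - d)
                sigma = f.width_cm / 4.0
                rate[ct.cell, mask] += f.peak_rate * gains * np.exp(-(d**2) / (2 * sigma**2))
        elif ct.kind == "object_locked" and slot_positions is not None:
            env = by_name["object"]
            mask = env_id == "object"
            lap_rel = lap_index[mask] - lap_min["object"]
            lap_rel = np.clip(lap_rel, 0, len(truth.object_table) - 1)
            slots = truth.object_table[lap_rel, ct.object_id]
            centers = (slot_positions[slots] - ct.object_offset_cm) % env.track_length
            d = np.abs(position[mask] - centers)
            d = np.minimum(d, env.track_length - d)
            sigma = 4.0  # narrow, window-detectable bump
            rate[ct.cell, mask] += cfg.peak_rate * np.exp(-(d**2) / (2 * sigma**2))

    rate = np.minimum(rate, cfg.rate_ceiling)
    events = rng.poisson(rate * dt).astype(float)

    # exponential calcium kernel, instantaneous rise
    k_len = int(round(5 * cfg.decay_s * cfg.frame_rate_hz))
    kernel = np.exp(-np.arange(k_len) * dt / cfg.decay_s)
    neuropil_common = np.cumsum(rng.standard_normal(n_samp)) * 0.05
    neuropil_common -= neuropil_common.mean()
    fluo_soma = np.empty_like(events)
    fluo_neuropil = np.empty_like(events)
    for c in range(cfg.n_cells):
        ca = np.convolve(events[c], kernel)[:n_samp]
        npil = 10.0 + neuropil_common + cfg.neuropil_sd * 0.1 * rng.standard_normal(n_samp)
        fluo_neuropil[c] = npil
        fluo_soma[c] = (
            cfg.fluo_offset
            + cfg.fluo_gain * 10.0 * ca
            + 0.7 * npil
            + cfg.noise_sd * rng.standard_normal(n_samp)
        )
    return rate, events, fluo_soma, fluo_neuropil


def _lap_gains(
    ct: CellTruth,
    f: FieldTruth,
    lap_rel: np.ndarray,
    epochs_by_lap: np.ndarray,
    lap_global: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-sample gain combining onset, ramp and per-lap jitter (per-lap constant)."""
    max_lap = int(lap_rel.max()) + 1
    g = np.ones(max_lap)
    for l in range(max_lap):
        if l < f.onset_lap:
            g[l] = 0.0
        elif f.ramp_laps > 0:
            g[l] = min(1.0, (l - f.onset_lap + 1) / f.ramp_laps)
    if ct.gain_jitter_sd > 0:
        for l in range(max_lap):
            gl = int(lap_global[np.searchsorted(lap_rel, l)]) if np.any(lap_rel == l) else None
            epoch = epochs_by_lap[gl] if gl is not None and gl < len(epochs_by_lap) else None
            if epoch in ct.jitter_epochs:
                g[l] *= max(0.05, 1.0 + ct.gain_jitter_sd * rng.standard_normal())
    return g[lap_rel]


# ---------------------------------------------------------------------------
# licks
# ---------------------------------------------------------------------------

def generate_licks(
    cfg: ScenarioConfig,
    trajectory,
    env: EnvironmentSpec,
    precision_target: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Lick times calibrated so the expected measured precision equals the target.

    Each (lap, bin) lick-bin is an independent Bernoulli draw: probability
    ``q_u`` in the 90 non-anticipatory scored+post bins and ``q_a`` in the 10
    anticipatory bins, with ``q_a`` solved from the target precision.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if precision_target is None:
        precision_target = cfg.lick_precision_target
    if not 0.0 <= precision_target <= 1.0:
        raise ValueError("precision_target must be in [0, 1]")
    times, position, velocity, lap_index, env_id = trajectory
    n_bins = env.n_bins
    ant = set()
    for r in env.reward_bins:
        for k in range(1, 6):
            ant.add((int(r) - k) % n_bins)
    n_ant = len(ant)
    q_u = cfg.lick_rate_uniform
    if precision_target >= 1.0:
        q_u, q_a = 0.0, 0.5
    else:
        # E[precision] = n_ant*q_a / (n_ant*q_a + (n_bins - n_ant - n_post)*q_u)
        n_scored_other = n_bins - 2 * n_ant  # 80 bins: scored minus anticipatory
        q_a = precision_target * n_scored_other * q_u / (n_ant * (1 - precision_target))
        q_a = min(q_a, 1.0)

    mask = env_id == env.name
    laps = np.unique(lap_index[mask])
    lick_times = []
    bins_all = env.position_to_bin(position)
    for lap in laps:
        sel = np.nonzero(mask & (lap_index == lap))[0]
        lap_bins = bins_all[sel]
        for b in range(n_bins):
            q = q_a if b in ant else q_u
            if q > 0 and rng.random() < q:
                hits = sel[lap_bins == b]
                if hits.size:
                    lick_times.append(times[hits[hits.size // 2]])
    return np.sort(np.array(lick_times))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def make_session(cfg: ScenarioConfig):
    """Generate a full session: (SessionRecording, [EnvironmentSpec], GroundTruth)."""
    rng = cfg.rng()
    trajectory = generate_trajectory(cfg, rng)
    times, position, velocity, lap_index, env_id = trajectory
    n_total_laps = int(lap_index.max()) + 1

    if cfg.scenario == "teleportation":
        fam = EnvironmentSpec("familiar", cfg.track_length_familiar, cfg.n_bins,
                              reward_bins=(30, 70))
        fam.tunnel_bins = fam.default_tunnel_bins(cfg.tunnel_length)
        nov = EnvironmentSpec("novel", cfg.track_length_novel, cfg.n_bins,
                              reward_bins=(20, 60))
        nov.tunnel_bins = nov.default_tunnel_bins(cfg.tunnel_length)
        envs = [fam, nov]
        epochs = np.array(
            ["familiar"] * cfg.n_laps_familiar + ["novel"] * (n_total_laps - cfg.n_laps_familiar),
            dtype=object,
        )
        object_table = None
        switch_lap = cfg.n_laps_familiar
    else:
        if cfg.scenario == "destabilized":
            pre = generate_object_table(cfg, cfg.n_laps_pre, rng, fixed=True)
            main = generate_object_table(cfg, n_total_laps - cfg.n_laps_pre, rng, fixed=False)
            object_table = np.vstack([pre, main])
            epochs = np.array(
                ["pre"] * cfg.n_laps_pre + ["destabilized"] * (n_total_laps - cfg.n_laps_pre),
                dtype=object,
            )
            switch_lap = cfg.n_laps_pre
        else:
            object_table = generate_object_table(cfg, n_total_laps, rng,
                                                 fixed=cfg.scenario == "fixed")
            epochs = np.array([cfg.scenario] * n_total_laps, dtype=object)
            switch_lap = None
        envs = [object_environment(cfg, n_total_laps, object_table)]

    cells = _plan_cells(cfg, rng, envs, epochs)
    truth = GroundTruth(
        cells=cells,
        scenario=cfg.scenario,
        epochs_by_lap=epochs,
        object_table=object_table,
        switch_lap=switch_lap,
    )
    rate, events, fluo_soma, fluo_neuropil = generate_population(cfg, truth, trajectory, envs, rng)

    lick_times = np.empty(0)
    for env in envs:
        lick_times = np.concatenate(
            [lick_times, generate_licks(cfg, trajectory, env, rng=rng)]
        )
    lick_times = np.sort(lick_times)

    rec = SessionRecording(
        sample_times=times,
        position=position,
        velocity=velocity,
        lap_index=lap_index,
        environment_id=env_id,
        frame_rate_hz=cfg.frame_rate_hz,
        fluo_soma=fluo_soma,
        fluo_neuropil=fluo_neuropil,
        deconv=events,
        lick_times=lick_times,
        reward_times=np.empty(0),
    )
    return rec, envs, truth


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Sidecar: YAML summary plus a per-cell CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "scenario": truth.scenario,
        "epochs_by_lap": [str(e) for e in truth.epochs_by_lap],
        "switch_lap": truth.switch_lap,
    }
    (path / "ground_truth.yaml").write_text(yaml.safe_dump(meta))
    rows = []
    for ct in truth.cells:
        if ct.fields:
            for f in ct.fields:
                rows.append({"cell": ct.cell, "kind": ct.kind, **dataclasses.asdict(f),
                             "object_id": ct.object_id, "object_offset_cm": ct.object_offset_cm,
                             "gain_jitter_sd": ct.gain_jitter_sd, "zone": ct.zone})
        else:
            rows.append({"cell": ct.cell, "kind": ct.kind, "environment": None,
                         "center_cm": None, "width_cm": None, "peak_rate": None,
                         "onset_lap": None, "com_drift_cm_per_lap": None, "ramp_laps": None,
                         "object_id": ct.object_id, "object_offset_cm": ct.object_offset_cm,
                         "gain_jitter_sd": ct.gain_jitter_sd, "zone": ct.zone})
    pd.DataFrame(rows).to_csv(path / "ground_truth_cells.csv", index=False)
    if truth.object_table is not None:
        pd.DataFrame(
            truth.object_table, columns=[f"object_{i}" for i in range(N_OBJECTS)]
        ).to_csv(path / "object_table.csv", index=False)


def simulate_to_file(cfg: ScenarioConfig, out_path) -> None:
    """Write a session container plus its ground-truth sidecar next to it."""
    rec, envs, truth = make_session(cfg)
    write_session(out_path, rec, envs)
    write_ground_truth(Path(out_path).parent / (Path(out_path).stem + "_truth"), truth)
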