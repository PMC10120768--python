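"""Session data model, container I/O and session-level quality control.

A session is one imaging run: time-aligned fluorescence traces, the animal's
trajectory on a circular track, lick/reward events, and an environment label
per sample.  Sessions are stored either as a single HDF5 file or as a
directory of CSV files with identical names (for toolchain-free inspection).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentSpec",
    "SessionRecording",
    "QcVerdict",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "qc_session",
    "drop_partial_laps",
    "active_cells",
]


class SessionFormatError(ValueError):
    """The container is missing a mandatory array or attribute."""


class SessionValidationError(ValueError):
    """The container parsed but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentSpec:
    """Geometry and task layout of one circular-track environment.

    Bins are 0-based with half-open intervals ``[k*bin_size, (k+1)*bin_size)``;
    bins ``0`` and ``n_bins - 1`` are spatially adjacent.  Lap starts are at
    the tunnel midpoint, so the tunnel straddles the position-wrap seam.
    """

    name: str
    track_length: float
    n_bins: int = 100
    reward_bins: tuple[int, int] = (25, 75)
    tunnel_bins: tuple[int, ...] = ()
    zone_boundaries: dict[str, tuple[int, int]] | None = None
    object_slots: dict[str, list[float]] | None = None
    lap_object_table: np.ndarray | None = None  # laps x 4 objects -> slot index

    @property
    def bin_size(self) -> float:
        return self.track_length / self.n_bins

    def position_to_bin(self, position: np.ndarray) -> np.ndarray:
        """Map positions (cm) to bin indices, clipping float round-off at the seam."""
        b = np.floor(np.asarray(position) / self.bin_size).astype(int)
        return np.clip(b, 0, self.n_bins - 1)

    def default_tunnel_bins(self, tunnel_length: float = 30.0) -> tuple[int, ...]:
        """Bins covered by a tunnel centered on the lap seam (position 0)."""
        half = tunnel_length / 2.0
        centers = (np.arange(self.n_bins) + 0.5) * self.bin_size
        dist = np.minimum(centers, self.track_length - centers)
        return tuple(int(i) for i in np.nonzero(dist < half)[0])

    def zone_of_bin(self, b: int) -> str | None:
        if self.zone_boundaries is None:
            return None
        for zone, (lo, hi) in self.zone_boundaries.items():
            if lo <= hi:
                if lo <= b < hi:
                    return zone
            elif b >= lo or b < hi:  # range wraps through the seam
                return zone
        return None

    def validate(self) -> None:
        if self.n_bins <= 0 or self.track_length <= 0:
            raise SessionValidationError("n_bins and track_length must be positive")
        if len(self.reward_bins) != 2:
            raise SessionValidationError("reward_bins must hold exactly two bin indices")
        for b in self.reward_bins:
            if not (0 <= int(b) < self.n_bins):
                raise SessionValidationError(f"reward bin {b} outside [0, {self.n_bins})")
        if self.lap_object_table is not None:
            tab = np.asarray(self.lap_object_table)
            if tab.ndim != 2 or tab.shape[1] != 4:
                raise SessionValidationError("lap_object_table must be laps x 4")
            for lap_row in tab:
                if len(set(int(s) for s in lap_row)) != 4:
                    raise SessionValidationError(
                        "lap_object_table row is not an injective 4-into-slots assignment"
                    )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "track_length": float(self.track_length),
            "n_bins": int(self.n_bins),
            "reward_bins": [int(b) for b in self.reward_bins],
            "tunnel_bins": [int(b) for b in self.tunnel_bins],
        }
        if self.zone_boundaries is not None:
            d["zone_boundaries"] = {k: [int(v[0]), int(v[1])] for k, v in self.zone_boundaries.items()}
        if self.object_slots is not None:
            d["object_slots"] = {k: [float(x) for x in v] for k, v in self.object_slots.items()}
        if self.lap_object_table is not None:
            d["lap_object_table"] = np.asarray(self.lap_object_table).astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        tab = d.get("lap_object_table")
        return cls(
            name=d["name"],
            track_length=float(d["track_length"]),
            n_bins=int(d.get("n_bins", 100)),
            reward_bins=tuple(d.get("reward_bins", (25, 75))),
            tunnel_bins=tuple(d.get("tunnel_bins", ())),
            zone_boundaries={k: tuple(v) for k, v in d["zone_boundaries"].items()}
            if d.get("zone_boundaries")
            else None,
            object_slots=d.get("object_slots"),
            lap_object_table=np.asarray(tab, dtype=int) if tab is not None else None,
        )


@dataclass
class SessionRecording:
    """Time-aligned traces, trajectory and events for one imaging session.

    All cell-indexed arrays are ``cells x samples``.  ``position`` is cm along
    the current environment's track in ``[0, track_length)``; ``lap_index`` is
    non-decreasing and increments only at the position wrap.
    """

    sample_times: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    lap_index: np.ndarray
    environment_id: np.ndarray  # string label per sample
    frame_rate_hz: float
    fluo_soma: np.ndarray | None = None
    fluo_neuropil: np.ndarray | None = None
    dff: np.ndarray | None = None
    deconv: np.ndarray | None = None
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    @property
    def n_cells(self) -> int:
        for arr in (self.fluo_soma, self.dff, self.deconv):
            if arr is not None:
                return arr.shape[0]
        return 0

    def env_mask(self, env_name: str) -> np.ndarray:
        return self.environment_id == env_name

    def laps_in_env(self, env_name: str) -> np.ndarray:
        return np.unique(self.lap_index[self.env_mask(env_name)])

    def validate(self, environments: Sequence[EnvironmentSpec] | None = None) -> None:
        n = self.n_samples
        if self.fluo_soma is None and self.dff is None:
            raise SessionFormatError("session must contain fluo_soma or dff")
        for name in ("position", "velocity", "lap_index", "environment_id"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise SessionValidationError(f"{name} length {len(arr)} != sample_times length {n}")
        if n > 1 and np.any(np.diff(self.sample_times) <= 0):
            raise SessionValidationError("sample_times must be strictly increasing")
        if np.any(np.diff(self.lap_index) < 0):
            raise SessionValidationError("lap_index must be non-decreasing")
        ncell = self.n_cells
        for name in ("fluo_soma", "fluo_neuropil", "dff", "deconv"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (ncell, n):
                raise SessionValidationError(
                    f"{name} shape {arr.shape} != (cells={ncell}, samples={n})"
                )
        if self.deconv is not None and np.any(self.deconv < 0):
            raise SessionValidationError("deconv must be nonnegative everywhere")
        if environments:
            by_name = {e.name: e for e in environments}
            for name in np.unique(self.environment_id):
                if name not in by_name:
                    raise SessionValidationError(f"environment_id {name!r} has no EnvironmentSpec")
                env = by_name[name]
                pos = self.position[self.env_mask(name)]
                if pos.size and (pos.min() < 0 or pos.max() >= env.track_length):
                    raise SessionValidationError(
                        f"position outside [0, {env.track_length}) in environment {name!r}"
                    )


@dataclass
class QcVerdict:
    """Pass/fail verdict for session inclusion, with one reason per failed rule."""

    passed: bool
    reasons: list[str]
    n_laps_min: int
    n_active_cells: int
    decoder_err_familiar: float


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_DATASETS = {
    "time": "sample_times",
    "position": "position",
    "velocity": "velocity",
    "lap": "lap_index",
    "fluo_soma": "fluo_soma",
    "fluo_neuropil": "fluo_neuropil",
    "dff": "dff",
    "deconv": "deconv",
    "licks": "lick_times",
    "rewards": "reward_times",
}


def write_session(path, rec: SessionRecording, environments: Sequence[EnvironmentSpec]) -> None:
    """Write a session container (HDF5 file, or CSV directory if *path* has no suffix)."""
    path = Path(path)
    rec.validate(environments)
    env_yaml = yaml.safe_dump([e.to_dict() for e in environments])
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for ds, attr in _DATASETS.items():
                arr = getattr(rec, attr)
                if arr is not None:
                    f.create_dataset(ds, data=np.asarray(arr))
            labels = np.unique(rec.environment_id)
            codes = np.searchsorted(labels, rec.environment_id)
            f.create_dataset("env", data=codes.astype(np.int32))
            f.attrs["env_names"] = [str(x) for x in labels]
            f.attrs["frame_rate_hz"] = float(rec.frame_rate_hz)
            f.attrs["environments"] = env_yaml
    else:
        path.mkdir(parents=True, exist_ok=True)
        for ds, attr in _DATASETS.items():
            arr = getattr(rec, attr)
            if arr is None:
                continue
            arr = np.asarray(arr)
            if arr.ndim == 2:
                pd.DataFrame(arr.T).to_csv(path / f"{ds}.csv", index=False)
            else:
                pd.DataFrame({ds: arr}).to_csv(path / f"{ds}.csv", index=False)
        pd.DataFrame({"env": rec.environment_id}).to_csv(path / "env.csv", index=False)
        meta = {"frame_rate_hz": float(rec.frame_rate_hz), "environments": yaml.safe_load(env_yaml)}
        (path / "meta.yaml").write_text(yaml.safe_dump(meta))


def read_session(path) -> tuple[SessionRecording, list[EnvironmentSpec]]:
    """Read a session container written by :func:`write_session`.

    Raises :class:`SessionFormatError` when a mandatory array is missing and
    :class:`SessionValidationError` when an invariant fails.
    """
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no session container at {path}")
    if path.is_dir():
        rec, envs = _read_csv_dir(path)
    else:
        rec, envs = _read_hdf5(path)
    rec.validate(envs)
    _check_env_switches(rec, envs)
    return rec, envs


def _read_hdf5(path: Path) -> tuple[SessionRecording, list[EnvironmentSpec]]:
    with h5py.File(path, "r") as f:
        for mandatory in ("time", "position", "velocity", "lap", "env"):
            if mandatory not in f:
                raise SessionFormatError(f"missing mandatory array {mandatory!r}")
        if "fluo_soma" not in f and "dff" not in f:
            raise SessionFormatError("missing mandatory array: one of 'fluo_soma' or 'dff'")
        kwargs = {}
        for ds, attr in _DATASETS.items():
            kwargs[attr] = f[ds][()] if ds in f else None
        env_names = [str(x) for x in f.attrs["env_names"]]
        codes = f["env"][()]
        kwargs["environment_id"] = np.asarray(env_names, dtype=object)[codes]
        kwargs["frame_rate_hz"] = float(f.attrs["frame_rate_hz"])
        envs = [EnvironmentSpec.from_dict(d) for d in yaml.safe_load(f.attrs["environments"])]
    for attr in ("lick_times", "reward_times"):
        if kwargs[attr] is None:
            kwargs[attr] = np.empty(0)
    return SessionRecording(**kwargs), envs


def _read_csv_dir(path: Path) -> tuple[SessionRecording, list[EnvironmentSpec]]:
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise SessionFormatError("missing meta.yaml in CSV session directory")
    meta = yaml.safe_load(meta_path.read_text())
    kwargs = {}
    for ds, attr in _DATASETS.items():
        p = path / f"{ds}.csv"
        if not p.exists():
            kwargs[attr] = None
            continue
        df = pd.read_csv(p)
        arr = df.values.T if df.shape[1] > 1 else df.iloc[:, 0].to_numpy()
        kwargs[attr] = np.asarray(arr, dtype=float)
    for mandatory in ("sample_times", "position", "velocity", "lap_index"):
        if kwargs[mandatory] is None:
            raise SessionFormatError(f"missing mandatory array {mandatory!r}")
    if kwargs["fluo_soma"] is None and kwargs["dff"] is None:
        raise SessionFormatError("missing mandatory array: one of 'fluo_soma' or 'dff'")
    env_path = path / "env.csv"
    if not env_path.exists():
        raise SessionFormatError("missing mandatory array 'env'")
    kwargs["environment_id"] = pd.read_csv(env_path)["env"].astype(str).to_numpy(dtype=object)
    kwargs["lap_index"] = np.asarray(kwargs["lap_index"], dtype=int)
    for attr in ("lick_times", "reward_times"):
        if kwargs[attr] is None:
            kwargs[attr] = np.empty(0)
    kwargs["frame_rate_hz"] = float(meta["frame_rate_hz"])
    envs = [EnvironmentSpec.from_dict(d) for d in meta["environments"]]
    return SessionRecording(**kwargs), envs


def _check_env_switches(rec: SessionRecording, envs: Sequence[EnvironmentSpec]) -> None:
    by_name = {e.name: e for e in envs}
    switch = np.nonzero(rec.environment_id[1:] != rec.environment_id[:-1])[0] + 1
    for i in switch:
        env = by_name[str(rec.environment_id[i])]
        tunnel = env.tunnel_bins or env.default_tunnel_bins()
        b = int(env.position_to_bin(rec.position[i]))
        if b not in tunnel:
            raise SessionValidationError(
                f"environment switch at sample {i} lies in bin {b}, outside tunnel bins"
            )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def active_cells(rec: SessionRecording, dff_sd_factor: float = 3.0) -> np.ndarray:
    """Boolean mask of cells with at least one detected event.

    A cell counts as active if its deconvolved trace has any positive sample;
    without a deconvolved channel, if any dF/F sample exceeds ``dff_sd_factor``
    session-level standard deviations of that cell's trace.
    """
    if rec.deconv is not None:
        return (rec.deconv > 0).any(axis=1)
    dff = rec.dff
    if dff is None:
        raise SessionFormatError("neither deconv nor dff available for activity counting")
    sd = dff.std(axis=1, keepdims=True)
    return (dff > dff_sd_factor * sd).any(axis=1) & (sd[:, 0] > 0)


def qc_session(
    rec: SessionRecording,
    decoder_err_familiar: float,
    analyzed_envs: Sequence[str] | None = None,
    min_laps: int = 10,
    min_cells: int = 50,
    max_decoder_err: float = 30.0,
) -> QcVerdict:
    """Apply the three session-inclusion rules.

    A session fails iff any of: fewer than ``min_laps`` laps in an analyzed
    environment, fewer than ``min_cells`` active cells, or a mean familiar
    decoder error above ``max_decoder_err`` cm.
    """
    if analyzed_envs is None:
        analyzed_envs = [str(x) for x in np.unique(rec.environment_id)]
    lap_counts = {e: len(rec.laps_in_env(e)) for e in analyzed_envs}
    n_laps_min = min(lap_counts.values()) if lap_counts else 0
    n_active = int(active_cells(rec).sum())
    reasons = []
    if n_laps_min < min_laps:
        worst = min(lap_counts, key=lap_counts.get)
        reasons.append(
            f"only {n_laps_min} laps in environment {worst!r} (< {min_laps})"
        )
    if n_active < min_cells:
        reasons.append(f"only {n_active} active cells (< {min_cells})")
    if decoder_err_familiar > max_decoder_err:
        reasons.append(
            f"familiar decoder error {decoder_err_familiar:.1f} cm (> {max_decoder_err} cm)"
        )
    return QcVerdict(
        passed=not reasons,
        reasons=reasons,
        n_laps_min=n_laps_min,
        n_active_cells=n_active,
        decoder_err_familiar=float(decoder_err_familiar),
    )


def drop_partial_laps(
    rec: SessionRecording,
    environments: Sequence[EnvironmentSpec],
    min_coverage: float = 0.9,
) -> SessionRecording:
    """Drop incomplete first/last laps of each environment block.

    A lap is kept if its samples cover at least ``min_coverage`` of the track.
    Only the first and last lap of each contiguous environment block are ever
    candidates for removal.
    """
    by_name = {e.name: e for e in environments}
    keep = np.ones(rec.n_samples, dtype=bool)
    lap = rec.lap_index
    for env_name in np.unique(rec.environment_id):
        env = by_name[str(env_name)]
        mask = rec.env_mask(str(env_name))
        laps = np.unique(lap[mask])
        for l in (laps[0], laps[-1]):
            sel = mask & (lap == l)
            pos = rec.position[sel]
            if pos.size == 0:
                continue
            coverage = (pos.max() - pos.min()) / env.track_length
            if coverage < min_coverage:
                keep &= ~sel
                logger.info("dropping partial lap %d in environment %s", l, env_name)
    if keep.all():
        return rec
    out = dataclasses.replace(
        rec,
        sample_times=rec.sample_times[keep],
        position=rec.position[keep],
        velocity=rec.velocity[keep],
        lap_index=rec.lap_index[keep],
        environment_id=rec.environment_id[keep],
    )
    for attr in ("fluo_soma", "fluo_neuropil", "dff", "deconv"):
        arr = getattr(rec, attr)
        if arr is not None:
            setattr(out, attr, arr[:, keep])
    return out
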