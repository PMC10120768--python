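"""End-to-end orchestration: QC, preprocessing, tuning, decoding, dynamics,
remapping, object tuning and behavior, with tidy CSV outputs and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import vrplace
from vrplace import behavior as behavior_mod
from vrplace import decoding, object_tuning, population_dynamics, remapping, tuning
from vrplace.preprocessing import PreprocessConfig, bin_activity, bin_velocity, get_signal
from vrplace.session_io import drop_partial_laps, qc_session, read_session

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"

ALL_STAGES = ("qc", "tuning", "decode", "dynamics", "remap", "objects", "behavior")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "drop_partial_laps": True,
    "stages": list(ALL_STAGES),
    "preprocess": {},
    "tuning": {},
    "decoder": {},
    "object_tuning": {},
    "behavior": {},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config over the documented defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if overrides:
        cfg.update(overrides)
    return cfg


def _save(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _stage_seed(seed: int, stage: str) -> int:
    # namespaced per-stage seeds so disabling one stage cannot shift another's draws
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def run_pipeline(session_path, config: dict | None = None, out_dir="vrplace_out") -> Path:
    """Run the enabled stages on one session container; returns the report directory.

    Each stage writes tidy CSVs under ``out_dir``; a JSON manifest records the
    package version, seed, enabled stages and a content hash per output file.
    A QC failure skips the remaining stages with a logged reason.
    """
    config = config or load_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config))
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))

    rec, envs = read_session(session_path)
    if config.get("drop_partial_laps", True):
        rec = drop_partial_laps(rec, envs)
    pre_cfg = PreprocessConfig(**config.get("preprocess", {}))
    tun_cfg = tuning.TuningConfig(**config.get("tuning", {}))
    dec_cfg = decoding.DecoderConfig(**config.get("decoder", {}))

    dff = get_signal(rec, "dff", pre_cfg)
    deconv = get_signal(rec, "deconv", pre_cfg)
    binned_dff = {e.name: bin_activity(rec, e, pre_cfg, "dff", signal=dff) for e in envs}
    binned_dec = {e.name: bin_activity(rec, e, pre_cfg, "deconv", signal=deconv) for e in envs}
    env_by_name = {e.name: e for e in envs}
    summary: dict = {
        "session": str(session_path),
        "seed": seed,
        "environments": [e.name for e in envs],
    }

    current = "setup"
    try:
        # ---- decoding (also feeds QC) -----------------------------------
        dec_out: dict[str, decoding.DecoderOutput] = {}
        if "decode" in stages or "qc" in stages:
            current = "decode"
            for e in envs:
                try:
                    o = decoding.decode_loocv(
                        rec, e, dec_cfg, pre_cfg, signal=deconv, binned=binned_dec[e.name]
                    )
                except ValueError as exc:
                    logger.warning("decoding skipped for %s: %s", e.name, exc)
                    continue
                dec_out[e.name] = o
                if "decode" in stages:
                    _save(o.windows, out / f"decode_windows_{e.name}.csv")
                    _save(o.per_lap, out / f"decode_per_lap_{e.name}.csv")
                summary[f"decoder_error_cm_{e.name}"] = o.mean_error_cm
                summary[f"decoder_error_best5_cm_{e.name}"] = o.best5_error_cm

        # ---- QC ---------------------------------------------------------
        if "qc" in stages:
            current = "qc"
            fam_name = "familiar" if "familiar" in env_by_name else envs[0].name
            fam_err = dec_out[fam_name].mean_error_cm if fam_name in dec_out else np.inf
            verdict = qc_session(rec, fam_err)
            summary["qc_passed"] = verdict.passed
            summary["qc_reasons"] = verdict.reasons
            (out / "qc.json").write_text(json.dumps(verdict.__dict__, indent=2, default=str))
            if not verdict.passed:
                logger.warning("session failed QC (%s); remaining stages skipped",
                               "; ".join(verdict.reasons))
                stages = [s for s in stages if s in ("qc",)]

        # ---- tuning -----------------------------------------------------
        pcc: dict[str, list[tuning.PccResult]] = {}
        if "tuning" in stages or "dynamics" in stages or "remap" in stages:
            current = "tuning"
            for e in envs:
                res = tuning.classify_pcc(
                    binned_dff[e.name],
                    binned_si=binned_dec[e.name],
                    env=e,
                    cfg=tun_cfg,
                    seed=_stage_seed(seed, f"tuning:{e.name}"),
                )
                pcc[e.name] = res
                if "tuning" in stages:
                    _save(tuning.pcc_table(res, e.name), out / f"pcc_{e.name}.csv")
                summary[f"pcc_fraction_{e.name}"] = tuning.pcc_fraction(res)

        # ---- population dynamics ---------------------------------------
        if "dynamics" in stages:
            current = "dynamics"
            for e in envs:
                b = binned_dff[e.name]
                order, heldout, peaks = tuning.order_by_peak(
                    b, seed=_stage_seed(seed, f"order:{e.name}")
                )
                _save(
                    pd.DataFrame({"cell": order, "peak_bin": peaks[order]}),
                    out / f"peak_order_{e.name}.csv",
                )
                _save(population_dynamics.in_out_ratio(b), out / f"in_out_ratio_{e.name}.csv")
                fields = [f for r in pcc[e.name] for f in r.fields]
                _save(population_dynamics.com_shift(b, fields, tun_cfg),
                      out / f"com_shift_{e.name}.csv")
                _save(population_dynamics.field_size_by_lap(b, fields),
                      out / f"field_size_{e.name}.csv")
            if "familiar" in binned_dff and "novel" in binned_dff:
                tc = population_dynamics.pv_timecourse(
                    binned_dff["familiar"], binned_dff["novel"]
                )
                for variant, df in tc.items():
                    _save(df, out / f"pv_timecourse_{variant}.csv")
                ga, drops = population_dynamics.group_activity(
                    binned_dff["familiar"], binned_dff["novel"], pcc["familiar"], pcc["novel"]
                )
                _save(ga, out / "group_activity.csv")
                summary["group_activity_drop_pct"] = drops

        # ---- remapping --------------------------------------------------
        if "remap" in stages:
            current = "remap"
            if "familiar" in pcc and "novel" in pcc:
                r, n, p = remapping.field_location_correlation(pcc["familiar"], pcc["novel"])
                r_x, n_x, p_x = remapping.field_location_correlation(
                    pcc["familiar"], pcc["novel"], exclude_tunnel=True
                )
                table, t, tp = remapping.overlap_vs_expected([(pcc["familiar"], pcc["novel"])])
                _save(table, out / "overlap.csv")
                summary["field_location_r"] = r
                summary["field_location_r_no_tunnel"] = r_x
            for e in envs:
                if e.zone_boundaries is None:
                    continue
                epochs = _epochs_for_env(rec, e, binned_dff[e.name], config)
                if len(pd.unique(epochs)) < 1:
                    continue
                var = remapping.lap_peak_variability(
                    binned_dff[e.name], pcc[e.name], epochs, e
                )
                _save(var, out / f"lap_peak_variability_{e.name}.csv")
                vel = bin_velocity(rec, e, pre_cfg)
                sp = remapping.speed_at_peak_variability(
                    binned_dff[e.name], vel, pcc[e.name], epochs, e
                )
                _save(sp, out / f"speed_at_peak_variability_{e.name}.csv")

        # ---- object tuning ----------------------------------------------
        if "objects" in stages:
            current = "objects"
            for e in envs:
                if e.lap_object_table is None or e.object_slots is None:
                    continue
                slot_bins = np.array([int(p / e.bin_size) for p in e.object_slots["B"]])
                table = np.asarray(e.lap_object_table)
                b = binned_dff[e.name]
                table = table[: b.n_laps]
                obj_bins = slot_bins[table]
                oc_kwargs = config.get("object_tuning", {})
                oc = object_tuning.ObjectTuningConfig(**oc_kwargs)
                cls = object_tuning.classify_tuning(
                    b, slot_bins, obj_bins, oc,
                    seed=_stage_seed(seed, f"objects:{e.name}"), env=e,
                )
                _save(object_tuning.tuning_table(cls), out / f"object_tuning_{e.name}.csv")
                cats = pd.Series([c.category for c in cls]).value_counts(normalize=True)
                summary[f"object_tuning_fractions_{e.name}"] = cats.to_dict()

        # ---- behavior ---------------------------------------------------
        if "behavior" in stages:
            current = "behavior"
            rows = []
            for e in envs:
                s = behavior_mod.lick_precision(rec, e)
                rows.append(
                    {
                        "env": e.name,
                        "precision": s.precision,
                        "anticipatory": s.anticipatory_count,
                        "post_reward": s.post_reward_count,
                        "total": s.total_count,
                        "chance_level": s.chance_level,
                    }
                )
                summary[f"lick_precision_{e.name}"] = s.precision
            _save(pd.DataFrame(rows), out / "behavior.csv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current!r} failed on session {session_path}: {exc}"
        ) from exc

    manifest = {
        "version": vrplace.__version__,
        "seed": seed,
        "stages": stages,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return out


def _epochs_for_env(rec, env, binned, config) -> np.ndarray:
    """Epoch label per binned lap row: from config, or a single default epoch."""
    epoch_cfg = config.get("epochs")
    lap_ids = binned.lap_ids
    if epoch_cfg is None:
        return np.array(["all"] * len(lap_ids), dtype=object)
    if isinstance(epoch_cfg, dict) and "switch_lap" in epoch_cfg:
        sw = int(epoch_cfg["switch_lap"])
        return np.array(
            [epoch_cfg.get("pre_label", "pre") if l < sw else epoch_cfg.get("post_label", "post")
             for l in lap_ids],
            dtype=object,
        )
    labels = np.asarray(epoch_cfg, dtype=object)
    return labels[np.asarray(lap_ids, dtype=int)]
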