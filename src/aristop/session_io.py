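"""Session bundles on disk and result writers.

A session bundle is a directory holding ``trials.csv`` (one row per trial),
``session.json`` (configuration, seeds, MVC, staircase history and generator
ground truth) and optionally ``emg/trial_NNNN.csv`` (one sample column per
channel). Synthetic sessions can omit the EMG files: traces are regenerated
bit-identically from the recorded per-trial seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNELS, HANDS, RunConfig
from .errors import SessionLoadError
from .types import Session, StaircaseState, SuppressionInterval, TrialRecord

logger = logging.getLogger(__name__)

__all__ = ["write_session", "read_session", "write_cohort", "read_cohort",
           "write_results"]

_TRIAL_COLUMNS = ["index", "block", "trial_type", "ssd", "rt_left",
                  "rt_right", "outcome", "feedback"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_session(session: Session, out_dir: str | Path,
                  with_emg: bool = False) -> Path:
    """Serialize a session bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = session.trials_df()[_TRIAL_COLUMNS]
    df.to_csv(out / "trials.csv", index=False)

    meta = {
        "participant": session.participant,
        "seed": session.seed,
        "mvc": session.mvc,
        "emg_seeds": session.emg_seeds,
        "config": session.config.to_dict(),
        "config_hash": session.config.config_hash(),
        "staircase": {
            "ssd": session.staircase.ssd,
            "step": session.staircase.step,
            "history": session.staircase.history,
        },
        "ground_truth": {t.index: _jsonable(t.ground_truth)
                         for t in session.trials},
        "emg_on_disk": bool(with_emg),
    }
    (out / "session.json").write_text(json.dumps(meta, indent=2))

    if with_emg:
        emg_dir = out / "emg"
        emg_dir.mkdir(exist_ok=True)
        for trial in session.trials:
            traces = session.emg_for_trial(trial.index)
            pd.DataFrame({ch: traces[ch].samples for ch in CHANNELS}).to_csv(
                emg_dir / f"trial_{trial.index:04d}.csv", index=False)
    return out


def _trial_from_row(row: pd.Series, ground_truth: dict) -> TrialRecord:
    response = {h: (None if pd.isna(row[f"rt_{h}"]) else float(row[f"rt_{h}"]))
                for h in HANDS}
    return TrialRecord(
        index=int(row["index"]), block=int(row["block"]),
        trial_type=str(row["trial_type"]),
        ssd=None if pd.isna(row["ssd"]) else float(row["ssd"]),
        response_time=response, outcome=str(row["outcome"]),
        feedback=str(row["feedback"]),
        ground_truth=ground_truth.get(str(int(row["index"])), {}))


def read_session(path: str | Path) -> Session:
    """Load a session bundle written by :func:`write_session`."""
    base = Path(path)
    meta_path = base / "session.json"
    trials_path = base / "trials.csv"
    if not meta_path.exists():
        raise SessionLoadError(f"missing sidecar {meta_path}")
    if not trials_path.exists():
        raise SessionLoadError(f"missing trial table {trials_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as err:
        raise SessionLoadError(f"corrupt JSON sidecar {meta_path}: {err}")
    for field in ("participant", "seed", "mvc", "emg_seeds", "config"):
        if field not in meta:
            raise SessionLoadError(f"sidecar missing field '{field}'")
    df = pd.read_csv(trials_path, float_precision="round_trip")
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SessionLoadError(f"trials.csv missing columns {sorted(missing)}")

    config = RunConfig.from_dict(meta["config"])
    ground_truth = meta.get("ground_truth", {})
    trials = [_trial_from_row(row, ground_truth) for _, row in df.iterrows()]

    if meta.get("emg_on_disk"):
        emg_dir = base / "emg"
        for t in trials:
            f = emg_dir / f"trial_{t.index:04d}.csv"
            if not f.exists():
                raise SessionLoadError(
                    f"trial {t.index} has no EMG file ({f})")

    sc = meta.get("staircase", {})
    staircase = StaircaseState(
        ssd=sc.get("ssd", config.session.initial_ssd()),
        step=sc.get("step", config.session.staircase_step),
        history=[tuple(h) for h in sc.get("history", [])])
    return Session(participant=meta["participant"], config=config,
                   seed=int(meta["seed"]), mvc=float(meta["mvc"]),
                   trials=trials, staircase=staircase,
                   emg_seeds=[int(s) for s in meta["emg_seeds"]])


def write_cohort(sessions: list[Session], out_dir: str | Path,
                 with_emg: bool = False) -> Path:
    out = Path(out_dir)
    for s in sessions:
        write_session(s, out / s.participant, with_emg=with_emg)
    return out


def read_cohort(path: str | Path) -> list[Session]:
    base = Path(path)
    dirs = sorted(d for d in base.iterdir() if (d / "session.json").exists())
    if not dirs:
        raise SessionLoadError(f"no session bundles under {base}")
    return [read_session(d) for d in dirs]


# ---------------------------------------------------------------------------

def _interval_dict(interval: SuppressionInterval | None) -> dict | None:
    return None if interval is None else dataclasses.asdict(interval)


def write_results(out_dir: str | Path,
                  pointwise: dict | None = None,
                  intervals: dict | None = None,
                  behavior: pd.DataFrame | None = None,
                  events: pd.DataFrame | None = None,
                  provenance: dict | None = None) -> Path:
    """Write analysis outputs as deterministic CSV/JSON.

    ``pointwise`` maps a comparison label to a PointwiseTestResult,
    ``intervals`` maps a label to a SuppressionInterval (or None). Every file
    embeds provenance (config hash, seed) when given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = provenance or {}
    if pointwise:
        for label, res in sorted(pointwise.items()):
            df = pd.DataFrame({
                "time_ms": res.times,
                "t": res.t_values,
                "p": res.p_values,
                "fdr_sig": res.fdr_mask.astype(int),
            })
            df.to_csv(out / f"pointwise_{label}.csv", index=False)
    if intervals is not None:
        payload = {"provenance": provenance,
                   "intervals": {label: _interval_dict(iv)
                                 for label, iv in sorted(intervals.items())}}
        (out / "intervals.json").write_text(json.dumps(payload, indent=2))
    if behavior is not None:
        behavior.to_csv(out / "behavior.csv")
    if events is not None:
        events.to_csv(out / "events.csv", index=False)
    if provenance:
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
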