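"""Readers and writers for the pipeline's file formats.

Two on-disk formats:

* **trial logs** — comma-separated text with a header row (one line per
  Go/Nogo trial) and ``#``-prefixed metadata lines carrying the seed and
  config hash;
* **epoch bundles** — a single HDF5 container with a shared ``/time_ms``
  axis, one dataset per epoch under ``/epochs``, and labels stored as
  attributes.

Pipeline configuration is plain YAML.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .epochs import ErpEpoch
from .synth import DatasetBundle, TrialRecord

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "config_hash",
    "read_trial_log",
    "write_trial_log",
    "read_epoch_bundle",
    "write_epoch_bundle",
    "load_yaml_config",
]

TRIAL_LOG_COLUMNS = ("subject_id", "group", "shape", "trial_index",
                     "is_different", "response", "response_time_ms",
                     "is_correct")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def config_hash(config: Any) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------- trial logs

def write_trial_log(trials: Sequence[TrialRecord], path: str | Path,
                    seed: int | None = None,
                    cfg_hash: str | None = None) -> None:
    """Write a trial log as headered CSV with ``#`` metadata lines."""
    path = Path(path)
    df = pd.DataFrame([{
        "subject_id": t.subject_id, "group": t.group, "shape": t.shape,
        "trial_index": t.trial_index, "is_different": t.is_different,
        "response": t.response,
        "response_time_ms": "" if t.response_time_ms is None
        else repr(t.response_time_ms),
        "is_correct": t.is_correct,
    } for t in trials], columns=list(TRIAL_LOG_COLUMNS))
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _parse_bool(v: Any) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial log.

    Malformed rows are rejected with a warning naming their line numbers;
    a ``response='none'`` row is coerced to ``is_correct=False`` (a trial
    without a click can never be correct).  A missing column raises,
    naming the column; a header-only file returns an empty list with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str,
                     keep_default_na=False, skip_blank_lines=True)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing required "
                         f"column(s): {missing}")
    if df.empty:
        warnings.warn(f"trial log {path} contains a header but no rows")
        return []

    records: list[TrialRecord] = []
    bad: list[tuple[int, str]] = []
    n_meta = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                n_meta += 1
            else:
                break
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = n_meta + 2 + pos  # header occupies the line after metadata
        try:
            rt_raw = row.response_time_ms.strip()
            response = row.response.strip()
            is_correct = _parse_bool(row.is_correct)
            if response == "none":
                is_correct = False  # enforce the no-response invariant
            records.append(TrialRecord(
                subject_id=row.subject_id,
                group=row.group,
                shape=row.shape,
                trial_index=int(row.trial_index),
                is_different=_parse_bool(row.is_different),
                response=response,
                response_time_ms=None if rt_raw == "" else float(rt_raw),
                is_correct=is_correct,
            ))
        except (ValueError, TypeError) as exc:
            bad.append((line_no, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad)
        warnings.warn(f"trial log {path}: rejected {len(bad)} malformed "
                      f"row(s) ({detail})")
    return records


# -------------------------------------------------------------- epoch bundles

_EPOCH_ATTRS = ("subject_id", "group", "condition", "shape")


def write_epoch_bundle(bundle: DatasetBundle | Sequence[ErpEpoch],
                       path: str | Path,
                       seed: int | None = None,
                       cfg_hash: str | None = None) -> None:
    """Write epochs (plus any trial log) to a single HDF5 container.

    All epochs must share one sample rate and time axis; a mismatch is an
    error because the bundle stores the axis once.
    """
    if isinstance(bundle, DatasetBundle):
        epochs = bundle.epochs
        trials = bundle.trials
        if seed is None:
            seed = bundle.seed
    else:
        epochs, trials = list(bundle), []
    if len(epochs) == 0:
        raise ValueError("cannot write an empty epoch bundle")
    first = epochs[0]
    for ep in epochs[1:]:
        if ep.sample_rate_hz != first.sample_rate_hz:
            raise ValueError("sample-rate mismatch across epochs in one bundle")
        if not np.array_equal(ep.time_ms, first.time_ms):
            raise ValueError("time-axis mismatch across epochs in one bundle")

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "erpsign-epoch-bundle"
        f.attrs["sample_rate_hz"] = first.sample_rate_hz
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if cfg_hash is not None:
            f.attrs["config_hash"] = cfg_hash
        f.create_dataset("time_ms", data=first.time_ms)
        grp = f.create_group("epochs")
        for i, ep in enumerate(epochs):
            ds = grp.create_dataset(f"{i:06d}", data=ep.amplitude_uV)
            for attr in _EPOCH_ATTRS:
                ds.attrs[attr] = getattr(ep, attr)
        if trials:
            tg = f.create_group("trials")
            cols: dict[str, list] = {c: [] for c in TRIAL_LOG_COLUMNS}
            for t in trials:
                for c in TRIAL_LOG_COLUMNS:
                    v = getattr(t, c)
                    cols[c].append(np.nan if v is None else v)
            for c, vals in cols.items():
                arr = np.asarray(vals)
                if arr.dtype.kind in ("U", "O"):
                    arr = arr.astype(h5py.string_dtype())
                tg.create_dataset(c, data=arr)


def read_epoch_bundle(path: str | Path) -> DatasetBundle:
    """Read a bundle back; a truncated or foreign file raises cleanly."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "erpsign-epoch-bundle":
                raise ValueError(f"{path} is not an epoch bundle")
            rate = float(f.attrs["sample_rate_hz"])
            seed = int(f.attrs.get("seed", -1))
            time_ms = f["time_ms"][()]
            epochs = []
            for key in sorted(f["epochs"].keys()):
                ds = f["epochs"][key]
                epochs.append(ErpEpoch(
                    time_ms=time_ms.copy(), amplitude_uV=ds[()],
                    sample_rate_hz=rate,
                    **{a: str(ds.attrs[a]) for a in _EPOCH_ATTRS}))
            trials: list[TrialRecord] = []
            if "trials" in f:
                tg = f["trials"]
                cols = {c: tg[c][()] for c in TRIAL_LOG_COLUMNS}
                n = len(cols["subject_id"])
                for i in range(n):
                    rt = cols["response_time_ms"][i]
                    trials.append(TrialRecord(
                        subject_id=cols["subject_id"][i].decode(),
                        group=cols["group"][i].decode(),
                        shape=cols["shape"][i].decode(),
                        trial_index=int(cols["trial_index"][i]),
                        is_different=bool(cols["is_different"][i]),
                        response=cols["response"][i].decode(),
                        response_time_ms=None if np.isnan(rt) else float(rt),
                        is_correct=bool(cols["is_correct"][i])))
    except OSError as exc:
        raise ValueError(f"cannot read epoch bundle {path}: {exc}") from exc
    return DatasetBundle(epochs=epochs, trials=trials, seed=seed)


# ------------------------------------------------------------------- configs

def load_yaml_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML key-value configuration file as a dict."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
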