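"""Readers and writers: epochs (HDF5 or CSV), results tables, JSON
summaries, YAML configs.

All text formats are UTF-8.  Epochs HDF5 layout: datasets ``/data``
(words x sensors x times, float64) and ``/words`` (UTF-8 labels), root
attributes ``sfreq`` (Hz) and ``tmin`` (seconds).  JSON summaries embed the
configuration echo, its hash, and the seeds used, so every output can be
traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .decoding import EpochsArray


def config_hash(config: Dict[str, Any]) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha1(blob).hexdigest()[:12]


def write_epochs_h5(epochs: EpochsArray, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "words", data=np.array(epochs.words, dtype=h5py.string_dtype("utf-8"))
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin"] = epochs.tmin


def read_epochs_h5(path: str | Path) -> EpochsArray:
    with h5py.File(path, "r") as f:
        for key in ("data", "words"):
            if key not in f:
                raise ValueError(f"{path}: missing dataset /{key}")
        for attr in ("sfreq", "tmin"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing attribute {attr}")
        data = f["data"][()]
        words = [w.decode("utf-8") if isinstance(w, bytes) else str(w) for w in f["words"][()]]
        return EpochsArray(data, float(f.attrs["sfreq"]), float(f.attrs["tmin"]), words)


def write_epochs_csv(epochs: EpochsArray, path: str | Path) -> None:
    """Small-fixture alternative: long CSV ``word,sensor,sample,value`` with
    ``# sfreq=... tmin=...`` header comments."""
    n_w, n_s, n_t = epochs.data.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sfreq={epochs.sfreq} tmin={epochs.tmin}\n")
        fh.write("word,sensor,sample,value\n")
        for i, w in enumerate(epochs.words):
            for s in range(n_s):
                for t in range(n_t):
                    fh.write(f"{w},{s},{t},{float(epochs.data[i, s, t])!r}\n")


def read_epochs_csv(path: str | Path) -> EpochsArray:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata comment line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh, float_precision="round_trip")
    words = list(dict.fromkeys(df["word"]))
    n_s = int(df["sensor"].max()) + 1
    n_t = int(df["sample"].max()) + 1
    data = np.zeros((len(words), n_s, n_t))
    widx = {w: i for i, w in enumerate(words)}
    data[df["word"].map(widx), df["sensor"], df["sample"]] = df["value"]
    return EpochsArray(data, float(meta["sfreq"]), float(meta["tmin"]), words)


def write_results_tsv(df: pd.DataFrame, path: str | Path, meta: Optional[Dict] = None) -> None:
    """TSV with ``#``-prefixed metadata lines (config hash, seeds, units)."""
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(f"# config_hash={config_hash(meta)}\n")
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json_summary(obj: Dict[str, Any], path: str | Path, config: Optional[Dict] = None) -> None:
    out = dict(obj)
    if config is not None:
        out["config"] = config
        out["config_hash"] = config_hash(config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(x: Any) -> Any:
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"cannot serialize {type(x)}")


def load_config_yaml(path: str | Path) -> Dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg
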