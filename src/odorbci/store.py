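"""HDF5 persistence for epoched sessions.

Layout: one group per participant, one subgroup per modality holding
``data``, ``times``, ``labels`` and ``intensity`` datasets, with ``sfreq``
and ``modality`` attributes; the file root carries ``schema_version``, the
generator config hash and the seed. Round trips are bit-exact. Events are
additionally exportable as a BIDS-like tab-separated table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import EpochSet

__all__ = ["SCHEMA_VERSION", "write_store", "read_store", "export_events",
           "config_hash"]

SCHEMA_VERSION = "1"


def config_hash(obj) -> str:
    """Stable short hash of a (nested, dataclass-friendly) configuration."""
    import dataclasses

    def enc(o):
        if dataclasses.is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_store(session: dict[str, EpochSet], path: str | Path, *,
                participant_id: str | None = None, seed: int | None = None,
                cfg_hash: str = "", mode: str = "a") -> Path:
    """Persist one participant's session (all modalities) to an HDF5 file."""
    path = Path(path)
    first = next(iter(session.values()))
    pid = participant_id or first.participant_id
    with h5py.File(path, mode) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if cfg_hash:
            f.attrs["config_hash"] = cfg_hash
        if seed is not None:
            f.attrs["seed"] = seed
        grp = f.require_group(pid)
        for name, es in session.items():
            if name in grp:
                del grp[name]
            g = grp.create_group(name)
            g.create_dataset("data", data=es.data)
            g.create_dataset("times", data=es.times)
            g.create_dataset("labels", data=es.labels)
            g.create_dataset("intensity",
                             data=np.array([str(s) for s in es.intensity],
                                           dtype=h5py.string_dtype()))
            g.attrs["sfreq"] = es.sfreq
            g.attrs["modality"] = es.modality
    return path


def read_store(path: str | Path,
               participant_id: str | None = None) -> dict[str, EpochSet]:
    """Read one participant's session back; errors on unknown schema."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ValueError(f"{path}: missing schema_version attribute")
        if str(version) != SCHEMA_VERSION:
            raise ValueError(f"{path}: unknown schema_version {version!r} "
                             f"(supported: {SCHEMA_VERSION})")
        pids = list(f.keys())
        pid = participant_id or pids[0]
        if pid not in f:
            raise KeyError(f"{path}: no participant group {pid!r}")
        session = {}
        for name, g in f[pid].items():
            try:
                session[name] = EpochSet(
                    data=g["data"][()], sfreq=float(g.attrs["sfreq"]),
                    times=g["times"][()], labels=g["labels"][()],
                    intensity=np.array([s.decode() if isinstance(s, bytes) else s
                                        for s in g["intensity"][()]], dtype=object),
                    modality=str(g.attrs["modality"]), participant_id=pid)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: corrupted group {pid}/{name}: {exc}")
    return session


def list_participants(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f.keys())


def export_events(session: dict[str, EpochSet], path: str | Path, *,
                  iti: float = 15.0, trials_per_block: int = 35) -> Path:
    """Write a BIDS-like events table (onset, duration, trial_type,
    intensity, block) as tab-separated values. Onsets are nominal, spaced
    by the inter-trial interval."""
    first = next(iter(session.values()))
    n = first.n_trials
    df = pd.DataFrame({
        "onset": np.arange(n) * iti,
        "duration": 2.0,
        "trial_type": np.where(first.labels == 1, "odor", "air"),
        "intensity": first.intensity.astype(str),
        "block": np.arange(n) // trials_per_block,
    })
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
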