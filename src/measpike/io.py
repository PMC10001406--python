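"""File formats: raw recordings (interleaved int16 + JSON sidecar), tidy CSV tables, configs.

A raw recording on disk is a pair ``<stem>.bin`` / ``<stem>.json``.  The binary
file holds sample-major interleaved signed 16-bit integers (sample 0 of every
channel, then sample 1, ...), the sidecar holds the metadata needed to
reconstruct voltages: sampling rate, channel count/ids and volts per LSB.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "write_raw",
    "read_raw",
    "write_table",
    "read_table",
    "write_snippets",
    "read_snippets",
    "config_hash",
]

# Intan RHD-series front ends digitize at 0.195 uV per bit; used as the
# default quantization step when synthesizing int16 traces.
INTAN_VOLTS_PER_LSB = 0.195e-6


@dataclass
class RawRecording:
    """Multichannel continuous voltage block with sampling metadata.

    ``data`` has shape ``(n_channels, n_samples)``.  Integer data are scaled
    by ``volts_per_lsb``; float data are taken to be volts already
    (``volts_per_lsb`` is then 1.0).
    """

    data: np.ndarray
    sampling_rate: float
    volts_per_lsb: float = 1.0
    channel_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if not self.channel_ids:
            self.channel_ids = list(range(self.data.shape[0]))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_volts(self, index: int) -> np.ndarray:
        """Channel trace in volts as float64 (by positional index)."""
        x = self.data[index].astype(np.float64)
        if self.volts_per_lsb != 1.0:
            x *= self.volts_per_lsb
        return x


def _atomic_write_bytes(path: Path, payload: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_raw(recording: RawRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.bin`` (interleaved int16) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    data = recording.data
    if data.dtype != np.int16:
        lsb = recording.volts_per_lsb if recording.volts_per_lsb != 1.0 else INTAN_VOLTS_PER_LSB
        data = np.clip(np.rint(data / lsb), -32768, 32767).astype(np.int16)
    else:
        lsb = recording.volts_per_lsb
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    _atomic_write_bytes(bin_path, np.ascontiguousarray(data.T).tobytes())
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate,
        "n_channels": recording.n_channels,
        "volts_per_lsb": lsb,
        "channel_ids": list(recording.channel_ids),
        "duration_s": recording.duration,
    }
    _atomic_write_bytes(json_path, json.dumps(sidecar, indent=1).encode())
    return bin_path, json_path


def read_raw(stem: str | Path) -> RawRecording:
    """Read a ``<stem>.bin`` / ``<stem>.json`` raw recording pair."""
    stem = Path(stem)
    json_path = stem.with_suffix(".json")
    try:
        meta = json.loads(json_path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"missing sidecar {json_path}") from None
    for key in ("sampling_rate_hz", "n_channels", "volts_per_lsb"):
        if key not in meta:
            raise ValueError(f"sidecar {json_path} lacks required field '{key}'")
    flat = np.fromfile(stem.with_suffix(".bin"), dtype=np.int16)
    n_channels = int(meta["n_channels"])
    if flat.size % n_channels:
        raise ValueError(
            f"{stem.with_suffix('.bin')}: {flat.size} samples not divisible by "
            f"n_channels={n_channels}"
        )
    data = flat.reshape(-1, n_channels).T
    return RawRecording(
        data=data,
        sampling_rate=float(meta["sampling_rate_hz"]),
        volts_per_lsb=float(meta["volts_per_lsb"]),
        channel_ids=list(meta.get("channel_ids", range(n_channels))),
    )


def config_hash(obj) -> str:
    """sha256 of the canonical JSON rendering of a config-like object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_table(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> Path:
    """Write a tidy CSV atomically, with an optional provenance comment header."""
    path = Path(path)
    header = f"# measpike config_sha256={provenance}\n" if provenance else ""
    payload = header + df.to_csv(index=False, float_format="%.10g")
    _atomic_write_bytes(path, payload.encode())
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_snippets(stacks: dict, path: str | Path) -> Path:
    """Write aligned snippet stacks to HDF5, keyed device/session/channel.

    ``stacks`` maps ``(device, session, channel)`` to a 2-D float array
    (one row per spike).
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        for (device, session, channel), stack in stacks.items():
            grp = fh.require_group(f"{device}/{session}")
            grp.create_dataset(str(channel), data=np.asarray(stack), compression="gzip")
    return path


def read_snippets(path: str | Path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                device, session, channel = name.split("/")
                out[(device, float(session), int(channel))] = obj[()]
        fh.visititems(visit)
    return out
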