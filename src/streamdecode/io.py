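"""File formats: delimited events tables and raw float32 recordings.

Events tables are tab-separated with columns ``onset`` (seconds, six
decimals), ``duration`` (seconds), ``event_type`` (``tone`` or ``press``),
``value`` (frequency in Hz for tones, percept label for presses),
``condition`` and ``delta_f``. Recordings are little-endian float32 binary
with a JSON sidecar describing sampling rate, length, channels and units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset", "duration", "event_type", "value", "condition", "delta_f"]


@dataclass
class ContinuousRecording:
    """A single-channel continuous source waveform."""

    data: np.ndarray
    sample_rate: float
    channels: tuple[str, ...] = ("auditory_cortex_mean",)
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[-1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def write_events(path: str | Path, table: pd.DataFrame) -> None:
    """Write an events table as TSV with microsecond onset precision."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"events table missing required columns: {missing}")
    out = table.loc[:, EVENT_COLUMNS].copy()
    out["onset"] = out["onset"].map(lambda v: f"{v:.6f}")
    out["duration"] = out["duration"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events table, validating columns and row parseability."""
    table = pd.read_csv(path, sep="\t", dtype={"value": str})
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    for col in ("onset", "duration"):
        try:
            table[col] = table[col].astype(float)
        except ValueError as exc:
            bad = pd.to_numeric(table[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed {col!r} at line {line}") from exc
    table["delta_f"] = table["delta_f"].astype(float)
    return table


def write_recording(stem: str | Path, rec: ContinuousRecording) -> None:
    """Write ``stem.f32`` (little-endian float32) and ``stem.json`` sidecar."""
    stem = Path(stem)
    data = np.asarray(rec.data, dtype="<f4")
    data.tofile(stem.with_suffix(".f32"))
    sidecar = {
        "sampling_rate_hz": rec.sample_rate,
        "n_samples": int(data.shape[-1]),
        "channels": list(rec.channels),
        "units": rec.units,
        **rec.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording(stem: str | Path) -> ContinuousRecording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").astype(np.float64)
    if data.shape[0] != sidecar["n_samples"]:
        raise ValueError(
            f"{stem}: sidecar declares {sidecar['n_samples']} samples, "
            f"file holds {data.shape[0]}"
        )
    meta = {
        k: v
        for k, v in sidecar.items()
        if k not in {"sampling_rate_hz", "n_samples", "channels", "units"}
    }
    return ContinuousRecording(
        data=data,
        sample_rate=float(sidecar["sampling_rate_hz"]),
        channels=tuple(sidecar["channels"]),
        units=sidecar["units"],
        meta=meta,
    )
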