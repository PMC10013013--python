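"""Multichannel physiological recordings and their on-disk CSV/JSON form."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical channel order used throughout the package
CHANNELS = ("ecg", "breathing", "perfusion")


@dataclass
class MultiChannelRecording:
    """Synchronized ECG / breathing / perfusion samples from one subject.

    Parameters
    ----------
    samples
        Real matrix of shape ``(n_channels, n_samples)``.
    channel_names
        Ordered labels, by convention ``("ecg", "breathing", "perfusion")``.
    sampling_rate
        Sampling frequency in Hz (all channels share it).
    subject_id
        Subject identifier.
    group
        Cohort label, ``"control"`` or ``"t1d"``.
    """

    samples: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    sampling_rate: float = 250.0
    subject_id: str = "unknown"
    group: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (= n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError as err:
            raise KeyError(f"no channel named {name!r}") from err
        return self.samples[idx]


def write_recording(rec: MultiChannelRecording, csv_path: str | Path) -> Path:
    """Write a recording as CSV (time_s + one column per channel) with a JSON sidecar.

    The sidecar ``<stem>.json`` holds ``subject_id``, ``group`` and
    ``sampling_rate_hz``. Returns the CSV path.
    """
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": rec.times})
    for name in rec.channel_names:
        df[name] = rec.channel(name)
    df.to_csv(csv_path, index=False, float_format="%.8g")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sampling_rate_hz": rec.sampling_rate,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_recording(csv_path: str | Path) -> MultiChannelRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    names = tuple(c for c in df.columns if c != "time_s")
    return MultiChannelRecording(
        samples=df[list(names)].to_numpy().T,
        channel_names=names,
        sampling_rate=float(meta["sampling_rate_hz"]),
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
    )
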