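"""Continuous sensor recording container and file I/O.

The on-disk container is a small HDF5 layout: dataset ``/data`` holding the
channels × samples array as 32-bit little-endian floats, and a ``/meta``
group whose attributes carry the sampling rate, start time and per-channel
names/types/positions/orientations.  A reader for the Neuromag/Elekta FIF
standard is provided as an optional convenience (requires ``mne``) and
converts to the same in-memory container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .forward import SensorArray


@dataclass
class SensorRecording:
    """Continuous multichannel time series with sensor metadata."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    array: SensorArray
    start: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.data.shape[0] != self.array.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but array describes "
                f"{self.array.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def save_recording(recording: SensorRecording, path: str | Path) -> None:
    """Write the HDF5 container (``/data`` float32 LE + ``/meta`` attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype("<f4"))
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = float(recording.sampling_rate)
        meta.attrs["start"] = float(recording.start)
        meta.attrs["label"] = recording.label
        meta.attrs["names"] = [n.encode() for n in recording.array.names]
        meta.attrs["types"] = [t.encode() for t in recording.array.types]
        meta.create_dataset("positions", data=recording.array.positions.astype("<f8"))
        meta.create_dataset("orientations", data=recording.array.orientations.astype("<f8"))


def load_recording(path: str | Path) -> SensorRecording:
    """Read the HDF5 container written by :func:`save_recording`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=np.float64)
        meta = f["meta"]
        array = SensorArray(
            positions=np.asarray(meta["positions"]),
            orientations=np.asarray(meta["orientations"]),
            types=[t.decode() if isinstance(t, bytes) else str(t) for t in meta.attrs["types"]],
            names=[n.decode() if isinstance(n, bytes) else str(n) for n in meta.attrs["names"]],
        )
        return SensorRecording(
            data=data,
            sampling_rate=float(meta.attrs["sampling_rate"]),
            array=array,
            start=float(meta.attrs["start"]),
            label=str(meta.attrs.get("label", "")),
        )


def read_fif_recording(path: str | Path) -> SensorRecording:
    """Read a Neuromag/Elekta FIF raw file into a :class:`SensorRecording`.

    Keeps MEG channels only (magnetometers and planar gradiometers).
    Requires the optional ``mne`` dependency.
    """
    import mne  # optional dependency; lazy import

    from .forward import MAGNETOMETER, PLANAR_GRADIOMETER

    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg=True, eeg=False, ref_meg=False)
    if len(picks) == 0:
        raise ValueError(f"{path}: no MEG channels found")
    data = raw.get_data(picks=picks)
    positions, orientations, types, names = [], [], [], []
    for idx in picks:
        ch = raw.info["chs"][idx]
        loc = ch["loc"]
        positions.append(loc[:3])
        orientations.append(loc[9:12])  # sensor normal (coil z-axis)
        kind = mne.channel_type(raw.info, idx)
        types.append(MAGNETOMETER if kind == "mag" else PLANAR_GRADIOMETER)
        names.append(ch["ch_name"])
    array = SensorArray(np.array(positions), np.array(orientations), types, names)
    return SensorRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        array=array,
        start=float(raw.first_samp / raw.info["sfreq"]),
        label=Path(path).stem,
    )
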