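"""Channel selection, amplitude-based epoch rejection, interference hooks.

The study's external-interference suppression (temporal signal space
separation) is a vendor/third-party algorithm and is deliberately not
re-implemented: the ``passthrough_tsss_settings`` method records the printed
settings (correlation threshold 0.9, 10 s window) in the provenance log and
returns the data unchanged.

Epoch rejection is disabled by default so the paradigm's printed epoch counts
reproduce exactly; enabling it is this package's hypothesis for the study's
reported rest-epoch deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward import MAGNETOMETER, PLANAR_GRADIOMETER, SensorArray
from .paradigm import EpochSet
from .recording import SensorRecording


@dataclass(frozen=True)
class InterferenceConfig:
    """External-interference handling.  Only settings recording is in scope."""

    method: str = "none"  # {"none", "passthrough_tsss_settings"}
    correlation_threshold: float = 0.9
    window: float = 10.0  # seconds

    def __post_init__(self) -> None:
        if self.method not in ("none", "passthrough_tsss_settings"):
            raise ValueError(f"unknown interference method: {self.method}")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be > 0")


def apply_interference_hook(
    recording: SensorRecording, config: InterferenceConfig
) -> tuple[SensorRecording, dict]:
    """Pass-through hook: returns data unchanged plus a provenance entry."""
    note = {"method": config.method}
    if config.method == "passthrough_tsss_settings":
        note.update(
            correlation_threshold=config.correlation_threshold,
            window_s=config.window,
            applied=False,
        )
    return recording, note


def select_channels(recording: SensorRecording, types) -> SensorRecording:
    """Subset a recording to the requested channel types, order preserved."""
    if isinstance(types, str):
        types = [types]
    types = list(types)
    unknown = set(types) - {MAGNETOMETER, PLANAR_GRADIOMETER}
    if unknown:
        raise ValueError(f"unknown channel types requested: {sorted(unknown)}")
    keep = [i for i, t in enumerate(recording.array.types) if t in types]
    if not keep:
        raise ValueError(
            f"no channels of type(s) {types} present "
            f"(recording has {sorted(set(recording.array.types))})"
        )
    arr = recording.array
    sub = SensorArray(
        positions=arr.positions[keep],
        orientations=arr.orientations[keep],
        types=[arr.types[i] for i in keep],
        names=[arr.names[i] for i in keep],
    )
    return SensorRecording(
        data=recording.data[keep],
        sampling_rate=recording.sampling_rate,
        array=sub,
        start=recording.start,
        label=recording.label,
    )


@dataclass(frozen=True)
class RejectionConfig:
    """Peak-to-peak amplitude rejection limits per channel type."""

    enabled: bool = False
    peak_to_peak_limit: dict[str, float] = field(
        default_factory=lambda: {MAGNETOMETER: math.inf, PLANAR_GRADIOMETER: math.inf}
    )
    flat_limit: float = 0.0

    def __post_init__(self) -> None:
        if self.enabled:
            for t, lim in self.peak_to_peak_limit.items():
                if lim <= 0:
                    raise ValueError(f"peak-to-peak limit for {t} must be > 0")
            if self.flat_limit < 0:
                raise ValueError("flat_limit must be >= 0")


@dataclass(frozen=True)
class RejectionRecord:
    condition: str
    run_index: int
    epoch_index: int
    decision: str  # "keep" | "reject"
    reason: str    # "" | "peak_to_peak" | "flat"
    peak_to_peak: float


def reject_epochs(
    epochs: EpochSet,
    config: RejectionConfig,
    channel_types: list[str] | None = None,
) -> tuple[EpochSet, list[RejectionRecord]]:
    """Drop epochs whose any-channel peak-to-peak amplitude is out of bounds.

    An epoch is rejected if any channel's peak-to-peak exceeds its type's
    limit, or if the maximum peak-to-peak across channels falls below
    ``flat_limit``.  Order is preserved; the log records every decision, so
    kept + rejected counts always equal the input count, and the operation is
    idempotent.
    """
    n = len(epochs)
    if channel_types is None:
        channel_types = [MAGNETOMETER] * epochs.n_channels
    log: list[RejectionRecord] = []
    keep_mask = np.ones(n, dtype=bool)
    limits = np.array(
        [config.peak_to_peak_limit.get(t, math.inf) for t in channel_types]
    )
    for i in range(n):
        ptp = np.ptp(epochs.epochs[i], axis=1) if n else np.zeros(0)
        max_ptp = float(ptp.max()) if ptp.size else 0.0
        decision, reason = "keep", ""
        if config.enabled:
            if np.any(ptp > limits):
                decision, reason = "reject", "peak_to_peak"
            elif max_ptp < config.flat_limit:
                decision, reason = "reject", "flat"
        keep_mask[i] = decision == "keep"
        prov = epochs.provenance[i]
        log.append(
            RejectionRecord(
                epochs.condition.value, prov.run_index, i, decision, reason, max_ptp
            )
        )
    kept = EpochSet(
        epochs.condition,
        epochs.epoch_length,
        epochs.sampling_rate,
        epochs.epochs[keep_mask],
        [p for p, k in zip(epochs.provenance, keep_mask) if k],
    )
    return kept, log


def write_rejection_log(log: list[RejectionRecord], path: str | Path) -> None:
    """TSV log: condition, run, epoch_index, decision, reason, peak_to_peak."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("condition\trun\tepoch_index\tdecision\treason\tpeak_to_peak\n")
        for r in log:
            fh.write(
                f"{r.condition}\t{r.run_index}\t{r.epoch_index}\t{r.decision}\t"
                f"{r.reason}\t{r.peak_to_peak:.6e}\n"
            )
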