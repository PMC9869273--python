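"""Hann-tapered epoch spectra, condition averages, and band power.

Each fixed-length epoch is multiplied by a Hann taper (so the signal decays
smoothly to zero at the edges), Fourier transformed, and converted to power
per frequency bin.  Epoch spectra are arithmetically averaged into one
representative spectrum per condition, and band power is the plain sum of
power over the bins belonging to the band.

Normalization: windowed power is divided by the sum of squared taper values,
so the expected per-bin power of white noise equals its sample variance and
is taper-invariant.

Band-edge convention.  The classical band edges overlap in print (theta and
alpha share 8 Hz; beta and gamma share 30 Hz) and leave a 12–13 Hz gap, so
bins are assigned half-open: delta [1, 4), theta [4, 8), alpha [8, 13),
beta [13, 31), gamma [31, 81) Hz.  At the 1 Hz resolution of 1 s epochs this
puts exactly the integer frequencies 8–12 in alpha ("all frequencies between
8 and 12 Hz") and makes the five bands an exact partition of the 1–80 Hz
analysis range, so the five band powers always sum to the broadband total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .paradigm import ConditionLabel, EpochSet


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high, got [{self.low}, {self.high})")

    def bins(self, frequencies: np.ndarray) -> np.ndarray:
        """Boolean mask of bins assigned to this band."""
        return (frequencies >= self.low) & (frequencies < self.high)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 31.0),
    BandDefinition("gamma", 31.0, 81.0),
)

#: Broadband analysis range [low, high) Hz; excludes DC and > 80 Hz bins.
DEFAULT_TOTAL_RANGE: tuple[float, float] = (1.0, 81.0)


def hann_taper(n: int) -> np.ndarray:
    """Periodic Hann window 0.5·(1 − cos(2πk/N)), k = 0..N−1."""
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n))


@dataclass
class EpochSpectrum:
    """One epoch's per-channel power spectrum on a 0..Nyquist grid."""

    power: np.ndarray        # (channels, bins), >= 0
    frequencies: np.ndarray  # Hz
    taper: str = "hann"


@dataclass
class ConditionSpectrum:
    """Epoch-averaged power spectrum representing one condition."""

    condition: ConditionLabel
    power: np.ndarray        # (channels, bins) mean power
    frequencies: np.ndarray
    n_epochs: int
    noise_subtracted: bool = False


def epoch_spectrum(
    epoch: np.ndarray, sampling_rate: float, taper: str = "hann"
) -> EpochSpectrum:
    """Hann-tapered power spectrum of one (channels × samples) epoch.

    ``power[c, k] = |DFT(w ⊙ x_c)[k]|² / Σw²`` on the one-sided grid
    0..Nyquist with resolution ``rate / n_samples`` (1 Hz for 1 s epochs).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < 2:
        raise ValueError("epoch must have at least 2 samples")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite samples")
    n = epoch.shape[1]
    if taper == "hann":
        w = hann_taper(n)
    elif taper == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown taper: {taper}")
    spec = np.fft.rfft(epoch * w[None, :], axis=1)
    power = (spec.real**2 + spec.imag**2) / np.sum(w**2)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return EpochSpectrum(power, freqs, taper)


def average_condition_spectrum(
    spectra: Sequence[EpochSpectrum],
    condition: ConditionLabel = ConditionLabel.REST,
) -> ConditionSpectrum:
    """Arithmetic mean of epoch spectra sharing one frequency grid."""
    if not spectra:
        raise ValueError("need at least one epoch spectrum")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.power.shape != spectra[0].power.shape or not np.array_equal(s.frequencies, f0):
            raise ValueError("epoch spectra have mismatched grids or shapes")
    mean = np.mean([s.power for s in spectra], axis=0)
    return ConditionSpectrum(condition, mean, f0.copy(), len(spectra))


def condition_spectrum(epochs: EpochSet, taper: str = "hann") -> ConditionSpectrum:
    """Per-epoch Hann spectra of an :class:`EpochSet`, averaged."""
    if len(epochs) == 0:
        raise ValueError(f"no epochs for condition {epochs.condition.value}")
    spectra = [
        epoch_spectrum(epochs.epochs[i], epochs.sampling_rate, taper)
        for i in range(len(epochs))
    ]
    return average_condition_spectrum(spectra, epochs.condition)


def band_power(spectrum: ConditionSpectrum, band: BandDefinition) -> np.ndarray:
    """Per-location total power: sum of mean power over the band's bins."""
    freqs = spectrum.frequencies
    if band.low >= freqs[-1] + (freqs[1] - freqs[0]):
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}) lies outside the "
            f"spectrum range (max {freqs[-1]} Hz)"
        )
    mask = band.bins(freqs)
    return spectrum.power[:, mask].sum(axis=1)


def total_power(
    spectrum: ConditionSpectrum,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
) -> np.ndarray:
    """Broadband power over [low, high) Hz per location (default 1–80 Hz)."""
    lo, hi = total_range
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies < hi)
    return spectrum.power[:, mask].sum(axis=1)


def relative_band_power(
    spectrum: ConditionSpectrum,
    band: BandDefinition,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
) -> np.ndarray:
    """Band power as a fraction of broadband power, in [0, 1] per location."""
    tot = total_power(spectrum, total_range)
    if np.any(tot <= 0):
        raise ValueError("zero total power: relative band power undefined")
    return band_power(spectrum, band) / tot


def subtract_noise_psd(
    condition: ConditionSpectrum, empty_room: ConditionSpectrum
) -> ConditionSpectrum:
    """Subtract the empty-room mean spectrum, flooring each bin at zero.

    Characterizes and removes environment noise measured without the subject;
    the result is flagged ``noise_subtracted`` in provenance.
    """
    if condition.power.shape != empty_room.power.shape or not np.array_equal(
        condition.frequencies, empty_room.frequencies
    ):
        raise ValueError("condition and empty-room spectra have mismatched grids")
    out = np.maximum(condition.power - empty_room.power, 0.0)
    return ConditionSpectrum(
        condition.condition, out, condition.frequencies.copy(), condition.n_epochs,
        noise_subtracted=True,
    )


@dataclass
class BandPowerMap:
    """Band-aggregated power per location, absolute and relative."""

    condition: ConditionLabel
    locations: list[str]
    bands: tuple[BandDefinition, ...]
    absolute: np.ndarray   # (locations, bands)
    relative: np.ndarray   # (locations, bands), rows sum to ~1 over partition
    n_epochs: int

    def power(self, normalization: str) -> np.ndarray:
        if normalization == "absolute":
            return self.absolute
        if normalization == "relative":
            return self.relative
        raise ValueError(f"unknown normalization: {normalization}")


def band_power_map(
    spectrum: ConditionSpectrum,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    locations: Sequence[str] | None = None,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
) -> BandPowerMap:
    """Aggregate a condition spectrum into per-location band powers."""
    n_loc = spectrum.power.shape[0]
    if locations is None:
        locations = [f"loc{i:03d}" for i in range(n_loc)]
    absolute = np.stack([band_power(spectrum, b) for b in bands], axis=1)
    tot = total_power(spectrum, total_range)
    if np.any(tot <= 0):
        raise ValueError("zero total power: relative normalization undefined")
    relative = absolute / tot[:, None]
    return BandPowerMap(
        spectrum.condition, list(locations), tuple(bands), absolute, relative,
        spectrum.n_epochs,
    )


def write_band_table(maps: Sequence[BandPowerMap], path: str | Path) -> None:
    """TSV band table: location, band, condition, power, relative_power."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("location\tband\tcondition\tpower\trelative_power\n")
        for m in maps:
            for i, loc in enumerate(m.locations):
                for j, b in enumerate(m.bands):
                    fh.write(
                        f"{loc}\t{b.name}\t{m.condition.value}\t"
                        f"{m.absolute[i, j]:.6e}\t{m.relative[i, j]:.6e}\n"
                    )
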