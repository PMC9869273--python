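"""Synthetic paradigm-locked MEG generator.

Stands in for the study's raw data: cortical ROI sources emit band-limited
oscillatory noise whose variance steps up or down during stimulation blocks,
the spherical-conductor forward model projects them to the helmet, and white
sensor noise is added.  Everything is seeded and bit-reproducible.

Source model
------------
Each atlas point carries one band-limited component per rhythm (delta, theta,
alpha, beta, gamma): white noise band-passed with a 4th-order zero-phase
Butterworth filter, scaled to a baseline RMS dipole moment, with a 1/f-like
amplitude profile across bands so alpha is a minority share of broadband
source power (as in resting cortex — the study's outcome, *relative* alpha
power, is only meaningful against such a broadband background).  A condition
modulation multiplies the component's variance by ``1 + percent/100`` inside
that condition's blocks, with step transitions at block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .atlas import SourceAtlas
from .forward import (
    MAGNETOMETER,
    PLANAR_GRADIOMETER,
    ConductorModel,
    SensorArray,
    build_leadfield,
)
from .paradigm import ConditionLabel, StimulusSchedule
from .recording import SensorRecording


@dataclass(frozen=True)
class BandComponent:
    """One oscillatory component of a ROI's source activity.

    ``baseline_amplitude`` is the RMS dipole moment (A·m) during rest;
    ``modulation`` maps conditions to the percent change of this component's
    *power* (variance) relative to rest.  REST itself is never modulated.
    """

    band: str
    center: float       # Hz
    bandwidth: float    # Hz (full width; passband = center ± bandwidth/2)
    baseline_amplitude: float
    modulation: dict[ConditionLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.center <= 0:
            raise ValueError(f"{self.band}: center and bandwidth must be > 0")
        if self.baseline_amplitude < 0:
            raise ValueError(f"{self.band}: baseline amplitude must be >= 0")
        for cond, pct in self.modulation.items():
            if pct <= -100:
                raise ValueError(
                    f"{self.band}/{cond}: percent change must be > -100, got {pct}"
                )
            if cond is ConditionLabel.REST and pct != 0:
                raise ValueError("REST modulation must be identically 0")

    @property
    def low(self) -> float:
        return self.center - self.bandwidth / 2

    @property
    def high(self) -> float:
        return self.center + self.bandwidth / 2


@dataclass(frozen=True)
class ModulationSpec:
    """Per-ROI source composition and condition-dependent power modulation."""

    components: dict[str, tuple[BandComponent, ...]]

    def for_roi(self, label: str) -> tuple[BandComponent, ...]:
        return self.components.get(label, ())


#: 1/f-like baseline RMS dipole moments (A·m) per rhythm.  Alpha carries
#: ~9% of broadband source variance, a realistic minority share.  Component
#: passbands are inset ~0.5 Hz from the analysis-band bin edges so that each
#: rhythm's energy lands in its own measurement band despite the finite
#: Butterworth roll-off (the filter is only −3 dB at its passband edge).
DEFAULT_BAND_PROFILE: dict[str, tuple[float, float, float]] = {
    # band: (center Hz, bandwidth Hz, baseline RMS moment A·m)
    "delta": (2.5, 2.0, 35e-9),
    "theta": (5.75, 2.3, 25e-9),
    "alpha": (10.0, 4.0, 15e-9),
    "beta": (22.0, 16.0, 16e-9),
    "gamma": (55.5, 47.0, 15e-9),
}

#: Alpha-power percent changes versus rest per ROI and odorant, mirroring the
#: reported effects: bilateral olfactory +40% (both odorants), somatosensory
#: -30% (both), left OFC and precentral +25–30% (PEA only), medial frontal
#: +5–10% (PEA only).
DEFAULT_ALPHA_MODULATIONS: dict[str, dict[ConditionLabel, float]] = {
    "olfactory_L": {ConditionLabel.PEA: 40.0, ConditionLabel.AMYL_ACETATE: 40.0},
    "olfactory_R": {ConditionLabel.PEA: 40.0, ConditionLabel.AMYL_ACETATE: 40.0},
    "somatosensory_L": {ConditionLabel.PEA: -30.0, ConditionLabel.AMYL_ACETATE: -30.0},
    "somatosensory_R": {ConditionLabel.PEA: -30.0, ConditionLabel.AMYL_ACETATE: -30.0},
    "orbitofrontal_L": {ConditionLabel.PEA: 27.5},
    "medial_frontal_L": {ConditionLabel.PEA: 7.5},
    "precentral_L": {ConditionLabel.PEA: 27.5},
}


def default_modulation_spec(
    roi_labels,
    alpha_modulations: dict[str, dict[ConditionLabel, float]] | None = None,
) -> ModulationSpec:
    """Five-band source composition for each ROI, alpha modulated per table.

    ``alpha_modulations`` defaults to :data:`DEFAULT_ALPHA_MODULATIONS`;
    pass ``{}`` for a null (no-modulation) scene.
    """
    if alpha_modulations is None:
        alpha_modulations = DEFAULT_ALPHA_MODULATIONS
    components: dict[str, tuple[BandComponent, ...]] = {}
    for label in roi_labels:
        comps = []
        for band, (center, bw, amp) in DEFAULT_BAND_PROFILE.items():
            mod = dict(alpha_modulations.get(label, {})) if band == "alpha" else {}
            comps.append(BandComponent(band, center, bw, amp, mod))
        components[label] = tuple(comps)
    return ModulationSpec(components)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white sensor noise, std per sample by channel type.

    Defaults correspond to ~5 fT/√Hz magnetometer noise (T) and
    ~3 fT/cm/√Hz planar-gradiometer noise (T/m) at a 500 Hz sampling rate.
    """

    std_by_type: dict[str, float] = field(
        default_factory=lambda: {MAGNETOMETER: 8e-14, PLANAR_GRADIOMETER: 5e-12}
    )
    interference_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t, s in self.std_by_type.items():
            if s < 0:
                raise ValueError(f"noise std for {t} must be >= 0, got {s}")
        if self.interference_amplitude < 0:
            raise ValueError("interference amplitude must be >= 0")


def _condition_envelope(
    schedule: StimulusSchedule,
    modulation: dict[ConditionLabel, float],
    n_samples: int,
    rate: float,
    start: float,
) -> np.ndarray:
    """Per-sample amplitude factor: sqrt(1 + pct/100) inside modulated blocks."""
    env = np.ones(n_samples)
    for seg in schedule.segments:
        pct = modulation.get(seg.condition, 0.0)
        if pct == 0.0:
            continue
        i0 = max(0, int(round((seg.onset - start) * rate)))
        i1 = min(n_samples, int(round((seg.end - start) * rate)))
        env[i0:i1] = np.sqrt(1.0 + pct / 100.0)
    return env


def _bandlimited_noise(
    rng: np.random.Generator, n_samples: int, rate: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order zero-phase Butterworth)."""
    nyq = rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band [{low}, {high}] Hz outside (0, Nyquist={nyq}) at rate {rate}"
        )
    x = rng.standard_normal(n_samples)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_source_timecourses(
    atlas: SourceAtlas,
    modulation: ModulationSpec,
    schedule: StimulusSchedule,
    sampling_rate: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Generate per-source time series locked to the stimulus schedule.

    Returns an ``(n_sources, n_samples)`` array in atlas source order, where
    ``n_samples = round(schedule.end × rate)``.  Within a condition's blocks
    each component's variance equals ``baseline² × (1 + percent/100)`` up to
    sampling error; transitions are steps at block boundaries.  Bit-identical
    for a fixed seed.
    """
    if not schedule.segments:
        raise ValueError("schedule is empty")
    n_samples = int(round(schedule.end * sampling_rate))
    start = schedule.segments[0].onset
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    sources = np.zeros((atlas.n_sources, n_samples))
    i = 0
    for roi in atlas.rois:
        comps = modulation.for_roi(roi.label)
        for _ in range(roi.n_points):
            child = seed.spawn(1)[0]
            rng = np.random.default_rng(child)
            for comp in comps:
                x = _bandlimited_noise(rng, n_samples, sampling_rate, comp.low, comp.high)
                env = _condition_envelope(
                    schedule, comp.modulation, n_samples, sampling_rate, start
                )
                sources[i] += comp.baseline_amplitude * env * x
            i += 1
    return sources


def project_and_mix(
    sources: np.ndarray,
    leadfield: np.ndarray,
    noise: NoiseSpec,
    array: SensorArray,
    sampling_rate: float,
    start: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    label: str = "simulated",
) -> SensorRecording:
    """Project sources through the leadfield and add seeded sensor noise.

    ``data = leadfield @ sources + noise`` with noise independent across
    channels and samples.  The noise seed comes from ``seed`` if given, else
    from ``noise.seed``.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if leadfield.shape[1] != sources.shape[0]:
        raise ValueError(
            f"leadfield has {leadfield.shape[1]} source columns but "
            f"{sources.shape[0]} source timecourses were given"
        )
    if leadfield.shape[0] != array.n_channels:
        raise ValueError("leadfield row count does not match sensor array")
    data = leadfield @ sources
    if seed is None:
        seed = noise.seed
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    stds = np.array([noise.std_by_type.get(t, 0.0) for t in array.types])
    data = data + stds[:, None] * rng.standard_normal(data.shape)
    if noise.interference_amplitude > 0:
        # common-mode low-frequency drift with a smooth spatial pattern
        t = np.arange(data.shape[1]) / sampling_rate
        drift = np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 0.7 * t + 1.0)
        pattern = 1.0 + 0.5 * np.cos(np.linspace(0, np.pi, array.n_channels))
        data = data + noise.interference_amplitude * pattern[:, None] * drift[None, :]
    return SensorRecording(data, sampling_rate, array, start=start, label=label)


def simulate_empty_room(
    array: SensorArray,
    noise: NoiseSpec,
    duration: float,
    sampling_rate: float,
    seed: int | np.random.SeedSequence | None = None,
) -> SensorRecording:
    """Subject-absent recording: sensor noise (plus optional interference)."""
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    n_samples = int(round(duration * sampling_rate))
    silent = np.zeros((0, n_samples))
    lf = np.zeros((array.n_channels, 0))
    rec = project_and_mix(
        silent.reshape(0, n_samples) if n_samples else silent,
        lf,
        noise,
        array,
        sampling_rate,
        seed=seed,
        label=ConditionLabel.EMPTY_ROOM.value,
    )
    return rec


def simulate_recording(
    schedule: StimulusSchedule,
    atlas: SourceAtlas,
    modulation: ModulationSpec,
    array: SensorArray,
    conductor: ConductorModel | None = None,
    noise: NoiseSpec | None = None,
    sampling_rate: float = 500.0,
    seed: int = 0,
) -> tuple[SensorRecording, np.ndarray]:
    """Full scene: sources → spherical forward model → sensors + noise.

    Returns the recording and the leadfield used (for matched-model inverse
    analysis).  A single ``seed`` drives both source and noise generation.
    """
    if conductor is None:
        conductor = ConductorModel()
    if noise is None:
        noise = NoiseSpec()
    atlas.validate_inside(conductor)
    root = np.random.SeedSequence(seed)
    src_seed, noise_seed = root.spawn(2)
    sources = simulate_source_timecourses(atlas, modulation, schedule, sampling_rate, src_seed)
    leadfield = build_leadfield(atlas, array, conductor)
    rec = project_and_mix(
        sources,
        leadfield,
        noise,
        array,
        sampling_rate,
        start=schedule.segments[0].onset if schedule.segments else 0.0,
        seed=noise_seed,
    )
    return rec, leadfield
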