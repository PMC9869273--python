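"""ROI-level source mapping via a regularized minimum-norm linear inverse.

Sensor epochs are mapped to source time courses with a Tikhonov-regularized
minimum-norm operator

    M = Lᵀ (L Lᵀ + λ · trace(L Lᵀ)/n_channels · I)⁻¹ ,

spectra are computed at every source point with the same Hann machinery used
at the sensors, band power is averaged over each ROI's points, and the
percent-change contrast is applied at ROI granularity.  Because the contrast
is a within-source power ratio across conditions, the minimum-norm amplitude
bias (a fixed per-source gain) cancels, which is what makes effect-size
recovery possible despite the ill-posed inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .atlas import SourceAtlas
from .contrast import DEFAULT_THRESHOLD, RelativeChangeMap, build_change_map
from .paradigm import ConditionLabel, EpochSet
from .spectral import (
    DEFAULT_BANDS,
    DEFAULT_TOTAL_RANGE,
    BandDefinition,
    BandPowerMap,
    band_power_map,
    condition_spectrum,
)

DEFAULT_LAMBDA = 3e-4


@dataclass
class InverseOperator:
    """Linear source estimator (sources × channels)."""

    matrix: np.ndarray
    regularization: float
    method: str = "tikhonov_minimum_norm"

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def compute_inverse(leadfield: np.ndarray, lam: float = DEFAULT_LAMBDA) -> InverseOperator:
    """Tikhonov minimum-norm operator for a (channels × sources) leadfield.

    ``lam`` is dimensionless: the ridge added to the Gram matrix is
    ``lam · trace(L Lᵀ)/n_channels``.  With ``lam = 0`` the Gram matrix must
    be non-singular (full row rank of Lᵀ); otherwise an error advises a
    positive ``lam``.
    """
    lf = np.asarray(leadfield, dtype=float)
    if not np.all(np.isfinite(lf)):
        raise ValueError("leadfield contains non-finite entries")
    if lam < 0:
        raise ValueError(f"regularization must be >= 0, got {lam}")
    n_ch = lf.shape[0]
    gram = lf @ lf.T
    ridge = lam * np.trace(gram) / n_ch
    reg = gram + ridge * np.eye(n_ch)
    if lam == 0:
        rank = np.linalg.matrix_rank(gram)
        if rank < n_ch:
            raise np.linalg.LinAlgError(
                f"L·Lᵀ is rank deficient ({rank} < {n_ch}); use λ > 0"
            )
    matrix = lf.T @ np.linalg.solve(reg, np.eye(n_ch))
    return InverseOperator(matrix, lam)


def apply_inverse_epochs(epochs: EpochSet, inverse: InverseOperator) -> EpochSet:
    """Map every sensor epoch to source space, preserving provenance."""
    if len(epochs) and epochs.n_channels != inverse.n_channels:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels but the inverse expects "
            f"{inverse.n_channels}"
        )
    if len(epochs) == 0:
        n_samp = epochs.epochs.shape[2]
        out = np.empty((0, inverse.n_sources, n_samp))
    else:
        out = np.einsum("sc,ecj->esj", inverse.matrix, epochs.epochs)
    return EpochSet(
        epochs.condition, epochs.epoch_length, epochs.sampling_rate, out,
        list(epochs.provenance),
    )


def roi_band_power(
    source_epochs_by_condition: Mapping[ConditionLabel | str, EpochSet],
    atlas: SourceAtlas,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
    noise_spectrum: "ConditionSpectrum | None" = None,
) -> dict[str, BandPowerMap]:
    """Per-ROI band power for each condition's source-space epochs.

    Runs the spectral chain (Hann epoch spectra → condition average → band
    sums) on the source time courses, then averages band power over each
    ROI's points (arithmetic mean — stable under atlas resolution changes).
    Relative normalization divides by the ROI-mean broadband power.

    ``noise_spectrum``, if given, is a source-space spectrum of the
    empty-room (subject-absent) recording passed through the same inverse;
    it is subtracted bin-wise (floored at zero) from every condition's
    spectrum before band aggregation, removing the noise-power bias that the
    linear inverse projects into every source estimate.
    """
    from .spectral import subtract_noise_psd

    slices = atlas.source_slices()
    for roi in atlas.rois:
        if roi.n_points == 0:
            raise ValueError(f"ROI {roi.label} is empty")
    out: dict[str, BandPowerMap] = {}
    for cond, epochs in source_epochs_by_condition.items():
        key = cond.value if isinstance(cond, ConditionLabel) else str(cond)
        if len(epochs) and epochs.n_channels != atlas.n_sources:
            raise ValueError(
                f"{key}: source epochs have {epochs.n_channels} rows but the "
                f"atlas defines {atlas.n_sources} sources"
            )
        spec = condition_spectrum(epochs)
        if noise_spectrum is not None:
            spec = subtract_noise_psd(spec, noise_spectrum)
        per_source = band_power_map(spec, bands, total_range=total_range)
        absolute = np.stack(
            [per_source.absolute[slices[r.label]].mean(axis=0) for r in atlas.rois]
        )
        # relative power recomputed from ROI-mean absolute band powers so the
        # five-band partition still sums to 1 per ROI
        broadband = np.stack(
            [
                per_source.absolute[slices[r.label]].sum(axis=1).mean()
                for r in atlas.rois
            ]
        )
        relative = absolute / broadband[:, None]
        out[key] = BandPowerMap(
            epochs.condition, atlas.labels, tuple(bands), absolute, relative,
            len(epochs),
        )
    return out


def roi_change_map(
    roi_powers: Mapping[str, BandPowerMap],
    threshold: float = DEFAULT_THRESHOLD,
    normalization: str = "absolute",
) -> RelativeChangeMap:
    """Percent-change contrast at ROI granularity (delegates to contrast)."""
    return build_change_map(roi_powers, threshold, normalization)
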