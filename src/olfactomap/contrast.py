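"""Percent-change contrast of band power versus rest, with the ≥20% mask.

The study's primary outcome: for every location and band, band power during
an olfactory condition is expressed as a percent change relative to rest,
``100 × (P_cond − P_rest) / P_rest``, and entries whose absolute change
reaches the significance threshold (default 20%, boundary inclusive) are
flagged.  The threshold is two-sided — decreases as large as the threshold
count as significant, matching the reporting of a somatosensory power
decrease alongside increases elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .paradigm import ConditionLabel
from .spectral import BandDefinition, BandPowerMap, ConditionSpectrum

DEFAULT_THRESHOLD = 20.0  # percent

#: Numerical slack for the boundary-inclusive threshold rule, so a change
#: that is exactly the threshold up to floating-point rounding is flagged.
_THRESHOLD_TOL = 1e-9

#: Label used for the pooled "olfactory stimulation" pseudo-condition
#: (PEA and amyl-acetate spectra averaged, weighted by epoch counts).
OLFACTORY_MEAN = "OLFACTORY_MEAN"


def percent_change(p_cond, p_rest):
    """``100 × (p_cond − p_rest) / p_rest``; both on the same normalization.

    Accepts scalars or arrays; raises if any baseline is non-positive.
    """
    p_cond = np.asarray(p_cond, dtype=float)
    p_rest = np.asarray(p_rest, dtype=float)
    if np.any(p_rest <= 0):
        raise ValueError("rest power must be > 0 (undefined baseline)")
    out = 100.0 * (p_cond - p_rest) / p_rest
    return float(out) if out.ndim == 0 else out


@dataclass
class RelativeChangeMap:
    """Percent change vs rest per (location, band, condition), with mask.

    ``changes[cond]`` is a (locations × bands) array; ``mask[cond]`` is True
    exactly where ``|change| >= threshold``.
    """

    locations: list[str]
    bands: tuple[BandDefinition, ...]
    changes: dict[str, np.ndarray]
    threshold: float
    normalization: str
    n_epochs: dict[str, int]
    n_epochs_rest: int = 0

    @property
    def mask(self) -> dict[str, np.ndarray]:
        t = self.threshold - _THRESHOLD_TOL
        return {c: np.abs(ch) >= t for c, ch in self.changes.items()}

    def any_significant(self) -> bool:
        return any(m.any() for m in self.mask.values())

    def entry(self, location: str, band: str, condition: str) -> tuple[float, bool]:
        i = self.locations.index(location)
        j = [b.name for b in self.bands].index(band)
        ch = self.changes[condition][i, j]
        return float(ch), bool(abs(ch) >= self.threshold - _THRESHOLD_TOL)


def build_change_map(
    band_powers: Mapping[ConditionLabel | str, BandPowerMap],
    threshold: float = DEFAULT_THRESHOLD,
    normalization: str = "absolute",
) -> RelativeChangeMap:
    """Contrast every non-rest condition's band power against rest.

    ``band_powers`` maps conditions to :class:`BandPowerMap` objects on a
    common location/band layout; REST must be present and is the baseline.
    The mask flags entries with ``|change| >= threshold`` (inclusive).
    """
    keyed = {
        (k.value if isinstance(k, ConditionLabel) else str(k)): v
        for k, v in band_powers.items()
    }
    rest_key = ConditionLabel.REST.value
    if rest_key not in keyed:
        raise ValueError("REST condition is required as the contrast baseline")
    rest = keyed[rest_key]
    p_rest = rest.power(normalization)
    changes: dict[str, np.ndarray] = {}
    n_epochs: dict[str, int] = {}
    for cond, bp in keyed.items():
        if cond == rest_key:
            continue
        if bp.locations != rest.locations or [b.name for b in bp.bands] != [
            b.name for b in rest.bands
        ]:
            raise ValueError(f"condition {cond}: layout differs from rest map")
        changes[cond] = percent_change(bp.power(normalization), p_rest)
        n_epochs[cond] = bp.n_epochs
    return RelativeChangeMap(
        list(rest.locations), tuple(rest.bands), changes, float(threshold),
        normalization, n_epochs, rest.n_epochs,
    )


def combine_stimulation_spectra(
    pea: ConditionSpectrum, amyl: ConditionSpectrum
) -> ConditionSpectrum:
    """Pooled olfactory-stimulation spectrum: epoch-weighted mean of PEA and
    amyl-acetate condition spectra (their averaged signals combined before
    the contrast)."""
    if pea.power.shape != amyl.power.shape or not np.array_equal(
        pea.frequencies, amyl.frequencies
    ):
        raise ValueError("PEA and amyl-acetate spectra have mismatched grids")
    n = pea.n_epochs + amyl.n_epochs
    mean = (pea.n_epochs * pea.power + amyl.n_epochs * amyl.power) / n
    # keyed as OLFACTORY_MEAN by callers; the enum label is a carrier only
    return ConditionSpectrum(pea.condition, mean, pea.frequencies.copy(), n)


def contrast_table(cmap: RelativeChangeMap) -> list[dict]:
    """Report rows sorted by |percent change| descending."""
    rows: list[dict] = []
    for cond, arr in cmap.changes.items():
        mask = np.abs(arr) >= cmap.threshold - _THRESHOLD_TOL
        for i, loc in enumerate(cmap.locations):
            for j, b in enumerate(cmap.bands):
                rows.append(
                    {
                        "location": loc,
                        "band": b.name,
                        "condition": cond,
                        "percent_change": float(arr[i, j]),
                        "significant": bool(mask[i, j]),
                        "n_epochs_cond": cmap.n_epochs.get(cond, 0),
                        "n_epochs_rest": cmap.n_epochs_rest,
                    }
                )
    rows.sort(key=lambda r: abs(r["percent_change"]), reverse=True)
    return rows


_TABLE_COLS = [
    "location", "band", "condition", "percent_change", "significant",
    "n_epochs_cond", "n_epochs_rest",
]


def write_contrast_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write contrast rows as TSV (header + one row per entry)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TABLE_COLS) + "\n")
        for r in rows:
            fh.write(
                f"{r['location']}\t{r['band']}\t{r['condition']}\t"
                f"{r['percent_change']:.6f}\t{int(r['significant'])}\t"
                f"{r['n_epochs_cond']}\t{r['n_epochs_rest']}\n"
            )


def read_contrast_table(path: str | Path) -> list[dict]:
    """Read back a TSV written by :func:`write_contrast_table`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _TABLE_COLS:
        raise ValueError(f"{path}: expected header {_TABLE_COLS}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        loc, band, cond, pc, sig, nc, nr = line.split("\t")
        rows.append(
            {
                "location": loc,
                "band": band,
                "condition": cond,
                "percent_change": float(pc),
                "significant": bool(int(sig)),
                "n_epochs_cond": int(nc),
                "n_epochs_rest": int(nr),
            }
        )
    return rows
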