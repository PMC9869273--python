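"""Labelled source-point atlas for ROI-level analysis.

ROIs are abstracted as small sets of oriented dipole locations in the head
frame (x right, y anterior, z superior, metres), not subject anatomy.  The
default atlas places nominal centroids for the regions reported in the
olfactory block-design study: bilateral olfactory cortex, bilateral primary
somatosensory cortex, left orbitofrontal cortex, left medial frontal cortex
and left precentral gyrus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward import ConductorModel, _tangential_unit


@dataclass(frozen=True)
class ROI:
    label: str
    points: np.ndarray       # (n_points, 3) metres
    orientations: np.ndarray  # (n_points, 3) unit vectors

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        ori = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        if pts.shape != ori.shape:
            raise ValueError(f"ROI {self.label}: points/orientations shape mismatch")
        if pts.shape[0] == 0:
            raise ValueError(f"ROI {self.label}: empty ROI")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"ROI {self.label}: zero orientation vector")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "orientations", ori / norms[:, None])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SourceAtlas:
    """Ordered collection of uniquely labelled ROIs."""

    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate ROI labels: {labels}")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    @property
    def n_sources(self) -> int:
        return sum(r.n_points for r in self.rois)

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def all_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (positions, orientations) in ROI order."""
        pos = np.concatenate([r.points for r in self.rois], axis=0)
        ori = np.concatenate([r.orientations for r in self.rois], axis=0)
        return pos, ori

    def source_slices(self) -> dict[str, slice]:
        """Map ROI label -> slice into the concatenated source axis."""
        out: dict[str, slice] = {}
        i = 0
        for r in self.rois:
            out[r.label] = slice(i, i + r.n_points)
            i += r.n_points
        return out

    def validate_inside(self, conductor: ConductorModel) -> None:
        pos, _ = self.all_points()
        radii = np.linalg.norm(pos - conductor.center, axis=1)
        if np.any(radii >= conductor.radius):
            bad = radii.max()
            raise ValueError(
                f"atlas point at radius {bad:.4f} m lies outside the conductor "
                f"sphere (radius {conductor.radius} m)"
            )


#: Nominal ROI centroids (m, head frame) — schematic positions inside a
#: 0.09 m sphere, not subject anatomy.
DEFAULT_ROI_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "olfactory_L": (-0.020, 0.030, -0.025),
    "olfactory_R": (0.020, 0.030, -0.025),
    "somatosensory_L": (-0.040, -0.020, 0.072),
    "somatosensory_R": (0.040, -0.020, 0.072),
    "orbitofrontal_L": (-0.028, 0.058, -0.012),
    "medial_frontal_L": (-0.008, 0.055, 0.048),
    "precentral_L": (-0.042, 0.008, 0.068),
}


def default_source_atlas(
    points_per_roi: int = 9,
    spread: float = 0.02,
    centroids: dict[str, tuple[float, float, float]] | None = None,
) -> SourceAtlas:
    """Build the default schematic atlas.

    Each ROI is a cortical patch modelled as ``points_per_roi`` dipoles laid
    out on a deterministic golden-angle disc of radius ``spread`` metres in
    the plane tangential to the centroid's radial direction.  A patch of
    order ten incoherent mesosources is the usual way to emulate extended
    cortical activity; it also gives the ROI-mean power estimate enough
    degrees of freedom to be stable at the paradigm's epoch counts.  All
    orientations are tangential (radial dipoles are magnetically silent in a
    spherical conductor, so tangential sources are the ones MEG sees).
    """
    if centroids is None:
        centroids = DEFAULT_ROI_CENTROIDS
    golden = np.pi * (3.0 - np.sqrt(5.0))
    rois = []
    for label, c in centroids.items():
        c = np.asarray(c, dtype=float)
        t1 = _tangential_unit(c)
        t2 = np.cross(c / np.linalg.norm(c), t1)
        pts = [c]
        for k in range(1, points_per_roi):
            rad = spread * np.sqrt(k / max(points_per_roi - 1, 1))
            ang = k * golden
            pts.append(c + rad * (np.cos(ang) * t1 + np.sin(ang) * t2))
        pts = np.stack(pts[:points_per_roi], axis=0)
        # orientations rotate through the tangential plane across the patch,
        # emulating cortical folding; orthogonal tangential dipoles at nearby
        # locations have distinct field patterns, so the patch is not a
        # single effective source
        ori = []
        for k, p in enumerate(pts):
            u1 = _tangential_unit(p)
            u2 = np.cross(p / np.linalg.norm(p), u1)
            phi = k * golden
            ori.append(np.cos(phi) * u1 + np.sin(phi) * u2)
        ori = np.stack(ori, axis=0)
        rois.append(ROI(label, pts, ori))
    return SourceAtlas(tuple(rois))


_ATLAS_HEADER = ["roi", "x", "y", "z", "ox", "oy", "oz"]


def write_atlas(atlas: SourceAtlas, path: str | Path) -> None:
    """Write an atlas as TSV: roi, x, y, z, ox, oy, oz (metres, head frame)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_ATLAS_HEADER) + "\n")
        for roi in atlas.rois:
            for p, o in zip(roi.points, roi.orientations):
                vals = [f"{v:.6f}" for v in (*p, *o)]
                fh.write(roi.label + "\t" + "\t".join(vals) + "\n")


def read_atlas(path: str | Path) -> SourceAtlas:
    """Read a TSV atlas, grouping consecutive rows by ROI label."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _ATLAS_HEADER:
        raise ValueError(f"{path}: expected header {_ATLAS_HEADER}")
    groups: dict[str, list[list[float]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}: line {lineno}: expected 7 columns")
        label = parts[0]
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(vals)
    rois = []
    for label in order:
        arr = np.asarray(groups[label])
        rois.append(ROI(label, arr[:, :3], arr[:, 3:]))
    return SourceAtlas(tuple(rois))
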