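"""Segmentation quality metrics.

Volumetric Dice, tolerance-based surface Dice, their per-scan average
("scan quality"), and the cohort-level best-of-variants score that drives
dataset-partition search.  All distances are Euclidean in millimetres and
respect anisotropic voxel spacing; surfaces are the centres of foreground
voxels with at least one face-adjacent background (or out-of-grid)
neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


class GridMismatchError(ValueError):
    """Two masks/images do not share shape or spacing."""


class EmptySurfaceError(ValueError):
    """Surface extraction requested on an empty mask."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return s


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid. Axis 0 is the slice (transversal) axis; spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 3D binary label field on the same grid as its image; spacing in mm."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.labels)
        uniq = np.unique(arr)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"mask labels must be in {{0,1}}, got values {uniq[:8]}")
        object.__setattr__(self, "labels", arr.astype(bool))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    def is_empty(self) -> bool:
        return not self.labels.any()


@dataclass(frozen=True)
class MetricConfig:
    """Metric conventions.

    tolerance_mm
        Surface-Dice tolerance tau. Default 2.0 mm, a conventional organ
        tolerance sitting between the 0.59 mm in-plane and 3 mm slice spacing
        of the acquisition this package emulates.
    empty_pair_value
        Value returned by both metrics when both masks are empty (two empty
        masks agree perfectly). One empty vs one nonempty mask scores 0.
    per_slice
        When True, best-of-variants scoring picks the best variant per
        transversal slice instead of per scan.
    """

    tolerance_mm: float = 2.0
    empty_pair_value: float = 1.0
    per_slice: bool = False

    def __post_init__(self):
        if self.tolerance_mm < 0:
            raise ValueError("tolerance_mm must be >= 0")
        if not 0.0 <= self.empty_pair_value <= 1.0:
            raise ValueError("empty_pair_value must be in [0, 1]")


@dataclass(frozen=True)
class QualityMatrix:
    """Per-scan, per-variant quality scores S[i, k] in [0, 1].

    Rows index validation scans i = 1..N, columns variants k = 1..K.
    """

    scores: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("scores must be a nonempty N x K matrix")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("quality scores must lie in [0, 1]")
        object.__setattr__(self, "scores", arr)

    @property
    def n_scans(self) -> int:
        return self.scores.shape[0]

    @property
    def n_variants(self) -> int:
        return self.scores.shape[1]


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError(f"mask spacings differ: {a.spacing} vs {b.spacing}")


def volumetric_dsc(a: BinaryMask, b: BinaryMask,
                   cfg: MetricConfig = MetricConfig()) -> float:
    """Volumetric Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    _check_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return cfg.empty_pair_value
    inter = int(np.logical_and(a.labels, b.labels).sum())
    return 2.0 * inter / (na + nb)


def extract_surface(m: BinaryMask) -> np.ndarray:
    """Surface voxel centres in mm, as an (n, 3) array.

    A foreground voxel is a surface voxel when at least one of its six
    face-adjacent neighbours is background or lies outside the grid.
    """
    if m.is_empty():
        raise EmptySurfaceError("cannot extract the surface of an empty mask")
    # border_value=0 makes out-of-grid neighbours count as background
    interior = ndimage.binary_erosion(
        m.labels, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    surface = m.labels & ~interior
    idx = np.argwhere(surface)
    return idx.astype(float) * np.asarray(m.spacing)


def surface_dsc(a: BinaryMask, b: BinaryMask,
                cfg: MetricConfig = MetricConfig()) -> float:
    """Surface Dice at tolerance ``cfg.tolerance_mm``.

    Fraction of the two surfaces' points lying within tau of the other
    surface, pooled over both surfaces.  Distances between surface-voxel
    centres, Euclidean in mm.
    """
    _check_same_grid(a, b)
    if a.is_empty() and b.is_empty():
        return cfg.empty_pair_value
    if a.is_empty() or b.is_empty():
        return 0.0
    sa = extract_surface(a)
    sb = extract_surface(b)
    tau = cfg.tolerance_mm
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    hits = int((d_ab <= tau).sum()) + int((d_ba <= tau).sum())
    return hits / (len(sa) + len(sb))


def scan_quality(pred: BinaryMask, ref: BinaryMask,
                 cfg: MetricConfig = MetricConfig()) -> float:
    """Per-scan quality: the mean of volumetric and surface Dice."""
    return 0.5 * (volumetric_dsc(pred, ref, cfg) + surface_dsc(pred, ref, cfg))


def slice_qualities(pred: BinaryMask, ref: BinaryMask,
                    cfg: MetricConfig = MetricConfig()) -> np.ndarray:
    """Per-transversal-slice quality, for per-slice best-of-variants scoring.

    Each slice is treated as a one-slice volume; slice pairs that are both
    empty score ``cfg.empty_pair_value``.
    """
    _check_same_grid(pred, ref)
    out = np.empty(pred.shape[0])
    for z in range(pred.shape[0]):
        pz = BinaryMask(pred.labels[z:z + 1], pred.spacing)
        rz = BinaryMask(ref.labels[z:z + 1], ref.spacing)
        out[z] = scan_quality(pz, rz, cfg)
    return out


def cohort_score(q: QualityMatrix) -> float:
    """Best-of-variants cohort score: mean over scans of the row-wise maximum.

    Models a clinician picking, for each scan, the most preferred of the K
    proposed variants.
    """
    return float(q.scores.max(axis=1).mean())


def quality_matrix(variant_masks, ref_masks,
                   cfg: MetricConfig = MetricConfig()) -> QualityMatrix:
    """Build S[i, k] for N scans x K variants.

    ``variant_masks`` is a sequence of per-scan variant lists (length K each);
    ``ref_masks`` the matching references.  In per-slice mode each entry is
    the scan's mean over slices of that variant's slice quality; the per-slice
    best-of maximisation is then done by :func:`per_slice_cohort_score`.
    """
    rows = []
    for variants, ref in zip(variant_masks, ref_masks, strict=True):
        rows.append([scan_quality(v, ref, cfg) for v in variants])
    return QualityMatrix(np.array(rows))


def per_slice_cohort_score(variant_masks, ref_masks,
                           cfg: MetricConfig = MetricConfig()) -> float:
    """Per-slice alternative of the cohort score.

    For each scan, quality is computed per transversal slice and the maximum
    over variants taken slice-wise before averaging over slices; the cohort
    score is the mean over scans.
    """
    per_scan = []
    for variants, ref in zip(variant_masks, ref_masks, strict=True):
        sq = np.stack([slice_qualities(v, ref, cfg) for v in variants])
        per_scan.append(sq.max(axis=0).mean())
    if not per_scan:
        raise ValueError("empty cohort")
    return float(np.mean(per_scan))
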