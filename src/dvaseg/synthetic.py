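"""Synthetic cohort generation with planted delineation styles.

Emulates the structure of a clinical segmentation dataset in which each scan
carries exactly one reference delineation, but the *way* of delineating
varies across scans: a scan-level "style" dilates or erodes the reference
contour near the organ's cranial/caudal poles (the base and apex thirds of
its slice range), where real observer variation is known to be largest,
while leaving the mid-gland third nearly unchanged.

The organ is a randomized superellipsoid on a small anisotropic grid
(default 32 x 48 x 48 voxels at 3.0 x 0.59 x 0.59 mm, echoing a transversal
MRI acquisition at desk scale).  Style offsets are applied by thresholding
the anisotropy-correct signed Euclidean distance transform in mm, not by
iterated voxel dilation.  All generation is reproducible from (seed,
parameters) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import BinaryMask, VolumeImage
from .study import GRADE_LEVELS, region_split

GRADES = np.array(GRADE_LEVELS)

DEFAULT_SHAPE = (32, 48, 48)
DEFAULT_SPACING = (3.0, 0.59, 0.59)
#: offsets beyond this could push the contour past the organ's waist
MAX_OFFSET_MM = 6.0


class GeometryError(ValueError):
    """The requested organ does not fit in the grid."""


@dataclass(frozen=True)
class StyleSpec:
    """A planted per-scan delineation style.

    polar_offset_mm moves the reference contour outward (+) or inward (-)
    in the outer thirds of the organ's slice range; mid_offset_mm does the
    same in the middle third (usually 0); noise_sd_mm adds per-slice random
    boundary jitter.
    """

    style_id: int
    polar_offset_mm: float = 0.0
    mid_offset_mm: float = 0.0
    noise_sd_mm: float = 0.0

    def __post_init__(self):
        if abs(self.polar_offset_mm) > MAX_OFFSET_MM:
            raise ValueError(f"|polar_offset_mm| must be <= {MAX_OFFSET_MM}")
        if abs(self.mid_offset_mm) > MAX_OFFSET_MM:
            raise ValueError(f"|mid_offset_mm| must be <= {MAX_OFFSET_MM}")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")


@dataclass(frozen=True)
class SyntheticScan:
    """One synthetic scan: image, its single reference mask, and provenance.

    ``style_id`` is the hidden ground-truth label used only for recovery
    diagnostics; it is never exposed to the model or the partition search.
    """

    image: VolumeImage
    reference: BinaryMask
    style_id: int
    scan_id: str
    seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    scans: tuple[SyntheticScan, ...]
    split: dict[str, tuple[int, ...]]
    style_mixture: tuple[float, ...]

    def subset(self, name: str) -> list[SyntheticScan]:
        return [self.scans[i] for i in self.split[name]]

    @property
    def style_labels(self) -> np.ndarray:
        return np.array([s.style_id for s in self.scans])

    def manifest(self) -> pd.DataFrame:
        names = {i: n for n, idxs in self.split.items() for i in idxs}
        return pd.DataFrame({
            "scan_id": [s.scan_id for s in self.scans],
            "style_id": [s.style_id for s in self.scans],
            "split": [names[i] for i in range(len(self.scans))],
            "seed": [s.seed for s in self.scans],
        })


def _base_organ(rng: np.random.Generator, shape, spacing) -> np.ndarray:
    """Randomized superellipsoid indicator on the grid."""
    shape = tuple(shape)
    spacing = np.asarray(spacing, dtype=float)
    extent = (np.array(shape) - 1) * spacing
    # semi-axes in mm: (z, y, x); z is the slice axis
    c = rng.uniform(18.0, 24.0)
    a = rng.uniform(8.0, 10.5)
    b = rng.uniform(8.0, 10.5)
    p = rng.uniform(2.0, 3.0)
    centre = extent / 2 + rng.uniform([-3.0, -1.0, -1.0], [3.0, 1.0, 1.0])
    if (centre[0] - c < 0 or centre[0] + c > extent[0]
            or centre[1] - b < 1.5 or centre[1] + b > extent[1] - 1.5
            or centre[2] - a < 1.5 or centre[2] + a > extent[2] - 1.5):
        raise GeometryError("organ exceeds the grid extent")
    zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                             indexing="ij")
    val = (np.abs((zz - centre[0]) / c) ** p
           + np.abs((yy - centre[1]) / b) ** p
           + np.abs((xx - centre[2]) / a) ** p)
    return val <= 1.0


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: positive inside."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _apply_style(base: np.ndarray, style: StyleSpec, spacing,
                 rng: np.random.Generator) -> np.ndarray:
    """Offset the base contour per slice region by thresholding the signed EDT."""
    if (style.polar_offset_mm == 0 and style.mid_offset_mm == 0
            and style.noise_sd_mm == 0):
        return base.copy()
    zs = np.flatnonzero(base.any(axis=(1, 2)))
    split = region_split(int(zs[0]), int(zs[-1]))
    offset_z = np.zeros(base.shape[0])
    for region, off in zip(split.regions,
                           (style.polar_offset_mm, style.mid_offset_mm,
                            style.polar_offset_mm)):
        offset_z[list(region)] = off
    if style.noise_sd_mm > 0:
        offset_z = offset_z + rng.normal(0.0, style.noise_sd_mm, base.shape[0])
    sd = _signed_distance_mm(base, spacing)
    return sd >= -offset_z[:, None, None]


def generate_scan(seed: int, style: StyleSpec,
                  shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING,
                  scan_id: str | None = None,
                  image_noise_sd: float = 0.05) -> SyntheticScan:
    """Generate one scan deterministically from (seed, style, grid).

    The base organ depends on the seed only, so the same seed under two
    styles yields offsets of the same underlying shape.  The image is the
    smoothed organ indicator plus Gaussian intensity noise.
    """
    base_rng = np.random.default_rng(seed)
    base = _base_organ(base_rng, shape, spacing)
    jitter_rng = np.random.default_rng([seed, style.style_id + 1_000_003])
    reference = _apply_style(base, style, spacing, jitter_rng)
    if not reference.any():
        raise GeometryError("style offsets emptied the reference mask")
    sigma_vox = 1.2 / np.asarray(spacing, dtype=float)
    intensity = ndimage.gaussian_filter(base.astype(float), sigma=sigma_vox)
    intensity = intensity + base_rng.normal(0.0, image_noise_sd, base.shape)
    return SyntheticScan(
        image=VolumeImage(intensity, tuple(spacing)),
        reference=BinaryMask(reference, tuple(spacing)),
        style_id=style.style_id,
        scan_id=scan_id or f"scan_{seed}",
        seed=seed,
    )


def generate_cohort(n_scans: int, styles: list[StyleSpec], mixture,
                    split_sizes: tuple[int, int, int], seed: int,
                    shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING,
                    image_noise_sd: float = 0.05,
                    min_style_counts: dict[str, int] | None = None,
                    max_reseeds: int = 50) -> SyntheticCohort:
    """Generate a cohort with seeded style assignment and train/val/test split.

    Every style must end up represented in the training split; if a seeded
    assignment misses one, the assignment is redrawn with a derived reseed
    (up to ``max_reseeds`` times) and the retry is recorded in the manifest
    seeds.  ``min_style_counts`` strengthens the requirement per split, e.g.
    ``{"train": 6, "val": 2}`` demands at least 6 scans of every style in
    training and 2 in validation (a validation split expressing every
    planted style is what makes style recovery identifiable from the
    best-of-variants score).  Impossible configurations (zero-probability
    style, training split smaller than the number of styles) raise
    immediately.
    """
    mixture = np.asarray(mixture, dtype=float)
    if len(mixture) != len(styles):
        raise ValueError("mixture length must match the number of styles")
    if not np.isclose(mixture.sum(), 1.0):
        raise ValueError("mixture must sum to 1")
    if sum(split_sizes) != n_scans:
        raise ValueError("split sizes must sum to n_scans")
    if (mixture <= 0).any() or split_sizes[0] < len(styles):
        raise ValueError(
            "every style needs positive probability and a train split of at "
            "least one scan per style")
    required = {"train": 1}
    if min_style_counts:
        required.update(min_style_counts)

    for attempt in range(max_reseeds + 1):
        rng = np.random.default_rng([seed, attempt])
        style_idx = rng.choice(len(styles), size=n_scans, p=mixture)
        order = rng.permutation(n_scans)
        split = {
            "train": tuple(sorted(order[:split_sizes[0]])),
            "val": tuple(sorted(order[split_sizes[0]:split_sizes[0] + split_sizes[1]])),
            "test": tuple(sorted(order[split_sizes[0] + split_sizes[1]:])),
        }
        ok = True
        for name, min_count in required.items():
            counts = np.bincount([style_idx[i] for i in split[name]],
                                 minlength=len(styles))
            if (counts < min_count).any():
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not satisfy the per-split style requirements in "
            f"{max_reseeds + 1} seeded attempts")

    scan_seeds = rng.integers(0, 2 ** 31 - 1, size=n_scans)
    scans = tuple(
        generate_scan(int(scan_seeds[i]), styles[style_idx[i]], shape, spacing,
                      scan_id=f"scan_{i:03d}", image_noise_sd=image_noise_sd)
        for i in range(n_scans))
    return SyntheticCohort(scans=scans, split=split,
                           style_mixture=tuple(mixture))


# ---------------------------------------------------------------------------
# Observer-study fixture generation
# ---------------------------------------------------------------------------

#: default grade probabilities per source (levels 1..4): the reference is
#: mostly approvable, the single-variant baseline needs corrections more
#: often, the two variants sit in between with different leanings.
DEFAULT_GRADE_PROBS = {
    "reference": (0.04, 0.06, 0.25, 0.65),
    "classical": (0.09, 0.15, 0.45, 0.31),
    "dvas_1": (0.07, 0.12, 0.38, 0.43),
    "dvas_2": (0.07, 0.12, 0.42, 0.39),
}


@dataclass(frozen=True)
class StudyFixture:
    grades_per_slice: pd.DataFrame
    grades_per_scan: pd.DataFrame
    ranks_per_scan: pd.DataFrame
    params: dict = field(hash=False)


def generate_study_fixture(seed: int, n_observers: int = 3, n_scans: int = 13,
                           grade_probs: dict | None = None,
                           slice_range: tuple[int, int] = (9, 16)) -> StudyFixture:
    """Seeded observer-study tables: per-slice and per-scan grades, ranks.

    Grades in {1..4} are drawn per (observer, source) from categorical
    distributions (``grade_probs``, defaulting to
    :data:`DEFAULT_GRADE_PROBS`); per-scan ranks are competition ranks of
    the per-scan grades (better grade, lower rank; ties share a rank).  The
    distribution parameters are returned in ``params``.
    """
    probs = dict(DEFAULT_GRADE_PROBS)
    if grade_probs:
        probs.update(grade_probs)
    sources = list(probs)
    rng = np.random.default_rng(seed)
    slice_rows, scan_rows, rank_rows = [], [], []
    for obs in range(1, n_observers + 1):
        for scan in range(1, n_scans + 1):
            n_slices = int(rng.integers(*slice_range))
            scan_grades = {}
            for source in sources:
                p = np.asarray(probs[source], dtype=float)
                g_slices = rng.choice(GRADES, size=n_slices, p=p)
                slice_rows.extend(
                    {"observer": obs, "scan": scan, "slice": z, "source": source,
                     "grade": int(g)} for z, g in enumerate(g_slices))
                g_scan = int(rng.choice(GRADES, p=p))
                scan_grades[source] = g_scan
                scan_rows.append({"observer": obs, "scan": scan,
                                  "slice": pd.NA, "source": source,
                                  "grade": g_scan})
            # competition ranks: rank 1 = best grade; equal grades tie
            grades = np.array([scan_grades[s] for s in sources])
            ranks = np.array([1 + int((grades > g).sum()) for g in grades])
            rank_rows.extend(
                {"observer": obs, "scan": scan, "source": s, "rank": int(r)}
                for s, r in zip(sources, ranks))
    grades_per_slice = pd.DataFrame(slice_rows)
    grades_per_scan = pd.DataFrame(scan_rows)
    grades_per_scan["slice"] = grades_per_scan["slice"].astype("Int64")
    return StudyFixture(grades_per_slice, grades_per_scan,
                        pd.DataFrame(rank_rows),
                        params={"grade_probs": probs, "seed": seed,
                                "n_observers": n_observers, "n_scans": n_scans})
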