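"""Observer-study analytics.

Grade/rank record handling for a blinded multi-observer segmentation
evaluation: best-of-two-variants aggregation, grade and rank count
distributions, Pearson chi-squared comparisons with Bonferroni correction,
Cohen's kappa on variant preferences, and region-wise (base / mid / apex)
relative-area analysis.

Record schema
-------------
Grade records: columns ``observer, scan, slice, source, grade`` with grade in
{1, 2, 3, 4} (1 = reject, 2 = major correction, 3 = minor correction,
4 = approve without correction); ``slice`` is empty (NA) for per-scan rows.
Rank records: ``observer, scan, source, rank`` with rank >= 1, ties allowed.
Sources: ``reference`` (clinically used manual segmentation), ``classical``
(single-decoder baseline), ``dvas_1`` / ``dvas_2`` (the two variants), plus
the derived ``dvas_best``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import BinaryMask, GridMismatchError

GRADE_LEVELS = (1, 2, 3, 4)
DVAS_SOURCES = ("dvas_1", "dvas_2")
DVAS_BEST = "dvas_best"


class IncompletePairError(ValueError):
    """A dvas_1 record lacks its dvas_2 counterpart (or vice versa)."""


# ---------------------------------------------------------------------------
# Packaged fixture: the published observer-study count table
# ---------------------------------------------------------------------------

def load_observer_study_counts() -> pd.DataFrame:
    """Load the packaged observer-study count table.

    Columns: observer, granularity (slice|scan), metric (grade|rank), source
    (reference|classical|dvas), c1..c4 — the number of grades or ranks equal
    to 1, 2, 3 and 4.  The ``dvas`` rows are counts after best-of-two
    merging, as published.
    """
    with resources.files("dvaseg.data").joinpath("observer_study_counts.csv").open() as fh:
        return pd.read_csv(fh)


def records_from_counts(counts: pd.DataFrame, granularity: str,
                        metric: str) -> pd.DataFrame:
    """Expand a count table into record-level rows (synthetic expansion).

    The published table aggregates over scans/slices, so record-level scan
    and slice identifiers are assigned arbitrarily (sorted order).  Because
    the published ``dvas`` counts are already best-of-two merged, the two
    variant sources are materialised as identical copies of the merged
    values; best-of merging over this synthetic expansion reproduces the
    published counts exactly.
    """
    sub = counts[(counts.granularity == granularity) & (counts.metric == metric)]
    rows = []
    for _, r in sub.iterrows():
        values = []
        for level in GRADE_LEVELS:
            values.extend([level] * int(r[f"c{level}"]))
        sources = DVAS_SOURCES if r["source"] == "dvas" else (r["source"],)
        for source in sources:
            for j, v in enumerate(values):
                rows.append({"observer": int(r["observer"]),
                             "scan": j + 1 if granularity == "scan" else 1 + j // 40,
                             "slice": pd.NA if granularity == "scan" else j,
                             "source": source, metric: v})
    df = pd.DataFrame(rows)
    df["slice"] = df["slice"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# Best-of-variants aggregation and count distributions
# ---------------------------------------------------------------------------

def _key_cols(records: pd.DataFrame) -> list[str]:
    return [c for c in ("observer", "scan", "slice") if c in records.columns]


def best_of_dvas(records: pd.DataFrame) -> pd.DataFrame:
    """Merge the two variant sources into ``dvas_best`` rows.

    Models the real-use situation where a clinician picks the preferred of
    the two proposed variants: the merged grade is the max of the two grades
    (higher is better); the merged rank is the min (lower is better).
    Returns the input records with the merged rows appended.
    """
    value = "grade" if "grade" in records.columns else "rank"
    keys = _key_cols(records)
    a = records[records.source == DVAS_SOURCES[0]].set_index(keys)[value]
    b = records[records.source == DVAS_SOURCES[1]].set_index(keys)[value]
    if len(a) != len(b) or not a.index.equals(b.index):
        raise IncompletePairError(
            "dvas_1 and dvas_2 records are not paired one-to-one")
    merged = np.maximum(a, b) if value == "grade" else np.minimum(a, b)
    out = merged.reset_index()
    out["source"] = DVAS_BEST
    return pd.concat([records, out[records.columns.tolist()]], ignore_index=True)


def grade_distribution(records: pd.DataFrame, observer, source) -> np.ndarray:
    """Counts over grades (or ranks) 1-4 for one observer and source."""
    value = "grade" if "grade" in records.columns else "rank"
    sel = records[(records.observer == observer) & (records.source == source)]
    return np.array([int((sel[value] == g).sum()) for g in GRADE_LEVELS])


def count_grade4_scans(records: pd.DataFrame, observer, source) -> int:
    """Number of scans graded 4 (approved without correction)."""
    sel = records[(records.observer == observer) & (records.source == source)]
    return int((sel["grade"] == 4).sum())


def count_rank_le(records: pd.DataFrame, observer, source, threshold: int) -> int:
    """Number of scans where the source ranked at or above ``threshold``."""
    if threshold < 1:
        raise ValueError("rank threshold must be >= 1")
    sel = records[(records.observer == observer) & (records.source == source)]
    return int((sel["rank"] <= threshold).sum())


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def chi_squared_grades(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-squared on the 2 x G contingency table of two count rows.

    Columns whose total is zero are dropped (with the degrees of freedom
    reduced accordingly); no continuity correction is applied.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length count vectors")
    table = np.stack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.size == 0 or table.sum() == 0:
        raise ValueError("chi-squared test undefined on an all-zero table")
    if table.shape[1] < 2:
        return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: chance-corrected agreement of two label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the product of marginals.  Returns 1.0 for identical
    sequences even when p_e = 1 (single shared label).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("label sequences must be equal-length and nonempty")
    alphabet = np.union1d(a, b)
    n = len(a)
    p_o = float((a == b).mean())
    p_e = sum(float((a == c).mean()) * float((b == c).mean()) for c in alphabet)
    if np.isclose(p_e, 1.0):
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def preference_labels(records: pd.DataFrame) -> pd.DataFrame:
    """Per-key preference between the two variants: variant1 / variant2 / tie.

    The variant with the strictly better grade (higher) or rank (lower)
    wins; equal values yield a tie.
    """
    value = "grade" if "grade" in records.columns else "rank"
    keys = _key_cols(records)
    a = records[records.source == DVAS_SOURCES[0]].set_index(keys)[value]
    b = records[records.source == DVAS_SOURCES[1]].set_index(keys)[value]
    if len(a) != len(b) or not a.index.equals(b.index):
        raise IncompletePairError(
            "dvas_1 and dvas_2 records are not paired one-to-one")
    better_a = (a > b) if value == "grade" else (a < b)
    better_b = (b > a) if value == "grade" else (b < a)
    label = np.where(better_a, "variant1", np.where(better_b, "variant2", "tie"))
    out = a.reset_index()[keys]
    out["preference"] = label
    return out


def observer_preference_kappas(records: pd.DataFrame) -> dict[tuple, float]:
    """Cohen's kappa for each observer pair's variant preferences."""
    prefs = preference_labels(records)
    keys = [c for c in ("scan", "slice") if c in prefs.columns]
    wide = prefs.pivot_table(index=keys, columns="observer",
                             values="preference", aggfunc="first")
    out = {}
    observers = list(wide.columns)
    for i, oa in enumerate(observers):
        for ob in observers[i + 1:]:
            pair = wide[[oa, ob]].dropna()
            out[(oa, ob)] = cohens_kappa(pair[oa].to_numpy(), pair[ob].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Region-wise analysis (base / mid-gland / apex)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSplit:
    """Three contiguous slice-index ranges partitioning the evaluated range."""

    base: range
    mid: range
    apex: range

    @property
    def regions(self) -> tuple[range, range, range]:
        return self.base, self.mid, self.apex


def region_split(first_slice: int, last_slice: int) -> RegionSplit:
    """Split [first, last] into three equally sized contiguous slice groups.

    Remainder slices are assigned one each to the earliest groups, so group
    sizes differ by at most 1.  At least 3 slices are required.
    """
    if last_slice < first_slice:
        raise ValueError("last_slice must be >= first_slice")
    n = last_slice - first_slice + 1
    if n < 3:
        raise ValueError("region split requires at least 3 slices")
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    bounds = np.cumsum([first_slice] + sizes)
    groups = [range(bounds[i], bounds[i + 1]) for i in range(3)]
    return RegionSplit(*groups)


def relative_area_by_region(variant: BinaryMask, reference: BinaryMask,
                            split: RegionSplit) -> tuple[float, float, float]:
    """Per-region in-plane area of the variant relative to the reference.

    For each region, the summed slice areas (in mm^2: voxel count times the
    in-plane spacing product) of the variant divided by the reference's.
    A region where the reference is empty yields NaN (undefined ratio).
    """
    if variant.shape != reference.shape:
        raise GridMismatchError("variant and reference grids differ")
    ratios = []
    for region in split.regions:
        zs = [z for z in region if 0 <= z < reference.shape[0]]
        v = int(variant.labels[zs].sum())
        r = int(reference.labels[zs].sum())
        ratios.append(v / r if r > 0 else float("nan"))
    return tuple(ratios)


def evaluated_slice_range(reference: BinaryMask, margin: int = 2) -> tuple[int, int]:
    """Slice range presented for evaluation: all slices containing the organ,
    expanded by ``margin`` slices beyond its borders (clipped to the grid)."""
    zs = np.flatnonzero(reference.labels.any(axis=(1, 2)))
    if len(zs) == 0:
        raise ValueError("reference mask is empty")
    return max(0, int(zs[0]) - margin), min(reference.shape[0] - 1,
                                            int(zs[-1]) + margin)
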