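"""Per-feature methylation summaries and methylated/unmethylated calls.

Genes and TE insertions are summarised by the weighted methylation level
of the sites they span (in a species-appropriate sequence context), a
classification threshold is chosen from the bimodal level distribution --
histogram-valley search cross-checked by deterministic 1-D k-means
(k = 2) -- and each feature is called methylated (level >= threshold),
unmethylated, or undetermined when it has no covered site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import Feature
from .methylome_core import SitesLike, WeightedLevel, _as_table, _context_mask

__all__ = [
    "FeatureMethylation",
    "ThresholdReport",
    "ClassificationResult",
    "FamilyReport",
    "summarize_features",
    "select_threshold",
    "kmeans_1d",
    "classify_features",
    "filter_te_set",
]

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNDETERMINED = "undetermined"


@dataclass(frozen=True, slots=True)
class FeatureMethylation:
    """Methylation summary and status of one feature."""

    feature_id: str
    context_mode: str
    level: WeightedLevel
    status: Optional[str] = None  # set by classify_features


@dataclass(frozen=True, slots=True)
class ThresholdReport:
    """Threshold diagnostics from valley search and 1-D k-means.

    ``chosen_threshold`` is the valley when the distribution is flagged
    bimodal, otherwise the k-means boundary.
    """

    valley_threshold: float
    kmeans_boundary: float
    kmeans_centers: Tuple[float, float]
    chosen_threshold: float
    bimodality_flag: bool


@dataclass(frozen=True)
class ClassificationResult:
    features: List[FeatureMethylation]
    threshold: float
    n_methylated: int
    n_unmethylated: int
    n_undetermined: int

    @property
    def fraction_methylated(self) -> float:
        classified = self.n_methylated + self.n_unmethylated
        if classified == 0:
            return float("nan")
        return self.n_methylated / classified


@dataclass(frozen=True)
class FamilyReport:
    family: str
    n_insertions: int
    n_methylated: int
    insertion_ids: Tuple[str, ...]


def summarize_features(
    sites: SitesLike,
    features: Sequence[Feature],
    context_mode: str = "CG",
    min_cov: int = 1,
) -> List[FeatureMethylation]:
    """Weighted level per feature over sites intersecting [start, end).

    Features with no covered site in the requested context get an
    undefined level (status will be ``undetermined`` after classification).
    Statuses are left unset; see :func:`classify_features`.
    """
    table = _as_table(sites)
    keep = _context_mask(table, context_mode) & (table.n_total >= min_cov)
    table = table.subset(keep)
    slices = table.chrom_slices()
    # Prefix sums per chrom allow O(log n) per-feature aggregation.
    prefix: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (lo, hi) in slices.items():
        cm = np.concatenate([[0], np.cumsum(table.n_meth[lo:hi])])
        ct = np.concatenate([[0], np.cumsum(table.n_total[lo:hi])])
        prefix[chrom] = (table.pos[lo:hi], cm, ct)
    out: List[FeatureMethylation] = []
    mode_name = context_mode if isinstance(context_mode, str) else (
        "+".join(sorted(str(c) for c in context_mode))
    )
    for f in features:
        if f.chrom in prefix:
            pos, cm, ct = prefix[f.chrom]
            i0 = int(np.searchsorted(pos, f.start, side="left"))
            i1 = int(np.searchsorted(pos, f.end, side="left"))
            lv = WeightedLevel.from_counts(
                i1 - i0, cm[i1] - cm[i0], ct[i1] - ct[i0]
            )
        else:
            lv = WeightedLevel.from_counts(0, 0, 0)
        out.append(FeatureMethylation(f.id, mode_name, lv))
    return out


def kmeans_1d(values: np.ndarray, max_iter: int = 200) -> Tuple[float, float]:
    """Deterministic Lloyd k-means with k = 2 on 1-D data.

    Centers are initialised at the data minimum and maximum; points
    equidistant from both centers join the lower cluster.  Returns the
    final centers in ascending order.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("k-means on constant data is degenerate")
    c_lo, c_hi = lo, hi
    for _ in range(max_iter):
        boundary = (c_lo + c_hi) / 2.0
        in_lo = x <= boundary  # ties break toward the lower center
        if in_lo.all() or not in_lo.any():
            break
        new_lo = float(x[in_lo].mean())
        new_hi = float(x[~in_lo].mean())
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    return c_lo, c_hi


def select_threshold(
    levels: Sequence[float],
    bin_width: float = 0.05,
    min_levels: int = 20,
) -> ThresholdReport:
    """Choose a methylated/unmethylated threshold from a level distribution.

    A fixed-width histogram is scanned for its two strongest modes (local
    maxima); the valley threshold is the midpoint of the lowest-density
    bin strictly between them.  The distribution is flagged bimodal when
    that valley bin holds fewer than half the counts of the smaller mode.
    Independently, deterministic 1-D k-means (k = 2) gives a boundary at
    the midpoint of its final centers.  The chosen threshold is the valley
    when bimodality holds, else the k-means boundary.
    """
    x = np.asarray([v for v in levels if np.isfinite(v)], dtype=float)
    if len(x) < min_levels:
        raise ValueError(
            f"need >= {min_levels} defined levels, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise ValueError("all levels identical: no threshold exists")
    n_bins = max(2, int(round(1.0 / bin_width)))
    counts, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0))

    # local maxima, collapsing plateaus to their leftmost bin
    modes = []
    for i in range(n_bins):
        if counts[i] == 0:
            continue
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n_bins - 1 else -1
        if counts[i] >= left and counts[i] >= right:
            if modes and modes[-1] == i - 1 and counts[i] == counts[i - 1]:
                continue
            modes.append(i)
    modes.sort(key=lambda i: (-counts[i], i))

    valley = float("nan")
    bimodal = False
    if len(modes) >= 2:
        m1, m2 = sorted(modes[:2])
        if m2 - m1 >= 2:
            between = np.arange(m1 + 1, m2)
            smaller_mode = min(counts[m1], counts[m2])
            # valley candidates: bins sparse enough to qualify under the
            # bimodality rule; any of them separates the modes, so pick
            # the one nearest the inter-mode midpoint.  Without such a
            # bin the distribution is not bimodal and the valley is
            # informational only (plain minimum).
            candidates = between[counts[between] < smaller_mode / 2.0]
            target = (m1 + m2) / 2.0
            if len(candidates):
                bimodal = True
                v_bin = int(candidates[np.argmin(np.abs(candidates - target))])
            else:
                v_bin = int(between[np.argmin(counts[between])])
            valley = float((edges[v_bin] + edges[v_bin + 1]) / 2.0)

    c_lo, c_hi = kmeans_1d(x)
    boundary = (c_lo + c_hi) / 2.0
    chosen = valley if bimodal else boundary
    return ThresholdReport(
        valley_threshold=valley,
        kmeans_boundary=boundary,
        kmeans_centers=(c_lo, c_hi),
        chosen_threshold=chosen,
        bimodality_flag=bimodal,
    )


def classify_features(
    summaries: Sequence[FeatureMethylation],
    threshold: float,
) -> ClassificationResult:
    """Set statuses: methylated iff the level is defined and >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    out: List[FeatureMethylation] = []
    n_m = n_u = n_und = 0
    for fm in summaries:
        if not fm.level.defined:
            status = UNDETERMINED
            n_und += 1
        elif fm.level.level >= threshold:
            status = METHYLATED
            n_m += 1
        else:
            status = UNMETHYLATED
            n_u += 1
        out.append(replace(fm, status=status))
    return ClassificationResult(out, threshold, n_m, n_u, n_und)


def filter_te_set(
    te_features: Sequence[Feature],
    te_summaries: Sequence[FeatureMethylation],
    threshold: float,
    min_len: int = 500,
    min_meth_insertions: int = 20,
) -> Dict[str, FamilyReport]:
    """Families retained for age/methylation reporting.

    Insertions shorter than *min_len* are dropped before counting; a
    family is retained iff at least *min_meth_insertions* of its remaining
    insertions are methylated at *threshold*.
    """
    by_id = {fm.feature_id: fm for fm in te_summaries}
    tallies: Dict[str, List[Tuple[str, bool]]] = {}
    for f in te_features:
        if f.length < min_len:
            continue
        fm = by_id.get(f.id)
        if fm is None:
            continue
        is_meth = fm.level.defined and fm.level.level >= threshold
        tallies.setdefault(f.class_label or "Unknown", []).append((f.id, is_meth))
    out: Dict[str, FamilyReport] = {}
    for family, rows in tallies.items():
        n_meth = sum(1 for _, m in rows if m)
        if n_meth >= min_meth_insertions:
            out[family] = FamilyReport(
                family=family,
                n_insertions=len(rows),
                n_methylated=n_meth,
                insertion_ids=tuple(i for i, _ in rows),
            )
    return out
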