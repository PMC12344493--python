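"""Sliding-window hypermethylated-region calling.

Each chromosome is tiled with fixed windows (default 500 bp, 250 bp step,
clipped at the chromosome end); windows whose weighted methylation level
strictly exceeds a cutoff (default 10%) and that hold a minimum number of
covered cytosines are retained and merged -- overlapping or book-ended --
into maximal regions whose mean level is recomputed from the pooled read
counts over the merged span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping

import numpy as np

from .io_formats import Feature
from .methylome_core import SitesLike, _as_table, _context_mask

__all__ = ["MethylatedRegion", "call_hypermethylated_regions"]


@dataclass(frozen=True, slots=True)
class MethylatedRegion:
    """A maximal merged run of passing windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_level: float
    n_windows: int
    n_sites: int

    def to_feature(self, region_id: str) -> Feature:
        return Feature(
            chrom=self.chrom, start=self.start, end=self.end, strand=".",
            id=region_id, kind="region",
        )


def call_hypermethylated_regions(
    sites: SitesLike,
    genome_lengths: Mapping[str, int],
    window: int = 500,
    step: int = 250,
    min_level: float = 0.10,
    context_mode: str = "CG",
    min_sites: int = 5,
    min_cov: int = 1,
) -> List[MethylatedRegion]:
    """Call hypermethylated regions from sliding windows.

    Windows are ``[k*step, k*step + window)`` clipped at the chromosome
    end; a window passes when its weighted level is strictly greater than
    *min_level* and it contains at least *min_sites* covered cytosines in
    *context_mode*.  Passing windows that overlap or abut are merged.
    An empty site stream yields an empty list; a site chromosome missing
    from *genome_lengths* raises :class:`ValueError`.
    """
    if step > window:
        raise ValueError(f"step ({step}) must be <= window ({window})")
    if not 0 < min_level < 1:
        raise ValueError(f"min_level must be in (0,1), got {min_level}")
    table = _as_table(sites)
    missing = [c for c in table.chrom_slices() if c not in genome_lengths]
    if missing:
        raise ValueError(
            f"chromosomes in sites absent from genome lengths: {missing}"
        )
    keep = _context_mask(table, context_mode) & (table.n_total >= min_cov)
    table = table.subset(keep)
    slices = table.chrom_slices()
    regions: List[MethylatedRegion] = []
    for chrom in sorted(slices):
        lo, hi = slices[chrom]
        pos = table.pos[lo:hi]
        cm = np.concatenate([[0], np.cumsum(table.n_meth[lo:hi])])
        ct = np.concatenate([[0], np.cumsum(table.n_total[lo:hi])])
        length = int(genome_lengths[chrom])
        n_win = max(0, (length - 1) // step + 1)
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * step
        ends = np.minimum(starts + window, length)
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        w_sites = i1 - i0
        w_meth = cm[i1] - cm[i0]
        w_total = ct[i1] - ct[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            w_level = np.where(w_total > 0, w_meth / np.maximum(w_total, 1), 0.0)
        passing = (w_level > min_level) & (w_sites >= min_sites) & (w_total > 0)
        idx = np.flatnonzero(passing)
        if len(idx) == 0:
            continue
        # merge overlapping or book-ended passing windows
        merged: List[List[int]] = []  # [start, end, n_windows]
        for k in idx:
            s, e = int(starts[k]), int(ends[k])
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] += 1
            else:
                merged.append([s, e, 1])
        for s, e, nw in merged:
            j0 = int(np.searchsorted(pos, s, side="left"))
            j1 = int(np.searchsorted(pos, e, side="left"))
            meth = int(cm[j1] - cm[j0])
            total = int(ct[j1] - ct[j0])
            regions.append(
                MethylatedRegion(
                    chrom=chrom, start=s, end=e,
                    mean_level=meth / total if total else float("nan"),
                    n_windows=nw, n_sites=j1 - j0,
                )
            )
    return regions
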