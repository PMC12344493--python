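"""Core methylation arithmetic.

Context classification against a genome, read-count-weighted methylation
levels, global per-context levels, spike-in conversion QC, CpG-dyad
symmetry and metaprofiles over features.

Levels are always weighted means of read counts (sum of methylated reads
over sum of total reads), never means of per-site fractions, so pooling a
disjoint partition of a region reproduces the whole-region level exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io_formats import CytosineSite, Feature

__all__ = [
    "WeightedLevel",
    "SpikeInQC",
    "DyadSymmetry",
    "SiteTable",
    "classify_context",
    "weighted_level",
    "global_context_levels",
    "spike_in_qc",
    "dyad_symmetry",
    "metaprofile",
    "Metaprofile",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: dinucleotide context labels
DINUC_CONTEXTS = ("CA", "CC", "CG", "CT")
#: trinucleotide context labels
TRINUC_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True, slots=True)
class WeightedLevel:
    """Read-count-weighted methylation level of a set of sites.

    ``level`` is NaN (and :attr:`defined` False) when no reads support it;
    an undefined level is never silently reported as 0.
    """

    level: float
    n_sites: int
    n_meth_reads: int
    n_total_reads: int

    @property
    def defined(self) -> bool:
        return self.n_total_reads > 0

    @classmethod
    def from_counts(cls, n_sites: int, n_meth: int, n_total: int) -> "WeightedLevel":
        level = n_meth / n_total if n_total > 0 else float("nan")
        return cls(level, int(n_sites), int(n_meth), int(n_total))


@dataclass(frozen=True, slots=True)
class SpikeInQC:
    """Spike-in control rates.

    ``nonconversion_rate`` is the all-C weighted level of the unmethylated
    control contig (the assay's false-positive floor); ``false_negative_rate``
    is one minus the CpG-context level of the methylated control contig.
    """

    nonconversion_rate: float
    false_negative_rate: float
    n_sites_unmethylated: int
    n_sites_methylated: int


@dataclass(frozen=True, slots=True)
class DyadSymmetry:
    """Pearson correlation of plus/minus levels across CpG dyads."""

    r: float
    n_dyads: int


# ---------------------------------------------------------------------------
# Context classification
# ---------------------------------------------------------------------------


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Extract an upper-case sequence window; works for plain strings and
    pyfaidx records alike."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    return str(genome[chrom][start:end]).upper()


def classify_context(
    genome: Mapping[str, object], chrom: str, pos: int, strand: str
) -> Tuple[str, str]:
    """Return ``(dinucleotide, trinucleotide)`` context of a cytosine.

    The dinucleotide is the cytosine plus the next base on its own strand;
    the trinucleotide collapses to ``CG`` if the next base is G, ``CHG`` if
    the base after next is G, otherwise ``CHH``.  ``NA`` is returned for a
    slot whenever the required window runs off the contig or contains N.
    Raises :class:`ValueError` if the base at *pos* is not a cytosine on
    the requested strand.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    length = len(genome[chrom])
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    if strand == "+":
        base = _fetch(genome, chrom, pos, pos + 1)
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base!r}, not C")
        nxt = _fetch(genome, chrom, pos + 1, pos + 2) if pos + 1 < length else ""
        nxt2 = _fetch(genome, chrom, pos + 2, pos + 3) if pos + 2 < length else ""
    else:
        base = _fetch(genome, chrom, pos, pos + 1)
        if base != "G":  # a minus-strand C is a Watson G
            raise ValueError(f"{chrom}:{pos}(-) is {base!r}, not C")
        nxt = (
            _fetch(genome, chrom, pos - 1, pos).translate(_COMPLEMENT)
            if pos - 1 >= 0
            else ""
        )
        nxt2 = (
            _fetch(genome, chrom, pos - 2, pos - 1).translate(_COMPLEMENT)
            if pos - 2 >= 0
            else ""
        )
    if nxt in ("", "N"):
        return "NA", "NA"
    dinuc = "C" + nxt
    if nxt == "G":
        return dinuc, "CG"
    if nxt2 in ("", "N"):
        return dinuc, "NA"
    return dinuc, "CHG" if nxt2 == "G" else "CHH"


# ---------------------------------------------------------------------------
# Columnar site container
# ---------------------------------------------------------------------------


class SiteTable:
    """Columnar container of cytosine sites sorted by (chrom, pos, strand).

    This is the workhorse representation behind every level computation;
    the streaming :class:`~methylgate.io_formats.CytosineSite` interface
    converts to and from it losslessly.
    """

    __slots__ = ("chrom", "pos", "strand", "dinuc", "trinuc", "n_meth",
                 "n_total", "_chrom_slices")

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        strand: np.ndarray,
        dinuc: np.ndarray,
        trinuc: np.ndarray,
        n_meth: np.ndarray,
        n_total: np.ndarray,
    ):
        chrom_u = np.asarray(chrom, dtype="U64")
        _, chrom_codes = np.unique(chrom_u, return_inverse=True)
        order = np.lexsort((strand, pos, chrom_codes))
        self.chrom = np.asarray(chrom, dtype=object)[order]
        self.pos = np.asarray(pos, dtype=np.int64)[order]
        self.strand = np.asarray(strand, dtype="U1")[order]
        self.dinuc = np.asarray(dinuc, dtype="U2")[order]
        self.trinuc = np.asarray(trinuc, dtype="U3")[order]
        self.n_meth = np.asarray(n_meth, dtype=np.int64)[order]
        self.n_total = np.asarray(n_total, dtype=np.int64)[order]
        if np.any(self.n_meth > self.n_total):
            raise ValueError("n_meth > n_total in site table")
        self._chrom_slices: Optional[Dict[str, Tuple[int, int]]] = None

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def from_sites(cls, sites: Iterable[CytosineSite]) -> "SiteTable":
        rows = list(sites)
        return cls(
            np.array([s.chrom for s in rows], dtype=object),
            np.array([s.pos for s in rows], dtype=np.int64),
            np.array([s.strand for s in rows], dtype="U1"),
            np.array([s.dinuc_context for s in rows], dtype="U2"),
            np.array([s.trinuc_context for s in rows], dtype="U3"),
            np.array([s.n_meth for s in rows], dtype=np.int64),
            np.array([s.n_total for s in rows], dtype=np.int64),
        )

    @classmethod
    def from_cgmap(cls, path) -> "SiteTable":
        """Vectorised CGmap loader (same dialect as ``read_cgmap``)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "base", "pos", "trinuc", "dinuc", "level",
                   "n_meth", "n_total"],
            dtype={"chrom": str, "base": str, "pos": np.int64,
                   "trinuc": str, "dinuc": str, "n_meth": np.int64,
                   "n_total": np.int64},
        )
        bad = ~df["base"].isin(["C", "G"])
        if bad.any():
            raise ValueError(
                f"{path}: unknown Watson-strand base at line "
                f"{int(np.flatnonzero(bad)[0]) + 1}"
            )
        if (df["n_meth"] > df["n_total"]).any():
            raise ValueError(f"{path}: n_meth > n_total")
        strand = np.where(df["base"].to_numpy() == "C", "+", "-")
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["pos"].to_numpy() - 1,
            strand,
            df["dinuc"].to_numpy(dtype="U2"),
            df["trinuc"].to_numpy(dtype="U3"),
            df["n_meth"].to_numpy(),
            df["n_total"].to_numpy(),
        )

    def to_sites(self) -> Iterator[CytosineSite]:
        for i in range(len(self)):
            yield CytosineSite(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                strand=str(self.strand[i]),
                dinuc_context=str(self.dinuc[i]),
                trinuc_context=str(self.trinuc[i]),
                n_meth=int(self.n_meth[i]),
                n_total=int(self.n_total[i]),
            )

    def subset(self, mask: np.ndarray) -> "SiteTable":
        return SiteTable(
            self.chrom[mask], self.pos[mask], self.strand[mask],
            self.dinuc[mask], self.trinuc[mask], self.n_meth[mask],
            self.n_total[mask],
        )

    def chrom_slices(self) -> Dict[str, Tuple[int, int]]:
        """``chrom -> (lo, hi)`` row ranges; positions within are sorted."""
        if self._chrom_slices is None:
            slices: Dict[str, Tuple[int, int]] = {}
            if len(self):
                chroms = self.chrom.astype("U64")
                uniq, starts = np.unique(chroms, return_index=True)
                order = np.argsort(starts)
                bounds = list(starts[order]) + [len(self)]
                for i, c in enumerate(uniq[order]):
                    slices[str(c)] = (int(bounds[i]), int(bounds[i + 1]))
            self._chrom_slices = slices
        return self._chrom_slices

    def context_mask(self, context_filter) -> np.ndarray:
        return _context_mask(self, context_filter)


SitesLike = Union[SiteTable, Iterable[CytosineSite]]


def _as_table(sites: SitesLike) -> SiteTable:
    if isinstance(sites, SiteTable):
        return sites
    return SiteTable.from_sites(sites)


def _context_mask(table: SiteTable, context_filter) -> np.ndarray:
    """Boolean mask of sites passing a context filter.

    Accepted filters: ``CG``/``CHG``/``CHH`` (trinucleotide), ``CX`` (all
    cytosines), ``non-CG``, or an explicit collection of dinucleotide
    labels such as ``{"CA", "CT"}``.
    """
    if isinstance(context_filter, str):
        mode = context_filter.upper().replace("NONCG", "NON-CG")
        if mode == "CX":
            return np.ones(len(table), dtype=bool)
        if mode in ("CG", "CHG", "CHH"):
            return table.trinuc == mode
        if mode == "NON-CG":
            return table.trinuc != "CG"
        raise ValueError(f"unknown context filter {context_filter!r}")
    wanted = {str(c).upper() for c in context_filter}
    unknown = wanted - set(DINUC_CONTEXTS)
    if unknown:
        raise ValueError(f"unknown dinucleotide contexts {sorted(unknown)}")
    return np.isin(table.dinuc, sorted(wanted))


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------


def weighted_level(
    sites: SitesLike,
    context_filter="CX",
    min_cov: int = 1,
) -> WeightedLevel:
    """Weighted methylation level over sites passing a context filter.

    Sites with ``n_total < min_cov`` are excluded.  When no site passes,
    the result is flagged undefined (NaN level) rather than 0.
    """
    table = _as_table(sites)
    mask = _context_mask(table, context_filter) & (table.n_total >= min_cov)
    return WeightedLevel.from_counts(
        int(mask.sum()),
        int(table.n_meth[mask].sum()),
        int(table.n_total[mask].sum()),
    )


def global_context_levels(
    sites: SitesLike,
    exclude_contigs: Sequence[str] = (),
    min_cov: int = 1,
) -> Dict[str, WeightedLevel]:
    """Genome-wide weighted levels per context.

    Returns one :class:`WeightedLevel` per dinucleotide context (CA, CC,
    CG, CT), per non-CpG trinucleotide context (CHG, CHH) and for all
    cytosines (CX).  Spike-in contigs should be passed via
    *exclude_contigs*.
    """
    table = _as_table(sites)
    if exclude_contigs:
        keep = ~np.isin(table.chrom.astype("U64"), list(exclude_contigs))
        table = table.subset(keep)
    out: Dict[str, WeightedLevel] = {}
    for dinuc in DINUC_CONTEXTS:
        out[dinuc] = weighted_level(table, {dinuc}, min_cov)
    for trinuc in ("CHG", "CHH"):
        out[trinuc] = weighted_level(table, trinuc, min_cov)
    out["CX"] = weighted_level(table, "CX", min_cov)
    return out


def spike_in_qc(
    sites: SitesLike,
    unmethylated_contig: str = "lambda",
    methylated_contig: str = "pUC19",
    min_cov: int = 1,
) -> SpikeInQC:
    """Conversion QC from the two spike-in control contigs.

    Non-conversion is the all-cytosine weighted level of the unmethylated
    control; the false-negative rate is one minus the CpG-context level of
    the methylated control.  A missing contig raises :class:`ValueError`
    naming it.
    """
    table = _as_table(sites)
    slices = table.chrom_slices()
    for name in (unmethylated_contig, methylated_contig):
        if name not in slices:
            raise ValueError(f"spike-in contig {name!r} absent from site stream")
    lo, hi = slices[unmethylated_contig]
    unmeth = table.subset(np.arange(lo, hi))
    lo, hi = slices[methylated_contig]
    meth = table.subset(np.arange(lo, hi))
    nc = weighted_level(unmeth, "CX", min_cov)
    fn = weighted_level(meth, "CG", min_cov)
    return SpikeInQC(
        nonconversion_rate=nc.level,
        false_negative_rate=1.0 - fn.level if fn.defined else float("nan"),
        n_sites_unmethylated=nc.n_sites,
        n_sites_methylated=fn.n_sites,
    )


def dyad_symmetry(sites: SitesLike, min_cov: int = 5) -> DyadSymmetry:
    """Pearson correlation of methylation across the two strands of CpGs.

    A dyad pairs the plus-strand C at position *i* with the minus-strand C
    at *i + 1*; both members must be CpG-context and covered by at least
    *min_cov* reads.  Fewer than two dyads raises :class:`ValueError`.
    """
    table = _as_table(sites)
    mask = (table.trinuc == "CG") & (table.n_total >= min_cov)
    chrom = table.chrom[mask].astype("U64")
    pos = table.pos[mask]
    strand = table.strand[mask]
    level = table.n_meth[mask] / table.n_total[mask]
    plus = strand == "+"
    df_p = pd.DataFrame({"chrom": chrom[plus], "key": pos[plus] + 1,
                         "lv_plus": level[plus]})
    df_m = pd.DataFrame({"chrom": chrom[~plus], "key": pos[~plus],
                         "lv_minus": level[~plus]})
    dyads = df_p.merge(df_m, on=["chrom", "key"], how="inner")
    n = len(dyads)
    if n < 2:
        raise ValueError(f"dyad symmetry requires >= 2 dyads, found {n}")
    x = dyads["lv_plus"].to_numpy()
    y = dyads["lv_minus"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        r = float("nan")  # degenerate: constant levels carry no correlation
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return DyadSymmetry(r=r, n_dyads=n)


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metaprofile:
    """Per-bin pooled counts over scaled feature bodies plus fixed flanks.

    Bin 0 is the 5' end of the upstream flank; minus-strand features are
    reversed before pooling.
    """

    meth: np.ndarray
    total: np.ndarray
    n_sites: np.ndarray
    body_bins: int
    flank_bins: int
    flank_bp: int
    mean_of_features: Optional[np.ndarray] = None

    @property
    def levels(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def metaprofile(
    sites: SitesLike,
    features: Sequence[Feature],
    body_bins: int = 20,
    flank_bp: int = 1000,
    flank_bins: int = 10,
    context_filter="CX",
    min_cov: int = 1,
    stat: str = "pooled",
) -> Metaprofile:
    """Average methylation profile over features with scaled bodies.

    Feature bodies are scaled to *body_bins*; flanks are fixed *flank_bp*
    windows split into *flank_bins*.  With ``stat="pooled"`` (default)
    read counts are pooled across features within each bin, consistent with
    weighted levels elsewhere; ``stat="mean"`` additionally reports the
    deepTools-style mean of per-feature bin levels.  Features shorter than
    *body_bins* are kept: sites map to bins by fractional position.
    """
    if stat not in ("pooled", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    table = _as_table(sites)
    cmask = _context_mask(table, context_filter) & (table.n_total >= min_cov)
    table = table.subset(cmask)
    slices = table.chrom_slices()
    total_bins = 2 * flank_bins + body_bins
    meth = np.zeros(total_bins, dtype=np.int64)
    total = np.zeros(total_bins, dtype=np.int64)
    n_sites = np.zeros(total_bins, dtype=np.int64)
    feature_levels = [] if stat == "mean" else None
    for f in features:
        if f.chrom not in slices:
            continue
        lo, hi = slices[f.chrom]
        pos = table.pos[lo:hi]
        w_lo = f.start - flank_bp
        w_hi = f.end + flank_bp
        i0 = lo + np.searchsorted(pos, w_lo, side="left")
        i1 = lo + np.searchsorted(pos, w_hi, side="left")
        if i1 <= i0:
            continue
        p = table.pos[i0:i1]
        m = table.n_meth[i0:i1]
        t = table.n_total[i0:i1]
        rel = p - f.start
        length = f.end - f.start
        bins = np.empty(len(p), dtype=np.int64)
        body = (rel >= 0) & (rel < length)
        up = rel < 0
        down = rel >= length
        bins[body] = flank_bins + np.minimum(
            rel[body] * body_bins // length, body_bins - 1
        )
        if flank_bins > 0 and flank_bp > 0:
            bins[up] = (rel[up] + flank_bp) * flank_bins // flank_bp
            bins[down] = (
                flank_bins + body_bins
                + np.minimum((rel[down] - length) * flank_bins // flank_bp,
                             flank_bins - 1)
            )
            keep = np.ones(len(p), dtype=bool)
        else:
            keep = body
        if f.strand == "-":
            bins = total_bins - 1 - bins
        np.add.at(meth, bins[keep], m[keep])
        np.add.at(total, bins[keep], t[keep])
        np.add.at(n_sites, bins[keep], 1)
        if feature_levels is not None:
            fm = np.zeros(total_bins)
            ft = np.zeros(total_bins)
            np.add.at(fm, bins[keep], m[keep])
            np.add.at(ft, bins[keep], t[keep])
            with np.errstate(invalid="ignore", divide="ignore"):
                feature_levels.append(np.where(ft > 0, fm / ft, np.nan))
    mean = None
    if feature_levels is not None and feature_levels:
        stacked = np.vstack(feature_levels)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stacked, axis=0)
    return Metaprofile(
        meth=meth, total=total, n_sites=n_sites, body_bins=body_bins,
        flank_bins=flank_bins, flank_bp=flank_bp, mean_of_features=mean,
    )
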