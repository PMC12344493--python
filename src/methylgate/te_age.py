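"""TE insertion ages from Kimura 2-parameter divergence to consensus.

Distances are computed from pairwise consensus/insertion alignments as
``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))`` where ``P`` and ``Q`` are
the transition and transversion proportions over comparable (non-gap,
non-N) columns.  The CpG-modified variant down-weights transitions at
consensus-CpG positions to 1/10 of a substitution (both members of the
dyad), the convention behind RepeatMasker's ``divCpGMod``; an alternative
weight of 0 is available via *cpg_transition_weight*.

A small pairwise-alignment reader is included for a plain-text dialect::

    >te_id<TAB>family[<TAB>chrom<TAB>start<TAB>end<TAB>strand]
    CONSENSUS-ALIGNED-SEQUENCE
    INSERTION-ALIGNED-SEQUENCE

Blocks may be separated by blank lines; the two sequence lines must have
equal length over the alphabet ``A C G T N -``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io_formats import Feature, ParseError
from .feature_methylation import FeatureMethylation

__all__ = [
    "InsertionAlignment",
    "K2PResult",
    "kimura2p",
    "age_methylation_profile",
    "read_align",
    "write_align",
]

_ALPHABET = set("ACGTN-")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True, slots=True)
class InsertionAlignment:
    """Pairwise alignment of one TE insertion against its family consensus."""

    te_id: str
    family: str
    consensus: str
    insertion: str
    feature: Optional[Feature] = None

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.insertion):
            raise ValueError(
                f"{self.te_id}: aligned sequences differ in length "
                f"({len(self.consensus)} vs {len(self.insertion)})"
            )
        bad = (set(self.consensus.upper()) | set(self.insertion.upper())) - _ALPHABET
        if bad:
            raise ValueError(f"{self.te_id}: illegal characters {sorted(bad)}")


@dataclass(frozen=True, slots=True)
class K2PResult:
    """Transition/transversion proportions and the K2P distance.

    ``d`` is NaN with ``saturated=True`` when the log arguments are
    non-positive (divergence beyond the model's reach).
    """

    P: float
    Q: float
    d: float
    n_compared: int
    cpg_modified: bool
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return not self.saturated and math.isfinite(self.d)


def _consensus_cpg_columns(consensus: str) -> np.ndarray:
    """Boolean flag per alignment column: consensus base lies in a CpG.

    CpG membership is evaluated on the gap-stripped consensus and mapped
    back to alignment columns; both members of the dyad are flagged.
    """
    cons = consensus.upper()
    cols = [i for i, b in enumerate(cons) if b != "-"]
    seq = "".join(cons[i] for i in cols)
    flag = np.zeros(len(cons), dtype=bool)
    for j in range(len(seq) - 1):
        if seq[j] == "C" and seq[j + 1] == "G":
            flag[cols[j]] = True
            flag[cols[j + 1]] = True
    return flag


def kimura2p(
    aln: InsertionAlignment,
    cpg_modified: bool = False,
    cpg_transition_weight: float = 0.1,
) -> K2PResult:
    """Kimura 2-parameter divergence of an insertion from its consensus.

    Gap and N columns are excluded from ``n_compared``.  With
    *cpg_modified*, a transition whose consensus column is part of a
    consensus CpG contributes *cpg_transition_weight* (default 1/10) of a
    substitution.  Requires at least one comparable column.
    """
    cons = aln.consensus.upper()
    ins = aln.insertion.upper()
    cpg = _consensus_cpg_columns(cons) if cpg_modified else None
    n = 0
    transitions = 0.0
    transversions = 0
    for i, (a, b) in enumerate(zip(cons, ins)):
        if a in ("-", "N") or b in ("-", "N"):
            continue
        n += 1
        if a == b:
            continue
        is_transition = (a in _PURINES and b in _PURINES) or (
            a in _PYRIMIDINES and b in _PYRIMIDINES
        )
        if is_transition:
            if cpg is not None and cpg[i]:
                transitions += cpg_transition_weight
            else:
                transitions += 1.0
        else:
            transversions += 1
    if n == 0:
        raise ValueError(f"{aln.te_id}: no comparable alignment columns")
    P = transitions / n
    Q = transversions / n
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return K2PResult(P, Q, float("nan"), n, cpg_modified, saturated=True)
    d = -0.5 * math.log(a1 * math.sqrt(a2))
    return K2PResult(P, Q, d, n, cpg_modified)


def age_methylation_profile(
    insertions: Sequence[InsertionAlignment],
    k2p_results: Mapping[str, K2PResult],
    te_summaries: Sequence[FeatureMethylation],
    age_bins: Sequence[float],
) -> pd.DataFrame:
    """Pooled methylation level per TE family and age bin.

    *age_bins* are K2P breakpoints; insertion *i* falls in bin *j* when
    ``age_bins[j] <= d < age_bins[j+1]``.  Saturated or out-of-range
    insertions land in an ``overflow`` bin.  Returns a tidy DataFrame with
    columns ``family, age_bin, n_insertions, n_meth_reads, n_total_reads,
    level``; families with no surviving insertion are absent.
    """
    breaks = sorted(float(b) for b in age_bins)
    if len(breaks) < 2:
        raise ValueError("need at least two age-bin breakpoints")
    labels = [f"[{breaks[j]:g},{breaks[j+1]:g})" for j in range(len(breaks) - 1)]
    by_id = {fm.feature_id: fm for fm in te_summaries}
    rows: Dict[Tuple[str, str], List[int]] = {}
    for aln in insertions:
        fm = by_id.get(aln.te_id)
        if fm is None:
            continue
        res = k2p_results.get(aln.te_id)
        if res is None or not res.defined or not (
            breaks[0] <= res.d < breaks[-1]
        ):
            label = "overflow"
        else:
            j = int(np.searchsorted(breaks, res.d, side="right")) - 1
            label = labels[j]
        key = (aln.family, label)
        acc = rows.setdefault(key, [0, 0, 0])
        acc[0] += 1
        acc[1] += fm.level.n_meth_reads
        acc[2] += fm.level.n_total_reads
    records = []
    for (family, label), (n_ins, meth, total) in sorted(rows.items()):
        records.append(
            {
                "family": family,
                "age_bin": label,
                "n_insertions": n_ins,
                "n_meth_reads": meth,
                "n_total_reads": total,
                "level": meth / total if total else float("nan"),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["family", "age_bin", "n_insertions", "n_meth_reads",
                 "n_total_reads", "level"],
    )


# ---------------------------------------------------------------------------
# Simplified pairwise .align reader/writer
# ---------------------------------------------------------------------------


def read_align(path: Union[str, Path]) -> List[InsertionAlignment]:
    """Read pairwise consensus/insertion blocks (dialect in module docs)."""
    alignments: List[InsertionAlignment] = []
    header: Optional[List[str]] = None
    seqs: List[str] = []
    header_line = 0

    def flush() -> None:
        nonlocal header, seqs
        if header is None:
            return
        if len(seqs) != 2:
            raise ParseError(
                f"{path}:{header_line}: block has {len(seqs)} sequence "
                "lines, expected 2 (consensus then insertion)"
            )
        feature = None
        if len(header) >= 6:
            feature = Feature(
                chrom=header[2], start=int(header[3]), end=int(header[4]),
                strand=header[5], id=header[0], kind="TE",
                class_label=header[1],
            )
        try:
            alignments.append(
                InsertionAlignment(
                    te_id=header[0],
                    family=header[1] if len(header) > 1 else "Unknown",
                    consensus=seqs[0].upper(),
                    insertion=seqs[1].upper(),
                    feature=feature,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}")
        header, seqs = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split("\t")
                header_line = lineno
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence line before any header"
                    )
                seqs.append(line)
    flush()
    return alignments


def write_align(
    alignments: Sequence[InsertionAlignment], path: Union[str, Path]
) -> int:
    with open(path, "w") as fh:
        for a in alignments:
            parts = [a.te_id, a.family]
            if a.feature is not None:
                f = a.feature
                parts += [f.chrom, str(f.start), str(f.end), f.strand]
            fh.write(">" + "\t".join(parts) + "\n")
            fh.write(a.consensus + "\n")
            fh.write(a.insertion + "\n")
    return len(alignments)
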