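"""Taxonomic-origin calls, methylation enrichment and viral neighborhoods.

Per-gene ancestry categories are derived from self-genus-filtered best-hit
tables at the superkingdom level (Eukaryote / Prokaryote / Virus plus
combinations).  Category enrichment in the methylated gene fraction is
tested with a two-sided Fisher exact test, and runs of viral-ancestry
genes are chained into candidate endogenized-virus neighborhoods.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

from .io_formats import Feature, HitRecord
from .feature_methylation import FeatureMethylation, METHYLATED, UNMETHYLATED

__all__ = [
    "AncestryCall",
    "EnrichmentResult",
    "ViralNeighborhood",
    "assign_category",
    "fisher_exact_two_sided",
    "enrichment_test",
    "detect_viral_neighborhoods",
    "CATEGORIES",
    "VIRAL_CATEGORIES",
]

#: domain label per superkingdom
_DOMAIN = {
    "Eukaryota": "Eukaryote",
    "Bacteria": "Prokaryote",
    "Archaea": "Prokaryote",
    "Viruses": "Virus",
}

CATEGORIES = (
    "Eukaryote", "Prokaryote", "Virus",
    "Eukaryote+Prokaryote", "Eukaryote+Virus", "Prokaryote+Virus",
    "Mixed", "Unassigned",
)

#: categories counted as viral when chaining neighborhoods
VIRAL_CATEGORIES = frozenset(
    {"Virus", "Eukaryote+Virus", "Prokaryote+Virus", "Mixed"}
)

_DOMAIN_ORDER = ("Eukaryote", "Prokaryote", "Virus")


@dataclass(frozen=True, slots=True)
class AncestryCall:
    """Taxonomic-origin category of one gene.

    ``viral_labels`` preserves the finest-rank labels of the gene's viral
    hits for downstream neighborhood-taxon summaries.
    """

    gene_id: str
    category: str
    n_hits: int
    viral_fraction: float
    viral_labels: Tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Fisher exact test of one category against methylation status.

    The 2x2 table is (methylated&category, methylated&other /
    unmethylated&category, unmethylated&other).  The odds ratio is the
    sample odds ratio; with a zero cell the Haldane 0.5 correction is
    applied and flagged.  A zero margin yields p = 1 and an undefined
    (NaN) odds ratio.
    """

    category: str
    table: Tuple[int, int, int, int]
    odds_ratio: float
    p_two_sided: float
    significant: bool
    alpha: float
    haldane_corrected: bool = False


@dataclass(frozen=True, slots=True)
class ViralNeighborhood:
    """A chained run of viral-ancestry genes (candidate GEVE)."""

    chrom: str
    start: int
    end: int
    gene_ids: Tuple[str, ...]
    n_viral: int
    n_total: int
    dominant_taxon: str


def assign_category(
    hits: Sequence[HitRecord],
    majority_rule: float = 0.2,
) -> AncestryCall:
    """Superkingdom-level ancestry category from a gene's retained hits.

    A domain is *represented* when its share of hits is at least
    *majority_rule* (default 20%).  One represented domain gives a pure
    category; two give the named combination; three give ``Mixed``; no
    hits at all give ``Unassigned``.
    """
    if not hits:
        return AncestryCall("", "Unassigned", 0, 0.0)
    gene_id = hits[0].gene_id
    shares = Counter(_DOMAIN[h.superkingdom] for h in hits)
    n = len(hits)
    represented = [
        dom for dom in _DOMAIN_ORDER if shares.get(dom, 0) / n >= majority_rule
    ]
    if not represented:  # unreachable with <=3 domains and rule <= 1/3
        category = "Unassigned"
    elif len(represented) == 1:
        category = represented[0]
    elif len(represented) == 2:
        category = "+".join(represented)
    else:
        category = "Mixed"
    viral_labels = tuple(
        h.taxonomy[-1] for h in hits if _DOMAIN[h.superkingdom] == "Virus"
    )
    return AncestryCall(
        gene_id=gene_id,
        category=category,
        n_hits=n,
        viral_fraction=shares.get("Virus", 0) / n,
        viral_labels=viral_labels,
    )


def _two_sided_pvalues(n: int, r: int, col: int) -> np.ndarray:
    """Two-sided Fisher p for every table with margins ``(n, r, col)``.

    Returns one p-value per feasible upper-left cell value ``a`` in
    ``[max(0, r + col - n), min(r, col)]``: the sum of hypergeometric
    point probabilities at most the observed one times ``1 + 1e-7``
    (tolerance for floating-point ties).
    """
    k_min = max(0, r + col - n)
    ks = np.arange(k_min, min(r, col) + 1)
    pmf = hypergeom.pmf(ks, n, r, col)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1.0 + 1e-7), side="right")
    return np.minimum(csum[idx - 1], 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``(a, b / c, d)``.

    Sums the hypergeometric probabilities of all tables with the same
    margins whose point probability is at most the observed one times
    ``1 + 1e-7`` (tolerance for floating-point ties).  A zero margin
    returns 1.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative cell count")
    n = a + b + c + d
    r = a + b  # row margin
    col = a + c  # column margin
    if r == 0 or col == 0 or r == n or col == n or n == 0:
        return 1.0
    k_min = max(0, r + col - n)
    return float(_two_sided_pvalues(n, r, col)[a - k_min])


def enrichment_test(
    calls: Mapping[str, AncestryCall],
    statuses: Sequence[FeatureMethylation],
    category: str,
    alpha: float = 0.001,
) -> EnrichmentResult:
    """Test whether *category* is enriched among methylated genes.

    Genes with undetermined methylation or an ``Unassigned`` ancestry are
    excluded from the 2x2 table.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    a = b = c = d = 0
    for fm in statuses:
        call = calls.get(fm.feature_id)
        if call is None or call.category == "Unassigned":
            continue
        if fm.status == METHYLATED:
            if call.category == category:
                a += 1
            else:
                b += 1
        elif fm.status == UNMETHYLATED:
            if call.category == category:
                c += 1
            else:
                d += 1
    p = fisher_exact_two_sided(a, b, c, d)
    haldane = False
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        odds = float("nan")
    elif 0 in (a, b, c, d):
        haldane = True
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        category=category,
        table=(a, b, c, d),
        odds_ratio=odds,
        p_two_sided=p,
        significant=p < alpha,
        alpha=alpha,
        haldane_corrected=haldane,
    )


def detect_viral_neighborhoods(
    gene_features: Sequence[Feature],
    calls: Mapping[str, AncestryCall],
    max_gap_genes: int = 3,
    max_gap_bp: int = 20_000,
    min_genes: int = 3,
    viral_categories: frozenset = VIRAL_CATEGORIES,
) -> List[ViralNeighborhood]:
    """Chain viral-ancestry genes into candidate integrated-virus regions.

    Genes are walked per chromosome in start order; a chain extends to the
    next viral gene when at most *max_gap_genes* non-viral genes intervene
    and the genomic gap is at most *max_gap_bp*.  Chains with at least
    *min_genes* viral members are emitted; the region spans the members'
    extremes, ``n_total`` counts every gene inside that span, and the
    dominant taxon is the modal finest-rank viral hit label.
    """
    by_chrom: Dict[str, List[Feature]] = {}
    for f in gene_features:
        by_chrom.setdefault(f.chrom, []).append(f)
    out: List[ViralNeighborhood] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end))
        viral_idx = [
            i for i, f in enumerate(genes)
            if calls.get(f.id) is not None
            and calls[f.id].category in viral_categories
        ]
        chains: List[List[int]] = []
        for i in viral_idx:
            if (
                chains
                and i - chains[-1][-1] - 1 <= max_gap_genes
                and genes[i].start - genes[chains[-1][-1]].end <= max_gap_bp
            ):
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            if len(chain) < min_genes:
                continue
            members = [genes[i] for i in chain]
            start = min(f.start for f in members)
            end = max(f.end for f in members)
            n_total = sum(1 for f in genes if f.start < end and f.end > start)
            labels = Counter()
            for f in members:
                labels.update(calls[f.id].viral_labels)
            dominant = labels.most_common(1)[0][0] if labels else ""
            out.append(
                ViralNeighborhood(
                    chrom=chrom, start=start, end=end,
                    gene_ids=tuple(f.id for f in members),
                    n_viral=len(members), n_total=n_total,
                    dominant_taxon=dominant,
                )
            )
    return out
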