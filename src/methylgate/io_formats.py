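"""Readers and writers for the on-disk formats used across the pipeline.

Formats handled here:

* **CGmap** -- 8-column TSV of per-cytosine methylation calls:
  ``chrom, watson_base (C|G), 1-based position, trinucleotide context
  (CG/CHG/CHH), dinucleotide context (CA/CC/CG/CT), level, methylated
  count, total count``.  The precomputed level column is never trusted;
  levels are always recomputed from the counts.
* **BED6 / GFF3** -- genomic features.  BED is 0-based half-open, GFF3 is
  1-based closed; both are converted to the internal 0-based half-open
  convention at this boundary.
* **Hit tables** -- per-gene best-hit TSVs with a semicolon-separated
  taxonomy string whose first label is the superkingdom and last label is
  the genus.
* **Newick trees** and **presence/absence matrices** (``1``/``0``/``?``).
* **bedGraph** output for methylation tracks.

All coordinate-carrying objects produced by this module are 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

SUPERKINGDOMS = frozenset({"Eukaryota", "Bacteria", "Archaea", "Viruses"})

__all__ = [
    "CytosineSite",
    "Feature",
    "HitRecord",
    "ParseError",
    "read_cgmap",
    "write_cgmap",
    "read_features",
    "write_bed",
    "write_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_species_tree",
    "read_presence_matrix",
    "write_presence_matrix",
    "write_bedgraph",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True, slots=True)
class CytosineSite:
    """One strand-resolved cytosine with read counts and sequence context.

    ``pos`` is the 0-based genomic coordinate of the cytosine itself; a CpG
    dyad therefore yields two sites (``+`` at *i*, ``-`` at *i + 1*).
    """

    chrom: str
    pos: int
    strand: str
    dinuc_context: str
    trinuc_context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_total < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if self.n_meth > self.n_total:
            raise ValueError(
                f"n_meth ({self.n_meth}) > n_total ({self.n_total}) "
                f"at {self.chrom}:{self.pos}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def level(self) -> float:
        """Per-site methylation fraction; NaN when the site is uncovered."""
        if self.n_total == 0:
            return float("nan")
        return self.n_meth / self.n_total


@dataclass(frozen=True, slots=True)
class Feature:
    """A genomic interval (gene, TE insertion, window, spike-in contig)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    kind: str = "gene"
    class_label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One best-hit record: gene, ordered taxonomy labels and scores.

    The taxonomy list runs from the superkingdom (first label) down to the
    genus (last label).
    """

    gene_id: str
    taxonomy: tuple
    bitscore: float
    evalue: float

    @property
    def superkingdom(self) -> str:
        return self.taxonomy[0]

    @property
    def genus(self) -> str:
        return self.taxonomy[-1]


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

_STRAND_FROM_BASE = {"C": "+", "G": "-"}
_BASE_FROM_STRAND = {"+": "C", "-": "G"}


def read_cgmap(
    path: Union[str, Path],
    genome: Optional[Mapping[str, str]] = None,
    on_mismatch: str = "warn",
) -> Iterator[CytosineSite]:
    """Stream :class:`CytosineSite` records from a CGmap file.

    Positions are converted 1-based -> 0-based and strand is derived from
    the Watson-strand base column (``C`` -> ``+``, ``G`` -> ``-``).  When a
    *genome* (any ``chrom -> sequence`` mapping, e.g. ``pyfaidx.Fasta``) is
    supplied, contexts are recomputed from the sequence and mismatching
    file annotations are flagged according to *on_mismatch*
    (``warn`` | ``error`` | ``ignore``); the recomputed contexts win.
    """
    if on_mismatch not in ("warn", "error", "ignore"):
        raise ValueError(f"unknown on_mismatch policy {on_mismatch!r}")
    from .methylome_core import classify_context  # local: avoid import cycle

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, base, pos_s, trinuc, dinuc, _level, meth_s, total_s = fields
            if base not in _STRAND_FROM_BASE:
                raise ParseError(
                    f"{path}:{lineno}: unknown Watson-strand base {base!r}"
                )
            try:
                pos1 = int(pos_s)
                n_meth = int(meth_s)
                n_total = int(total_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}")
            if n_meth > n_total or n_meth < 0 or n_total < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid counts "
                    f"n_meth={n_meth}, n_total={n_total}"
                )
            strand = _STRAND_FROM_BASE[base]
            pos = pos1 - 1
            if genome is not None:
                new_dinuc, new_trinuc = classify_context(
                    genome, chrom, pos, strand
                )
                if (new_dinuc, new_trinuc) != (dinuc, trinuc):
                    msg = (
                        f"{path}:{lineno}: context mismatch at "
                        f"{chrom}:{pos1}({strand}): file says "
                        f"({dinuc},{trinuc}), genome says "
                        f"({new_dinuc},{new_trinuc})"
                    )
                    if on_mismatch == "error":
                        raise ParseError(msg)
                    if on_mismatch == "warn":
                        logger.warning(msg)
                dinuc, trinuc = new_dinuc, new_trinuc
            yield CytosineSite(
                chrom=chrom,
                pos=pos,
                strand=strand,
                dinuc_context=dinuc,
                trinuc_context=trinuc,
                n_meth=n_meth,
                n_total=n_total,
            )


def write_cgmap(sites: Iterable[CytosineSite], path: Union[str, Path]) -> int:
    """Write sites in CGmap layout; returns the number of lines written."""
    n = 0
    with open(path, "w") as fh:
        for s in sites:
            level = 0.0 if s.n_total == 0 else s.n_meth / s.n_total
            fh.write(
                f"{s.chrom}\t{_BASE_FROM_STRAND[s.strand]}\t{s.pos + 1}\t"
                f"{s.trinuc_context}\t{s.dinuc_context}\t{level:.6g}\t"
                f"{s.n_meth}\t{s.n_total}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Features: BED6 / GFF3
# ---------------------------------------------------------------------------

#: GFF3 feature types recognised by default and their internal kind.
DEFAULT_GFF3_KIND_MAP = {
    "gene": "gene",
    "transposable_element": "TE",
    "repeat_region": "TE",
    "dispersed_repeat": "TE",
}


def _parse_gff3_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_features(
    path: Union[str, Path],
    format: str,
    kind: Optional[str] = None,
    kind_map: Optional[Mapping[str, str]] = None,
) -> List[Feature]:
    """Read features from a BED6 or GFF3 file into 0-based half-open intervals.

    For GFF3, only feature types in *kind_map* (default
    :data:`DEFAULT_GFF3_KIND_MAP`) are kept, keyed by their ``ID``
    attribute; *kind* overrides the mapped kind for every record.
    Duplicate feature ids raise :class:`ParseError` listing them.
    """
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown feature format {format!r}")
    features: List[Feature] = []
    if format == "bed":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: BED line has fewer than 3 columns"
                    )
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates")
                if start >= end:
                    raise ParseError(
                        f"{path}:{lineno}: start >= end ({start} >= {end})"
                    )
                name = fields[3] if len(fields) > 3 and fields[3] != "." else (
                    f"{chrom}:{start}-{end}"
                )
                strand = fields[5] if len(fields) > 5 else "."
                features.append(
                    Feature(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        id=name,
                        kind=kind or "gene",
                    )
                )
    else:
        effective_map = dict(kind_map or DEFAULT_GFF3_KIND_MAP)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(
                        f"{path}:{lineno}: GFF3 line has {len(fields)} columns"
                    )
                ftype = fields[2]
                if ftype not in effective_map:
                    continue
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates")
                start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
                if start >= end:
                    raise ParseError(
                        f"{path}:{lineno}: empty interval after conversion"
                    )
                attrs = _parse_gff3_attributes(fields[8])
                fid = attrs.get("ID") or f"{fields[0]}:{start}-{end}"
                features.append(
                    Feature(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        strand=fields[6] if fields[6] in "+-" else ".",
                        id=fid,
                        kind=kind or effective_map[ftype],
                        class_label=attrs.get("class", ""),
                    )
                )
    seen: Dict[str, int] = {}
    for f in features:
        seen[f.id] = seen.get(f.id, 0) + 1
    dupes = sorted(fid for fid, n in seen.items() if n > 1)
    if dupes:
        raise ParseError(f"{path}: duplicate feature ids: {', '.join(dupes)}")
    return features


def write_bed(features: Iterable[Feature], path: Union[str, Path]) -> int:
    n = 0
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.id or '.'}\t0\t{f.strand}\n"
            )
            n += 1
    return n


def write_gff3(features: Iterable[Feature], path: Union[str, Path]) -> int:
    """Write features as GFF3 (kind -> type column, class_label -> class=)."""
    type_from_kind = {"gene": "gene", "TE": "transposable_element"}
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.class_label:
                attrs += f";class={f.class_label}"
            fh.write(
                f"{f.chrom}\tmethylgate\t{type_from_kind.get(f.kind, f.kind)}\t"
                f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def read_hit_table(
    path: Union[str, Path],
    self_genus: str,
    max_hits: int = 10,
) -> Dict[str, List[HitRecord]]:
    """Read a per-gene best-hit TSV and return ``gene_id -> [HitRecord]``.

    Expected columns: ``gene_id, taxonomy, bitscore, evalue`` (header
    optional).  Per gene, at most *max_hits* best-scoring records are kept
    (descending bitscore, ascending e-value), then every record whose genus
    equals *self_genus* is discarded.  Records with an unparseable taxonomy
    (empty, or first label not a superkingdom) are skipped with a warning.
    """
    records: Dict[str, List[HitRecord]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header
                continue
            if len(fields) < 4:
                logger.warning(
                    "%s:%d: hit line has %d columns, skipped", path, lineno,
                    len(fields),
                )
                continue
            gene_id, tax_s = fields[0], fields[1]
            taxonomy = tuple(t.strip() for t in tax_s.split(";") if t.strip())
            if not taxonomy or taxonomy[0] not in SUPERKINGDOMS:
                logger.warning(
                    "%s:%d: unparseable taxonomy %r, record skipped",
                    path, lineno, tax_s,
                )
                continue
            try:
                bitscore = float(fields[2])
                evalue = float(fields[3])
            except ValueError:
                logger.warning("%s:%d: bad scores, record skipped", path, lineno)
                continue
            records.setdefault(gene_id, []).append(
                HitRecord(gene_id, taxonomy, bitscore, evalue)
            )
    out: Dict[str, List[HitRecord]] = {}
    for gene_id, hits in records.items():
        hits.sort(key=lambda h: (-h.bitscore, h.evalue))
        hits = hits[:max_hits]
        out[gene_id] = [h for h in hits if h.genus != self_genus]
    return out


def write_hit_table(
    hits: Mapping[str, Sequence[HitRecord]], path: Union[str, Path]
) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("gene_id\ttaxonomy\tbitscore\tevalue\n")
        for gene_id in hits:
            for h in hits[gene_id]:
                fh.write(
                    f"{gene_id}\t{';'.join(h.taxonomy)}\t{h.bitscore:g}\t"
                    f"{h.evalue:g}\n"
                )
                n += 1
    return n


# ---------------------------------------------------------------------------
# Trees and presence/absence matrices
# ---------------------------------------------------------------------------


def read_species_tree(path: Union[str, Path]) -> dendropy.Tree:
    """Read a rooted newick species tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ParseError(f"{path}: duplicate leaf labels in species tree: {exc}")
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError(f"{path}: duplicate leaf labels in species tree")
    return tree


_STATE_FROM_CODE = {"1": "present", "0": "absent", "?": "potential"}


def read_presence_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a species x family matrix with ``1``/``0``/``?`` cells.

    Returns a DataFrame of strings in ``{present, absent, potential}`` with
    species as the index.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(df.values.ravel()) - set(_STATE_FROM_CODE)
    if bad:
        raise ParseError(f"{path}: unknown presence codes {sorted(bad)}")
    return df.map(_STATE_FROM_CODE.__getitem__)


def write_presence_matrix(
    matrix: pd.DataFrame, path: Union[str, Path]
) -> None:
    code = {"present": "1", "absent": "0", "potential": "?"}
    matrix.map(code.__getitem__).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(
    sites: Iterable[CytosineSite],
    path: Union[str, Path],
    min_cov: int = 1,
) -> int:
    """Write per-site methylation levels as a bedGraph track."""
    n = 0
    with open(path, "w") as fh:
        for s in sites:
            if s.n_total < min_cov:
                continue
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.level:.6g}\n")
            n += 1
    return n
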