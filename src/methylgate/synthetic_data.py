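"""Ground-truthed synthetic methylome bundles.

Generates a complete input set -- genome FASTA, gene/TE annotation,
per-cytosine CGmap calls, best-hit tables, TE/consensus alignments and
spike-in controls -- with known truth for every downstream question:
which genes are methylated (bimodal level distribution), which TE
insertions are young and hypermethylated, where viral-ancestry gene
clusters sit, and what the conversion error rates are.  One integer seed
fans out to independent substreams (layout, sequence, TE evolution,
levels, counts, hits) so the whole bundle is byte-reproducible.

Also provides random gain/loss phyletic profiles on random trees for
exercising the Dollo reconstruction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Feature, write_gff3
from .methylome_core import SiteTable
from .te_age import InsertionAlignment, write_align

__all__ = [
    "TEFamilySpec",
    "ViralClusterSpec",
    "SpikeInSpec",
    "SimulationSpec",
    "MethylomeBundle",
    "simulate_methylome",
    "simulate_profiles",
    "ProfileBundle",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TEFamilySpec:
    """One TE family: consensus, copy number, age and methylation truth."""

    name: str
    class_label: str
    consensus_length: int = 800
    n_insertions: int = 30
    divergence: float = 0.05  # target K2P distance of insertions
    ts_tv_ratio: float = 2.0
    meth_level: float = 0.7
    methylated: bool = True


@dataclass(frozen=True)
class ViralClusterSpec:
    n_clusters: int = 2
    genes_per_cluster: int = 8
    methylated: bool = True
    taxon: str = "Mimiviridae"


@dataclass(frozen=True)
class SpikeInSpec:
    unmethylated_name: str = "lambda"
    unmethylated_length: int = 20_000
    methylated_name: str = "pUC19"
    methylated_length: int = 2_700
    false_negative_rate: float = 0.02  # CpG methylation on control = 1 - this


def _default_te_families() -> Tuple[TEFamilySpec, ...]:
    # young copies hypermethylated, old copies not: plants an
    # age -> methylation gradient recoverable downstream
    return (
        TEFamilySpec("LINE-A", "LINE", 800, 30, 0.03, 2.0, 0.80, True),
        TEFamilySpec("LTR-B", "LTR", 900, 30, 0.10, 2.0, 0.50, True),
        TEFamilySpec("DNA-C", "DNA", 700, 30, 0.25, 2.0, 0.10, True),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterisation of one synthetic methylome bundle."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length: int = 200_000
    gc_content: float = 0.45
    n_genes: int = 1_000
    gene_length_mean: int = 800
    gene_length_sd: int = 150
    methylated_gene_fraction: float = 0.02
    beta_hi: Tuple[float, float] = (8.0, 2.0)
    jitter_sd: float = 0.03
    epsilon: float = 0.003  # non-conversion rate (background truth level)
    mean_depth: float = 30.0
    context_mode: str = "CG"
    te_families: Tuple[TEFamilySpec, ...] = field(
        default_factory=_default_te_families
    )
    viral: ViralClusterSpec = field(default_factory=ViralClusterSpec)
    spike_in: SpikeInSpec = field(default_factory=SpikeInSpec)
    hit_noise_prok_fraction: float = 0.05
    viral_noise_fraction: float = 0.0
    self_genus: str = "Selfia"
    self_hit_fraction: float = 0.1

    def validate(self) -> None:
        for name in ("gc_content", "methylated_gene_fraction", "epsilon",
                     "hit_noise_prok_fraction", "viral_noise_fraction",
                     "self_hit_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if not 0.0 <= self.spike_in.false_negative_rate <= 1.0:
            raise ValueError("false_negative_rate must be in [0,1]")
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("need at least one gene and one chromosome")


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class MethylomeBundle:
    """In-memory synthetic bundle plus writers for the on-disk formats."""

    spec: SimulationSpec
    genome: Dict[str, str]
    features: List[Feature]  # genes then TEs
    sites: SiteTable
    hits_table: pd.DataFrame  # gene_id, taxonomy, bitscore, evalue
    alignments: List[InsertionAlignment]
    genes_truth: pd.DataFrame
    tes_truth: pd.DataFrame
    clusters_truth: pd.DataFrame

    @property
    def gene_features(self) -> List[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    @property
    def te_features(self) -> List[Feature]:
        return [f for f in self.features if f.kind == "TE"]

    @property
    def genome_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: Union[str, Path]) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "features": out / "features.gff3",
            "cgmap": out / "calls.cgmap",
            "hits": out / "hits.tsv",
            "alignments": out / "te_alignments.align",
            "genes_truth": out / "truth_genes.tsv",
            "tes_truth": out / "truth_tes.tsv",
            "clusters_truth": out / "truth_clusters.tsv",
            "spec": out / "spec.json",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        write_gff3(self.features, paths["features"])
        t = self.sites
        base = np.where(t.strand == "+", "C", "G")
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(t.n_total > 0, t.n_meth / np.maximum(t.n_total, 1), 0.0)
        pd.DataFrame(
            {
                "chrom": t.chrom, "base": base, "pos": t.pos + 1,
                "trinuc": t.trinuc, "dinuc": t.dinuc,
                "level": np.round(level, 6),
                "n_meth": t.n_meth, "n_total": t.n_total,
            }
        ).to_csv(paths["cgmap"], sep="\t", header=False, index=False)
        self.hits_table.to_csv(paths["hits"], sep="\t", index=False)
        write_align(self.alignments, paths["alignments"])
        self.genes_truth.to_csv(paths["genes_truth"], sep="\t", index=False)
        self.tes_truth.to_csv(paths["tes_truth"], sep="\t", index=False)
        with open(paths["spec"], "w") as fh:
            json.dump(dataclasses.asdict(self.spec), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.clusters_truth.to_csv(paths["clusters_truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

_TRANSITION = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"GTAC"):  # A<->G, C<->T
    _TRANSITION[_a] = _b
# transversion targets per base, two options each
_TV1 = np.zeros(256, dtype=np.uint8)
_TV2 = np.zeros(256, dtype=np.uint8)
for _a, (_x, _y) in zip(b"ACGT", [b"CT", b"AG", b"CT", b"AG"]):
    _TV1[_a] = _x
    _TV2[_a] = _y


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=probs)]


def evolve_k2p(
    consensus: np.ndarray, divergence: float, ts_tv_ratio: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutate a sequence under the Kimura 2-parameter model.

    Substitution probabilities follow the analytic K2P transition matrix
    at total branch length *divergence* with transition/transversion rate
    ratio *ts_tv_ratio*; this is deliberately independent of the distance
    estimator so the two can cross-validate.
    """
    kappa = ts_tv_ratio
    beta_t = divergence / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta_t) - 0.5 * np.exp(-2 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * np.exp(-4 * beta_t)
    u = rng.random(len(consensus))
    pick = rng.random(len(consensus)) < 0.5
    out = consensus.copy()
    ts_mask = u < p_ts
    tv_mask = (u >= p_ts) & (u < p_ts + 2 * p_tv_each)
    out[ts_mask] = _TRANSITION[out[ts_mask]]
    tv_a = tv_mask & pick
    tv_b = tv_mask & ~pick
    out[tv_a] = _TV1[consensus[tv_a]]
    out[tv_b] = _TV2[consensus[tv_b]]
    return out


def _context_arrays(
    codes: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions, strands and contexts of every classifiable cytosine."""
    length = len(codes)
    plus = np.flatnonzero(codes == ord("C"))
    plus = plus[plus < length - 2]  # need two downstream bases
    minus = np.flatnonzero(codes == ord("G"))
    minus = minus[minus >= 2]
    p_n1 = codes[plus + 1]
    p_n2 = codes[plus + 2]
    m_n1 = _COMP[codes[minus - 1]]
    m_n2 = _COMP[codes[minus - 2]]

    def _labels(n1: np.ndarray, n2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        dinuc = np.array(["CA", "CC", "CG", "CT"], dtype="U2")[
            np.searchsorted(_BASES, n1)
        ]
        trinuc = np.where(
            n1 == ord("G"), "CG", np.where(n2 == ord("G"), "CHG", "CHH")
        ).astype("U3")
        return dinuc, trinuc

    p_d, p_t = _labels(p_n1, p_n2)
    m_d, m_t = _labels(m_n1, m_n2)
    pos = np.concatenate([plus, minus])
    strand = np.concatenate(
        [np.full(len(plus), "+", dtype="U1"), np.full(len(minus), "-", dtype="U1")]
    )
    dinuc = np.concatenate([p_d, m_d])
    trinuc = np.concatenate([p_t, m_t])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], dinuc[order], trinuc[order], codes


def _context_site_mask(dinuc: np.ndarray, trinuc: np.ndarray, mode: str) -> np.ndarray:
    mode = mode.upper()
    if mode == "CX":
        return np.ones(len(dinuc), dtype=bool)
    if mode in ("CG", "CHG", "CHH"):
        return trinuc == mode
    if mode in ("NON-CG", "NONCG"):
        return trinuc != "CG"
    raise ValueError(f"unknown context mode {mode!r}")


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def simulate_methylome(spec: SimulationSpec) -> MethylomeBundle:
    """Generate a complete ground-truthed methylome bundle from *spec*.

    Raises :class:`ValueError` before producing any output when the
    requested features cannot be placed within the chromosome length.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    (ss_layout, ss_seq, ss_te, ss_levels, ss_counts, ss_hits) = root.spawn(6)
    rng_layout = np.random.default_rng(ss_layout)
    rng_seq = np.random.default_rng(ss_seq)
    rng_te = np.random.default_rng(ss_te)
    rng_levels = np.random.default_rng(ss_levels)
    rng_counts = np.random.default_rng(ss_counts)
    rng_hits = np.random.default_rng(ss_hits)

    # ---- layout: genes (in order) then TEs, per chromosome -------------
    genes_per_chrom = -(-spec.n_genes // spec.n_chroms)
    gene_lengths = np.maximum(
        200,
        rng_layout.normal(
            spec.gene_length_mean, spec.gene_length_sd, spec.n_genes
        ).astype(int),
    )
    te_plan: List[Tuple[TEFamilySpec, int]] = []  # (family, copy index)
    for fam in spec.te_families:
        for k in range(fam.n_insertions):
            te_plan.append((fam, k))
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    gene_rows: List[Feature] = []
    te_rows: List[Feature] = []
    cursor = {c: 0 for c in chrom_names}

    def _gap() -> int:
        return int(rng_layout.integers(60, 160))

    for g in range(spec.n_genes):
        chrom = chrom_names[g // genes_per_chrom]
        start = cursor[chrom] + _gap()
        end = start + int(gene_lengths[g])
        strand = "+" if rng_layout.random() < 0.5 else "-"
        gene_rows.append(
            Feature(chrom=chrom, start=start, end=end, strand=strand,
                    id=f"g{g:05d}", kind="gene")
        )
        cursor[chrom] = end
    for i, (fam, k) in enumerate(te_plan):
        chrom = chrom_names[i % spec.n_chroms]
        start = cursor[chrom] + _gap()
        end = start + fam.consensus_length
        te_id = f"te_{fam.name}_{k:03d}"
        te_rows.append(
            Feature(chrom=chrom, start=start, end=end, strand="+",
                    id=te_id, kind="TE", class_label=fam.class_label)
        )
        cursor[chrom] = end
    overfull = {c: cur for c, cur in cursor.items() if cur > spec.chrom_length}
    if overfull:
        raise ValueError(
            f"features exceed chromosome length {spec.chrom_length}: "
            f"{overfull}"
        )

    # ---- viral clusters: runs of consecutive genes ---------------------
    vc = spec.viral
    cluster_records = []
    cluster_gene_ids: List[str] = []
    genes_by_chrom: Dict[str, List[Feature]] = {}
    for f in gene_rows:
        genes_by_chrom.setdefault(f.chrom, []).append(f)
    for c in range(vc.n_clusters):
        chrom = chrom_names[c % spec.n_chroms]
        rank = c // spec.n_chroms
        start_idx = 2 + rank * (vc.genes_per_cluster + 10)
        members = genes_by_chrom.get(chrom, [])[
            start_idx:start_idx + vc.genes_per_cluster
        ]
        if len(members) < vc.genes_per_cluster:
            raise ValueError(
                f"cannot place viral cluster {c}: not enough genes on {chrom}"
            )
        ids = [f.id for f in members]
        cluster_gene_ids.extend(ids)
        cluster_records.append(
            {
                "cluster_id": f"vc{c}",
                "chrom": chrom,
                "start": min(f.start for f in members),
                "end": max(f.end for f in members),
                "n_genes": len(ids),
                "methylated": vc.methylated,
                "gene_ids": ",".join(ids),
            }
        )
    cluster_set = set(cluster_gene_ids)

    # ---- methylation truth per feature ---------------------------------
    host_gene_ids = [f.id for f in gene_rows if f.id not in cluster_set]
    n_meth_host = int(round(spec.methylated_gene_fraction * len(host_gene_ids)))
    meth_host = set(
        rng_levels.choice(host_gene_ids, size=n_meth_host, replace=False)
    ) if n_meth_host else set()
    methylated_genes = set(meth_host)
    if vc.methylated:
        methylated_genes |= cluster_set
    a_hi, b_hi = spec.beta_hi
    feature_level: Dict[str, float] = {}
    for f in gene_rows:
        if f.id in methylated_genes:
            feature_level[f.id] = float(
                np.clip(rng_levels.beta(a_hi, b_hi), 0.02, 0.98)
            )
    fam_by_te: Dict[str, TEFamilySpec] = {}
    for f, (fam, _k) in zip(te_rows, te_plan):
        fam_by_te[f.id] = fam
        if fam.methylated:
            feature_level[f.id] = float(
                np.clip(
                    rng_levels.normal(fam.meth_level, 0.05), 0.02, 0.98
                )
            )

    # ---- sequences ------------------------------------------------------
    genome_codes: Dict[str, np.ndarray] = {}
    consensus: Dict[str, np.ndarray] = {}
    for fam in spec.te_families:
        consensus[fam.name] = _random_sequence(
            rng_te, fam.consensus_length, spec.gc_content
        )
    alignments: List[InsertionAlignment] = []
    te_truth_rows = []
    te_feature_by_plan = {i: f for i, f in enumerate(te_rows)}
    for chrom in chrom_names:
        codes = _random_sequence(rng_seq, spec.chrom_length, spec.gc_content)
        genome_codes[chrom] = codes
    for i, (fam, _k) in enumerate(te_plan):
        f = te_feature_by_plan[i]
        cons = consensus[fam.name]
        mutated = evolve_k2p(cons, fam.divergence, fam.ts_tv_ratio, rng_te)
        genome_codes[f.chrom][f.start:f.end] = mutated
        cons_s = cons.tobytes().decode()
        ins_s = mutated.tobytes().decode()
        alignments.append(
            InsertionAlignment(
                te_id=f.id, family=fam.class_label, consensus=cons_s,
                insertion=ins_s, feature=f,
            )
        )
        # realized divergence bookkeeping (plain mismatch counting,
        # independent of the estimator module)
        same = cons == mutated
        is_ts = _TRANSITION[cons] == mutated
        n = len(cons)
        p_real = float(np.sum(~same & is_ts)) / n
        q_real = float(np.sum(~same & ~is_ts)) / n
        te_truth_rows.append(
            {
                "te_id": f.id, "family": fam.name,
                "class_label": fam.class_label, "chrom": f.chrom,
                "start": f.start, "end": f.end, "length": f.length,
                "methylated": fam.methylated,
                "true_level": feature_level.get(f.id, spec.epsilon),
                "target_divergence": fam.divergence,
                "realized_P": p_real, "realized_Q": q_real,
            }
        )

    # spike-in contigs
    sp = spec.spike_in
    genome_codes[sp.unmethylated_name] = _random_sequence(
        rng_seq, sp.unmethylated_length, 0.5
    )
    genome_codes[sp.methylated_name] = _random_sequence(
        rng_seq, sp.methylated_length, 0.5
    )

    # ---- per-site truth levels and observed counts ----------------------
    all_features = gene_rows + te_rows
    feats_by_chrom: Dict[str, List[Feature]] = {}
    for f in all_features:
        feats_by_chrom.setdefault(f.chrom, []).append(f)
    frames = []
    for chrom in list(chrom_names) + [sp.unmethylated_name, sp.methylated_name]:
        codes = genome_codes[chrom]
        pos, strand, dinuc, trinuc, _ = _context_arrays(codes)
        p_true = np.full(len(pos), spec.epsilon)
        if chrom == sp.methylated_name:
            p_true[trinuc == "CG"] = 1.0 - sp.false_negative_rate
        elif chrom != sp.unmethylated_name:
            in_context = _context_site_mask(dinuc, trinuc, spec.context_mode)
            for f in feats_by_chrom.get(chrom, []):
                lvl = feature_level.get(f.id)
                if lvl is None:
                    continue
                i0 = int(np.searchsorted(pos, f.start, side="left"))
                i1 = int(np.searchsorted(pos, f.end, side="left"))
                if i1 <= i0:
                    continue
                sub = in_context[i0:i1]
                n_in = int(sub.sum())
                if n_in == 0:
                    continue
                jitter = rng_levels.normal(0.0, spec.jitter_sd, n_in)
                segment = p_true[i0:i1]
                segment[sub] = np.clip(lvl + jitter, 0.005, 0.995)
        cov = rng_counts.poisson(spec.mean_depth, len(pos))
        keep = cov > 0
        n_meth = rng_counts.binomial(cov[keep], p_true[keep])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": pos[keep], "strand": strand[keep],
                    "dinuc": dinuc[keep], "trinuc": trinuc[keep],
                    "n_meth": n_meth, "n_total": cov[keep],
                }
            )
        )
    sites_df = pd.concat(frames, ignore_index=True)
    sites = SiteTable(
        sites_df["chrom"].to_numpy(dtype=object),
        sites_df["pos"].to_numpy(),
        sites_df["strand"].to_numpy(dtype="U1"),
        sites_df["dinuc"].to_numpy(dtype="U2"),
        sites_df["trinuc"].to_numpy(dtype="U3"),
        sites_df["n_meth"].to_numpy(),
        sites_df["n_total"].to_numpy(),
    )

    # ---- hit table ------------------------------------------------------
    euk_pool = [f"EukGenus{i}" for i in range(20)]
    prok_pool = [f"BactGenus{i}" for i in range(10)]
    vir_pool = [f"{vc.taxon}Genus{i}" for i in range(4)]
    hit_rows = []
    gene_category_truth: Dict[str, str] = {}
    for f in gene_rows:
        gid = f.id
        if gid in cluster_set:
            gene_category_truth[gid] = "Virus"
            for j in range(10):
                genus = vir_pool[int(rng_hits.integers(0, len(vir_pool)))]
                hit_rows.append(
                    (gid, f"Viruses;Nucleocytoviricota;{vc.taxon};{genus}",
                     500.0 - 5 * j, 1e-60 * 10 ** j)
                )
            continue
        if rng_hits.random() < spec.viral_noise_fraction:
            gene_category_truth[gid] = "Virus"
            for j in range(10):
                genus = vir_pool[int(rng_hits.integers(0, len(vir_pool)))]
                hit_rows.append(
                    (gid, f"Viruses;Phycodnaviridae;{genus}",
                     400.0 - 5 * j, 1e-50 * 10 ** j)
                )
            continue
        n_prok = 0
        if rng_hits.random() < spec.hit_noise_prok_fraction:
            n_prok = int(rng_hits.integers(2, 5))
        gene_category_truth[gid] = (
            "Eukaryote+Prokaryote" if n_prok >= 2 else "Eukaryote"
        )
        if rng_hits.random() < spec.self_hit_fraction:
            for j in range(2):
                hit_rows.append(
                    (gid, f"Eukaryota;Amoebozoa;{spec.self_genus}",
                     450.0 - j, 1e-70)
                )
        for j in range(10):
            if j < n_prok:
                genus = prok_pool[int(rng_hits.integers(0, len(prok_pool)))]
                tax = f"Bacteria;Pseudomonadota;{genus}"
            else:
                genus = euk_pool[int(rng_hits.integers(0, len(euk_pool)))]
                tax = f"Eukaryota;Opisthokonta;{genus}"
            hit_rows.append((gid, tax, 400.0 - 7 * j, 1e-50 * 10 ** j))
    hits_table = pd.DataFrame(
        hit_rows, columns=["gene_id", "taxonomy", "bitscore", "evalue"]
    )

    # ---- truth tables ---------------------------------------------------
    genes_truth = pd.DataFrame(
        [
            {
                "gene_id": f.id, "chrom": f.chrom, "start": f.start,
                "end": f.end, "strand": f.strand,
                "methylated": f.id in methylated_genes,
                "true_level": feature_level.get(f.id, float("nan")),
                "category": gene_category_truth[f.id],
                "cluster_id": next(
                    (r["cluster_id"] for r in cluster_records
                     if f.id in r["gene_ids"].split(",")), ""
                ),
            }
            for f in gene_rows
        ]
    )
    tes_truth = pd.DataFrame(te_truth_rows)
    clusters_truth = pd.DataFrame(
        cluster_records,
        columns=["cluster_id", "chrom", "start", "end", "n_genes",
                 "methylated", "gene_ids"],
    )
    genome = {c: codes.tobytes().decode() for c, codes in genome_codes.items()}
    return MethylomeBundle(
        spec=spec, genome=genome, features=all_features, sites=sites,
        hits_table=hits_table, alignments=alignments,
        genes_truth=genes_truth, tes_truth=tes_truth,
        clusters_truth=clusters_truth,
    )


# ---------------------------------------------------------------------------
# Phyletic profiles for Dollo testing
# ---------------------------------------------------------------------------


@dataclass
class ProfileBundle:
    tree: dendropy.Tree
    matrix: pd.DataFrame  # species x family, states present/absent
    truth: pd.DataFrame  # family, gain_node, loss_branches

    def newick(self) -> str:
        return self.tree.as_string(schema="newick")


def _random_rooted_tree(
    rng: np.random.Generator, n_species: int
) -> dendropy.Tree:
    """Random rooted binary tree built by successive joins."""
    taxa = dendropy.TaxonNamespace([f"S{i}" for i in range(n_species)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_species):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(f"S{i}")
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    # deterministic preorder internal labels
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = f"N{counter}"
            counter += 1
    return tree


def simulate_profiles(
    seed: int,
    n_species: int = 12,
    n_families: int = 200,
    loss_rate: float = 0.2,
) -> ProfileBundle:
    """Random gain/loss phyletic profiles with recorded truth.

    Each family is gained at one uniformly chosen tree node and then lost
    independently along each descendant branch with probability
    *loss_rate* (a lost subtree stays lost).  Families extinct in every
    leaf are resampled and never emitted.
    """
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError(f"loss_rate must be in [0,1), got {loss_rate}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tree = _random_rooted_tree(rng, n_species)
    nodes = list(tree.preorder_node_iter())
    species = [f"S{i}" for i in range(n_species)]
    matrix = pd.DataFrame(
        "absent", index=species, columns=[f"F{i}" for i in range(n_families)]
    )
    truth_rows = []
    for fam in matrix.columns:
        while True:
            gain = nodes[int(rng.integers(0, len(nodes)))]
            lost_ids = set()
            losses = []
            present_leaves = []
            for node in gain.preorder_iter():
                if node is not gain:
                    parent_lost = id(node.parent_node) in lost_ids
                    if parent_lost or rng.random() < loss_rate:
                        lost_ids.add(id(node))
                        if not parent_lost:
                            losses.append(
                                node.taxon.label if node.is_leaf() else node.label
                            )
                        continue
                if node.is_leaf() and id(node) not in lost_ids:
                    present_leaves.append(node.taxon.label)
            if present_leaves:
                break
        matrix.loc[present_leaves, fam] = "present"
        truth_rows.append(
            {
                "family": fam,
                "gain_node": gain.taxon.label if gain.is_leaf() else gain.label,
                "loss_branches": ",".join(sorted(losses)),
                "n_present": len(present_leaves),
            }
        )
    return ProfileBundle(tree=tree, matrix=matrix, truth=pd.DataFrame(truth_rows))
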