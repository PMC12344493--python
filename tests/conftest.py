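import numpy as np
import pytest

from methylgate.io_formats import CytosineSite, Feature
from methylgate.methylome_core import SiteTable
from methylgate.synthetic_data import (
    SimulationSpec,
    TEFamilySpec,
    ViralClusterSpec,
    simulate_methylome,
)


def make_site(chrom="chr1", pos=0, strand="+", dinuc="CG", trinuc="CG",
              m=0, t=0):
    return CytosineSite(
        chrom=chrom, pos=pos, strand=strand, dinuc_context=dinuc,
        trinuc_context=trinuc, n_meth=m, n_total=t,
    )


def make_table(rows):
    """rows: (chrom, pos, strand, dinuc, trinuc, m, t) tuples."""
    return SiteTable.from_sites(make_site(*r) for r in rows)


def random_table(rng, chrom="chr1", n=200, span=5000, depth=10, p=0.3):
    """Random sparse site table with binomial counts, CX-ish contexts."""
    pos = np.sort(rng.choice(span, size=min(n, span), replace=False))
    strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
    dinuc = rng.choice(["CA", "CC", "CG", "CT"], size=len(pos))
    trinuc = np.where(dinuc == "CG", "CG",
                      rng.choice(["CHG", "CHH"], size=len(pos)))
    total = rng.poisson(depth, len(pos))
    meth = rng.binomial(total, p)
    return SiteTable(
        np.full(len(pos), chrom, dtype=object), pos, strand, dinuc,
        trinuc.astype("U3"), meth, total,
    )


SMALL_SPEC = SimulationSpec(
    seed=11, n_genes=400, n_chroms=4, chrom_length=160_000,
)


@pytest.fixture(scope="session")
def small_bundle():
    """400-gene bundle shared across module tests (seed fixed)."""
    return simulate_methylome(SMALL_SPEC)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Very small bundle for format round-trips and CLI smoke tests."""
    spec = SimulationSpec(
        seed=5, n_genes=40, n_chroms=2, chrom_length=40_000,
        te_families=(
            TEFamilySpec("LINE-A", "LINE", 600, 6, 0.03, 2.0, 0.8, True),
        ),
        viral=ViralClusterSpec(n_clusters=1, genes_per_cluster=4),
    )
    return simulate_methylome(spec)


@pytest.fixture(scope="session")
def tiny_bundle_dir(tiny_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    tiny_bundle.write(out)
    return out
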