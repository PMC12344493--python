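import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylgate import methylome_core as core
from methylgate.io_formats import Feature
from conftest import make_table


class TestClassifyContext:
    def test_cg(self):
        assert core.classify_context({"chr1": "ACGT"}, "chr1", 1, "+") == \
            ("CG", "CG")

    def test_chg(self):
        assert core.classify_context({"chr1": "ACAGT"}, "chr1", 1, "+") == \
            ("CA", "CHG")

    def test_chh(self):
        assert core.classify_context({"chr1": "ACATT"}, "chr1", 1, "+") == \
            ("CA", "CHH")

    def test_final_base_is_na(self):
        assert core.classify_context({"chr1": "AAC"}, "chr1", 2, "+") == \
            ("NA", "NA")

    def test_trinuc_na_dinuc_defined(self):
        # next base exists (non-G) but base after next runs off the contig
        assert core.classify_context({"chr1": "ACA"}, "chr1", 1, "+") == \
            ("CA", "NA")

    def test_cg_at_penultimate_base_still_cg(self):
        # a terminal CpG is fully determined by the next base alone
        assert core.classify_context({"chr1": "ACG"}, "chr1", 1, "+") == \
            ("CG", "CG")

    def test_minus_strand(self):
        # Watson ACGT: the G at position 2 is a minus-strand C whose
        # next base (Watson pos 1 complemented) is G -> CpG
        assert core.classify_context({"chr1": "ACGT"}, "chr1", 2, "-") == \
            ("CG", "CG")

    def test_minus_strand_chg(self):
        # Watson "CAG": minus C at pos 2; next = comp(A) = T; after = comp(C) = G
        assert core.classify_context({"chr1": "CAG"}, "chr1", 2, "-") == \
            ("CT", "CHG")

    def test_n_in_window_is_na(self):
        assert core.classify_context({"chr1": "ACNT"}, "chr1", 1, "+") == \
            ("NA", "NA")

    def test_not_a_cytosine_raises(self):
        with pytest.raises(ValueError, match="not C"):
            core.classify_context({"chr1": "ACGT"}, "chr1", 0, "+")


class TestWeightedLevel:
    def test_equal_sites(self):
        t = make_table([("chr1", 1, "+", "CG", "CG", 5, 10),
                        ("chr1", 5, "+", "CG", "CG", 5, 10)])
        assert core.weighted_level(t, "CG").level == pytest.approx(0.5)

    def test_weighting_not_mean_of_fractions(self):
        t = make_table([("chr1", 1, "+", "CG", "CG", 3, 4),
                        ("chr1", 5, "+", "CG", "CG", 0, 4)])
        assert core.weighted_level(t, "CG").level == pytest.approx(0.375)

    def test_zero_sites_flagged_undefined(self):
        t = make_table([("chr1", 1, "+", "CA", "CHH", 3, 4)])
        lv = core.weighted_level(t, "CG")
        assert not lv.defined
        assert math.isnan(lv.level)

    def test_min_cov_excludes(self):
        t = make_table([("chr1", 1, "+", "CG", "CG", 5, 5),
                        ("chr1", 5, "+", "CG", "CG", 0, 2)])
        lv = core.weighted_level(t, "CG", min_cov=3)
        assert lv.n_sites == 1
        assert lv.level == pytest.approx(1.0)

    def test_binomial_simulation_recovery(self):
        rng = np.random.default_rng(1234)
        n = 10_000
        total = rng.poisson(20, n) + 1
        meth = rng.binomial(total, 0.32)
        t = core.SiteTable(
            np.full(n, "chr1", dtype=object), np.arange(n),
            np.full(n, "+"), np.full(n, "CG"), np.full(n, "CG"),
            meth, total,
        )
        lv = core.weighted_level(t, "CG")
        se = math.sqrt(0.32 * 0.68 / lv.n_total_reads)
        assert abs(lv.level - 0.32) < 3 * se

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("chr%d" % (i % 2), int(rng.integers(0, 1000)), "+",
                 "CG", "CG", int(m), int(m) + int(rng.integers(0, 5)))
                for i, m in enumerate(rng.integers(0, 10, 50))]
        a = core.weighted_level(make_table(rows), "CG")
        b = core.weighted_level(make_table(rows[::-1]), "CG")
        assert a == b

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=30),
           st.integers(1, 28))
    @settings(max_examples=60, deadline=None)
    def test_pooling_conservation(self, counts, cut):
        """Partition a region, recombine by count pooling: exact identity."""
        rows = [("chr1", i, "+", "CG", "CG", min(m, t), t)
                for i, (m, t) in enumerate(counts)]
        whole = core.weighted_level(make_table(rows), "CG")
        cut = min(cut, len(rows))
        parts = [rows[:cut], rows[cut:]]
        pooled_m = pooled_t = pooled_s = 0
        for part in parts:
            if not part:
                continue
            lv = core.weighted_level(make_table(part), "CG")
            pooled_m += lv.n_meth_reads
            pooled_t += lv.n_total_reads
            pooled_s += lv.n_sites
        assert (pooled_m, pooled_t, pooled_s) == (
            whole.n_meth_reads, whole.n_total_reads, whole.n_sites
        )


class TestGlobalLevels:
    def test_contexts_partition(self, small_bundle):
        g = core.global_context_levels(
            small_bundle.sites,
            exclude_contigs=["lambda", "pUC19"],
        )
        total = sum(g[c].n_total_reads for c in ("CA", "CC", "CG", "CT"))
        assert total == g["CX"].n_total_reads

    def test_background_contexts_at_epsilon(self, small_bundle):
        eps = small_bundle.spec.epsilon
        g = core.global_context_levels(
            small_bundle.sites, exclude_contigs=["lambda", "pUC19"]
        )
        for ctx in ("CA", "CC", "CT", "CHG", "CHH"):
            se = math.sqrt(eps * (1 - eps) / g[ctx].n_total_reads)
            assert abs(g[ctx].level - eps) < 3 * se, ctx
        assert g["CG"].level > 0.02  # methylated genes live here

    def test_all_zero_counts(self):
        t = make_table([("chr1", 1, "+", "CG", "CG", 0, 5),
                        ("chr1", 3, "+", "CA", "CHH", 0, 5)])
        g = core.global_context_levels(t)
        assert g["CG"].level == 0.0
        assert g["CG"].n_meth_reads == 0
        assert not g["CC"].defined


def _spike_table(rng, contig, n_sites, depth, p, context="CHH", dinuc="CA"):
    total = rng.poisson(depth, n_sites)
    keep = total > 0
    pos = np.arange(n_sites)[keep]
    total = total[keep]
    meth = rng.binomial(total, p)
    return core.SiteTable(
        np.full(len(pos), contig, dtype=object), pos,
        np.full(len(pos), "+"), np.full(len(pos), dinuc),
        np.full(len(pos), context), meth, total,
    )


def _concat(tables):
    return core.SiteTable(
        np.concatenate([t.chrom for t in tables]),
        np.concatenate([t.pos for t in tables]),
        np.concatenate([t.strand for t in tables]),
        np.concatenate([t.dinuc for t in tables]),
        np.concatenate([t.trinuc for t in tables]),
        np.concatenate([t.n_meth for t in tables]),
        np.concatenate([t.n_total for t in tables]),
    )


class TestSpikeInQC:
    @pytest.mark.parametrize("eps", [0.001, 0.003, 0.01])
    def test_nonconversion_grid(self, eps):
        rng = np.random.default_rng(int(eps * 1e5))
        lam = _spike_table(rng, "lambda", 100_000, 30, eps)
        puc = _spike_table(rng, "pUC19", 300, 30, 0.98, "CG", "CG")
        qc = core.spike_in_qc(_concat([lam, puc]))
        se = math.sqrt(eps * (1 - eps) / lam.n_total.sum())
        assert abs(qc.nonconversion_rate - eps) < 3 * se

    def test_fully_methylated_control_zero_false_negative(self):
        rng = np.random.default_rng(9)
        lam = _spike_table(rng, "lambda", 1000, 30, 0.003)
        puc = _spike_table(rng, "pUC19", 200, 30, 1.0, "CG", "CG")
        qc = core.spike_in_qc(_concat([lam, puc]))
        assert qc.false_negative_rate == pytest.approx(0.0)

    def test_missing_contig_named(self):
        rng = np.random.default_rng(9)
        puc = _spike_table(rng, "pUC19", 200, 30, 0.98, "CG", "CG")
        with pytest.raises(ValueError, match="lambda"):
            core.spike_in_qc(puc)


class TestDyadSymmetry:
    def _dyads(self, plus_levels, minus_levels, cov=10):
        rows = []
        for i, (lp, lm) in enumerate(zip(plus_levels, minus_levels)):
            pos = 10 * i
            rows.append(("chr1", pos, "+", "CG", "CG",
                         int(round(lp * cov)), cov))
            rows.append(("chr1", pos + 1, "-", "CG", "CG",
                         int(round(lm * cov)), cov))
        return make_table(rows)

    def test_mirrored_input_r_one(self):
        levels = [0.1, 0.5, 0.9, 0.3, 0.7]
        sym = core.dyad_symmetry(self._dyads(levels, levels), min_cov=5)
        assert sym.r == pytest.approx(1.0)
        assert sym.n_dyads == 5

    def test_independent_levels_near_zero(self):
        rng = np.random.default_rng(77)
        n = 10_000
        a = rng.random(n)
        b = rng.random(n)
        sym = core.dyad_symmetry(self._dyads(a, b, cov=100), min_cov=5)
        assert abs(sym.r) < 0.05

    def test_single_dyad_errors(self):
        with pytest.raises(ValueError, match="2"):
            core.dyad_symmetry(self._dyads([0.5], [0.5]), min_cov=1)

    def test_min_cov_filters_members(self):
        t = make_table([
            ("chr1", 0, "+", "CG", "CG", 5, 10),
            ("chr1", 1, "-", "CG", "CG", 5, 10),
            ("chr1", 10, "+", "CG", "CG", 1, 2),   # below min_cov
            ("chr1", 11, "-", "CG", "CG", 1, 10),
            ("chr1", 20, "+", "CG", "CG", 9, 10),
            ("chr1", 21, "-", "CG", "CG", 9, 10),
        ])
        sym = core.dyad_symmetry(t, min_cov=5)
        assert sym.n_dyads == 2


def _uniform_sites(chrom, span, m, t, step=1):
    rows = [(chrom, p, "+", "CA", "CHH", m, t) for p in range(0, span, step)]
    return make_table(rows)


class TestMetaprofile:
    FEATS = [
        Feature("chr1", 1000, 1400, "+", "f1"),
        Feature("chr1", 2000, 2600, "-", "f2"),
        Feature("chr1", 3000, 3050, "+", "f3"),  # shorter than body_bins
    ]

    def test_uniform_methylation_flat_profile(self):
        sites = _uniform_sites("chr1", 5000, 4, 10)
        prof = core.metaprofile(sites, self.FEATS, body_bins=10,
                                flank_bp=200, flank_bins=4)
        assert np.allclose(prof.levels, 0.4)

    def test_methylation_only_outside_features(self):
        rows = []
        for p in range(0, 5000, 2):
            inside = any(f.start <= p < f.end for f in self.FEATS)
            rows.append(("chr1", p, "+", "CA", "CHH", 0 if inside else 5, 10))
        prof = core.metaprofile(make_table(rows), self.FEATS, body_bins=10,
                                flank_bp=100, flank_bins=2)
        body = prof.levels[2:12]
        flanks = np.concatenate([prof.levels[:2], prof.levels[12:]])
        assert np.all(body == 0)
        assert np.all(flanks > 0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        rows = []
        for p in sorted(rng.choice(5000, 800, replace=False)):
            t = int(rng.integers(1, 20))
            rows.append(("chr1", int(p), "+", "CA", "CHH",
                         int(rng.integers(0, t + 1)), t))
        table = make_table(rows)
        body_bins, flank_bp, flank_bins = 7, 150, 3
        prof = core.metaprofile(table, self.FEATS, body_bins, flank_bp,
                                flank_bins)
        # independent per-site binning by exhaustive interval arithmetic
        nb = 2 * flank_bins + body_bins
        meth = np.zeros(nb, dtype=int)
        total = np.zeros(nb, dtype=int)
        for f in self.FEATS:
            for (chrom, p, strand, dn, tn, m, t) in rows:
                if chrom != f.chrom:
                    continue
                L = f.end - f.start
                if f.start <= p < f.end:
                    b = flank_bins + min((p - f.start) * body_bins // L,
                                         body_bins - 1)
                elif f.start - flank_bp <= p < f.start:
                    b = (p - (f.start - flank_bp)) * flank_bins // flank_bp
                elif f.end <= p < f.end + flank_bp:
                    b = flank_bins + body_bins + min(
                        (p - f.end) * flank_bins // flank_bp, flank_bins - 1)
                else:
                    continue
                if f.strand == "-":
                    b = nb - 1 - b
                meth[b] += m
                total[b] += t
        assert np.array_equal(prof.meth, meth)
        assert np.array_equal(prof.total, total)

    def test_strand_flip_reverses_profile(self):
        rng = np.random.default_rng(8)
        rows = [("chr1", int(p), "+", "CA", "CHH", int(rng.integers(0, 5)), 5)
                for p in sorted(rng.choice(5000, 500, replace=False))]
        table = make_table(rows)
        flip = {"+": "-", "-": "+"}
        flipped = [Feature(f.chrom, f.start, f.end, flip[f.strand], f.id)
                   for f in self.FEATS]
        a = core.metaprofile(table, self.FEATS, 8, 200, 4)
        b = core.metaprofile(table, flipped, 8, 200, 4)
        assert np.array_equal(a.meth, b.meth[::-1])
        assert np.array_equal(a.total, b.total[::-1])

    def test_short_feature_not_dropped(self):
        sites = _uniform_sites("chr1", 5000, 2, 10)
        prof = core.metaprofile(sites, [self.FEATS[2]], body_bins=60,
                                flank_bp=0, flank_bins=0)
        assert prof.total.sum() > 0  # 50 bp feature, 60 bins: still counted

    def test_mean_stat_reported(self):
        sites = _uniform_sites("chr1", 5000, 3, 10)
        prof = core.metaprofile(sites, self.FEATS, 5, 100, 2, stat="mean")
        assert prof.mean_of_features is not None
        assert np.allclose(prof.mean_of_features, 0.3)
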