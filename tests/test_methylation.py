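"""Context assignment, site filters, tiling, the group test and DMR calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sweepmeth as sm
from sweepmeth.errors import ValidationError
from sweepmeth.io import Gene, Genome, Transcript
from sweepmeth.methylation import MethylDataset

from conftest import make_table  # noqa: F401  (shared helpers live here)


def make_ds(positions, meth, unmeth, contexts=None, strands=None, contig="c1"):
    meth = np.asarray(meth, dtype=np.int64)
    unmeth = np.asarray(unmeth, dtype=np.int64)
    n_sites, n_samples = meth.shape
    sites = pd.DataFrame(
        {
            "contig": [contig] * n_sites,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strands or ["+"] * n_sites,
            "context": contexts or ["CG"] * n_sites,
        }
    )
    return MethylDataset(
        [f"m{i}" for i in range(n_samples)], sites, meth, unmeth,
        (meth + unmeth) > 0,
    )


class TestAssignContext:
    def test_plus_strand_examples(self):
        genome = Genome({"c1": "ACGT", "c2": "CAG", "c3": "CTT"})
        assert sm.assign_context(genome, "c1", 1, "+") == "CG"
        assert sm.assign_context(genome, "c2", 0, "+") == "CHG"
        assert sm.assign_context(genome, "c3", 0, "+") == "CHH"

    def test_minus_strand_reverse_complement(self):
        # plus CCG: the G at pos 2 is a minus-strand C whose minus-strand
        # context reads CGG -> CG
        genome = Genome({"c1": "CCG"})
        assert sm.assign_context(genome, "c1", 2, "-") == "CG"

    def test_insufficient_context_is_dropped(self):
        genome = Genome({"c1": "ACGC"})
        assert sm.assign_context(genome, "c1", 3, "+") is None  # runs off end
        genome = Genome({"c1": "CN"})
        assert sm.assign_context(genome, "c1", 0, "+") is None  # N in context

    def test_partition_on_synthetic_dataset(self, methyl_sim):
        ds = sm.combine_reports(methyl_sim.reports)
        assert set(ds.sites["context"]) <= {"CG", "CHG", "CHH"}
        assert ds.sites["context"].notna().all()


class TestFilterCytosines:
    def test_depth_floor_boundary(self):
        ds = make_ds([10, 20, 30], [[5], [6], [4]], [[4], [4], [6]])
        # coverages 9, 10, 10: exactly-10 retained, 9 dropped
        filtered, report = sm.filter_cytosines(ds)
        assert filtered.covered[:, 0].tolist() == [False, True, True]
        assert report["per_sample"]["m0"]["n_below_depth"] == 1

    def test_percentile_cap_removes_extreme_coverage(self):
        rng = np.random.default_rng(1)
        cov = rng.integers(10, 101, size=10_000)
        cov[:10] = 10_000  # PCR-duplicate-like spikes
        meth = (cov * 0.5).astype(np.int64)
        ds = make_ds(np.arange(10_000) * 3, meth[:, None], (cov - meth)[:, None])
        filtered, report = sm.filter_cytosines(ds)
        assert report["per_sample"]["m0"]["n_capped"] == 10
        assert not filtered.covered[:10, 0].any()
        assert filtered.covered[10:, 0].all()

    def test_sample_with_no_covered_sites_is_named(self):
        ds = make_ds([10], [[2]], [[3]])
        with pytest.raises(ValidationError, match="m0"):
            sm.filter_cytosines(ds)


class TestTiling:
    def test_tile_boundary_at_200(self):
        meth = np.full((6, 1), 15)
        unmeth = np.full((6, 1), 15)
        ds = make_ds([150, 160, 170, 210, 220, 230], meth, unmeth)
        tiles = sm.tile_counts(ds)
        assert tiles.tiles[["start", "end"]].values.tolist() == [[0, 200], [200, 400]]

    def test_tile_below_min_covered_cytosines_excluded(self):
        ds = make_ds([10, 20], np.full((2, 1), 15), np.full((2, 1), 15))
        tiles = sm.tile_counts(ds)  # 2 covered < default 3
        assert len(tiles.tiles) == 0

    def test_pooled_counts_conserve_site_counts(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(600, size=12, replace=False))
        meth = rng.integers(5, 20, size=(12, 2))
        unmeth = rng.integers(5, 20, size=(12, 2))
        ds = make_ds(pos, meth, unmeth)
        tiles = sm.tile_counts(ds, sm.MethylParams(min_covered_cytosines_per_tile=1))
        np.testing.assert_array_equal(tiles.meth.sum(axis=0), meth.sum(axis=0))
        np.testing.assert_array_equal(tiles.unmeth.sum(axis=0), unmeth.sum(axis=0))
        # hand sums per tile
        for i, row in tiles.tiles.iterrows():
            sel = (pos >= row["start"]) & (pos < row["end"])
            np.testing.assert_array_equal(tiles.meth[i], meth[sel].sum(axis=0))

    def test_non_tile_contexts_excluded(self):
        ds = make_ds(
            [10, 20, 30, 40],
            np.full((4, 1), 15), np.full((4, 1), 15),
            contexts=["CG", "CG", "CG", "CHH"],
        )
        tiles = sm.tile_counts(ds)
        assert tiles.tiles.loc[0, "n_cytosines"] == 3


def fisher_two_sided_oracle(m1, u1, m2, u2):
    """Two-sided Fisher p by direct hypergeometric summation."""
    n = m1 + u1
    k = m1 + m2
    total = m1 + u1 + m2 + u2
    p_obs = stats.hypergeom.pmf(m1, total, k, n)
    p = 0.0
    for x in range(max(0, n - (u1 + u2)), min(n, k) + 1):
        px = stats.hypergeom.pmf(x, total, k, n)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestTileTest:
    def test_null_identical_counts(self):
        p, fallback = sm.tile_test([50, 50, 50], [50, 50, 50],
                                   [50, 50, 50], [50, 50, 50])
        assert not fallback
        assert p == pytest.approx(1.0)

    def test_extreme_single_sample_difference(self):
        p, fallback = sm.tile_test([90], [10], [10], [90])
        assert fallback
        assert p < 1e-10

    def test_one_vs_one_equals_fisher_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            m1, u1, m2, u2 = rng.integers(0, 60, size=4)
            if (m1 + u1) == 0 or (m2 + u2) == 0:
                continue
            p, fallback = sm.tile_test([m1], [u1], [m2], [u2])
            assert fallback
            oracle = fisher_two_sided_oracle(int(m1), int(u1), int(m2), int(u2))
            assert p == pytest.approx(oracle, rel=1e-6, abs=1e-12)

    def test_matches_statsmodels_glm_deviance(self):
        """Closed-form LRT equals an IRLS-fitted binomial GLM's deviance."""
        import statsmodels.api as sma

        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.integers(1, 60, size=6)
            u = rng.integers(1, 60, size=6)
            p, _ = sm.tile_test(m[:3], u[:3], m[3:], u[3:])
            endog = np.column_stack([m, u])
            x_full = sma.add_constant(np.repeat([0.0, 1.0], 3))
            full = sma.GLM(endog, x_full, family=sma.families.Binomial()).fit()
            null = sma.GLM(endog, np.ones((6, 1)),
                           family=sma.families.Binomial()).fit()
            g = 2.0 * (full.llf - null.llf)
            assert p == pytest.approx(float(stats.chi2.sf(max(g, 0.0), 1)),
                                      rel=1e-8, abs=1e-12)

    def test_power_at_planted_forty_point_difference(self):
        """3v3 samples, depth 30, 0.4 planted difference: p < 0.01 in at
        least 95% of seeded replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 60
        for _ in range(reps):
            cov = rng.poisson(30 * 5, size=6)  # ~5 CpGs per sample per tile
            m = np.concatenate([
                rng.binomial(cov[:3], 0.7), rng.binomial(cov[3:], 0.3)
            ])
            p, _ = sm.tile_test(m[:3], cov[:3] - m[:3], m[3:], cov[3:] - m[3:])
            hits += p < 0.01
        assert hits / reps >= 0.95


class TestAdjustFdr:
    def test_hand_step_up(self):
        q = sm.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert sm.adjust_fdr([0.5]) == pytest.approx([0.5])

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        q = sm.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_input(self):
        assert sm.adjust_fdr(np.array([])).size == 0


class TestCallDmrs:
    def _tested(self, diffs, ps):
        return pd.DataFrame(
            {
                "contig": "c1", "start": np.arange(len(diffs)) * 200,
                "end": np.arange(1, len(diffs) + 1) * 200,
                "n_cytosines": 5, "m1": 0.5, "m2": 0.5,
                "diff": diffs, "p": ps, "fisher_fallback": False,
            }
        )

    def test_thresholds_are_strict_conjunctions(self):
        called, counts = sm.call_dmrs(self._tested([0.20, 0.30, 0.30], [1e-5, 0.02, 1e-6]))
        # diff below 25 pts -> ns; q above 0.01 -> ns
        assert called["status"].tolist() == ["ns", "ns", "hyper"]

    def test_direction_signs(self):
        called, counts = sm.call_dmrs(self._tested([0.4, -0.4], [1e-9, 1e-9]))
        assert called["status"].tolist() == ["hyper", "hypo"]
        assert counts["hyper"] + counts["hypo"] == counts["total_dmrs"]

    def test_bookkeeping_identity(self, methyl_sim):
        ds = sm.combine_reports(methyl_sim.reports)
        ds, _ = sm.filter_cytosines(ds)
        tiles = sm.tile_counts(ds)
        called, counts = sm.call_dmrs(sm.test_tiles(tiles, methyl_sim.groups))
        assert counts["hyper"] + counts["hypo"] + counts["ns"] == counts["tested"]
        assert counts["hyper"] + counts["hypo"] == counts["total_dmrs"]


class TestGlobalSummary:
    def test_levels_and_methylated_calls(self):
        # 4 CpG sites in one group: two clearly methylated, two at zero
        ds = make_ds(
            [10, 20, 30, 40],
            [[30, 30], [47, 30], [0, 0], [0, 0]],
            [[0, 0], [13, 10], [30, 30], [30, 30]],
        )
        genome = Genome({"c1": "CG" * 100})  # 200 genomic cytosines
        groups = {"m0": "A", "m1": "A"}
        out = sm.global_summary(ds, genome, groups)
        g = out["groups"]["A"]
        assert g["n_methylated_sites"] == 2
        assert g["pct_methylated_of_genomic"] == pytest.approx(100 * 2 / 200)
        # call-weighted CG level = total meth calls / total calls
        total_m = 30 + 30 + 47 + 30
        total = total_m + 13 + 10 + 120
        assert g["context_levels"]["CG"]["call_weighted"] == pytest.approx(
            total_m / total
        )

    def test_zero_meth_site_not_called_methylated(self):
        ds = make_ds([10], [[0]], [[30]])
        out = sm.global_summary(ds, Genome({"c1": "C" * 50}), {"m0": "A"})
        assert out["groups"]["A"]["n_methylated_sites"] == 0


class TestDmrGeneFeatures:
    @pytest.fixture
    def gene(self):
        tx = Transcript(
            "t1",
            exons=[(1000, 1100), (1200, 1300), (1400, 1500)],
            cds=[(1250, 1300), (1400, 1450)],
            utr5=[(1000, 1100), (1200, 1250)],
            utr3=[(1450, 1500)],
        )
        return Gene("G", "c1", "+", [tx])

    def test_promoter_upstream_of_plus_tss(self, gene):
        feats = sm.dmr_gene_features("c1", 400, 600, [gene])
        assert ("G", "promoter-2kb-upstream") in feats

    def test_five_utr_intron(self, gene):
        # intron (1100, 1200) sits between two 5'UTR exons
        feats = sm.dmr_gene_features("c1", 1150, 1160, [gene])
        assert feats == [("G", "5utr-intron")]

    def test_internal_intron_is_plain_intron(self, gene):
        feats = sm.dmr_gene_features("c1", 1350, 1360, [gene])
        assert feats == [("G", "intron")]

    def test_cds_and_utr_exons(self, gene):
        assert ("G", "cds-exon") in sm.dmr_gene_features("c1", 1260, 1270, [gene])
        assert ("G", "5utr-exon") in sm.dmr_gene_features("c1", 1010, 1020, [gene])
        assert ("G", "3utr-exon") in sm.dmr_gene_features("c1", 1460, 1470, [gene])

    def test_intergenic_when_nothing_within_reach(self, gene):
        assert sm.dmr_gene_features("c1", 5000, 5200, [gene]) == [("", "intergenic")]

    def test_minus_strand_promoter(self):
        tx = Transcript("t", [(1000, 1500)], [(1100, 1400)])
        gene = Gene("G", "c1", "-", [tx])
        feats = sm.dmr_gene_features("c1", 1600, 1700, [gene])
        assert ("G", "promoter-2kb-upstream") in feats
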