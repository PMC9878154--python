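"""Window construction, pooled Hp, Weir-Cockerham Fst and candidate calling."""

import numpy as np
import pandas as pd
import pytest

import sweepmeth as sm
from sweepmeth.errors import ValidationError
from sweepmeth.io import Gene, Transcript

from conftest import make_table


def wc_oracle(gt, g1, g2):
    """Independent straight-line transcription of the two-population
    Weir-Cockerham (1984) variance components, per site, ratio of sums."""
    r = 2
    sum_a = sum_abc = 0.0
    for row in gt:
        x1 = [int(v) for v in row[g1] if v >= 0]
        x2 = [int(v) for v in row[g2] if v >= 0]
        n1, n2 = len(x1), len(x2)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(x1) / (2 * n1)
        p2 = sum(x2) / (2 * n2)
        h1 = sum(1 for v in x1 if v == 1) / n1
        h2 = sum(1 for v in x2 if v == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    fst = sum_a / sum_abc if sum_abc != 0 else float("nan")
    return sum_a, sum_abc, fst


class TestMakeWindows:
    def test_standard_tiling(self):
        wins = sm.make_windows({"c1": 250_000}, sm.WindowSpec())
        assert len(wins) == 5
        assert wins[-1] == ("c1", 200_000, 250_000)

    def test_length_equal_to_size(self):
        wins = sm.make_windows({"c1": 100_000}, sm.WindowSpec())
        assert wins == [("c1", 0, 100_000), ("c1", 50_000, 100_000)]

    def test_short_contig_single_truncated_window(self):
        wins = sm.make_windows({"c1": 40_000}, sm.WindowSpec())
        assert wins == [("c1", 0, 40_000)]


class TestPooledHp:
    def test_maximal_diversity(self):
        assert sm.pooled_hp(np.array([10.0]), np.array([10.0])) == 0.5

    def test_all_fixed(self):
        assert sm.pooled_hp(np.array([20.0, 20.0]), np.array([0.0, 0.0])) == 0.0

    def test_hand_arithmetic(self):
        # (30,10) and (35,5): 2*65*15/80^2
        hp = sm.pooled_hp(np.array([30.0, 35.0]), np.array([10.0, 5.0]))
        assert hp == pytest.approx(0.304688, abs=1e-6)

    def test_bounded_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(0, 40, size=(8, 2)).astype(float)
            nmaj = counts.max(axis=1)
            nmin = counts.min(axis=1)
            if nmaj.sum() + nmin.sum() == 0:
                continue
            hp = sm.pooled_hp(nmaj, nmin)
            assert 0.0 <= hp <= 0.5


class TestWcFst:
    def test_no_differentiation_is_nonpositive(self):
        # identical allele frequencies, sample sizes and het counts
        row = [0, 0, 1, 1, 2, 0, 1, 0, 1, 2]
        gt = np.array([row + row], dtype=np.int8)
        a, b, c, valid = sm.wc_fst_components(gt, np.arange(10), np.arange(10, 20))
        assert valid[0]
        assert a[0] <= 1e-12

    def test_fixed_difference_is_one(self):
        gt = np.array([[2] * 10 + [0] * 10], dtype=np.int8)
        a, b, c, _ = sm.wc_fst_components(gt, np.arange(10), np.arange(10, 20))
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)

    def test_one_site_against_transcription_oracle(self):
        # n1=n2=10 diploids, p1=0.8, p2=0.2, 4 observed hets in each group
        g1 = [2] * 6 + [1] * 4  # 16 alt alleles / 20 -> p=0.8, 4 hets
        g2 = [0] * 6 + [1] * 4  # 4 alt alleles / 20 -> p=0.2, 4 hets
        gt = np.array([g1 + g2], dtype=np.int8)
        a, b, c, _ = sm.wc_fst_components(gt, np.arange(10), np.arange(10, 20))
        oa, oabc, ofst = wc_oracle(gt, np.arange(10), np.arange(10, 20))
        assert a[0] == pytest.approx(oa, abs=1e-12)
        assert (a[0] + b[0] + c[0]) == pytest.approx(oabc, abs=1e-12)

    def test_random_windows_match_oracle(self):
        rng = np.random.default_rng(123)
        g1, g2 = np.arange(6), np.arange(6, 12)
        for _ in range(200):
            n_sites = int(rng.integers(1, 20))
            gt = rng.integers(-1, 3, size=(n_sites, 12)).astype(np.int8)
            a, b, c, valid = sm.wc_fst_components(gt, g1, g2)
            oa, oabc, _ = wc_oracle(gt, g1, g2)
            assert a.sum() == pytest.approx(oa, abs=1e-10)
            assert (a + b + c)[valid].sum() == pytest.approx(oabc, abs=1e-10)

    def test_site_excluded_when_group_too_small(self):
        gt = np.array([[1, -1, -1, -1, 1, 1, 0, 2]], dtype=np.int8)
        _, _, _, valid = sm.wc_fst_components(gt, np.arange(4), np.arange(4, 8))
        assert not valid[0]  # group 1 has a single called genotype


class TestEmpiricalThreshold:
    def test_rank_arithmetic_high_tail(self):
        thr, n = sm.empirical_threshold(np.arange(1, 21), 0.10, "high")
        assert (thr, n) == (18.0, 2)

    def test_low_tail_mirror(self):
        thr, n = sm.empirical_threshold(np.arange(1, 21), 0.10, "low")
        assert (thr, n) == (3.0, 2)

    def test_all_equal_nothing_beyond(self):
        thr, n = sm.empirical_threshold(np.full(50, 7.0), 0.10, "high")
        assert (thr, n) == (7.0, 0)

    def test_invalid_quantile(self):
        with pytest.raises(ValidationError):
            sm.empirical_threshold(np.arange(5), 1.5, "high")


class TestScanAndCandidates:
    def test_interior_snps_fall_in_exactly_two_windows(self):
        wins = sm.make_windows({"c1": 400_000}, sm.WindowSpec())
        for pos in (100_000, 123_456, 250_000, 299_999):
            hits = sum(1 for (_, s, e) in wins if s <= pos < e)
            assert hits == 2

    def test_candidate_requires_both_outlier_flags(self, sweep_sim):
        filtered, _ = sm.filter_sites(sweep_sim.table, sm.QcParams())
        wins = sm.scan_windows(filtered, sweep_sim.groups,
                               sweep_sim.params.contig_lengths)
        wins, _ = sm.select_candidates(wins)
        only_fst = wins[wins["fst_outlier"] & ~wins["hp_outlier"]]
        assert not only_fst["candidate"].any()
        assert (wins["candidate"] == (wins["hp_outlier"] & wins["fst_outlier"])).all()

    def test_hp_tail_high_and_low_are_disjoint(self, sweep_sim):
        filtered, _ = sm.filter_sites(sweep_sim.table, sm.QcParams())
        wins = sm.scan_windows(filtered, sweep_sim.groups,
                               sweep_sim.params.contig_lengths)
        low, _ = sm.select_candidates(wins, sm.SweepThresholds(hp_tail="low"))
        high, _ = sm.select_candidates(wins, sm.SweepThresholds(hp_tail="high"))
        both = low["hp_outlier"] & high["hp_outlier"]
        assert not both.any()

    def test_hp_bounds_and_fst_cap_on_simulation(self, sweep_sim):
        filtered, _ = sm.filter_sites(sweep_sim.table, sm.QcParams())
        wins = sm.scan_windows(filtered, sweep_sim.groups,
                               sweep_sim.params.contig_lengths)
        analyzed = wins[wins["analyzed"]]
        assert ((analyzed["hp_group1"] >= 0) & (analyzed["hp_group1"] <= 0.5)).all()
        assert ((analyzed["hp_group2"] >= 0) & (analyzed["hp_group2"] <= 0.5)).all()
        assert (analyzed["fst"] <= 1.0 + 1e-12).all()

    def test_single_site_window_fst_equals_per_site(self):
        gt = np.concatenate(
            [np.random.default_rng(5).integers(0, 3, size=(1, 20))], axis=0
        ).astype(np.int8)
        table = make_table(gt, pos=[10])
        groups = {f"S{i}": ("A" if i < 10 else "B") for i in range(20)}
        wins = sm.scan_windows(
            table, groups, {"c1": 100}, sm.WindowSpec(100, 100, 1)
        )
        a, b, c, valid = sm.wc_fst_components(gt, np.arange(10), np.arange(10, 20))
        assert wins.loc[0, "fst"] == pytest.approx(
            a[0] / (a[0] + b[0] + c[0]), abs=1e-12
        )

    def test_hudson_estimator_agrees_on_strong_signal(self, sweep_sim):
        """Sensitivity check: Hudson and Weir-Cockerham rank the planted
        windows the same way and agree at a fixed difference."""
        gt = np.array([[2] * 10 + [0] * 10], dtype=np.int8)
        num, den, valid = sm.sweep.hudson_fst_components(
            gt, np.arange(10), np.arange(10, 20)
        )
        assert valid[0]
        assert num[0] / den[0] == pytest.approx(1.0)
        filtered, _ = sm.filter_sites(sweep_sim.table, sm.QcParams())
        wc = sm.scan_windows(filtered, sweep_sim.groups,
                             sweep_sim.params.contig_lengths)
        hu = sm.scan_windows(filtered, sweep_sim.groups,
                             sweep_sim.params.contig_lengths,
                             estimator="hudson")
        both = wc["analyzed"] & hu["analyzed"]
        corr = np.corrcoef(wc.loc[both, "fst"], hu.loc[both, "fst"])[0, 1]
        assert corr > 0.95

    def test_stronger_sweep_raises_truth_window_fst(self):
        """Mean Fst inside planted windows grows with the divergence F."""
        means = []
        for f in (0.05, 0.4):
            vals = []
            for seed in range(3):
                params = sm.SweepSimParams(
                    n_contigs=1, contig_length=300_000,
                    sweep_windows=[("chr1", 100_000, 200_000)], sweep_f=f,
                )
                sim = sm.simulate_sweep_genotypes(params, seed=seed)
                filtered, _ = sm.filter_sites(sim.table, sm.QcParams())
                wins = sm.scan_windows(filtered, sim.groups, params.contig_lengths)
                truth = wins[(wins["start"] == 100_000) & (wins["end"] == 200_000)]
                vals.append(float(truth["fst"].iloc[0]))
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestGenesInWindows:
    def _gene(self, gid, start, end, contig="c1"):
        tx = Transcript(f"{gid}.t", [(start, end)])
        return Gene(gid, contig, "+", [tx])

    def test_hand_drawn_overlap_fixture(self):
        genes = [
            self._gene("g1", 10, 50),     # inside window 1
            self._gene("g2", 95, 120),    # straddles window 1 edge
            self._gene("g3", 150, 190),   # between windows
            self._gene("g4", 250, 260),   # inside window 2
            self._gene("g5", 400, 500),   # beyond both
        ]
        cand = pd.DataFrame(
            {"contig": ["c1", "c1"], "start": [0, 200], "end": [100, 300],
             "candidate": [True, True]}
        )
        assert sm.genes_in_windows(cand, genes) == ["g1", "g2", "g4"]

    def test_gene_straddling_two_windows_counted_once(self):
        genes = [self._gene("g1", 90, 110)]
        cand = pd.DataFrame(
            {"contig": ["c1", "c1"], "start": [0, 100], "end": [100, 200],
             "candidate": [True, True]}
        )
        assert sm.genes_in_windows(cand, genes) == ["g1"]

    def test_gene_in_non_candidate_window_excluded(self):
        genes = [self._gene("g1", 10, 50)]
        cand = pd.DataFrame(
            {"contig": ["c1"], "start": [0], "end": [100], "candidate": [False]}
        )
        assert sm.genes_in_windows(cand, genes) == []
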