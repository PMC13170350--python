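"""Rate CIs, exact tests, hotspot scan and permutation association."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import lohscan.stats as lst
from lohscan.simulate import default_genome


# -- independent oracles -----------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (fractions)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (Fraction(math.comb(r1, x)) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                if prob(x) <= p_obs)
    return float(total)


def mw_exact_oracle(x, y):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in grp for yj in rest if xi > yj))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestRateCI:
    def test_reproduces_printed_iloh_row(self):
        est = lst.rate_ci(158, 10858)
        assert round(est.rate * 1e3) == 15
        assert round(est.ci_low * 1e3) == 12
        assert round(est.ci_high * 1e3) == 17

    def test_reproduces_printed_idup_row(self):
        est = lst.rate_ci(3, 10858)
        assert round(est.ci_low * 1e3, 2) == 0.06
        assert round(est.ci_high * 1e3, 2) == 0.81

    def test_zero_count_closed_form_upper(self):
        est = lst.rate_ci(0, 100)
        assert est.ci_low == 0.0 and est.rate == 0.0
        assert est.ci_high * 100 == pytest.approx(-math.log(0.025), rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lst.rate_ci(5, 0)
        with pytest.raises(ValueError):
            lst.rate_ci(-1, 10)

    def test_bounds_monotone_in_count(self):
        ests = [lst.rate_ci(k, 1000) for k in range(30)]
        for a, b in zip(ests, ests[1:]):
            assert b.ci_low >= a.ci_low and b.ci_high >= a.ci_high

    def test_coverage_at_small_and_large_means(self):
        # exact Poisson CIs are conservative: coverage >= ~95%
        rng = np.random.default_rng(42)
        N = 1000.0
        for lam in (1, 5, 50):
            ks = rng.poisson(lam, size=1000)
            cover = 0
            for k in ks:
                e = lst.rate_ci(int(k), N)
                cover += e.ci_low <= lam / N <= e.ci_high
            assert cover / 1000 >= 0.93


class TestFisher:
    def test_complex_event_comparison(self):
        # 74/351 complex events vs the reference 167/1215
        assert lst.fisher_2x2(74, 277, 167, 1048) == pytest.approx(0.001, abs=5e-4)

    def test_small_table_exact_value(self):
        assert lst.fisher_2x2(2, 3, 4, 1) == pytest.approx(132 / 252, rel=1e-12)

    def test_zero_margins(self):
        assert lst.fisher_2x2(0, 10, 0, 10) == 1.0
        assert lst.fisher_2x2(0, 0, 0, 0) == 1.0

    def test_matches_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(80):
            a, b, c, d = rng.integers(0, 8, size=4)
            assert lst.fisher_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)


class TestChisq:
    def test_hotspot_configuration(self):
        stat, p = lst.chisq_gof([22, 329], [65 / 12071, 1 - 65 / 12071])
        assert stat == pytest.approx(215.12, abs=0.5)
        assert p < 1e-6

    def test_observed_equal_expected(self):
        stat, p = lst.chisq_gof([50, 50], [0.5, 0.5])
        assert stat == 0.0 and p == 1.0

    def test_cold_chromosome(self, toy_genome=None):
        g = default_genome(scale=1.0, seed=0)
        stat, p = lst.region_chisq(
            [("chrIX", 100)], g, "chrIX")  # degenerate but exercises plumbing
        # the documented configuration: 1 of 351 breakpoints on chrIX
        share = g.chromosome("chrIX").length / g.genome_length
        stat, p = lst.chisq_gof([1, 350], [share, 1 - share])
        assert p < 0.001

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            lst.chisq_gof([5, 5], [0.0, 1.0])


class TestPoissonTwoRate:
    def test_three_vs_zero_equal_exposure(self):
        assert lst.poisson_two_rate(3, 100, 0, 100) == pytest.approx(0.25)

    def test_symmetric_counts_give_one(self):
        assert lst.poisson_two_rate(7, 50, 7, 50) == 1.0

    def test_zero_total(self):
        assert lst.poisson_two_rate(0, 10, 0, 10) == 1.0

    def test_fourfold_elevated_class_detected(self):
        # 22 A:T>T:A substitutions vs a reference strain's ~5 at equal divisions
        assert lst.poisson_two_rate(22, 10858, 5, 10858) < 0.05


class TestMannWhitney:
    def test_tiny_sample_exact(self):
        u, p = lst.mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, rel=1e-9)

    def test_identical_samples(self):
        _, p = lst.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        _, p = lst.mann_whitney(x, y)
        assert p < 1e-4

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for n, m in [(2, 3), (3, 3), (4, 5), (5, 6)]:
            x = rng.permutation(100)[:n].astype(float)
            y = rng.permutation(200)[100:100 + m].astype(float)
            _, p = lst.mann_whitney(x, y)
            assert p == pytest.approx(mw_exact_oracle(x, y), rel=1e-9)


class TestHotspotScan:
    def test_planted_cluster_detected(self):
        g = default_genome(scale=1.0, seed=1)
        rng = np.random.default_rng(7)
        lens = g.chrom_lengths
        names = g.chrom_names
        probs = np.array([lens[c] for c in names]) / g.genome_length
        chroms = rng.choice(names, 329, p=probs)
        bp = [(c, int(rng.integers(1, lens[c] + 1))) for c in chroms]
        bp += [("chrVII", int(p)) for p in rng.integers(1_000_001, 1_065_001, 22)]
        windows, regions = lst.hotspot_scan(bp, g)
        hot = [w for w in windows if w.chromosome == "chrVII" and w.q < 0.001
               and w.start <= 1_000_001 and w.end >= 1_064_000]
        assert hot, "planted 22/351 cluster not detected"
        assert any(c == "chrVII" for c, s, e in regions)

    def test_single_breakpoint_no_hotspot(self):
        g = default_genome(scale=0.1, seed=1)
        windows, regions = lst.hotspot_scan([("chrI", 5000)], g, window=6500,
                                            step=1000)
        assert regions == []

    def test_short_chromosome_single_bin(self):
        g = default_genome(scale=0.02, seed=1)
        windows, _ = lst.hotspot_scan([("chrI", 100)], g, window=10_000_000)
        assert len(windows) == 16


class TestAssociation:
    def test_full_coverage_track_gives_p_one(self, toy_genome):
        import pandas as pd
        feats = pd.concat([toy_genome.features, pd.DataFrame(
            [{"track": "all", "chrom": c.name, "start": 1, "end": c.length,
              "label": "all"} for c in toy_genome.chromosomes])],
            ignore_index=True)
        from lohscan.model import GenomeMap
        g = GenomeMap(toy_genome.chromosomes, toy_genome.snps, feats,
                      toy_genome.arrays)
        bp = [("chrA", p) for p in (100, 5000, 70_000)]
        (res,) = lst.feature_association(bp, g, "all", n_perm=199, seed=1)
        assert res.p == 1.0 and res.observed == 3

    def test_maximal_enrichment_gives_minimal_p(self, toy_genome):
        # every breakpoint inside the single snRNA interval (0.25% of chrB)
        bp = [("chrB", 10_050)] * 20
        (res,) = lst.feature_association(bp, toy_genome, "snRNA_gene",
                                         n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)
        assert res.direction == "over"

    def test_empty_track_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="empty"):
            lst.feature_association([("chrA", 1)], toy_genome, "nope", n_perm=100)

    def test_null_p_values_roughly_uniform(self, toy_genome):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(100):
            bp = [("chrA", int(rng.integers(1, 100_001))) for _ in range(40)]
            (r,) = lst.feature_association(bp, toy_genome, "repeat",
                                           n_perm=199, seed=int(rng.integers(2**31)))
            ps.append(r.p)
        # counts are strongly discrete, so the p-values are conservative;
        # the property that matters is validity: P(p <= a) <= a (+ MC slack)
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.2):
            assert np.mean(ps <= alpha) <= alpha + 0.06


class TestRateTable:
    def test_table_reproduction_from_counts(self, toy_genome):
        from lohscan.model import EventCall, MutationCall, paper_design
        counts = {"I_LOH": 158, "T_LOH": 193, "I_DEL": 23, "I_DUP": 3,
                  "T_DEL": 9, "T_DUP": 8, "MONOSOMY": 32}
        events = []
        for cls, k in counts.items():
            for i in range(k):
                events.append(EventCall(f"i{i}", cls, "chrA", 1, 100))
        muts = [MutationCall("i", "chrA", 1, "SNV", "A", "T") for _ in range(89)]
        muts += [MutationCall("i", "chrA", 1, "INDEL", "AT", "A") for _ in range(14)]
        tbl = lst.rate_table(events, muts, paper_design(),
                             reference_rates=lst.WT_REFERENCE_RATES)
        tbl = tbl.set_index("class")
        assert tbl.loc["T_LOH", "rate_printed"] == 18
        assert tbl.loc["T_LOH", "fold_printed"] == 14
        assert tbl.loc["SNV", "rate_printed"] == 8.2
        assert tbl.loc["I_DUP", "ci_low_printed"] == 0.06
        assert tbl.loc["aneuploidy_UPD", "k"] == 32

    def test_zero_events_upper_bounds_only(self):
        from lohscan.model import paper_design
        tbl = lst.rate_table([], [], paper_design(), reference_rates={})
        assert (tbl["rate"] == 0).all()
        assert (tbl["ci_low"] == 0).all()
        assert (tbl["ci_high"] > 0).all()


class TestBH:
    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_bh_monotone_and_bounded(self, ps):
        qs = lst.bh_adjust(ps)
        assert ((qs >= np.array(ps) - 1e-12) | np.isclose(qs, ps)).all()
        assert (qs <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()
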