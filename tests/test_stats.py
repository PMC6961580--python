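"""Cohort comparisons: GC, trend, composition, motifs, PAM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from koscan import (
    compare_gc,
    gc_bin_table,
    gc_trend,
    motif_enrichment,
    pam_distribution,
    positional_composition,
)
from koscan.errors import ConfigError, InsufficientDataError
from koscan.stats import cochran_armitage

from conftest import make_site

PREFIX = "GGATATAT"  # seed-neutral 8-nt 5' filler (2 GC, outside the seed)


def cohort(seed_pos: list[str], seed_neg: list[str], pam="AGG"):
    sites = [make_site(PREFIX + s, pam=pam, label="positive") for s in seed_pos]
    sites += [make_site(PREFIX + s, pam=pam, label="negative") for s in seed_neg]
    return sites


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric tail enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-7)].sum())


class TestCompareGC:
    def test_maximal_separation(self):
        sites = cohort(["GCGCGCGCGCGC"] * 3, ["ATATATATATAT"] * 3)
        res = compare_gc(sites)
        assert res["mean_gc_seed_positive"] == 100.0
        assert res["mean_gc_seed_negative"] == 0.0
        assert res["gc_test_p"] < 0.05

    def test_identical_cohorts(self):
        seeds = ["GCGCGCGCGCGC", "ATATATATATAT", "GGGGGGAAAAAA"] * 4
        res = compare_gc(cohort(seeds, seeds))
        assert res["mean_gc_seed_positive"] == res["mean_gc_seed_negative"]
        assert res["gc_test_p"] > 0.9

    def test_empty_cohort_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_gc([make_site(PREFIX + "A" * 12, label="positive")])

    def test_synthetic_defaults_direction(self, default_sites):
        res = compare_gc(default_sites)
        assert res["mean_gc_seed_positive"] > res["mean_gc_seed_negative"]


class TestBinTable:
    def test_single_bin(self):
        # seed with 7 GC
        seed = "GCGCGCGTATAT"
        tab = gc_bin_table(cohort([seed, seed], [seed]))
        assert tab.loc[7, "n_positive"] == 2
        assert tab.loc[7, "n_negative"] == 1
        assert tab.loc[7, "positive_rate"] == pytest.approx(2 / 3)
        assert tab.drop(index=7)[["n_positive", "n_negative"]].to_numpy().sum() == 0

    def test_marginals_conserved(self, default_sites):
        tab = gc_bin_table(default_sites)
        n_pos = sum(s.label == "positive" for s in default_sites)
        n_neg = sum(s.label == "negative" for s in default_sites)
        assert tab["n_positive"].sum() == n_pos
        assert tab["n_negative"].sum() == n_neg
        assert len(tab) == 13

    def test_gc_over_half_is_bins_7_up(self, default_sites):
        from koscan.stats import GC_OVER_HALF_MIN_COUNT, build_cohort_report

        tab = gc_bin_table(default_sites)
        report = build_cohort_report(default_sites)
        share = tab.loc[GC_OVER_HALF_MIN_COUNT:, "n_positive"].sum() / tab["n_positive"].sum()
        assert report.frac_gc_over_half_positive == pytest.approx(share)


def _bin_frame(n_pos, n_neg):
    n_pos, n_neg = np.asarray(n_pos), np.asarray(n_neg)
    total = n_pos + n_neg
    rate = np.where(total > 0, n_pos / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"n_positive": n_pos, "n_negative": n_neg, "positive_rate": rate},
        index=pd.Index(range(len(n_pos)), name="gc_count"),
    )


class TestTrend:
    def test_perfect_line(self):
        # positive_rate == gc_count / 12 exactly over bins 0..12
        n_total = 12
        n_pos = [k for k in range(13)]
        n_neg = [12 - k for k in range(13)]
        res = gc_trend(_bin_frame(n_pos, n_neg))
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["trend_stat"] > 0

    def test_constant_rate(self):
        res = gc_trend(_bin_frame([5] * 6, [5] * 6))
        assert res["pearson_r"] == 0.0
        assert res["trend_p"] == pytest.approx(1.0)

    def test_too_few_bins(self):
        with pytest.raises(InsufficientDataError):
            gc_trend(_bin_frame([1, 2], [1, 2]))

    def test_cochran_armitage_vs_permutation(self):
        """Normal-approximation CA p-value agrees with a seeded Monte Carlo
        permutation null on a moderately sized table."""
        rng = np.random.default_rng(0)
        scores = np.arange(5.0)
        n_total = np.full(5, 40)
        rate = 0.3 + 0.05 * scores
        n_pos = rng.binomial(n_total, rate)
        z, p = cochran_armitage(n_pos, n_total, scores)

        # permutation: shuffle pooled labels over sites, recompute numerator
        labels = np.repeat(np.arange(5), n_total)
        flags = np.concatenate(
            [np.r_[np.ones(k), np.zeros(n - k)] for k, n in zip(n_pos, n_total)]
        )
        p_bar = flags.mean()
        obs = abs(np.sum(scores * (n_pos - n_total * p_bar)))
        hits = 0
        reps = 20_000
        for _ in range(reps):
            rng.shuffle(flags)
            perm_pos = np.bincount(labels[flags == 1], minlength=5)
            if abs(np.sum(scores * (perm_pos - n_total * p_bar))) >= obs - 1e-9:
                hits += 1
        assert p == pytest.approx(hits / reps, abs=0.02)

    def test_sign_agreement_on_monotone_data(self):
        res = gc_trend(_bin_frame([1, 4, 9, 16], [9, 6, 1, 0]))
        assert np.sign(res["pearson_r"]) == np.sign(res["trend_stat"]) == 1

    def test_slope_sign_recovered(self):
        """The fitted trend sign matches the generating logistic slope sign
        in at least 95 of 100 default-scale replicates."""
        from koscan import SyntheticConfig, simulate_sites
        from koscan.io import sites_from_frame

        ok = 0
        for seed in range(100):
            df = simulate_sites(SyntheticConfig(rng_seed=seed))
            res = gc_trend(gc_bin_table(sites_from_frame(df)))
            ok += res["pearson_r"] > 0
        assert ok >= 95


class TestPositionalComposition:
    def test_leading_bases_flagged(self):
        pos_seed, neg_seed = "GCGCGCGCGCGC", "GCGCGCGCGCGC"
        sites = [
            make_site("GG" + "ATATAT" + pos_seed, label="positive") for _ in range(25)
        ] + [make_site("AT" + "ATATAT" + neg_seed, label="negative") for _ in range(25)]
        comp = positional_composition(sites)
        cell = comp.set_index(["position", "base"])
        assert cell.loc[(-20, "G"), "frac_positive"] == 1.0
        assert cell.loc[(-20, "G"), "frac_negative"] == 0.0
        assert cell.loc[(-20, "G"), "q_value"] < 0.001
        assert cell.loc[(-19, "G"), "q_value"] < 0.001

    def test_identical_cohorts_all_q_one(self):
        seeds = ["GCGCGCGCGCGC", "ATATATATATAT"] * 5
        comp = positional_composition(cohort(seeds, seeds))
        assert (comp["q_value"] == 1.0).all()

    def test_only_constructed_cell_flagged(self):
        """A cohort differing only in C at position -1 flags exactly that
        cell; the Fisher p there matches hypergeometric enumeration."""
        base11 = "GCGCGCGCGCG"  # positions -12..-2 identical in all sites

        def batch(label, counts):
            sites = []
            for base, k in counts.items():
                sites += [
                    make_site(PREFIX + base11 + base, label=label) for _ in range(k)
                ]
            return sites

        sites = batch("positive", {"C": 30, "A": 57, "G": 57, "T": 56})
        sites += batch("negative", {"C": 70, "A": 44, "G": 43, "T": 43})
        comp = positional_composition(sites)
        flagged = comp[comp["q_value"] < 0.05]
        assert list(flagged[["position", "base"]].itertuples(index=False)) == [(-1, "C")]
        p = flagged["p_value"].iloc[0]
        assert p == pytest.approx(fisher_enumeration_oracle(30, 170, 70, 130), rel=1e-6)

    def test_t7_positions_flagged_and_excludable(self, default_sites):
        comp = positional_composition(default_sites)
        assert comp[comp["position"] == -20]["t7_biased"].all()
        assert len(comp) == 80
        reduced = positional_composition(default_sites, exclude_t7_positions=True)
        assert len(reduced) == 72
        assert set(reduced["position"]) == set(range(-18, 0))

    def test_fractions_sum_to_one(self, default_sites):
        comp = positional_composition(default_sites)
        sums = comp.groupby("position")[["frac_positive", "frac_negative"]].sum()
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_bh_is_monotone_step_up(self, default_sites):
        comp = positional_composition(default_sites).sort_values("p_value")
        assert (comp["q_value"].to_numpy() >= comp["p_value"].to_numpy() - 1e-12).all()
        assert (np.diff(comp["q_value"].to_numpy()) >= -1e-12).all()


class TestFisherOracle:
    def test_matches_enumeration_small_margins(self):
        """scipy's two-sided Fisher test (our 2x2 engine) equals direct
        hypergeometric enumeration on random tables with margins <= 30."""
        rng = np.random.default_rng(42)
        tables = [(0, 0, 0, 1), (1, 0, 0, 1), (15, 15, 15, 15), (30, 0, 0, 30)]
        while len(tables) < 200:
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b <= 30 and c + d <= 30 and (a + b) and (c + d):
                tables.append((int(a), int(b), int(c), int(d)))
        for a, b, c, d in tables:
            p_scipy = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p_scipy == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), rel=1e-7, abs=1e-12
            )


class TestMotifEnrichment:
    def test_maximal_separation_collapsed(self):
        sites = cohort(["GCGCGCGCGCGC"] * 10, ["ATATATATATAT"] * 10)
        res = motif_enrichment(sites, 2, "collapsed").set_index("motif")
        assert np.isnan(res.loc["SS", "enrichment_ratio"])  # denominator 0
        assert res.loc["SS", "q_value"] < 0.01
        assert res.loc["WW", "enrichment_ratio"] == 0.0

    def test_identical_cohorts_ratio_one(self):
        seeds = ["GCATGCATGCAT", "ATATGCGCATAT"] * 5
        res = motif_enrichment(cohort(seeds, seeds), 3, "collapsed")
        assert np.allclose(res["enrichment_ratio"], 1.0)
        assert (res["q_value"] == 1.0).all()

    def test_family_sizes(self, default_sites):
        assert len(motif_enrichment(default_sites, 2, "literal")) == 16
        assert len(motif_enrichment(default_sites, 3, "literal")) == 64
        assert len(motif_enrichment(default_sites, 2, "collapsed")) == 4
        assert len(motif_enrichment(default_sites, 3, "collapsed")) == 4

    def test_per_position_mode(self):
        seeds = ["GCGCGCGCGCGC"] * 3
        res = motif_enrichment(cohort(seeds, ["ATATATATATAT"] * 3), 2, "collapsed", per_position=True)
        assert len(res) == 4 * 11
        ss = res[(res["motif"] == "SS")]
        assert (ss["freq_positive"] == 1.0).all()

    def test_bad_k_and_alphabet(self):
        sites = cohort(["GCGCGCGCGCGC"], ["ATATATATATAT"])
        with pytest.raises(ConfigError):
            motif_enrichment(sites, 4, "literal")
        with pytest.raises(ConfigError):
            motif_enrichment(sites, 2, "bogus")

    def test_gc_motifs_enriched_in_default_cohort(self, default_sites):
        """GC-dependent labeling makes strong-base motifs (SS, SNS) the most
        enriched patterns in the positive cohort."""
        for k in (2, 3):
            res = motif_enrichment(default_sites, k, "collapsed").set_index("motif")
            top = res["enrichment_ratio"].idxmax()
            assert top == ("SS" if k == 2 else "SNS")
            assert res.loc[top, "enrichment_ratio"] > 1


class TestPAM:
    def test_uniform_equal_counts(self):
        seeds_p = ["GCGCGCGCGCGC"] * 4
        sites = []
        for pam in ("AGG", "CGG", "GGG", "TGG"):
            sites += [make_site(PREFIX + s, pam=pam, label="positive") for s in seeds_p]
            sites += [make_site(PREFIX + s, pam=pam, label="negative") for s in seeds_p]
        freq, p = pam_distribution(sites)
        assert p == pytest.approx(1.0)
        assert np.allclose(freq.to_numpy(), 0.25)

    def test_disjoint_pams(self):
        sites = [make_site(PREFIX + "GCGCGCGCGCGC", pam="GGG", label="positive") for _ in range(30)]
        sites += [make_site(PREFIX + "GCGCGCGCGCGC", pam="TGG", label="negative") for _ in range(30)]
        _, p = pam_distribution(sites)
        assert p < 1e-6

    def test_chi_square_by_hand(self):
        counts = {"AGG": (10, 40), "CGG": (20, 30), "GGG": (30, 20), "TGG": (40, 10)}
        sites = []
        for pam, (np_, nn) in counts.items():
            sites += [make_site(PREFIX + "GCGCGCGCGCGC", pam=pam, label="positive")] * np_
            sites += [make_site(PREFIX + "GCGCGCGCGCGC", pam=pam, label="negative")] * nn
        _, p = pam_distribution(sites)
        # first-principles chi-square on the 2x4 table
        obs = np.array([[10, 20, 30, 40], [40, 30, 20, 10]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert p == pytest.approx(float(sps.chi2.sf(chi2, df=3)), rel=1e-9)

    def test_frequencies_sum_to_one(self, default_sites):
        freq, _ = pam_distribution(default_sites)
        assert np.allclose(freq.sum(axis=1), 1.0)
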