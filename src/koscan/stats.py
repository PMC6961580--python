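"""Comparative statistics between positive and negative target-site cohorts.

A "positive" site is a tested gRNA site that yielded detectable mutations in
injected founder embryos; a "negative" site did not. This module quantifies
how sequence features of the 12-nt seed region differ between the two
cohorts: seed GC content (cohort means and a two-sample test), success rate
stratified by seed GC count (with a trend test), per-position base
composition, PAM trinucleotide usage, and k-mer motif enrichment.

Test choices (configurable in principle, fixed here as sane nonparametric
defaults for count data): Mann-Whitney U (two-sided) for the GC comparison
and per-site motif fractions, Fisher's exact test for every 2x2 cell,
chi-square for the 2x4 PAM homogeneity table, Cochran-Armitage for trend,
and Benjamini-Hochberg within each test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InsufficientDataError
from .sequence import PROTOSPACER_LEN, SEED_LEN, TargetSite, match_motif

#: Seed GC count strictly above 50% of 12 nt starts at 7 (6/12 is exactly 50%).
GC_OVER_HALF_MIN_COUNT = 7

#: Positions whose base composition is confounded by guide design rather
#: than biology: T7 transcription forces G at the 5' end of the protospacer.
T7_BIASED_POSITIONS = (-19, -20)

PAM_TRINUCLEOTIDES = ("AGG", "CGG", "GGG", "TGG")


def _split_cohorts(sites: list[TargetSite]) -> tuple[list[TargetSite], list[TargetSite]]:
    pos = [s for s in sites if s.label == "positive"]
    neg = [s for s in sites if s.label == "negative"]
    if not pos or not neg:
        raise InsufficientDataError(
            f"need both cohorts; got {len(pos)} positive, {len(neg)} negative"
        )
    return pos, neg


def _seed_gc_counts(sites: list[TargetSite]) -> np.ndarray:
    return np.array([s.seed.count("G") + s.seed.count("C") for s in sites])


def compare_gc(sites: list[TargetSite]) -> dict[str, float]:
    """Seed-GC% cohort means and a two-sided Mann-Whitney U test.

    Returns a dict with the mean seed GC% of each cohort and of all tested
    sites, the mean full-protospacer GC% over all tested sites, and the U
    statistic and two-sided p-value comparing per-site seed GC% between
    cohorts.
    """
    pos, neg = _split_cohorts(sites)
    gc_pos = _seed_gc_counts(pos) * 100.0 / SEED_LEN
    gc_neg = _seed_gc_counts(neg) * 100.0 / SEED_LEN
    tested = pos + neg
    full_gc = np.array(
        [
            (s.protospacer.count("G") + s.protospacer.count("C"))
            * 100.0
            / PROTOSPACER_LEN
            for s in tested
        ]
    )
    if np.ptp(np.concatenate([gc_pos, gc_neg])) == 0:
        stat, p = float(len(gc_pos)) * len(gc_neg) / 2.0, 1.0
    else:
        res = sps.mannwhitneyu(gc_pos, gc_neg, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_gc_seed_positive": float(gc_pos.mean()),
        "mean_gc_seed_negative": float(gc_neg.mean()),
        "mean_gc_seed_all": float(np.concatenate([gc_pos, gc_neg]).mean()),
        "mean_gc_full_all": float(full_gc.mean()),
        "gc_test_stat": stat,
        "gc_test_p": p,
    }


def gc_bin_table(sites: list[TargetSite]) -> pd.DataFrame:
    """Positive/negative counts per seed GC count (13 bins, 0..12).

    ``positive_rate`` is NaN in empty bins. Marginal sums equal the cohort
    sizes by construction.
    """
    pos, neg = _split_cohorts(sites)
    bins = np.arange(SEED_LEN + 1)
    n_pos = np.bincount(_seed_gc_counts(pos), minlength=SEED_LEN + 1)
    n_neg = np.bincount(_seed_gc_counts(neg), minlength=SEED_LEN + 1)
    total = n_pos + n_neg
    with np.errstate(invalid="ignore"):
        rate = np.where(total > 0, n_pos / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"n_positive": n_pos, "n_negative": n_neg, "positive_rate": rate},
        index=pd.Index(bins, name="gc_count"),
    )


def cochran_armitage(n_positive: np.ndarray, n_total: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage test for linear trend in binned proportions.

    Z-statistic and two-sided normal p-value; returns (0.0, 1.0) when the
    variance degenerates (all bins in one stratum, or a pooled rate of 0/1).
    """
    keep = n_total > 0
    n_positive, n_total, scores = n_positive[keep], n_total[keep], scores[keep]
    big_n = n_total.sum()
    p_bar = n_positive.sum() / big_n
    num = float(np.sum(scores * (n_positive - n_total * p_bar)))
    var = p_bar * (1 - p_bar) * (
        np.sum(n_total * scores**2) - np.sum(n_total * scores) ** 2 / big_n
    )
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def gc_trend(
    bin_table: pd.DataFrame, min_bin_total: int = 0
) -> dict[str, float]:
    """Success-rate trend across seed GC-count bins.

    Two complementary views: an unweighted Pearson correlation of the
    per-bin positive rate against GC count over populated bins (optionally
    dropping bins with fewer than ``min_bin_total`` sites), and a
    count-weighted Cochran-Armitage trend test. Their signs agree on
    monotone data.
    """
    total = bin_table["n_positive"] + bin_table["n_negative"]
    populated = bin_table[total >= max(min_bin_total, 1)]
    if len(populated) < 3:
        raise InsufficientDataError("need at least 3 populated GC bins for a trend")
    rate = populated["positive_rate"].to_numpy()
    x = populated.index.to_numpy(dtype=float)
    if np.ptp(rate) == 0:
        pearson_r, pearson_p = 0.0, 1.0  # flat curve: no trend by definition
    else:
        r = sps.pearsonr(x, rate)
        pearson_r, pearson_p = float(r.statistic), float(r.pvalue)
    z, p = cochran_armitage(
        bin_table["n_positive"].to_numpy(),
        (bin_table["n_positive"] + bin_table["n_negative"]).to_numpy(),
        bin_table.index.to_numpy(dtype=float),
    )
    return {
        "pearson_r": pearson_r,
        "pearson_p": pearson_p,
        "trend_stat": z,
        "trend_p": p,
    }


def _fisher_family(rows: list[dict], alpha: float = 0.05) -> pd.DataFrame:
    """Attach BH q-values to a family of test rows (in place on a copy)."""
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def positional_composition(
    sites: list[TargetSite], exclude_t7_positions: bool = False
) -> pd.DataFrame:
    """Per-position, per-base cohort composition with Fisher tests.

    One row per (position, base) over positions -1 (PAM-proximal) .. -20 and
    bases ACGT: the fraction of each cohort carrying that base there, a
    two-sided Fisher exact p for the 2x2 (base vs not-base, positive vs
    negative) table, and a BH q-value over the whole 80-cell family.
    Positions -19/-20 are flagged ``t7_biased`` (their G excess reflects the
    T7 transcription requirement, not targeting efficiency) and can be
    excluded from the family entirely.
    """
    pos, neg = _split_cohorts(sites)
    n_pos, n_neg = len(pos), len(neg)
    rows = []
    for position in range(-1, -PROTOSPACER_LEN - 1, -1):
        if exclude_t7_positions and position in T7_BIASED_POSITIONS:
            continue
        idx = PROTOSPACER_LEN + position  # -1 -> index 19
        bases_pos = [s.protospacer[idx] for s in pos]
        bases_neg = [s.protospacer[idx] for s in neg]
        for base in "ACGT":
            k_pos = bases_pos.count(base)
            k_neg = bases_neg.count(base)
            _, p = sps.fisher_exact(
                [[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]], alternative="two-sided"
            )
            rows.append(
                {
                    "position": position,
                    "base": base,
                    "n_positive": k_pos,
                    "n_negative": k_neg,
                    "frac_positive": k_pos / n_pos,
                    "frac_negative": k_neg / n_neg,
                    "p_value": float(p),
                    "t7_biased": position in T7_BIASED_POSITIONS,
                }
            )
    return _fisher_family(rows)


def _collapsed_motifs(k: int) -> list[str]:
    if k == 2:
        return ["".join(m) for m in product("SW", repeat=2)]
    return [a + "N" + b for a, b in product("SW", repeat=2)]


def motif_enrichment(
    sites: list[TargetSite],
    k: int,
    motif_alphabet: str = "literal",
    per_position: bool = False,
) -> pd.DataFrame:
    """Seed k-mer motif enrichment between positive and negative cohorts.

    With the ``literal`` alphabet the family is all 16 dinucleotides or 64
    trinucleotides; with ``collapsed`` it is the strong/weak patterns
    (SS/SW/WS/WW for k=2, SNS/SNW/WNS/WNW for k=3), which fold the GC signal
    into four degrees of freedom.

    Aggregated mode (default) compares the per-site fraction of seed
    windows matching each motif with a two-sided Mann-Whitney U test;
    ``per_position`` mode tests presence of the motif at each individual
    window position with Fisher's exact test. BH correction is applied
    within the emitted family either way. ``enrichment_ratio`` is NaN when
    the negative-cohort frequency is 0.
    """
    if k not in (2, 3):
        raise ConfigError(f"motif enrichment supports k in {{2, 3}}, got {k}")
    if motif_alphabet == "literal":
        motifs = ["".join(m) for m in product("ACGT", repeat=k)]
    elif motif_alphabet == "collapsed":
        motifs = _collapsed_motifs(k)
    else:
        raise ConfigError(f"unknown motif alphabet {motif_alphabet!r}")

    pos, neg = _split_cohorts(sites)
    n_windows = SEED_LEN - k + 1
    hits_pos = {m: [match_motif(s.seed, m) for s in pos] for m in motifs}
    hits_neg = {m: [match_motif(s.seed, m) for s in neg] for m in motifs}

    rows = []
    if per_position:
        for m in motifs:
            for w in range(n_windows):
                k_pos = sum(w in h for h in hits_pos[m])
                k_neg = sum(w in h for h in hits_neg[m])
                _, p = sps.fisher_exact(
                    [[k_pos, len(pos) - k_pos], [k_neg, len(neg) - k_neg]],
                    alternative="two-sided",
                )
                f_pos, f_neg = k_pos / len(pos), k_neg / len(neg)
                rows.append(
                    {
                        "motif": m,
                        "k": k,
                        "position": w,
                        "freq_positive": f_pos,
                        "freq_negative": f_neg,
                        "enrichment_ratio": f_pos / f_neg if f_neg > 0 else np.nan,
                        "p_value": float(p),
                    }
                )
    else:
        for m in motifs:
            frac_pos = np.array([len(h) / n_windows for h in hits_pos[m]])
            frac_neg = np.array([len(h) / n_windows for h in hits_neg[m]])
            if np.ptp(np.concatenate([frac_pos, frac_neg])) == 0:
                p = 1.0
            else:
                p = float(
                    sps.mannwhitneyu(frac_pos, frac_neg, alternative="two-sided").pvalue
                )
            f_pos, f_neg = float(frac_pos.mean()), float(frac_neg.mean())
            rows.append(
                {
                    "motif": m,
                    "k": k,
                    "freq_positive": f_pos,
                    "freq_negative": f_neg,
                    "enrichment_ratio": f_pos / f_neg if f_neg > 0 else np.nan,
                    "p_value": p,
                }
            )
    return _fisher_family(rows)


def pam_distribution(sites: list[TargetSite]) -> tuple[pd.DataFrame, float]:
    """Per-cohort frequency of the four NGG PAMs with a homogeneity test.

    Returns (frequency table, chi-square p-value for the 2x4 table).
    Columns with zero total are dropped from the test (their expected counts
    would be zero).
    """
    pos, neg = _split_cohorts(sites)
    counts = pd.DataFrame(
        {
            "positive": [sum(s.pam == t for s in pos) for t in PAM_TRINUCLEOTIDES],
            "negative": [sum(s.pam == t for s in neg) for t in PAM_TRINUCLEOTIDES],
        },
        index=pd.Index(PAM_TRINUCLEOTIDES, name="pam"),
    ).T
    freq = counts.div(counts.sum(axis=1), axis=0)
    table = counts.loc[:, counts.sum(axis=0) > 0].to_numpy()
    if table.shape[1] < 2:
        p = 1.0
    else:
        p = float(sps.chi2_contingency(table).pvalue)
    return freq, p


@dataclass
class CohortReport:
    """Everything the positive-vs-negative comparison produces, in one object."""

    mean_gc_seed_positive: float
    mean_gc_seed_negative: float
    mean_gc_seed_all: float
    mean_gc_full_all: float
    gc_test_stat: float
    gc_test_p: float
    frac_gc_over_half_positive: float
    frac_gc_over_half_negative: float
    pearson_r: float
    pearson_p: float
    trend_stat: float
    trend_p: float
    pam_p: float
    n_positive: int
    n_negative: int
    bin_table: pd.DataFrame = field(repr=False)
    positional_composition: pd.DataFrame = field(repr=False)
    motif_enrichment_2nt: pd.DataFrame = field(repr=False)
    motif_enrichment_3nt: pd.DataFrame = field(repr=False)
    pam_distribution: pd.DataFrame = field(repr=False)

    def scalars(self) -> dict[str, float | int]:
        """The scalar summary fields, JSON-ready."""
        return {
            k: getattr(self, k)
            for k in (
                "n_positive",
                "n_negative",
                "mean_gc_seed_positive",
                "mean_gc_seed_negative",
                "mean_gc_seed_all",
                "mean_gc_full_all",
                "gc_test_stat",
                "gc_test_p",
                "frac_gc_over_half_positive",
                "frac_gc_over_half_negative",
                "pearson_r",
                "pearson_p",
                "trend_stat",
                "trend_p",
                "pam_p",
            )
        }


def build_cohort_report(
    sites: list[TargetSite],
    motif_alphabet: str = "collapsed",
    exclude_t7_positions: bool = False,
    min_bin_total: int = 0,
) -> CohortReport:
    """Run the full positive-vs-negative feature comparison.

    ``frac_gc_over_half_*`` is the share of each cohort whose seed GC count
    is at least 7 of 12 — strictly more than 50% GC (6/12 is exactly half).
    """
    gc = compare_gc(sites)
    bins = gc_bin_table(sites)
    trend = gc_trend(bins, min_bin_total=min_bin_total)
    comp = positional_composition(sites, exclude_t7_positions=exclude_t7_positions)
    pam_freq, pam_p = pam_distribution(sites)
    pos, neg = _split_cohorts(sites)
    gc_pos = _seed_gc_counts(pos)
    gc_neg = _seed_gc_counts(neg)
    return CohortReport(
        **gc,
        frac_gc_over_half_positive=float((gc_pos >= GC_OVER_HALF_MIN_COUNT).mean()),
        frac_gc_over_half_negative=float((gc_neg >= GC_OVER_HALF_MIN_COUNT).mean()),
        **trend,
        pam_p=pam_p,
        n_positive=len(pos),
        n_negative=len(neg),
        bin_table=bins,
        positional_composition=comp,
        motif_enrichment_2nt=motif_enrichment(sites, 2, motif_alphabet),
        motif_enrichment_3nt=motif_enrichment(sites, 3, motif_alphabet),
        pam_distribution=pam_freq,
    )
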