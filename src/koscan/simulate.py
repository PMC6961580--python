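"""Synthetic knockout-campaign data with the statistical structure the
analysis pipeline assumes.

The generator stands in for the two supplementary tables a real campaign
would provide: a labeled gRNA target-site table and a germline allele
table. Its defaults encode the campaign-scale stated world:

* ~1333 genes with a shifted-geometric number of tested guides per gene
  averaging 2277/1333, so a default campaign tests about 2277 guides;
* protospacers drawn with per-base GC probability 0.509 (the observed
  all-sites seed GC fraction) and one forced leading G for T7 in vitro
  transcription, which puts the expected full-protospacer GC near 53%;
* a logistic success model on the centered seed GC count,
  ``P(positive) = expit(b0 + b1 * (gc_count - 6))``, centering at 6 so the
  intercept is the log-odds of success at exactly 50% seed GC. The slope
  default (0.1588) is solved so the expected seed-GC% gap between cohorts
  is 3.9 points (52.9% positive vs 49.0% negative), and the intercept is
  solved numerically so the marginal positive rate matches 1086/2277;
* a deletion/insertion/delins lesion mixture of (0.614, 0.111, 0.275) with
  shifted-geometric sizes whose means are 10.9, 6.4 and (del 9.0, ins 10.3)
  bp respectively, plus a small probability (24/954) of a two-gRNA "big
  indel" deletion exceeding 200 bp. Delins lesions are drawn in canonical
  form — the inserted segment differs from the deleted segment at both
  boundary bases — so the recorded truth is always the minimal
  single-locus parse the classifier can identify;
* germline transmission, F2 advancement and phenotype-screen probabilities
  of 636/1029, 703/1039 and 47/701 per gene/allele.

The logistic link and the geometric size family are modelling devices of
this package (maximum-entropy choices given that only rates and means are
stated), not mechanistic claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import binom

from .campaign import CampaignCounts
from .errors import ConfigError, SimulationError
from .sequence import SEED_LEN

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the campaign simulator. Defaults are the stated world."""

    n_genes: int = 1333
    sites_per_gene_mean: float = 2277 / 1333
    #: per-base probabilities (A, C, G, T) for protospacer generation;
    #: C+G = 0.509 reproduces the observed all-sites seed GC of 50.9%
    base_composition: tuple[float, float, float, float] = (
        0.2455,
        0.2545,
        0.2545,
        0.2455,
    )
    #: leading bases forced for T7 in vitro transcription: "GG", "G" or "none"
    t7_mode: str = "G"
    logistic_slope: float = 0.1588
    #: None means "solve for target_positive_rate given the slope"
    logistic_intercept: float | None = None
    target_positive_rate: float = 1086 / 2277
    germline_prob: float = 636 / 1029
    alleles_per_germline_gene_mean: float = 1039 / 636
    f2_prob: float = 703 / 1039
    phenotype_prob: float = 47 / 701
    lesion_mixture: tuple[float, float, float] = (0.614, 0.111, 0.275)
    del_size_mean: float = 10.9
    ins_size_mean: float = 6.4
    delins_del_size_mean: float = 9.0
    delins_ins_size_mean: float = 10.3
    big_indel_prob: float = 24 / 954
    big_indel_threshold: int = 200
    #: big-indel size = threshold + shifted geometric with this mean
    big_indel_excess_mean: float = 100.0
    context_len: int = 600
    rng_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.lesion_mixture) - 1.0) > 1e-9:
            raise ConfigError("lesion mixture probabilities must sum to 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ConfigError("base composition must sum to 1")
        for name in (
            "del_size_mean",
            "ins_size_mean",
            "delins_del_size_mean",
            "delins_ins_size_mean",
            "sites_per_gene_mean",
            "alleles_per_germline_gene_mean",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1 (shifted-geometric mean)")
        for name in (
            "target_positive_rate",
            "germline_prob",
            "f2_prob",
            "phenotype_prob",
            "big_indel_prob",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be a probability")
        if self.t7_mode not in ("GG", "G", "none"):
            raise ConfigError(f"t7_mode must be GG, G or none, got {self.t7_mode!r}")

    @property
    def gc_prob(self) -> float:
        return self.base_composition[1] + self.base_composition[2]


def calibrate_intercept(
    slope: float, target_rate: float, gc_prob: float = 0.5
) -> float:
    """Intercept b0 such that the marginal positive rate hits ``target_rate``.

    The seed GC count of a random protospacer is Binomial(12, gc_prob), so
    the marginal rate is an expectation over that distribution; solved by
    root finding.
    """
    g = np.arange(SEED_LEN + 1)
    w = binom.pmf(g, SEED_LEN, gc_prob)

    def marginal(b0: float) -> float:
        return float(np.sum(w * expit(b0 + slope * (g - 6)))) - target_rate

    return float(brentq(marginal, -20, 20, xtol=1e-12))


def _shifted_geometric(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Positive-integer sizes with the given mean (support >= 1 bp)."""
    if mean <= 1:
        return np.ones(size, dtype=int)
    return rng.geometric(1.0 / mean, size=size)


def _random_sequences(
    rng: np.random.Generator, n: int, length: int, composition
) -> np.ndarray:
    idx = rng.choice(4, size=(n, length), p=list(composition))
    return BASES[idx]


def simulate_sites(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a labeled target-site table (one row per tested gRNA).

    Columns follow the site-table schema: site_id, gene_id, contig, start,
    end, strand, protospacer, pam, t7_ready, label. Reproducible
    byte-for-byte for a given config (including its seed).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    sites_per_gene = _shifted_geometric(
        rng, config.sites_per_gene_mean, config.n_genes
    )
    n_sites = int(sites_per_gene.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), sites_per_gene)

    proto = _random_sequences(rng, n_sites, 20, config.base_composition)
    if config.t7_mode == "GG":
        proto[:, :2] = "G"
    elif config.t7_mode == "G":
        proto[:, 0] = "G"
    pam_n = _random_sequences(rng, n_sites, 1, config.base_composition)

    seed_gc = np.isin(proto[:, -SEED_LEN:], ["G", "C"]).sum(axis=1)
    b0 = (
        config.logistic_intercept
        if config.logistic_intercept is not None
        else calibrate_intercept(
            config.logistic_slope, config.target_positive_rate, config.gc_prob
        )
    )
    p_success = expit(b0 + config.logistic_slope * (seed_gc - 6))
    positive = rng.random(n_sites) < p_success

    strand = np.where(rng.random(n_sites) < 0.5, "+", "-")
    # arbitrary non-overlapping layout on one synthetic contig
    start = 100 + np.arange(n_sites) * 100
    within = np.concatenate([np.arange(k) for k in sites_per_gene])
    df = pd.DataFrame(
        {
            "site_id": [
                f"g{gi + 1:04d}_s{wi + 1}" for gi, wi in zip(gene_idx, within)
            ],
            "gene_id": [f"gene{gi + 1:04d}" for gi in gene_idx],
            "contig": "chrSim",
            "start": start,
            "end": start + 20,
            "strand": strand,
            "protospacer": ["".join(row) for row in proto],
            "pam": [n + "GG" for n in pam_n[:, 0]],
            "label": np.where(positive, "positive", "negative"),
        }
    )
    df.insert(8, "t7_ready", df["protospacer"].str.startswith("G"))
    return df


def _draw_lesion(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[str, int, int]:
    """(class, del_len, ins_len) for one allele."""
    if rng.random() < config.big_indel_prob:
        excess = int(_shifted_geometric(rng, config.big_indel_excess_mean, 1)[0])
        return "big_indel", config.big_indel_threshold + excess, 0
    cls = ("deletion", "insertion", "delins")[
        rng.choice(3, p=list(config.lesion_mixture))
    ]
    if cls == "deletion":
        return cls, int(_shifted_geometric(rng, config.del_size_mean, 1)[0]), 0
    if cls == "insertion":
        return cls, 0, int(_shifted_geometric(rng, config.ins_size_mean, 1)[0])
    return (
        cls,
        int(_shifted_geometric(rng, config.delins_del_size_mean, 1)[0]),
        int(_shifted_geometric(rng, config.delins_ins_size_mean, 1)[0]),
    )


def simulate_alleles(
    config: SyntheticConfig | None = None,
    n_alleles: int = 954,
    gene_ids: list[str] | None = None,
    coding: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate an allele table with hidden ground truth.

    Each row carries the (wt_seq, mut_seq) pair the classifier sees plus
    ``true_*`` columns recording the lesion actually applied, for recovery
    tests. The lesion is applied at a cut site in the middle of a random
    wild-type context; a draw that cannot fit the context is retried a
    bounded number of times.
    """
    config = config or SyntheticConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if gene_ids is not None and len(gene_ids) != n_alleles:
        raise ConfigError("gene_ids must have one entry per allele")

    rows = []
    for i in range(n_alleles):
        for _attempt in range(50):
            cls, del_len, ins_len = _draw_lesion(rng, config)
            # keep >= 1 anchor base on each side of the lesion
            if del_len <= config.context_len - 2:
                break
        else:
            raise SimulationError("could not draw a lesion fitting the context")
        wt = "".join(_random_sequences(rng, 1, config.context_len, (0.25,) * 4)[0])
        cut = config.context_len // 2
        bp = min(max(cut - del_len // 2, 1), config.context_len - del_len - 1)
        ins_seq = (
            "".join(_random_sequences(rng, 1, ins_len, (0.25,) * 4)[0])
            if ins_len
            else ""
        )
        if del_len and ins_len:
            # canonical delins: the inserted segment must differ from the
            # deleted segment at both boundary bases, otherwise the drawn
            # lesion is equivalent to a smaller one and the truth label
            # would not be the minimal (identifiable) parse
            del_seg = wt[bp : bp + del_len]
            first = ins_seq[0]
            if ins_len == 1:
                banned = {del_seg[0], del_seg[-1]}
                if first in banned:
                    ins_seq = str(rng.choice(sorted(set("ACGT") - banned)))
            else:
                if first == del_seg[0]:
                    ins_seq = (
                        str(rng.choice(sorted(set("ACGT") - {del_seg[0]})))
                        + ins_seq[1:]
                    )
                if ins_seq[-1] == del_seg[-1]:
                    ins_seq = ins_seq[:-1] + str(
                        rng.choice(sorted(set("ACGT") - {del_seg[-1]}))
                    )
        mut = wt[:bp] + ins_seq + wt[bp + del_len :]
        rows.append(
            {
                "allele_id": f"al{i + 1:05d}",
                "gene_id": gene_ids[i] if gene_ids is not None else f"gene{i + 1:05d}",
                "wt_seq": wt,
                "mut_seq": mut,
                "n_grnas": 2 if cls == "big_indel" else 1,
                "coding": coding,
                "true_class": cls,
                "true_del_len": del_len,
                "true_ins_len": ins_len,
                "true_breakpoint": bp,
            }
        )
    columns = [
        "allele_id",
        "gene_id",
        "wt_seq",
        "mut_seq",
        "n_grnas",
        "coding",
        "true_class",
        "true_del_len",
        "true_ins_len",
        "true_breakpoint",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class SimulatedCampaign:
    sites: pd.DataFrame
    alleles: pd.DataFrame
    counts: CampaignCounts
    config: SyntheticConfig = field(repr=False)


def simulate_campaign(config: SyntheticConfig | None = None) -> SimulatedCampaign:
    """End-to-end coherent campaign: sites, germline alleles and counts.

    Germline alleles are drawn only for genes that have at least one
    positive site; the returned :class:`CampaignCounts` is an independent
    tally of the generated tables, so its invariants hold by construction.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    sites = simulate_sites(config)
    by_gene = sites.groupby("gene_id")["label"].apply(
        lambda s: (s == "positive").any()
    )
    mutated_genes = sorted(by_gene[by_gene].index)

    germline_genes = [
        g for g in mutated_genes if rng.random() < config.germline_prob
    ]
    alleles_per_gene = _shifted_geometric(
        rng, config.alleles_per_germline_gene_mean, len(germline_genes)
    )
    gene_ids = [
        g for g, k in zip(germline_genes, alleles_per_gene) for _ in range(k)
    ]
    alleles = simulate_alleles(
        config, n_alleles=len(gene_ids), gene_ids=gene_ids, rng=rng
    )

    to_f2 = rng.random(len(alleles)) < config.f2_prob
    alleles["f2"] = to_f2
    f2_alleles = alleles[to_f2]
    screened = f2_alleles
    with_phenotype = rng.random(len(screened)) < config.phenotype_prob

    counts = CampaignCounts(
        genes_total=config.n_genes,
        genes_mutated=len(mutated_genes),
        grnas_tested=len(sites),
        grnas_efficient=int((sites["label"] == "positive").sum()),
        genes_germline=len(germline_genes),
        alleles_germline=len(alleles),
        alleles_f2=int(to_f2.sum()),
        genes_f2=f2_alleles["gene_id"].nunique(),
        alleles_screened=len(screened),
        alleles_with_phenotype=int(with_phenotype.sum()),
    )
    return SimulatedCampaign(sites=sites, alleles=alleles, counts=counts, config=config)


def null_config(**overrides) -> SyntheticConfig:
    """A config with no GC effect (slope 0), for type-I-error checks."""
    base = SyntheticConfig(logistic_slope=0.0, **overrides)
    return replace(base)
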