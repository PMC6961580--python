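"""Bookkeeping arithmetic for a chromosome-wide knockout campaign.

Holds the raw integer counts a campaign accumulates (genes attempted and
mutated, guides tested and efficient, germline alleles, phenotype screens)
and derives every reported percentage from them, with one fixed rounding
convention so printed numbers are reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from ._util import round_half_away
from .errors import InconsistentCountsError, UndefinedRatioError


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero to one decimal."""
    if denominator == 0:
        raise UndefinedRatioError("percentage with zero denominator")
    if numerator < 0 or denominator < 0:
        raise UndefinedRatioError("percentage of negative counts")
    return round_half_away(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class CampaignCounts:
    """Raw campaign counts from which all summary rates derive.

    ``genes_germline`` counts genes with at least one germline-transmitted
    allele; ``alleles_screened``/``alleles_with_phenotype`` refer to the
    early-phenotype screen of F2 alleles.
    """

    genes_total: int
    genes_mutated: int
    grnas_tested: int
    grnas_efficient: int
    genes_germline: int
    alleles_germline: int
    alleles_f2: int
    genes_f2: int
    alleles_screened: int
    alleles_with_phenotype: int

    def validate(self) -> None:
        d = asdict(self)
        for name, value in d.items():
            if value < 0:
                raise InconsistentCountsError(f"{name} is negative")
        orderings = [
            ("genes_mutated", "genes_total"),
            ("grnas_efficient", "grnas_tested"),
            ("genes_germline", "genes_mutated"),
            ("genes_f2", "genes_germline"),
            ("alleles_f2", "alleles_germline"),
            ("alleles_with_phenotype", "alleles_screened"),
        ]
        for small, large in orderings:
            if d[small] > d[large]:
                raise InconsistentCountsError(f"{small} > {large}")


def summarize_campaign(counts: CampaignCounts) -> dict[str, float | int]:
    """All derived campaign rates, as a flat JSON-ready dict.

    The germline-gene rate uses mutated genes (not all attempted genes) as
    its denominator: germline transmission is only at stake for genes that
    were mutated in founders in the first place.
    """
    counts.validate()

    def rate(num: int, den: int) -> float:
        return percentage(num, den) if den else float("nan")

    report: dict[str, float | int] = dict(asdict(counts))
    report["mutated_gene_rate"] = rate(counts.genes_mutated, counts.genes_total)
    report["efficient_grna_rate"] = rate(counts.grnas_efficient, counts.grnas_tested)
    report["germline_gene_rate"] = rate(counts.genes_germline, counts.genes_mutated)
    report["f2_advance_rate"] = rate(counts.alleles_f2, counts.alleles_germline)
    report["phenotype_rate"] = rate(counts.alleles_with_phenotype, counts.alleles_screened)
    return report
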