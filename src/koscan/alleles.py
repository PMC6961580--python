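"""Classification of Sanger-confirmed mutant alleles against wild type.

Each allele is modelled as a single contiguous lesion: a deletion, an
insertion, or a combined deletion+insertion (delins) at one breakpoint.
This matches how CRISPR/Cas9 alleles arise — one double-strand break (or one
resected interval between two cuts) repaired by end joining. The diff is a
maximal-common-prefix / maximal-common-suffix anchor: the prefix is
maximised first, so in a repeat run the breakpoint lands deterministically
at the 3' end of the run.

Frame effect is pure length arithmetic: a coding lesion whose net length
change is a multiple of 3 is in-frame, otherwise a frameshift. Premature
stop codons or splice disruption are not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

from ._util import round_half_away
from .errors import InsufficientDataError, MalformedSequenceError

#: Deletions longer than this (bp) are classed as "big indels" — in a
#: two-gRNA design these are the intended large genomic deletions, and they
#: are summarised separately from single-cut indel statistics.
BIG_INDEL_THRESHOLD = 200

LESION_CLASSES = ("none", "deletion", "insertion", "delins", "big_indel")


@dataclass(frozen=True)
class AlleleRecord:
    """One mutant allele with its wild-type reference context."""

    allele_id: str
    gene_id: str
    wt_seq: str
    mut_seq: str
    n_grnas: int = 1
    coding: bool = True


@dataclass
class MutationCall:
    """The lesion explaining one mutant allele.

    Removing ``del_seq`` at ``breakpoint`` from the wild-type sequence and
    inserting ``ins_seq`` there reconstructs the mutant sequence exactly.
    """

    allele_id: str
    gene_id: str
    lesion_class: str
    del_seq: str
    ins_seq: str
    breakpoint: int
    coding: bool = True

    @property
    def del_len(self) -> int:
        return len(self.del_seq)

    @property
    def ins_len(self) -> int:
        return len(self.ins_seq)

    @property
    def net_change(self) -> int:
        return self.ins_len - self.del_len

    @property
    def frame_effect(self) -> str:
        return frame_effect(self)


def _check_dna(seq: str, name: str) -> str:
    s = seq.upper()
    if set(s) - set("ACGT"):
        raise MalformedSequenceError(f"{name} contains non-ACGT characters")
    return s


def diff_allele(record: AlleleRecord, big_indel_threshold: int = BIG_INDEL_THRESHOLD) -> MutationCall:
    """Diff a mutant allele against wild type and classify the lesion.

    The maximal common prefix P of (wt, mut) is taken first, then the
    maximal common suffix S of the remainders subject to
    ``|P| + |S| <= min(|wt|, |mut|)``. This greedy order attains the minimal
    single-locus edit (any feasible (prefix, suffix) split is dominated by
    the maximal ones) and fixes the breakpoint deterministically.
    """
    wt = _check_dna(record.wt_seq, "wt_seq")
    mut = _check_dna(record.mut_seq, "mut_seq")
    limit = min(len(wt), len(mut))

    p = 0
    while p < limit and wt[p] == mut[p]:
        p += 1
    s = 0
    while s < limit - p and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]:
        s += 1

    del_seq = wt[p : len(wt) - s]
    ins_seq = mut[p : len(mut) - s]
    call = MutationCall(
        allele_id=record.allele_id,
        gene_id=record.gene_id,
        lesion_class="none",
        del_seq=del_seq,
        ins_seq=ins_seq,
        breakpoint=p,
        coding=record.coding,
    )
    call.lesion_class = classify(call, big_indel_threshold=big_indel_threshold)
    return call


def classify(call: MutationCall, big_indel_threshold: int = BIG_INDEL_THRESHOLD) -> str:
    """Lesion class from deletion/insertion lengths.

    Deletions longer than ``big_indel_threshold`` are "big indels"
    regardless of any inserted bases.
    """
    if call.del_len == 0 and call.ins_len == 0:
        return "none"
    if call.del_len > big_indel_threshold:
        return "big_indel"
    if call.ins_len == 0:
        return "deletion"
    if call.del_len == 0:
        return "insertion"
    return "delins"


def frame_effect(call: MutationCall) -> str:
    """``in_frame`` / ``frameshift`` for coding lesions, else ``not_applicable``."""
    if not call.coding or call.lesion_class == "none":
        return "not_applicable"
    return "in_frame" if call.net_change % 3 == 0 else "frameshift"


def apply_call(wt_seq: str, call: MutationCall) -> str:
    """Reconstruct the mutant sequence from a call (round-trip check)."""
    p = call.breakpoint
    return wt_seq[:p] + call.ins_seq + wt_seq[p + call.del_len :]


@dataclass
class IndelSummary:
    """Cohort-level indel statistics.

    Big indels (two-gRNA large deletions) are counted, then excluded from
    the class and frame denominators; ``none`` calls are likewise excluded.
    Percentages are rounded half-away-from-zero to one decimal. Size means
    are in bp over the relevant class only (``nan`` for an empty class).
    """

    n_total: int
    n_big_indel: int
    n_deletion: int
    n_insertion: int
    n_delins: int
    n_in_frame: int
    n_frameshift: int
    frac_deletion: float
    frac_insertion: float
    frac_delins: float
    frac_in_frame: float
    frac_frameshift: float
    mean_del_size: float
    mean_ins_size: float
    mean_delins_del_size: float
    mean_delins_ins_size: float


def summarize_alleles(calls: list[MutationCall]) -> IndelSummary:
    """Summarise a cohort of mutation calls.

    The denominator for class and frame fractions is the number of real,
    non-big-indel lesions; frame fractions additionally restrict to coding
    lesions.
    """
    if not calls:
        raise InsufficientDataError("no mutation calls to summarize")

    lesions = [c for c in calls if c.lesion_class != "none"]
    big = [c for c in lesions if c.lesion_class == "big_indel"]
    rest = [c for c in lesions if c.lesion_class != "big_indel"]
    dels = [c for c in rest if c.lesion_class == "deletion"]
    ins = [c for c in rest if c.lesion_class == "insertion"]
    delins = [c for c in rest if c.lesion_class == "delins"]
    coding = [c for c in rest if c.coding]
    in_frame = [c for c in coding if c.net_change % 3 == 0]

    def frac(k: int, n: int) -> float:
        return round_half_away(100.0 * k / n, 1) if n else float("nan")

    def size_mean(values: list[int]) -> float:
        return mean(values) if values else float("nan")

    n_rest = len(rest)
    n_coding = len(coding)
    return IndelSummary(
        n_total=len(calls),
        n_big_indel=len(big),
        n_deletion=len(dels),
        n_insertion=len(ins),
        n_delins=len(delins),
        n_in_frame=len(in_frame),
        n_frameshift=n_coding - len(in_frame),
        frac_deletion=frac(len(dels), n_rest),
        frac_insertion=frac(len(ins), n_rest),
        frac_delins=frac(len(delins), n_rest),
        frac_in_frame=frac(len(in_frame), n_coding),
        frac_frameshift=frac(n_coding - len(in_frame), n_coding),
        mean_del_size=size_mean([c.del_len for c in dels]),
        mean_ins_size=size_mean([c.ins_len for c in ins]),
        mean_delins_del_size=size_mean([c.del_len for c in delins]),
        mean_delins_ins_size=size_mean([c.ins_len for c in delins]),
    )
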