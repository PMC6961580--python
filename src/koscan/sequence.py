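"""DNA sequence primitives for SpCas9 target-site analysis.

A target site is a 20-nt protospacer immediately followed (5'->3' on the
targeted strand) by an NGG PAM. Coordinates are always reported 0-based,
half-open, on the forward strand of the reference, so sites can be written
directly to BED. Minus-strand sites carry their protospacer and PAM as
5'->3' strings on the targeted (minus) strand.

The PAM-proximal 12 nt of the protospacer form the *seed* region, the part
of the guide most critical for target recognition; GC statistics and motif
profiles are computed over the seed unless stated otherwise. The PAM itself
is never included in any GC computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    MalformedMotifError,
    MalformedSequenceError,
    UndefinedInputError,
    UnsupportedKError,
)

PROTOSPACER_LEN = 20
PAM_LEN = 3
SEED_LEN = 12

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_dna(sequence: str, *, strict_acgt: bool = False) -> str:
    seq = sequence.upper()
    allowed = set("ACGT") if strict_acgt else set(IUPAC)
    bad = set(seq) - allowed
    if bad:
        raise MalformedSequenceError(
            f"non-{'ACGT' if strict_acgt else 'IUPAC'} characters in sequence: "
            f"{sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class TargetSite:
    """One candidate or tested gRNA target site.

    ``start``/``end`` delimit the 20-nt protospacer on the forward strand of
    ``contig`` (0-based, half-open). ``protospacer`` and ``pam`` are written
    5'->3' on the targeted strand, so for minus-strand sites they are the
    reverse complement of the forward-strand reference slice.
    """

    site_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    label: str = "untested"

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if len(self.pam) != PAM_LEN or not self.pam.endswith("GG"):
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.end - self.start != PROTOSPACER_LEN or self.start < 0:
            raise ValueError(f"bad coordinates [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.label not in ("positive", "negative", "untested"):
            raise ValueError(f"unknown label {self.label!r}")
        _validate_dna(self.protospacer, strict_acgt=True)
        _validate_dna(self.pam, strict_acgt=True)

    @property
    def t7_ready(self) -> bool:
        """True when the protospacer starts with at least one G.

        T7 RNA polymerase initiates transcription efficiently only on one or
        two leading G nucleotides, so sites without a leading G need a
        mismatched 5' G appended to the guide.
        """
        return self.protospacer.startswith("G")

    @property
    def seed(self) -> str:
        """The 12 PAM-proximal protospacer nucleotides."""
        return self.protospacer[-SEED_LEN:]


@dataclass
class SeedProfile:
    """Positional and compositional features of one protospacer's seed.

    ``positional_base`` maps positions -1 (adjacent to the PAM) through -20
    (5'-distal) to the base at that position of the full protospacer.
    ``kmer_counts`` maps ``(k, motif, window_start)`` to occurrence counts
    within the seed, window_start being the 0-based offset into the seed.
    """

    seed: str
    gc_count: int
    gc_percent: float
    positional_base: dict[int, str] = field(default_factory=dict)
    kmer_counts: dict[tuple[int, str, int], int] = field(default_factory=dict)


def gc_content(sequence: str) -> tuple[int, float]:
    """GC count and percentage of a DNA string.

    Returns ``(count, 100 * count / len)``. Callers computing site GC must
    pass the protospacer (or seed) only — never the PAM.
    """
    if not sequence:
        raise UndefinedInputError("gc_content of empty sequence is undefined")
    seq = _validate_dna(sequence)
    count = seq.count("G") + seq.count("C")
    return count, 100.0 * count / len(seq)


def t7_compatibility(protospacer: str) -> str:
    """Classify a 20-mer's T7 in-vitro-transcription readiness.

    ``"GG"`` when the first two bases are both G (ideal for T7), ``"G"``
    when only the first base is G, ``"none"`` otherwise.
    """
    if protospacer[:2] == "GG":
        return "GG"
    if protospacer[:1] == "G":
        return "G"
    return "none"


def match_motif(sequence: str, motif: str) -> list[int]:
    """All (overlapping) 0-based start positions where `motif` matches.

    The motif is an IUPAC string; e.g. ``"SS"`` matches any strong-strong
    dinucleotide and ``"SNS"`` any strong/any/strong trinucleotide.
    """
    seq = _validate_dna(sequence)
    motif = motif.upper()
    try:
        sets = [IUPAC[c] for c in motif]
    except KeyError as exc:
        raise MalformedMotifError(f"invalid IUPAC code {exc.args[0]!r} in motif") from exc
    k = len(motif)
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + j] in sets[j] for j in range(k))
    ]


def kmer_profile(seed: str, k: int) -> dict[tuple[str, int], int]:
    """Positional k-mer occurrences over a 12-nt seed, overlapping windows.

    Returns a sparse map ``(motif, window_start) -> count``; for a single
    seed each of the ``12 - k + 1`` windows contributes exactly one count.
    """
    if k not in (1, 2, 3):
        raise UnsupportedKError(f"k must be 1, 2 or 3, got {k}")
    seq = _validate_dna(seed, strict_acgt=True)
    counts: dict[tuple[str, int], int] = {}
    for i in range(len(seq) - k + 1):
        key = (seq[i : i + k], i)
        counts[key] = counts.get(key, 0) + 1
    return counts


def extract_seed(site: TargetSite) -> SeedProfile:
    """Seed features of one target site.

    The seed is the last 12 protospacer bases (positions -1..-12 relative to
    the PAM). GC is computed over the seed only; positional bases cover the
    full protospacer (-1..-20).
    """
    seed = site.seed
    count, percent = gc_content(seed)
    positional = {
        -(j + 1): site.protospacer[PROTOSPACER_LEN - 1 - j]
        for j in range(PROTOSPACER_LEN)
    }
    kmers = {
        (k, motif, pos): n
        for k in (1, 2, 3)
        for (motif, pos), n in kmer_profile(seed, k).items()
    }
    return SeedProfile(
        seed=seed,
        gc_count=count,
        gc_percent=percent,
        positional_base=positional,
        kmer_counts=kmers,
    )


def scan_target_sites(
    sequence: str,
    contig_name: str = "seq",
    require_t7: bool = False,
    gene_id: str = "",
) -> list[TargetSite]:
    """Find every SpCas9 target site (NGG PAM) on both strands.

    Windows containing N or other ambiguity codes are skipped rather than
    rejected, since real assemblies contain gaps; characters outside the
    IUPAC alphabet raise :class:`MalformedSequenceError`. With ``require_t7``
    only sites whose protospacer begins with G (transcribable from a T7
    promoter without a mismatched 5' base) are returned. Output is sorted by
    (start, strand); sequences shorter than 23 nt yield an empty list.
    """
    seq = _validate_dna(sequence)
    n = len(seq)
    sites: list[TargetSite] = []
    if n < PROTOSPACER_LEN + PAM_LEN:
        return sites

    def _is_acgt(fragment: str) -> bool:
        return all(c in "ACGT" for c in fragment)

    # forward strand: protospacer [i, i+20), PAM [i+20, i+23) reading NGG
    for i in range(n - PROTOSPACER_LEN - PAM_LEN + 1):
        proto = seq[i : i + PROTOSPACER_LEN]
        pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + PAM_LEN]
        if pam[1:] == "GG" and _is_acgt(proto) and _is_acgt(pam):
            sites.append((i, "+", proto, pam))
    # minus strand: protospacer occupies forward [i, i+20), PAM forward
    # [i-3, i); NGG on the minus strand shows as CCN on the forward strand
    for i in range(PAM_LEN, n - PROTOSPACER_LEN + 1):
        fwd_proto = seq[i : i + PROTOSPACER_LEN]
        fwd_pam = seq[i - PAM_LEN : i]
        if fwd_pam[:2] == "CC" and _is_acgt(fwd_proto) and _is_acgt(fwd_pam):
            sites.append((i, "-", revcomp(fwd_proto), revcomp(fwd_pam)))

    sites.sort(key=lambda t: (t[0], t[1]))
    out = []
    for idx, (start, strand, proto, pam) in enumerate(sites):
        if require_t7 and not proto.startswith("G"):
            continue
        out.append(
            TargetSite(
                site_id=f"{contig_name}:{start}-{start + PROTOSPACER_LEN}:{strand}",
                gene_id=gene_id,
                contig=contig_name,
                start=start,
                end=start + PROTOSPACER_LEN,
                strand=strand,
                protospacer=proto,
                pam=pam,
            )
        )
    return out
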