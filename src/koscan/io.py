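"""Readers and writers for the pipeline's on-disk formats.

Tables are tab-delimited with a required header, UTF-8, no quoting (TSV is
used precisely so sequence fields never need quoting). Scanned sites can be
written as BED6 (0-based half-open, name=site_id, score=seed GC count).
Reports are JSON with a ``schema_version`` field and embed the parameter
set that produced them, so every output is self-describing.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .alleles import AlleleRecord, MutationCall
from .errors import SchemaError
from .sequence import TargetSite

SCHEMA_VERSION = "1.0"

SITE_COLUMNS = [
    "site_id",
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "protospacer",
    "pam",
    "t7_ready",
    "label",
]

ALLELE_COLUMNS = ["allele_id", "gene_id", "wt_seq", "mut_seq", "n_grnas", "coding"]

CALL_COLUMNS = [
    "allele_id",
    "gene_id",
    "lesion_class",
    "del_len",
    "ins_len",
    "net_change",
    "del_seq",
    "ins_seq",
    "breakpoint",
    "frame_effect",
]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} has unknown columns (ignored): {extra}", stacklevel=3)


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


def read_fasta(path: str) -> dict[str, str]:
    """Sequences by record id; lowercase is uppercased, U mapped to T."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            warnings.warn(f"record {rec.id}: U bases mapped to T", stacklevel=2)
            seq = seq.replace("U", "T")
        out[rec.id] = seq
    return out


def read_site_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, SITE_COLUMNS, f"site table {path!r}")
    return df[SITE_COLUMNS].astype({"t7_ready": bool})


def write_site_table(df: pd.DataFrame, path: str) -> None:
    _check_columns(df, SITE_COLUMNS, "site table")
    _atomic_write(path, df[SITE_COLUMNS].to_csv(sep="\t", index=False))


def sites_from_frame(df: pd.DataFrame) -> list[TargetSite]:
    """Validated TargetSite objects; schema violations name the row."""
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sites.append(
                TargetSite(
                    site_id=str(row.site_id),
                    gene_id=str(row.gene_id),
                    contig=str(row.contig),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    protospacer=str(row.protospacer),
                    pam=str(row.pam),
                    label=str(row.label),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"site table row {i + 2}: {exc}") from exc
    return sites


def frame_from_sites(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = [
        {
            "site_id": s.site_id,
            "gene_id": s.gene_id,
            "contig": s.contig,
            "start": s.start,
            "end": s.end,
            "strand": s.strand,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "t7_ready": s.t7_ready,
            "label": s.label,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def read_allele_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ALLELE_COLUMNS, f"allele table {path!r}")
    return df


def write_allele_table(df: pd.DataFrame, path: str) -> None:
    _check_columns(df, ALLELE_COLUMNS, "allele table")
    cols = [c for c in df.columns]  # keep truth columns if present
    _atomic_write(path, df[cols].to_csv(sep="\t", index=False))


def alleles_from_frame(df: pd.DataFrame) -> list[AlleleRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                AlleleRecord(
                    allele_id=str(row.allele_id),
                    gene_id=str(row.gene_id),
                    wt_seq=str(row.wt_seq),
                    mut_seq=str(row.mut_seq),
                    n_grnas=int(row.n_grnas),
                    coding=bool(row.coding),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"allele table row {i + 2}: {exc}") from exc
    return records


def frame_from_calls(calls: Iterable[MutationCall]) -> pd.DataFrame:
    rows = [
        {
            "allele_id": c.allele_id,
            "gene_id": c.gene_id,
            "lesion_class": c.lesion_class,
            "del_len": c.del_len,
            "ins_len": c.ins_len,
            "net_change": c.net_change,
            "del_seq": c.del_seq,
            "ins_seq": c.ins_seq,
            "breakpoint": c.breakpoint,
            "frame_effect": c.frame_effect,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_bed(sites: Iterable[TargetSite], path: str) -> None:
    """BED6: protospacer interval, name=site_id, score=seed GC count."""
    lines = []
    for s in sites:
        score = s.seed.count("G") + s.seed.count("C")
        lines.append(
            f"{s.contig}\t{s.start}\t{s.end}\t{s.site_id}\t{score}\t{s.strand}"
        )
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def write_vcf_like(
    records: list[AlleleRecord], calls: list[MutationCall], path: str
) -> None:
    """Minimal VCF-style TSV for the calls (CHROM=gene_id, 1-based POS).

    REF/ALT follow the VCF indel convention: the base immediately left of
    the breakpoint anchors both alleles (the first wild-type base anchors
    lesions at offset 0).
    """
    by_id = {r.allele_id: r for r in records}
    lines = ["#CHROM\tPOS\tID\tREF\tALT"]
    for c in calls:
        wt = by_id[c.allele_id].wt_seq.upper()
        if c.lesion_class == "none":
            continue
        bp = c.breakpoint
        if bp > 0:
            anchor = wt[bp - 1]
            pos = bp  # 1-based position of the anchor base
            ref = anchor + c.del_seq
            alt = anchor + c.ins_seq
        else:
            anchor = wt[c.del_len] if c.del_len < len(wt) else ""
            pos = 1
            ref = c.del_seq + anchor
            alt = c.ins_seq + anchor
        lines.append(f"{c.gene_id}\t{pos}\t{c.allele_id}\t{ref}\t{alt}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_report(payload: dict, path: str, params: dict | None = None) -> None:
    """JSON report with schema version and the parameters that produced it."""
    doc = {"schema_version": SCHEMA_VERSION, "params": params or {}, **payload}
    _atomic_write(path, json.dumps(doc, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, float):
        return obj
    raise TypeError(f"not JSON serializable: {type(obj)}")
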