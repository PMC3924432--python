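"""Annotation-track I/O: GTF 2.2 and genePred readers, genePred/GTF writers.

``load_track`` auto-detects the format from the extension or the first
data line. Internal coordinates are 0-based half-open; GTF input is
converted from its 1-based inclusive convention. The CDS span recorded on
a transcript covers start through stop codon inclusive.
"""

from __future__ import annotations

import os
from typing import Optional

import gffutils

from .model import RetspliceError, TranscriptModel, ValidationError


class ParseError(RetspliceError):
    """A malformed record, reported with its 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


GTF_EXTS = {".gtf", ".gff"}
GENEPRED_EXTS = {".genepred", ".gp"}


def detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in GTF_EXTS:
        return "gtf"
    if ext in GENEPRED_EXTS:
        return "genepred"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 9 and ";" in fields[8]:
                return "gtf"
            if len(fields) in (10, 15):
                return "genepred"
            break
    raise ParseError(path, 1, "cannot determine annotation format")


def load_track(path: str, track_label: str) -> list:
    """Parse one annotation track into a list of :class:`TranscriptModel`.

    Raises :class:`ParseError` (with line number) for malformed records and
    :class:`ValidationError` for records that parse but violate transcript
    invariants (e.g. an exon outside the declared transcript span).
    """
    fmt = detect_format(path)
    if fmt == "gtf":
        return _load_gtf(path, track_label)
    return _load_genepred(path, track_label)


# -- GTF ----------------------------------------------------------------


def _prevalidate_gtf(path: str) -> None:
    # Structural line checks so errors carry a line number; semantic
    # parsing (attributes, feature grouping) is delegated to gffutils.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if end < start:
                raise ParseError(path, lineno, f"feature end {end} < start {start}")
            if "transcript_id" not in fields[8] or "gene_id" not in fields[8]:
                raise ParseError(path, lineno, "missing gene_id/transcript_id attribute")


def _load_gtf(path: str, track_label: str) -> list:
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_tx: dict = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        txid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = per_tx.setdefault(
            txid,
            {"chrom": feat.seqid, "strand": feat.strand, "gene_id": gid,
             "exons": [], "cds": []},
        )
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            rec["exons"].append(iv)
        else:
            rec["cds"].append(iv)
    out = []
    for txid, rec in per_tx.items():
        exons = tuple(sorted(rec["exons"]))
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        else:
            cds_start = cds_end = None
        out.append(
            TranscriptModel(
                id=txid, chrom=rec["chrom"], strand=rec["strand"], exons=exons,
                cds_start=cds_start, cds_end=cds_end,
                gene_id=rec["gene_id"], source_track=track_label,
            )
        )
    return out


# -- genePred -----------------------------------------------------------


def _load_genepred(path: str, track_label: str) -> list:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) not in (10, 15):
                raise ParseError(path, lineno, f"expected 10 or 15 fields, got {len(f)}")
            try:
                name, chrom, strand = f[0], f[1], f[2]
                tx_start, tx_end = int(f[3]), int(f[4])
                cds_start, cds_end = int(f[5]), int(f[6])
                n_exons = int(f[7])
                starts = [int(x) for x in f[8].rstrip(",").split(",")]
                ends = [int(x) for x in f[9].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinate field")
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ParseError(path, lineno, "exonCount does not match exon lists")
            exons = tuple(zip(starts, ends))
            for s, e in exons:
                if s < tx_start or e > tx_end:
                    raise ValidationError(
                        f"{path}:{lineno}: exon [{s},{e}) outside transcript span "
                        f"[{tx_start},{tx_end})"
                    )
            if cds_start == cds_end:  # genePred convention for non-coding
                cds_start = cds_end = None
            gene_id = f[11] if len(f) == 15 else name
            out.append(
                TranscriptModel(
                    id=name, chrom=chrom, strand=strand, exons=exons,
                    cds_start=cds_start, cds_end=cds_end,
                    gene_id=gene_id, source_track=track_label,
                )
            )
    return out


# -- writers ------------------------------------------------------------


def write_genepred(transcripts, path: str) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            cs = tx.cds_start if tx.is_coding else tx.end
            ce = tx.cds_end if tx.is_coding else tx.end
            starts = ",".join(str(s) for s, _ in tx.exons) + ","
            ends = ",".join(str(e) for _, e in tx.exons) + ","
            fh.write(
                "\t".join(
                    [tx.id, tx.chrom, tx.strand, str(tx.start), str(tx.end),
                     str(cs), str(ce), str(len(tx.exons)), starts, ends]
                )
                + "\n"
            )


def write_gtf(transcripts, path: str, source: str = "retsplice") -> None:
    """Emit exon and CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id or tx.id}"; transcript_id "{tx.id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.is_coding:
                for s, e in tx.exons:
                    cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{tx.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t.\t{attrs}\n"
                        )


def write_dedup_report(nrt, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("track\tn_input\tn_unique\n")
        for row in nrt.dedup_report or []:
            fh.write(f"{row['track']}\t{row['n_input']}\t{row['n_unique']}\n")
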