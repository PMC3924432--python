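"""Splice-junction I/O, annotated/novel partitioning, and isoform
abundance-ratio classes.

Junction file dialect (TSV, BED-flavored, no header): chrom, intronStart,
intronEnd, name, readCount, strand — coordinates 0-based half-open over
the spliced-out intron. The writer adds a seventh ``status`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import NRTranscriptome, RetspliceError, strands_compatible

ANNOTATED = "annotated"
NOVEL = "novel"

NOVEL_MAJOR = "novel_major"
EQUAL = "equal"
ANNOTATED_MAJOR = "annotated_major"


class JunctionParseError(RetspliceError):
    pass


@dataclass(frozen=True)
class Junction:
    """An intron interval with supporting read count."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    reads: int = 0
    name: str = ""
    status: Optional[str] = None
    sample: str = ""

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise RetspliceError(f"negative read count on {self.key()}")
        if self.end - self.start < 1:
            raise RetspliceError(f"intron length < 1 at {self.key()}")

    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def coord_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_duplicates(junctions: Iterable[Junction]) -> List[Junction]:
    """Sum reads over rows sharing (chrom, start, end, strand); first-seen
    name is kept. Output sorted by coordinate."""
    acc: Dict[tuple, Junction] = {}
    for j in junctions:
        k = j.key()
        if k in acc:
            acc[k] = replace(acc[k], reads=acc[k].reads + j.reads)
        else:
            acc[k] = j
    return sorted(acc.values(), key=lambda j: (j.chrom, j.start, j.end, j.strand))


def read_junctions(path: str, sample: str = "") -> List[Junction]:
    """Parse a junction file; duplicate coordinate rows are merged by
    summing their read counts."""
    out: List[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise JunctionParseError(f"{path}:{lineno}: expected >= 6 fields")
            try:
                start, end, reads = int(f[1]), int(f[2]), int(f[4])
            except ValueError:
                raise JunctionParseError(f"{path}:{lineno}: non-integer field")
            if reads < 0:
                raise JunctionParseError(f"{path}:{lineno}: negative read count")
            if start >= end:
                raise JunctionParseError(f"{path}:{lineno}: start >= end")
            status = f[6] if len(f) > 6 else None
            out.append(Junction(chrom=f[0], start=start, end=end, name=f[3],
                                reads=reads, strand=f[5], status=status,
                                sample=sample))
    return merge_duplicates(out)


def write_junctions(junctions: Iterable[Junction], path: str) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.name or '.'}\t{j.reads}"
                f"\t{j.strand}\t{j.status or '.'}\n"
            )


# -- partitioning -------------------------------------------------------


def partition(junctions: Sequence[Junction],
              nrt: NRTranscriptome) -> Tuple[List[Junction], List[Junction]]:
    """Split junctions into (annotated, novel) against the reference.

    A junction is annotated iff its intron coordinates exactly match a
    catalog entry; strand is compared only when both sides are stranded.
    """
    annotated, novel = [], []
    for j in junctions:
        if nrt.has_junction(j.chrom, j.start, j.end, j.strand):
            annotated.append(replace(j, status=ANNOTATED))
        else:
            novel.append(replace(j, status=NOVEL))
    return annotated, novel


# -- novel:annotated abundance ratio ------------------------------------


@dataclass(frozen=True)
class RatioClass:
    value: str  # novel_major | equal | annotated_major
    fold: float


def _classify_fold(fold: float) -> str:
    if fold >= 2.0:
        return NOVEL_MAJOR
    if fold <= 0.5:
        return ANNOTATED_MAJOR
    return EQUAL


def ratio_class(novel: Junction,
                annotated_junctions: Sequence[Junction],
                policy: str = "max") -> Optional[RatioClass]:
    """Class of a novel junction's abundance relative to its annotated
    counterpart.

    The counterpart is chosen among annotated junctions sharing at least
    one splice site (intron start or end) with the novel junction, on a
    compatible strand: the maximum-read one under the default ``max``
    policy, or the summed reads of all sharing junctions under ``sum``.
    Returns None when no annotated junction shares a site. A zero-read
    comparator yields an infinite fold (novel_major).
    """
    if policy not in ("max", "sum"):
        raise ValueError("policy must be 'max' or 'sum'")
    sharing = [
        a for a in annotated_junctions
        if a.chrom == novel.chrom
        and strands_compatible(a.strand, novel.strand)
        and (a.start == novel.start or a.end == novel.end)
        and (a.start, a.end) != (novel.start, novel.end)
    ]
    if not sharing:
        return None
    denom = (max(a.reads for a in sharing) if policy == "max"
             else sum(a.reads for a in sharing))
    fold = math.inf if denom == 0 else novel.reads / denom
    return RatioClass(value=_classify_fold(fold), fold=fold)


def ratio_histogram(novel_junctions: Sequence[Junction],
                    annotated_junctions: Sequence[Junction],
                    policy: str = "max") -> pd.DataFrame:
    """Percent of classified novel junctions per ratio class."""
    counts = {NOVEL_MAJOR: 0, EQUAL: 0, ANNOTATED_MAJOR: 0}
    by_site: Dict[tuple, list] = {}
    for a in annotated_junctions:
        by_site.setdefault((a.chrom, "L", a.start), []).append(a)
        by_site.setdefault((a.chrom, "R", a.end), []).append(a)
    for j in novel_junctions:
        cands = by_site.get((j.chrom, "L", j.start), []) + by_site.get(
            (j.chrom, "R", j.end), [])
        rc = ratio_class(j, cands, policy=policy) if cands else None
        if rc is not None:
            counts[rc.value] += 1
    total = sum(counts.values())
    rows = [{"ratio_class": k, "n": v,
             "pct": 100.0 * v / total if total else 0.0}
            for k, v in counts.items()]
    return pd.DataFrame(rows)


def total_reads(junctions: Iterable[Junction]) -> int:
    return sum(j.reads for j in junctions)
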