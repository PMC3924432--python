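"""Per-base coverage tracks and expression/saturation statistics.

The track is held as a dense per-chromosome depth vector (chromosomes in
this package's analyses are sub-megabase, so dense storage is simplest);
bedGraph I/O run-length encodes on the way out.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import RetspliceError


class CoverageTrack:
    """Depth-of-coverage over a genome.

    Parameters
    ----------
    depths:
        Mapping of chromosome name to a per-base integer depth vector.
    read_length:
        Length used to convert a depth integral into an approximate read
        count when per-feature read counts are not supplied directly.
    total_mapped_reads:
        Total mapped reads; if omitted it is estimated as the genome-wide
        depth integral divided by ``read_length``.
    """

    def __init__(self, depths: Dict[str, np.ndarray], read_length: int = 100,
                 total_mapped_reads: Optional[int] = None):
        self.depths = {c: np.asarray(v) for c, v in depths.items()}
        for chrom, v in self.depths.items():
            if (v < 0).any():
                raise RetspliceError(f"negative depth on {chrom}")
        self.read_length = read_length
        if total_mapped_reads is None:
            integral = sum(int(v.sum()) for v in self.depths.values())
            total_mapped_reads = max(1, integral // read_length)
        self.total_mapped_reads = int(total_mapped_reads)

    # -- I/O ------------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path: str, chrom_lengths: Optional[Dict[str, int]] = None,
                      **kw) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "depth"],
                         dtype={"chrom": str})
        lengths = dict(chrom_lengths or {})
        for chrom, sub in df.groupby("chrom"):
            lengths.setdefault(chrom, int(sub["end"].max()))
        depths = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
        for chrom, sub in df.groupby("chrom"):
            v = depths[chrom]
            for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
                v[s:e] = d
        return cls(depths, **kw)

    def to_bedgraph(self, path: str, emit_zero: bool = False) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.depths):
                v = self.depths[chrom]
                if len(v) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(v)]))
                for s, e in zip(starts, ends):
                    d = int(v[s])
                    if d or emit_zero:
                        fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")

    # -- queries --------------------------------------------------------

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.depths:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        v = self.depths[chrom][start:end]
        return float(v.mean()) if len(v) else 0.0

    def depth_integral(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self.depths:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        return int(self.depths[chrom][start:end].sum())

    def covered_run(self, chrom: str, edge: int, direction: int,
                    min_depth: float, max_len: int = 10**9) -> int:
        """Length of the contiguous run with depth >= min_depth extending
        from ``edge`` rightward (direction=+1, starting at edge) or
        leftward (direction=-1, ending at edge)."""
        if chrom not in self.depths:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        v = self.depths[chrom]
        n = 0
        if direction > 0:
            i = edge
            while i < len(v) and v[i] >= min_depth and n < max_len:
                i += 1
                n += 1
        else:
            i = edge - 1
            while i >= 0 and v[i] >= min_depth and n < max_len:
                i -= 1
                n += 1
        return n


# -- expression ---------------------------------------------------------


def rpkm(exonic_reads: float, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return exonic_reads / (length_bp / 1000.0) / (total_mapped / 1e6)


def copies_per_cell(rpkm_value: float) -> Tuple[float, float]:
    """Approximate transcript copies per cell from RPKM, using the
    convention that 1-4 RPKM corresponds to one transcript per cell;
    the low bound divides by 4, the high bound by 1."""
    return (rpkm_value / 4.0, rpkm_value / 1.0)


def transcript_expression(transcripts, coverage: CoverageTrack,
                          counts: Optional[Dict[str, float]] = None) -> pd.DataFrame:
    """Per-transcript expression table (exonic reads, RPKM, copies/cell).

    If a per-transcript read-count mapping is supplied it is used directly;
    otherwise exonic reads are estimated from the coverage depth integral
    divided by the read length.
    """
    rows = []
    total = coverage.total_mapped_reads
    for tx in transcripts:
        length = tx.exonic_length()
        if counts is not None and tx.id in counts:
            reads = float(counts[tx.id])
        else:
            integral = sum(coverage.depth_integral(tx.chrom, s, e) for s, e in tx.exons)
            reads = integral / coverage.read_length
        val = rpkm(reads, length, total)
        lo, hi = copies_per_cell(val)
        rows.append({"transcript_id": tx.id, "exonic_reads": reads,
                     "length_kb": length / 1000.0, "rpkm": val,
                     "copies_per_cell_lo": lo, "copies_per_cell_hi": hi})
    return pd.DataFrame(rows)


# -- detection and saturation ------------------------------------------


def exon_detected(exon, coverage: CoverageTrack, min_avg_depth: float) -> bool:
    """An exon is detected when its mean per-base depth is >= the threshold
    (inclusive)."""
    chrom, start, end = exon[0], exon[1], exon[2]
    return coverage.mean_depth(chrom, start, end) >= min_avg_depth


def saturation_curve(read_sets: Sequence[Tuple[int, CoverageTrack]],
                     exon_catalog: Iterable,
                     thresholds: Sequence[float] = (1, 5)) -> pd.DataFrame:
    """Fraction of catalog exons detected per nested read subsample.

    ``read_sets`` is an increasing sequence of (n_reads, CoverageTrack);
    each subsample must be a prefix of the next (per-base depths
    monotonically non-decreasing), which is verified.
    """
    prev = None
    for n_reads, track in read_sets:
        if prev is not None:
            pn, pt = prev
            if n_reads < pn:
                raise RetspliceError("read subsamples must be increasing")
            for chrom, v in pt.depths.items():
                if chrom not in track.depths or (track.depths[chrom] < v).any():
                    raise RetspliceError("subsamples are not nested")
        prev = (n_reads, track)
    catalog = list(exon_catalog)
    rows = []
    for n_reads, track in read_sets:
        for thr in thresholds:
            detected = sum(1 for ex in catalog if exon_detected(ex, track, thr))
            rows.append({"n_reads": n_reads, "threshold": thr,
                         "n_detected": detected,
                         "frac_detected": detected / len(catalog) if catalog else 0.0})
    return pd.DataFrame(rows)


def junction_saturation(subsamples: Sequence[Tuple[int, Iterable]],
                        reference_keys: Iterable) -> pd.DataFrame:
    """Fraction of a reference junction/event key set present per subsample.

    Each subsample is (n_reads, iterable of (chrom, start, end) keys with
    nonzero reads); subsets must be nested.
    """
    ref = set(reference_keys)
    prev: set = set()
    rows = []
    first = True
    for n_reads, keys in subsamples:
        cur = set(keys)
        if not first and not prev.issubset(cur):
            raise RetspliceError("junction subsamples are not nested")
        first = False
        prev = cur
        hit = len(ref & cur)
        rows.append({"n_reads": n_reads, "n_detected": hit,
                     "frac_detected": hit / len(ref) if ref else 0.0})
    return pd.DataFrame(rows)


# -- abundance histogram and concordance --------------------------------

DEFAULT_RPKM_EDGES = (0, 1, 5, 25, 100, 1000, 10000, float("inf"))


def abundance_histogram(records: pd.DataFrame,
                        edges: Sequence[float] = DEFAULT_RPKM_EDGES) -> pd.DataFrame:
    """Counts of transcripts per RPKM bin (left-closed bins)."""
    vals = records["rpkm"].to_numpy()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = int(((vals >= lo) & (vals < hi)).sum())
        rows.append({"rpkm_lo": lo, "rpkm_hi": hi, "n": n,
                     "pct": 100.0 * n / len(vals) if len(vals) else 0.0})
    return pd.DataFrame(rows)


def detection_concordance(sample_a: pd.DataFrame, sample_b: pd.DataFrame,
                          min_rpkm: float = 1.0) -> float:
    """Fraction of shared transcripts whose detection status (RPKM >= cutoff)
    agrees between two samples."""
    a = sample_a.set_index("transcript_id")["rpkm"]
    b = sample_b.set_index("transcript_id")["rpkm"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        return float("nan")
    agree = ((a.loc[common] >= min_rpkm) == (b.loc[common] >= min_rpkm)).sum()
    return float(agree / len(common))
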