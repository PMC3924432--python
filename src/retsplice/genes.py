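"""Intergenic novel-gene calling and coding-potential assessment.

Discovered novel exons (unanchored internal exons and terminal exons with
no annotated host) are chained through shared novel junctions; a
connected component is reported as a putative novel gene when every exon
is intergenic, the component has >= 3 exons, and the exon-averaged read
depth exceeds the depth threshold. A component containing any exon that
overlaps an annotated locus is rejected whole.

Coding potential follows a longest-ORF rule: all six frames are scanned
for ATG..stop spans; a gene whose longest such ORF exceeds 80 amino acids
is called protein_coding, otherwise lincRNA_candidate. Homology search of
candidate ORFs is an external step: the module writes a protein FASTA of
candidates and stops there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .coverage import CoverageTrack
from .events import NovelExon
from .junctions import Junction
from .model import GenomicInterval, NRTranscriptome, RetspliceError
from .orf import GenomeSource, STOP_CODONS, revcomp

PROTEIN_CODING = "protein_coding"
LINCRNA = "lincRNA_candidate"
ORF_AA_THRESHOLD = 80  # strict: coding iff orf_aa > 80


@dataclass
class NovelGeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # (start, end) pairs, sorted
    junctions: tuple  # connecting Junction objects
    mean_depth: float
    n_isoforms: int
    orf_aa: Optional[int] = None
    coding_call: Optional[str] = None

    @property
    def length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


def _count_paths(exons: Sequence[tuple], junctions: Sequence[Junction]) -> int:
    """Number of distinct junction paths from the first to the last exon
    (a proxy for isoform multiplicity within the component)."""
    g = nx.DiGraph()
    for s, e in exons:
        g.add_node((s, e))
    idx_by_start = {s: (s, e) for s, e in exons}
    idx_by_end = {e: (s, e) for s, e in exons}
    for j in junctions:
        u = idx_by_end.get(j.start)
        v = idx_by_start.get(j.end)
        if u is not None and v is not None:
            g.add_edge(u, v)
    first, last = min(exons), max(exons)
    if first == last:
        return 1
    try:
        return max(1, sum(1 for _ in nx.all_simple_paths(g, first, last)))
    except nx.NodeNotFound:
        return 1


def chain_novel_genes(novel_exons: Sequence[NovelExon],
                      novel_junctions: Sequence[Junction],
                      coverage: CoverageTrack,
                      nrt: NRTranscriptome,
                      min_exons: int = 3,
                      min_depth: float = 5.0) -> List[NovelGeneModel]:
    """Chain novel exons into putative novel genes (see module docstring).

    ``mean_depth`` is computed over exonic bases only and must strictly
    exceed ``min_depth``.
    """
    g = nx.Graph()
    exon_keys = []
    for e in novel_exons:
        k = (e.exon.chrom, e.exon.start, e.exon.end)
        g.add_node(k, strand=e.exon.strand)
        exon_keys.append(k)
    by_start: Dict[tuple, tuple] = {(c, s): (c, s, e) for c, s, e in exon_keys}
    by_end: Dict[tuple, tuple] = {(c, e): (c, s, e) for c, s, e in exon_keys}
    junction_edges: Dict[tuple, Junction] = {}
    for j in novel_junctions:
        u = by_end.get((j.chrom, j.start))
        v = by_start.get((j.chrom, j.end))
        if u is not None and v is not None and u != v:
            g.add_edge(u, v)
            junction_edges[(u, v)] = j
            junction_edges[(v, u)] = j

    genes: List[NovelGeneModel] = []
    for comp in nx.connected_components(g):
        keys = sorted(comp)
        chrom = keys[0][0]
        ivs = [GenomicInterval(c, s, e) for c, s, e in keys]
        # criterion 1: no exon of the component may overlap an annotated locus
        if any(nrt.overlaps_locus(iv) for iv in ivs):
            continue
        # criterion 2: component size
        if len(keys) < min_exons:
            continue
        # criterion 3: exon-averaged depth, strict
        total = sum(coverage.depth_integral(c, s, e) for c, s, e in keys)
        nbases = sum(e - s for _, s, e in keys)
        mean_depth = total / nbases if nbases else 0.0
        if not mean_depth > min_depth:
            continue
        comp_junctions = tuple(sorted(
            {junction_edges[(u, v)] for u, v in g.edges(keys)
             if (u, v) in junction_edges},
            key=lambda j: (j.start, j.end)))
        strands = {g.nodes[k]["strand"] for k in keys} - {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        exons = tuple((s, e) for _, s, e in keys)
        genes.append(NovelGeneModel(
            gene_id="", chrom=chrom, strand=strand, exons=exons,
            junctions=comp_junctions, mean_depth=mean_depth,
            n_isoforms=_count_paths(exons, comp_junctions)))
    genes.sort(key=lambda x: (x.chrom, x.span))
    for i, gene in enumerate(genes, start=1):
        gene.gene_id = f"NG{i}"
    return genes


def validate_gene(gene: NovelGeneModel, coverage: CoverageTrack,
                  nrt: NRTranscriptome, min_exons: int = 3,
                  min_depth: float = 5.0) -> bool:
    """Independent re-check of the three calling criteria for a reported
    gene (used as a post-hoc validator)."""
    ivs = [GenomicInterval(gene.chrom, s, e) for s, e in gene.exons]
    if any(nrt.overlaps_locus(iv) for iv in ivs):
        return False
    if gene.n_exons < min_exons:
        return False
    total = sum(coverage.depth_integral(gene.chrom, s, e) for s, e in gene.exons)
    nbases = sum(e - s for s, e in gene.exons)
    return (total / nbases if nbases else 0.0) > min_depth


# -- coding potential ---------------------------------------------------


def _longest_orf_aa(seq: str) -> int:
    """Longest ATG..stop ORF over all six frames, in amino acids excluding
    the stop; 0 when no complete ORF exists."""
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            start: Optional[int] = None
            i = frame
            while i + 3 <= len(strand_seq):
                codon = strand_seq[i:i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        best = max(best, (i - start) // 3)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
                i += 3
    return best


def gene_sequence(gene: NovelGeneModel, genome: GenomeSource) -> str:
    return "".join(genome.fetch(gene.chrom, s, e) for s, e in gene.exons)


def coding_potential(gene: NovelGeneModel, genome: GenomeSource) -> str:
    """Six-frame longest-ORF coding call; also records ``orf_aa`` on the
    gene. Coding iff the longest ATG-initiated, stop-terminated ORF is
    strictly longer than 80 aa."""
    seq = gene_sequence(gene, genome)
    gene.orf_aa = _longest_orf_aa(seq)
    gene.coding_call = PROTEIN_CODING if gene.orf_aa > ORF_AA_THRESHOLD else LINCRNA
    return gene.coding_call


def gene_report(genes: Sequence[NovelGeneModel]) -> pd.DataFrame:
    rows = []
    for gene in genes:
        lo, hi = gene.span if gene.exons else (0, 0)
        rows.append({"gene_id": gene.gene_id, "chrom": gene.chrom,
                     "start": lo, "end": hi, "strand": gene.strand,
                     "n_exons": gene.n_exons, "length_bp": gene.length_bp,
                     "n_isoforms": gene.n_isoforms,
                     "mean_depth": round(gene.mean_depth, 3),
                     "orf_aa": gene.orf_aa if gene.orf_aa is not None else "",
                     "coding_call": gene.coding_call or ""})
    cols = ["gene_id", "chrom", "start", "end", "strand", "n_exons",
            "length_bp", "n_isoforms", "mean_depth", "orf_aa", "coding_call"]
    return pd.DataFrame(rows, columns=cols)


def genes_to_transcripts(genes: Sequence[NovelGeneModel]):
    """Novel-gene models as (non-coding) transcript models, for genePred
    serialization alongside the annotated reference."""
    from .model import TranscriptModel
    return [TranscriptModel(id=g.gene_id, chrom=g.chrom,
                            strand=g.strand if g.strand != "." else "+",
                            exons=g.exons, gene_id=g.gene_id,
                            source_track="novel")
            for g in genes]


def write_gene_bed12(genes: Sequence[NovelGeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - lo) for s, _ in g.exons) + ","
            strand = g.strand if g.strand != "." else "."
            fh.write(f"{g.chrom}\t{lo}\t{hi}\t{g.gene_id}\t"
                     f"{int(g.mean_depth)}\t{strand}\t{lo}\t{hi}\t0\t"
                     f"{g.n_exons}\t{sizes}\t{starts}\n")


def write_orf_fasta(genes: Sequence[NovelGeneModel], genome: GenomeSource,
                    path: str) -> None:
    """Protein FASTA of the longest candidate ORF per coding gene, for an
    external homology search."""
    from Bio.Seq import Seq

    with open(path, "w") as fh:
        for gene in genes:
            if gene.coding_call != PROTEIN_CODING:
                continue
            seq = gene_sequence(gene, genome)
            best, best_len = None, 0
            for strand_seq in (seq, revcomp(seq)):
                for frame in range(3):
                    start = None
                    i = frame
                    while i + 3 <= len(strand_seq):
                        codon = strand_seq[i:i + 3]
                        if codon in STOP_CODONS:
                            if start is not None and (i - start) // 3 > best_len:
                                best_len = (i - start) // 3
                                best = strand_seq[start:i]
                            start = None
                        elif codon == "ATG" and start is None:
                            start = i
                        i += 3
            if best:
                prot = str(Seq(best).translate())
                fh.write(f">{gene.gene_id} orf_aa={best_len}\n{prot}\n")
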