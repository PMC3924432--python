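"""Novel-gene chaining, coding potential, and the gene report."""

import random

import numpy as np
import pytest

from retsplice.coverage import CoverageTrack
from retsplice.events import NovelExon
from retsplice.genes import (_longest_orf_aa, chain_novel_genes,
                             coding_potential, gene_report, validate_gene,
                             NovelGeneModel)
from retsplice.junctions import Junction
from retsplice.model import GenomicInterval, TranscriptModel, build_nonredundant
from retsplice.orf import GenomeSource, revcomp


def exon(start, end, chrom="chr1"):
    return NovelExon(GenomicInterval(chrom, start, end), None, None, (), "terminal")


def J(start, end, chrom="chr1"):
    return Junction(chrom=chrom, start=start, end=end, strand="+", reads=5)


@pytest.fixture()
def annotated_far_away():
    tx = TranscriptModel(id="ann", chrom="chr1", strand="+",
                         exons=((50_000, 50_100), (50_500, 50_600)))
    return build_nonredundant([[tx]])


def chain_coverage(depth_val=10, n=20_000):
    depth = np.zeros(n, dtype=np.int64)
    return depth, CoverageTrack({"chr1": depth})


class TestChaining:
    def test_three_connected_intergenic_exons_form_a_gene(self, annotated_far_away):
        depth, cov = chain_coverage()
        exons = [exon(1000, 1100), exon(1800, 1900), exon(2600, 2700)]
        for e in exons:
            depth[e.exon.start:e.exon.end] = 10
        genes = chain_novel_genes(exons, [J(1100, 1800), J(1900, 2600)],
                                  cov, annotated_far_away)
        assert len(genes) == 1
        g = genes[0]
        assert g.n_exons == 3 and g.gene_id == "NG1"
        assert validate_gene(g, cov, annotated_far_away)

    def test_two_exon_component_rejected(self, annotated_far_away):
        depth, cov = chain_coverage()
        exons = [exon(1000, 1100), exon(1800, 1900)]
        depth[1000:1900] = 10
        assert not chain_novel_genes(exons, [J(1100, 1800)], cov,
                                     annotated_far_away)

    def test_low_depth_component_rejected(self, annotated_far_away):
        depth, cov = chain_coverage()
        exons = [exon(1000, 1100), exon(1800, 1900), exon(2600, 2700)]
        for e in exons:
            depth[e.exon.start:e.exon.end] = 5  # mean 5 is not > 5
        assert not chain_novel_genes(exons, [J(1100, 1800), J(1900, 2600)],
                                     cov, annotated_far_away)

    def test_component_touching_annotation_rejected_whole(self, annotated_far_away):
        depth, cov = chain_coverage(n=60_000)
        exons = [exon(1000, 1100), exon(1800, 1900), exon(2600, 2700),
                 exon(50_050, 50_150)]  # overlaps the annotated locus
        for e in exons:
            depth[e.exon.start:e.exon.end] = 10
        js = [J(1100, 1800), J(1900, 2600), J(2700, 50_050)]
        assert not chain_novel_genes(exons, js, cov, annotated_far_away)
        # removing the offending exon restores the call (monotonicity)
        assert len(chain_novel_genes(exons[:3], js[:2], cov,
                                     annotated_far_away)) == 1

    def test_planted_genes_recovered_exactly(self, study):
        truth = study.res.truth
        planted = {(r.chrom, r.start, r.end) for r in truth.itertuples()
                   if r.kind == "novel_gene"}
        got = {(g.chrom, g.span[0], g.span[1]) for g in study.genes}
        assert got == planted
        for g in study.genes:
            assert validate_gene(g, study.res.coverage, study.nrt)


class TestCodingPotential:
    def make_gene(self, seq, chrom="chrG"):
        gene = NovelGeneModel(gene_id="NGx", chrom=chrom, strand="+",
                              exons=((0, len(seq)),), junctions=(),
                              mean_depth=10, n_isoforms=1)
        return gene, GenomeSource({chrom: seq})

    def orf_seq(self, n_aa):
        return "ATG" + "GCT" * (n_aa - 1) + "TAA"

    def test_90_aa_orf_is_protein_coding(self):
        gene, genome = self.make_gene("CCT" * 10 + self.orf_seq(90) + "TCC" * 10)
        assert coding_potential(gene, genome) == "protein_coding"
        assert gene.orf_aa == 90

    @pytest.mark.parametrize("n_aa,expect", [
        (79, "lincRNA_candidate"), (80, "lincRNA_candidate"),
        (81, "protein_coding"),
    ])
    def test_threshold_is_strictly_greater_than_80(self, n_aa, expect):
        gene, genome = self.make_gene("CT" * 15 + self.orf_seq(n_aa) + "TC" * 15)
        assert coding_potential(gene, genome) == expect

    def test_orf_without_stop_does_not_count(self):
        gene, genome = self.make_gene("ATG" + "GCT" * 100)  # no in-frame stop
        assert coding_potential(gene, genome) == "lincRNA_candidate"
        assert gene.orf_aa == 0

    def test_six_frame_symmetry(self):
        rng = random.Random(8)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(400))
            assert _longest_orf_aa(seq) == _longest_orf_aa(revcomp(seq))

    def test_random_sequences_match_exhaustive_scanner(self):
        rng = random.Random(13)
        stops = {"TAA", "TAG", "TGA"}

        def brute(seq):
            best = 0
            for s in (seq, revcomp(seq)):
                for frame in range(3):
                    codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
                    for i, c in enumerate(codons):
                        if c != "ATG":
                            continue
                        for k in range(i + 1, len(codons)):
                            if codons[k] in stops:
                                best = max(best, k - i)
                                break
                    # every ATG..first-stop span enumerated above
            return best

        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 500)))
            assert _longest_orf_aa(seq) == brute(seq)


class TestReport:
    def test_empty_input_gives_header_only(self):
        df = gene_report([])
        assert len(df) == 0 and "coding_call" in df.columns

    def test_report_has_planted_exon_counts_and_is_deterministic(self, study):
        truth = study.res.truth
        detail = {(r.chrom, r.start, r.end): r.detail
                  for r in truth.itertuples() if r.kind == "novel_gene"}
        df1 = gene_report(study.genes)
        df2 = gene_report(study.genes)
        assert df1.to_csv() == df2.to_csv()
        for row in df1.itertuples():
            n_exp, coding_exp = detail[(row.chrom, row.start, row.end)].split(":")
            assert row.n_exons == int(n_exp)
            assert row.coding_call == coding_exp


def test_novel_genes_round_trip_through_genepred(tmp_path, study):
    from retsplice.annotation import load_track, write_genepred
    from retsplice.genes import genes_to_transcripts, write_gene_bed12
    txs = genes_to_transcripts(study.genes)
    p = tmp_path / "ng.genePred"
    write_genepred(txs, str(p))
    back = load_track(str(p), "ng")
    assert {(t.chrom, t.exons) for t in back} == {(t.chrom, t.exons) for t in txs}
    bed = tmp_path / "ng.bed"
    write_gene_bed12(study.genes, str(bed))
    assert sum(1 for _ in open(bed)) == len(study.genes)
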