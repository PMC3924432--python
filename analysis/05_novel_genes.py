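"""Chain intergenic novel exons into putative novel genes and assess
their coding potential.

Unanchored novel exons (no annotated host) are connected through shared
novel junctions; components with >= 3 wholly intergenic exons and mean
exonic depth > 5 become gene models. A six-frame longest-ORF scan calls
each model protein-coding (ORF > 80 aa) or a lincRNA candidate, and the
candidate ORFs are written as protein FASTA for an external homology
search.
"""

from common import RESULTS, classify, load_inputs, load_reference

from retsplice.annotation import write_genepred
from retsplice.genes import (coding_potential, chain_novel_genes, gene_report,
                             genes_to_transcripts, write_gene_bed12,
                             write_orf_fasta)


def main():
    nrt = load_reference()
    junctions, coverage, genome, truth = load_inputs()
    _, novel, events = classify(nrt, junctions, coverage)

    candidates = events.unanchored_exons + [
        t for t in events.terminal_exons if not t.host_transcripts]
    genes = chain_novel_genes(candidates, novel, coverage, nrt)
    for g in genes:
        coding_potential(g, genome)
    report = gene_report(genes)
    report.to_csv(RESULTS / "novel_genes.tsv", sep="\t", index=False)
    write_orf_fasta(genes, genome, str(RESULTS / "novel_gene_orfs.faa"))
    write_genepred(genes_to_transcripts(genes),
                   str(RESULTS / "novel_genes.genePred"))
    write_gene_bed12(genes, str(RESULTS / "novel_genes.bed"))

    n_coding = sum(g.coding_call == "protein_coding" for g in genes)
    print(f"{len(genes)} novel genes from {len(candidates)} intergenic "
          f"novel exons; {n_coding} protein-coding, "
          f"{len(genes) - n_coding} lincRNA candidates")
    if len(report):
        print(f"lengths {report.length_bp.min()}-{report.length_bp.max()} bp, "
              f"{report.n_exons.min()}-{report.n_exons.max()} exons")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
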