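"""Expression levels and detection-saturation curves.

Computes per-transcript RPKM and approximate copies per cell from the
coverage track, the abundance histogram, and — over nested read
subsamples — the fraction of annotated exons detected at mean depth >= 1
and >= 5 together with the fraction of novel junctions recovered.
"""

from common import RESULTS, classify, load_inputs, load_reference

from retsplice.coverage import (abundance_histogram, detection_concordance,
                                junction_saturation, saturation_curve,
                                transcript_expression)
from retsplice.simulate import nested_subsamples

FRACTIONS = [0.1, 0.25, 0.5, 0.75, 1.0]


def main():
    nrt = load_reference()
    junctions, coverage, genome, truth = load_inputs()
    _, novel, _ = classify(nrt, junctions, coverage)

    expr = transcript_expression(nrt.transcripts, coverage)
    expr.to_csv(RESULTS / "expression.tsv", sep="\t", index=False)
    hist = abundance_histogram(expr)
    hist.to_csv(RESULTS / "abundance_histogram.tsv", sep="\t", index=False)
    print(f"expression for {len(expr)} transcripts "
          f"(total mapped ~{coverage.total_mapped_reads} reads)")
    print(hist.to_string(index=False))

    subs = nested_subsamples(coverage, junctions, FRACTIONS)
    curve = saturation_curve([(s["n_reads"], s["coverage"]) for s in subs],
                             sorted(nrt.exon_catalog), thresholds=(1, 5))
    curve.to_csv(RESULTS / "exon_saturation.tsv", sep="\t", index=False)
    print("annotated-exon detection by read depth:")
    print(curve.to_string(index=False))

    novel_keys = {j.coord_key() for j in novel}
    jcurve = junction_saturation(
        [(s["n_reads"], [j.coord_key() for j in s["junctions"]])
         for s in subs], novel_keys)
    jcurve.to_csv(RESULTS / "novel_event_saturation.tsv", sep="\t",
                  index=False)
    print("novel-junction recovery by read depth:")
    print(jcurve.to_string(index=False))

    half = subs[2]
    expr_half = transcript_expression(nrt.transcripts, half["coverage"])
    conc = detection_concordance(expr, expr_half)
    print(f"detection concordance, full vs 50% subsample: {100 * conc:.1f}%")


if __name__ == "__main__":
    main()
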