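"""Annotate the reading-frame consequence of every classified event.

Each event is spliced into its host transcript model and translated from
the annotated CDS start; the breakdown mirrors the in-frame / frameshift
/ UTR (or ncRNA) split per event class, with the in-frame share of
UTR-resident exons and the mean exons skipped by frame class.
"""

from common import RESULTS, classify, load_inputs, load_reference

from retsplice.orf import added_removed_sequence, frame_breakdown, frame_table


def main():
    nrt = load_reference()
    junctions, coverage, genome, truth = load_inputs()
    _, _, events = classify(nrt, junctions, coverage)

    frame_table(events, nrt, genome).to_csv(
        RESULTS / "events_frame.tsv", sep="\t", index=False)
    breakdown, extras = frame_breakdown(events, nrt, genome)
    breakdown.to_csv(RESULTS / "frame_breakdown.tsv", sep="\t", index=False)
    print(breakdown.to_string(index=False))
    for key, val in sorted(extras.items()):
        print(f"{key}: {val:.2f}")

    added, removed = added_removed_sequence(events.alt_sites)
    with open(RESULTS / "alt_site_sequence_change.tsv", "w") as fh:
        fh.write("direction\tbp\nadded\t%d\nremoved\t%d\n" % (added, removed))
    print(f"alternate splice sites add {added} bp and remove {removed} bp "
          f"of transcribed sequence")


if __name__ == "__main__":
    main()
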