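"""Shared paths and loaders for the numbered analysis scripts.

The simulated raw data (genome FASTA, GTF tracks, junction BED, bedGraph
coverage, truth TSV) lives under scratch/sim; derived tables go to
results/. Scripts re-read the on-disk formats rather than passing Python
objects, so each stage exercises the package's I/O paths the way a run
on real aligner output would.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
STUDY_SEED = 11

TRACK_LABELS = ["trackA", "trackB", "trackC"]


def load_reference():
    from retsplice.annotation import load_track
    from retsplice.model import build_nonredundant
    tracks = [load_track(str(SIM_DIR / f"{label}.gtf"), label)
              for label in TRACK_LABELS]
    return build_nonredundant(tracks)


def load_inputs():
    import pandas as pd
    from retsplice.coverage import CoverageTrack
    from retsplice.junctions import read_junctions
    from retsplice.orf import GenomeSource
    junctions = read_junctions(str(SIM_DIR / "junctions.bed"))
    coverage = CoverageTrack.from_bedgraph(str(SIM_DIR / "coverage.bedGraph"))
    genome = GenomeSource(str(SIM_DIR / "genome.fa"))
    truth = pd.read_csv(SIM_DIR / "truth.tsv", sep="\t")
    return junctions, coverage, genome, truth


def classify(nrt, junctions, coverage):
    from retsplice.events import classify_all
    from retsplice.junctions import partition
    annotated, novel = partition(junctions, nrt)
    events = classify_all(novel, nrt, coverage)
    return annotated, novel, events
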