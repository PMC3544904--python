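"""Call CNVs on the simulated cohort with both algorithms.

Runs the HMM decoder and the permutation-gated segmenter over every
sample and pseudochromosome of the cohort written by 01_simulate_cohort,
then intersects the two call sets.  Reports per-group call burden —
the analogue of the study's observation of ~0.70 consensus calls per case
and ~0.66 per control — and writes all three call tables.
"""

from pathlib import Path

from cnvpanel import io
from cnvpanel.consensus import intersect_calls
from cnvpanel.hmm import call_hmm
from cnvpanel.segment import SegmentationConfig, call_segments

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
BASE = ROOT / "scratch"


def main() -> None:
    cohort = BASE / "cohort"
    panel = io.read_manifest(cohort / "panel.tsv")
    phenotypes = io.read_phenotypes(cohort / "phenotypes.tsv")
    data = io.read_intensities(str(cohort / "intensities"), phenotypes)

    hmm_calls = call_hmm(data, panel)
    seg_calls = call_segments(data, panel, SegmentationConfig(rng_seed=SEED))
    inter, hmm_only, seg_only = intersect_calls(hmm_calls, seg_calls, panel)

    io.write_calls(hmm_calls, BASE / "calls_hmm.tsv")
    io.write_calls(seg_calls, BASE / "calls_segment.tsv")
    io.write_calls(inter, BASE / "calls_intersection.tsv")

    is_case = phenotypes.set_index("sample_id")["status"] == "case"
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    for label, cs in (("hmm", hmm_calls), ("segment", seg_calls), ("consensus", inter)):
        case_calls = cs.calls["sample_id"].map(is_case).sum()
        print(
            f"{label:>9}: {len(cs)} calls "
            f"({case_calls / n_cases:.2f}/case, "
            f"{(len(cs) - case_calls) / n_controls:.2f}/control)"
        )
    print(f"calls supported by one caller only: hmm {len(hmm_only)}, segment {len(seg_only)}")


if __name__ == "__main__":
    main()
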