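"""Per-region case/control association and validation selection.

Builds the carriers-by-status table for every CNVR (losses and gains
tested independently; X regions additionally stratified by sex), computes
the exact two-sided Fisher p-value and sample odds ratio, applies the
selection gate (OR >= 2.0 and >= 2 case carriers) with up to six case
samples listed per selected region, and draws the Manhattan-style plot.
"""

from pathlib import Path

import pandas as pd

from cnvpanel import io
from cnvpanel.association import (
    associate_regions,
    manhattan_plot,
    results_frame,
    select_for_validation,
)
from cnvpanel.consensus import carrier_matrix

ROOT = Path(__file__).resolve().parent.parent
BASE = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = BASE / "cohort"
    panel = io.read_manifest(cohort / "panel.tsv")
    phenotypes = io.read_phenotypes(cohort / "phenotypes.tsv")
    cnvrs = io.read_cnvrs(RESULTS / "cnvrs.tsv")
    callsets = [
        io.read_calls(BASE / "calls_hmm.tsv"),
        io.read_calls(BASE / "calls_segment.tsv"),
        io.read_calls(BASE / "calls_intersection.tsv"),
    ]
    matrix = carrier_matrix(cnvrs, callsets, panel,
                            sample_ids=list(phenotypes["sample_id"]))
    qc = pd.read_csv(RESULTS / "qc_report.tsv", sep="\t")
    excluded = set(qc.loc[qc["excluded"], "sample_id"])

    results = associate_regions(matrix, phenotypes, exclude=excluded)
    results = select_for_validation(results, matrix=matrix, phenotypes=phenotypes)
    df = results_frame(results)
    df.to_csv(RESULTS / "association.tsv", sep="\t", index=False, float_format="%.6g")
    manhattan_plot(results, str(RESULTS / "manhattan.png"))

    combined = df[df["sex_stratum"] == "all"]
    selected = combined[combined["selected"]]
    print(f"{len(combined)} region-type tests, {len(selected)} selected for validation")
    top = combined.nsmallest(5, "p_value")[
        ["region_id", "type", "odds_ratio", "p_value", "case_carriers", "control_carriers"]
    ]
    print("most significant regions:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
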