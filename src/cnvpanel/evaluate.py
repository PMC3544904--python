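"""Truth-based evaluation and study-scale emulation.

Helpers that score pipeline output against a simulator truth table
(per-carrier precision/recall, split-rate calibration, odds-ratio interval
coverage) and build a cohort emulating the published study: one
pseudochromosome per reported CNV region, carrier frequencies taken from
the printed carrier counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import odds_ratio as _exact_odds_ratio

from .association import associate_regions
from .consensus import carrier_matrix, define_cnvrs, intersect_calls
from .hmm import HmmModel, call_hmm
from .segment import SegmentationConfig, call_segments, segment_univariate
from .simulate import simulate_cohort
from .tables import study_regions
from .types import (
    CallSet,
    CarrierMatrix,
    CohortDesign,
    RegionSpec,
    TruthTable,
    baseline_copy_number,
)

__all__ = [
    "true_carrier_sets",
    "carrier_precision",
    "segmentation_false_split_rate",
    "study_emulation_specs",
    "run_dual_caller_cohort",
    "odds_ratio_ci_coverage",
]


def true_carrier_sets(
    truth: TruthTable, phenotypes: pd.DataFrame, specs: list[RegionSpec]
) -> dict[tuple[str, str], set[str]]:
    """(region_id, type) -> sample ids that truly carry that variant."""
    pheno = phenotypes.set_index("sample_id")
    sex = pheno["sex"]
    out: dict[tuple[str, str], set[str]] = {}
    for spec in specs:
        carriers = set()
        cn = truth.cn[spec.region_id]
        for sample_id, value in cn.items():
            base = baseline_copy_number(spec.chromosome, sex[sample_id])
            if (spec.cnv_type == "loss" and value < base) or (
                spec.cnv_type == "gain" and value > base
            ):
                carriers.add(sample_id)
        out[(spec.region_id, spec.cnv_type)] = carriers
    return out


def carrier_precision(
    matrix: CarrierMatrix,
    truth_sets: dict[tuple[str, str], set[str]],
    provenance: str | None = None,
) -> tuple[float, int, int]:
    """(precision, true positives, flagged) of carrier entries.

    ``provenance="both"`` restricts to intersection-supported carriers;
    ``"hmm"``/``"segment"`` restrict to entries that caller supports (alone
    or jointly).  Precision of an empty flag set is reported as 1.0.
    """
    tp = flagged = 0
    for region in matrix.regions:
        truth = truth_sets.get((region.region_id, region.type), set())
        col = matrix.status[region.cnvr_id]
        prov = matrix.provenance[region.cnvr_id]
        for sample_id in col.index[col]:
            support = prov[sample_id]
            if provenance == "both" and support != "both":
                continue
            if provenance in ("hmm", "segment") and support not in (provenance, "both"):
                continue
            flagged += 1
            tp += sample_id in truth
    return (tp / flagged if flagged else 1.0), tp, flagged


def segmentation_false_split_rate(
    n_replicates: int = 1000,
    n_markers: int = 20,
    noise_sd: float = 1.0,
    config: SegmentationConfig | None = None,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise vectors the segmenter splits at all."""
    config = config or SegmentationConfig(rng_seed=seed)
    rng = np.random.default_rng(seed)
    split = 0
    for _ in range(n_replicates):
        x = rng.normal(0.0, noise_sd, n_markers)
        split += len(segment_univariate(x, config, rng)) > 1
    return split / n_replicates


_COORD_RE = re.compile(r"chr([0-9XY]+):(\d+)-(\d+)")


def study_emulation_specs(scale: float = 1.0) -> list[RegionSpec]:
    """One region per published row, carrier frequencies from printed counts.

    Chromosome and region width follow the printed coordinates; start
    positions are laid out synthetically (2 Mb apart per chromosome) so
    that rows reported at overlapping genomic coordinates — the array
    probes them independently — occupy disjoint pseudochromosomes.
    ``scale`` multiplies both carrier frequencies (for power studies at
    reduced cohort size it stays 1.0).
    """
    df = study_regions()
    specs = []
    next_start: dict[str, int] = {}
    for row in df.itertuples(index=False):
        m = _COORD_RE.match(row.coords)
        chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        width = max(end - start, 2000)
        pos = next_start.get(chrom, 10_000_000)
        next_start[chrom] = pos + width + 2_000_000
        specs.append(
            RegionSpec(
                region_id=row.row_id,
                chromosome=chrom,
                start_bp=pos,
                end_bp=pos + width,
                cnv_type=row.type,
                case_carrier_freq=min(scale * row.case_carriers / row.n_case, 1.0),
                control_carrier_freq=min(scale * row.control_carriers / row.n_control, 1.0),
            )
        )
    return specs


@dataclass
class DualCallerResult:
    panel: object
    phenotypes: pd.DataFrame
    truth: TruthTable
    hmm_calls: CallSet
    segment_calls: CallSet
    intersection: CallSet
    matrix: CarrierMatrix
    results: list


def run_dual_caller_cohort(
    design: CohortDesign,
    specs: list[RegionSpec],
    seg_config: SegmentationConfig | None = None,
    hmm_model: HmmModel | None = None,
) -> DualCallerResult:
    """Simulate, call with both algorithms, intersect, associate."""
    panel, pheno, truth, data = simulate_cohort(design, specs)
    hmm_calls = call_hmm(data, panel, hmm_model)
    seg_calls = call_segments(
        data, panel, seg_config or SegmentationConfig(rng_seed=design.rng_seed)
    )
    inter, _, _ = intersect_calls(hmm_calls, seg_calls, panel)
    union = CallSet(
        "mixed",
        pd.concat(
            [hmm_calls.calls, seg_calls.calls, inter.calls], ignore_index=True
        ),
    )
    cnvrs = define_cnvrs(union, panel)
    matrix = carrier_matrix(
        cnvrs, [hmm_calls, seg_calls, inter], panel, sample_ids=data.sample_ids
    )
    results = associate_regions(matrix, pheno)
    return DualCallerResult(
        panel, pheno, truth, hmm_calls, seg_calls, inter, matrix, results
    )


def odds_ratio_ci_coverage(
    result: DualCallerResult, specs: list[RegionSpec], level: float = 0.95
) -> tuple[int, int]:
    """(covered, total): planted regions whose generating odds ratio falls
    inside the exact conditional CI of the estimated table.

    Each planted region is matched to its largest detected CNVR of the
    same type within its pseudochromosome; regions with no detected CNVR
    count as uncovered.
    """
    by_key: dict[tuple[str, str], list] = {}
    regions = {r.cnvr_id: r for r in result.matrix.regions}
    for res in result.results:
        if res.sex_stratum != "all":
            continue
        reg = regions[res.region_id]
        by_key.setdefault((reg.region_id, reg.type), []).append(res)
    covered = total = 0
    for spec in specs:
        total += 1
        cands = by_key.get((spec.region_id, spec.cnv_type))
        if not cands:
            continue
        res = max(cands, key=lambda r: r.table.a + r.table.b)
        t = res.table
        odds_case = spec.case_carrier_freq / (1 - spec.case_carrier_freq)
        odds_ctrl = spec.control_carrier_freq / (1 - spec.control_carrier_freq)
        true_or = odds_case / odds_ctrl
        ci = _exact_odds_ratio([[t.a, t.b], [t.c, t.d]]).confidence_interval(level)
        if ci.low <= true_or <= ci.high:
            covered += 1
    return covered, total
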