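"""Sample-level quality control applied before association.

The one data-driven rule modeled here is removal of samples with excessive
CNV calls (a hallmark of noisy arrays): a sample is excluded when its total
call count across both callers exceeds median + k*MAD of the cohort.
Laboratory QC, relatedness and ancestry filtering are accepted as a
user-supplied exclusion list instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CallSet, IntensityDataset, SampleQcReport

__all__ = ["filter_excessive_calls", "qc_report_frame", "read_exclusion_list"]


def filter_excessive_calls(
    callsets: list[CallSet],
    sample_ids: list[str],
    k: float = 5.0,
    data: IntensityDataset | None = None,
    lrr_sd_threshold: float | None = None,
) -> list[SampleQcReport]:
    """Flag samples whose total call count exceeds median + k*MAD.

    The rule is disabled (with a warning) on cohorts of fewer than 10
    samples, and when the MAD is zero (all counts identical) nothing is
    excluded.  Optionally also excludes samples whose per-sample LRR
    standard deviation exceeds ``lrr_sd_threshold`` (intensity noise).
    Deterministic and invariant to sample order.
    """
    counts = {s: {"hmm": 0, "segment": 0} for s in sample_ids}
    for cs in callsets:
        if cs.caller not in ("hmm", "segment"):
            continue
        for s, n in cs.calls.groupby("sample_id").size().items():
            if s in counts:
                counts[s][cs.caller] = int(n)
    totals = np.array([counts[s]["hmm"] + counts[s]["segment"] for s in sample_ids])

    rule_active = len(sample_ids) >= 10
    if not rule_active:
        warnings.warn("fewer than 10 samples: excessive-call rule disabled")
    median = float(np.median(totals)) if len(totals) else 0.0
    mad = float(np.median(np.abs(totals - median))) if len(totals) else 0.0
    # MAD degenerates to 0 on near-homogeneous cohorts; fall back to a
    # 1-call scale so identical counts exclude nobody but gross outliers
    # are still caught
    cutoff = median + k * max(mad, 1.0) if rule_active else np.inf

    lrr_sd = {}
    if data is not None:
        sds = data.lrr.std(axis=1, ddof=1)
        lrr_sd = sds.to_dict()

    reports = []
    for s, total in zip(sample_ids, totals):
        sd = float(lrr_sd.get(s, np.nan))
        if total > cutoff:
            reason = "excessive_calls"
        elif lrr_sd_threshold is not None and np.isfinite(sd) and sd > lrr_sd_threshold:
            reason = "intensity_noise"
        else:
            reason = "none"
        reports.append(
            SampleQcReport(
                sample_id=s,
                n_calls_hmm=counts[s]["hmm"],
                n_calls_segment=counts[s]["segment"],
                lrr_sd=sd,
                excluded=reason != "none",
                exclusion_reason=reason,
            )
        )
    return reports


def qc_report_frame(reports: list[SampleQcReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "n_calls_hmm": [r.n_calls_hmm for r in reports],
            "n_calls_segment": [r.n_calls_segment for r in reports],
            "lrr_sd": [r.lrr_sd for r in reports],
            "excluded": [r.excluded for r in reports],
            "exclusion_reason": [r.exclusion_reason for r in reports],
        }
    )


def read_exclusion_list(path: str) -> set[str]:
    """One sample_id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
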