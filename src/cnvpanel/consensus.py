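"""Dual-caller consensus: call intersection, CNVR definition, carrier matrix.

Calls confirmed by both an HMM decoder and an independent segmentation
caller are far more reliable than calls private to either, so the carrier
status that feeds association records which caller(s) support it and the
intersection call set is computed explicitly.  All interval arithmetic is
0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CALL_COLUMNS,
    CallSet,
    CarrierMatrix,
    CnvRegion,
    ProbePanel,
    empty_calls,
)

__all__ = ["intersect_calls", "define_cnvrs", "carrier_matrix"]


def _count_probes(panel: ProbePanel | None, region_id: str, start: int, end: int) -> int:
    if panel is None:
        return 0
    probes = panel.region_probes(region_id)
    pos0 = probes["pos"].to_numpy() - 1  # 0-based probe coordinates
    return int(((pos0 >= start) & (pos0 < end)).sum())


def intersect_calls(
    a: CallSet, b: CallSet, panel: ProbePanel | None = None
) -> tuple[CallSet, CallSet, CallSet]:
    """Base-pair intersection of same-sample, same-type overlapping calls.

    Returns ``(intersection, a_only, b_only)``: every overlapping same-type
    pair contributes its interval intersection to the consensus set; calls
    with no same-type overlap in the other set are retained in the
    caller-only sets.  ``n_probes`` of intersection calls is recounted
    against the panel when one is provided.
    """
    rows = []
    a_hit = np.zeros(len(a.calls), dtype=bool)
    b_hit = np.zeros(len(b.calls), dtype=bool)
    if len(a.calls) and len(b.calls):
        b_groups = {
            key: sub for key, sub in b.calls.groupby(["sample_id", "region_id", "type"])
        }
        for ai, call in a.calls.iterrows():
            key = (call["sample_id"], call["region_id"], call["type"])
            sub = b_groups.get(key)
            if sub is None:
                continue
            for bi, other in sub.iterrows():
                lo = max(call["start"], other["start"])
                hi = min(call["end"], other["end"])
                if lo >= hi:
                    continue
                a_hit[a.calls.index.get_loc(ai)] = True
                b_hit[b.calls.index.get_loc(bi)] = True
                rows.append(
                    (
                        call["sample_id"],
                        call["chrom"],
                        int(lo),
                        int(hi),
                        call["region_id"],
                        call["type"],
                        _count_probes(panel, call["region_id"], int(lo), int(hi)),
                        "intersection",
                        float(np.mean([call["mean_lrr"], other["mean_lrr"]])),
                    )
                )
    inter = (
        pd.DataFrame(rows, columns=list(CALL_COLUMNS)).drop_duplicates(
            subset=["sample_id", "chrom", "start", "end", "type"]
        )
        if rows
        else empty_calls()
    )
    a_only = CallSet(a.caller, a.calls.loc[~a_hit].copy()) if len(a.calls) else CallSet(a.caller)
    b_only = CallSet(b.caller, b.calls.loc[~b_hit].copy()) if len(b.calls) else CallSet(b.caller)
    return CallSet("intersection", inter), a_only, b_only


def define_cnvrs(
    calls: CallSet, panel: ProbePanel, boundary: str = "union"
) -> list[CnvRegion]:
    """Merge overlapping same-type calls across samples into CNV regions.

    Within each pseudochromosome and type, connected components of the
    interval-overlap graph form one CNVR whose coordinates are the union
    span (default) or the common core (``boundary="intersection"``, using
    the component-wide overlap of member calls where it exists, else the
    union span).
    """
    if boundary not in ("union", "intersection"):
        raise ValueError("boundary must be union|intersection")
    out: list[CnvRegion] = []
    if not len(calls.calls):
        return out
    order = {rid: i for i, rid in enumerate(panel.region_ids)}
    unknown = set(calls.calls["region_id"]) - set(order)
    if unknown:
        raise ValueError(f"calls outside panel pseudochromosomes: {sorted(unknown)[:3]}")
    grouped = sorted(
        calls.calls.groupby(["region_id", "type"]),
        key=lambda kv: (order[kv[0][0]], kv[0][1]),
    )
    for (region_id, typ), sub in grouped:
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        comp_start = comp_end = None
        core_lo = core_hi = None
        members = 0
        k = sum(1 for r in out if r.region_id == region_id and r.type == typ)
        chrom = str(sub["chrom"].iloc[0])

        def emit():
            nonlocal k
            lo, hi = comp_start, comp_end
            if boundary == "intersection" and core_lo is not None and core_lo < core_hi:
                lo, hi = core_lo, core_hi
            out.append(
                CnvRegion(
                    cnvr_id=f"{region_id}_{typ}_{k}",
                    region_id=region_id,
                    chromosome=chrom,
                    start=int(lo),
                    end=int(hi),
                    type=typ,
                    source="merged",
                    n_carriers=members,
                )
            )
            k += 1

        for _, call in sub.iterrows():
            s, e = int(call["start"]), int(call["end"])
            if comp_start is None:
                comp_start, comp_end, core_lo, core_hi, members = s, e, s, e, 1
            elif s < comp_end:  # overlaps current component
                comp_end = max(comp_end, e)
                core_lo, core_hi = max(core_lo, s), min(core_hi, e)
                members += 1
            else:
                emit()
                comp_start, comp_end, core_lo, core_hi, members = s, e, s, e, 1
        if comp_start is not None:
            emit()
    return out


def carrier_matrix(
    cnvrs: list[CnvRegion],
    callsets: list[CallSet],
    panel: ProbePanel,
    min_reciprocal_overlap: float | None = None,
    sample_ids: list[str] | None = None,
) -> CarrierMatrix:
    """Per-sample carrier status for each CNVR, with caller provenance.

    A sample carries (region, type) iff it has a same-type call overlapping
    at least one probe of the region (default), or, when
    ``min_reciprocal_overlap`` is given, a call whose overlap covers at
    least that fraction of both the call and the region.  Provenance is
    "both" when supported by both callers (directly or via an intersection
    call set), else the single caller's name.
    """
    if sample_ids is None:
        sample_ids = sorted(
            {s for cs in callsets for s in cs.calls["sample_id"].unique()}
        )
    else:
        sample_ids = list(sample_ids)
    all_calls = pd.concat(
        [cs.calls for cs in callsets if len(cs.calls)], ignore_index=True
    ) if any(len(cs.calls) for cs in callsets) else empty_calls()

    status = pd.DataFrame(
        False,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[r.cnvr_id for r in cnvrs],
    )
    prov = pd.DataFrame("", index=status.index, columns=status.columns)

    for region in cnvrs:
        probes = panel.region_probes(region.region_id)
        pos0 = probes["pos"].to_numpy() - 1
        region_probes = pos0[(pos0 >= region.start) & (pos0 < region.end)]
        sub = all_calls[
            (all_calls["region_id"] == region.region_id)
            & (all_calls["type"] == region.type)
        ]
        for _, call in sub.iterrows():
            s, e = int(call["start"]), int(call["end"])
            if min_reciprocal_overlap is None:
                hit = bool(((region_probes >= s) & (region_probes < e)).any())
            else:
                ov = min(e, region.end) - max(s, region.start)
                hit = (
                    ov > 0
                    and ov >= min_reciprocal_overlap * (e - s)
                    and ov >= min_reciprocal_overlap * (region.end - region.start)
                )
            if not hit:
                continue
            sid = call["sample_id"]
            if sid not in status.index:
                continue  # e.g. sample excluded by QC
            status.at[sid, region.cnvr_id] = True
            caller = call["caller"]
            prev = prov.at[sid, region.cnvr_id]
            if caller == "intersection":
                new = "both"
            elif prev in ("", caller):
                new = caller
            else:
                new = "both"
            if prev != "both":
                prov.at[sid, region.cnvr_id] = new

    return CarrierMatrix(cnvrs, status, prov)
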