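"""Dual-caller intersection, CNVR definition, carrier matrix."""

import numpy as np
import pandas as pd
import pytest

from cnvpanel.consensus import carrier_matrix, define_cnvrs, intersect_calls
from cnvpanel.simulate import design_panel
from cnvpanel.types import CALL_COLUMNS, CallSet, RegionSpec, empty_calls


@pytest.fixture()
def panel():
    return design_panel(
        [
            RegionSpec("r0", "1", 1_000_000, 1_050_000, "loss"),
            RegionSpec("r1", "2", 2_000_000, 2_050_000, "gain"),
        ]
    )


def calls_df(rows):
    """rows: (sample_id, chrom, start, end, region_id, type, caller)"""
    return pd.DataFrame(
        [
            (s, c, st, en, rid, t, 5, caller, -0.5 if t == "loss" else 0.4)
            for s, c, st, en, rid, t, caller in rows
        ],
        columns=list(CALL_COLUMNS),
    )


class TestIntersectCalls:
    def test_identical_calls_intersect_to_same_interval(self):
        a = CallSet("hmm", calls_df([("s1", "1", 100, 200, "r0", "loss", "hmm")]))
        b = CallSet("segment", calls_df([("s1", "1", 100, 200, "r0", "loss", "segment")]))
        inter, a_only, b_only = intersect_calls(a, b)
        assert len(inter) == 1
        row = inter.calls.iloc[0]
        assert (row["start"], row["end"]) == (100, 200)
        assert row["caller"] == "intersection"
        assert len(a_only) == 0 and len(b_only) == 0

    def test_partial_overlap_yields_interval_intersection(self):
        a = CallSet("hmm", calls_df([("s1", "1", 100, 200, "r0", "loss", "hmm")]))
        b = CallSet("segment", calls_df([("s1", "1", 150, 300, "r0", "loss", "segment")]))
        inter, _, _ = intersect_calls(a, b)
        row = inter.calls.iloc[0]
        assert (row["start"], row["end"]) == (150, 200)

    def test_opposite_types_never_intersect(self):
        a = CallSet("hmm", calls_df([("s1", "1", 100, 200, "r0", "loss", "hmm")]))
        b = CallSet("segment", calls_df([("s1", "1", 100, 200, "r0", "gain", "segment")]))
        inter, a_only, b_only = intersect_calls(a, b)
        assert len(inter) == 0
        assert len(a_only) == 1 and len(b_only) == 1  # both survive caller-only

    def test_different_samples_never_intersect(self):
        a = CallSet("hmm", calls_df([("s1", "1", 100, 200, "r0", "loss", "hmm")]))
        b = CallSet("segment", calls_df([("s2", "1", 100, 200, "r0", "loss", "segment")]))
        inter, _, _ = intersect_calls(a, b)
        assert len(inter) == 0

    def test_intersection_never_larger_than_inputs(self, rng):
        def random_set(caller, n):
            rows = []
            for i in range(n):
                s = f"s{rng.integers(3)}"
                start = int(rng.integers(0, 500))
                end = start + int(rng.integers(1, 200))
                typ = "loss" if rng.random() < 0.5 else "gain"
                rows.append((s, "1", start, end, "r0", typ, caller))
            return CallSet(caller, calls_df(rows))

        def covered_bp(cs):
            out = {}
            for _, c in cs.calls.iterrows():
                key = (c["sample_id"], c["type"])
                ivs = out.setdefault(key, [])
                ivs.append((c["start"], c["end"]))
            total = {}
            for key, ivs in out.items():
                ivs.sort()
                bp, hi = 0, -1
                for s, e in ivs:
                    s = max(s, hi)
                    if e > s:
                        bp += e - s
                        hi = e
                    hi = max(hi, e)
                total[key] = bp
            return total

        for _ in range(20):
            a, b = random_set("hmm", 6), random_set("segment", 6)
            inter, _, _ = intersect_calls(a, b)
            ca, cb, ci = covered_bp(a), covered_bp(b), covered_bp(inter)
            for key, bp in ci.items():
                assert bp <= ca.get(key, 0)
                assert bp <= cb.get(key, 0)


class TestDefineCnvrs:
    def test_two_disjoint_clusters_make_two_regions(self, panel):
        calls = CallSet("hmm", calls_df([
            ("s1", "1", 1_000_000, 1_010_000, "r0", "loss", "hmm"),
            ("s2", "1", 1_005_000, 1_012_000, "r0", "loss", "hmm"),
            ("s3", "1", 1_030_000, 1_040_000, "r0", "loss", "hmm"),
        ]))
        cnvrs = define_cnvrs(calls, panel)
        assert len(cnvrs) == 2
        assert cnvrs[0].start == 1_000_000 and cnvrs[0].end == 1_012_000
        assert cnvrs[0].n_carriers == 2

    def test_overlapping_calls_union_span(self, panel):
        rows = [
            (f"s{i}", "1", 1_000_000 + 1000 * i, 1_020_000 + 1000 * i, "r0", "loss", "hmm")
            for i in range(5)
        ]
        cnvrs = define_cnvrs(CallSet("hmm", calls_df(rows)), panel)
        assert len(cnvrs) == 1
        assert cnvrs[0].start == 1_000_000
        assert cnvrs[0].end == 1_024_000

    def test_intersection_boundary_mode_gives_common_core(self, panel):
        rows = [
            ("s1", "1", 1_000_000, 1_020_000, "r0", "loss", "hmm"),
            ("s2", "1", 1_010_000, 1_030_000, "r0", "loss", "hmm"),
        ]
        core = define_cnvrs(CallSet("hmm", calls_df(rows)), panel, boundary="intersection")
        assert core[0].start == 1_010_000 and core[0].end == 1_020_000

    def test_types_kept_separate(self, panel):
        rows = [
            ("s1", "1", 1_000_000, 1_020_000, "r0", "loss", "hmm"),
            ("s2", "1", 1_000_000, 1_020_000, "r0", "gain", "hmm"),
        ]
        cnvrs = define_cnvrs(CallSet("hmm", calls_df(rows)), panel)
        assert len(cnvrs) == 2
        assert {r.type for r in cnvrs} == {"loss", "gain"}

    def test_empty_call_set_gives_no_regions(self, panel):
        assert define_cnvrs(CallSet("hmm", empty_calls()), panel) == []


class TestCarrierMatrix:
    def make(self, panel, rows, sample_ids=("s1", "s2", "s3")):
        calls = calls_df(rows)
        by_caller = {c: calls[calls["caller"] == c] for c in calls["caller"].unique()}
        callsets = [CallSet(c, df) for c, df in by_caller.items()]
        union = CallSet("mixed", calls)
        cnvrs = define_cnvrs(union, panel)
        return cnvrs, carrier_matrix(cnvrs, callsets, panel, sample_ids=list(sample_ids))

    def test_intersection_supported_carrier_has_both_provenance(self, panel):
        rows = [
            ("s1", "1", 1_000_000, 1_020_000, "r0", "loss", "hmm"),
            ("s1", "1", 1_000_000, 1_020_000, "r0", "loss", "segment"),
        ]
        cnvrs, matrix = self.make(panel, rows)
        cid = cnvrs[0].cnvr_id
        assert matrix.status.loc["s1", cid]
        assert matrix.provenance.loc["s1", cid] == "both"
        assert not matrix.status.loc["s2", cid]

    def test_call_overlapping_zero_probes_is_not_carrier(self, panel):
        # inside probes are spaced ~5.5 kb apart; a 1 kb call placed
        # between two of them overlaps the CNVR interval but no probe
        region = panel.region_probes("r0")
        inside = region.loc[region["role"] == "inside", "pos"].to_numpy()
        gap_start = int(inside[1]) + 1000  # 0-based, mid-gap
        rows = [
            ("s1", "1", 1_000_000, 1_030_000, "r0", "loss", "hmm"),
            ("s2", "1", gap_start, gap_start + 1000, "r0", "loss", "hmm"),
        ]
        assert inside[2] - 1 > gap_start + 1000, "gap must be probe-free"
        cnvrs, matrix = self.make(panel, rows)
        cid = cnvrs[0].cnvr_id
        assert matrix.status.loc["s1", cid]
        assert not matrix.status.loc["s2", cid]

    def test_empty_call_sets_give_all_false(self, panel):
        cnvrs, matrix = self.make(
            panel, [("s1", "1", 1_000_000, 1_020_000, "r0", "loss", "hmm")]
        )
        empty = carrier_matrix(cnvrs, [CallSet("hmm", empty_calls())], panel,
                               sample_ids=["s1", "s2"])
        assert not empty.status.to_numpy().any()

    def test_reciprocal_overlap_mode(self, panel):
        # 2 kb call inside a 24 kb region: probe rule says carrier,
        # 50% reciprocal overlap says not
        region = panel.region_probes("r0")
        inside = region.loc[region["role"] == "inside", "pos"].to_numpy()
        s = int(inside[1]) - 1
        rows = [
            ("s1", "1", 1_000_000, 1_024_000, "r0", "loss", "hmm"),
            ("s2", "1", s, s + 2000, "r0", "loss", "hmm"),
        ]
        calls = calls_df(rows)
        cnvrs = define_cnvrs(CallSet("hmm", calls), panel)
        cid = cnvrs[0].cnvr_id
        probe_rule = carrier_matrix(cnvrs, [CallSet("hmm", calls)], panel,
                                    sample_ids=["s1", "s2"])
        recip = carrier_matrix(cnvrs, [CallSet("hmm", calls)], panel,
                               min_reciprocal_overlap=0.5, sample_ids=["s1", "s2"])
        assert probe_rule.status.loc["s2", cid]
        assert not recip.status.loc["s2", cid]
        assert recip.status.loc["s1", cid]
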