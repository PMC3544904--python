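"""Exact Fisher statistics, odds ratios, stratification, selection rules."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from cnvpanel.association import (
    associate_regions,
    fisher_two_sided,
    results_frame,
    sample_odds_ratio,
    select_for_validation,
)
from cnvpanel.consensus import carrier_matrix
from cnvpanel.tables import recompute_statistics, study_regions
from cnvpanel.types import (
    CallSet,
    CarrierMatrix,
    CnvRegion,
    ContingencyTable,
    SelectionCriteria,
    empty_calls,
)


def fisher_enumeration_oracle(t: ContingencyTable) -> float:
    """Exact-rational enumeration of the point-probability two-sided p.

    Sums hypergeometric point probabilities (as exact fractions) of every
    table with the observed margins whose probability is <= the observed
    table's.  Independent of the log-gamma implementation.
    """
    m = t.a + t.b
    n = t.n_case + t.n_control
    denom = math.comb(n, m)
    lo, hi = max(0, m - t.n_control), min(m, t.n_case)
    pmf = {
        k: Fraction(math.comb(t.n_case, k) * math.comb(t.n_control, m - k), denom)
        for k in range(lo, hi + 1)
    }
    obs = pmf[t.a]
    return float(sum(p for p in pmf.values() if p <= obs))


def table(a, n_case, b, n_control):
    return ContingencyTable(a=a, c=n_case - a, b=b, d=n_control - b)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "a,n_case,b,n_control,expected",
        [
            (2, 1544, 0, 5762, 4.46e-2),  # rare deletion seen in 2 cases only
            (1, 1544, 0, 5762, 2.11e-1),  # singleton case carrier
            (4, 1542, 1, 5755, 8.26e-3),  # NRXN1-promoter deletion counts
            (60, 1544, 50, 5762, 1.01e-14),
        ],
    )
    def test_published_counts_reproduce_printed_p(self, a, n_case, b, n_control, expected):
        p = fisher_two_sided(table(a, n_case, b, n_control))
        assert f"{p:.2e}" == f"{expected:.2e}"

    def test_no_carriers_anywhere_gives_one(self):
        assert fisher_two_sided(table(0, 10, 0, 20)) == 1.0

    def test_matches_enumeration_oracle_on_small_margins(self, rng):
        for _ in range(300):
            n_case = int(rng.integers(1, 30))
            n_control = int(rng.integers(1, 30))
            a = int(rng.integers(0, n_case + 1))
            b = int(rng.integers(0, n_control + 1))
            t = table(a, n_case, b, n_control)
            assert fisher_two_sided(t) == pytest.approx(
                fisher_enumeration_oracle(t), rel=1e-9
            )

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(100):
            n_case = int(rng.integers(1, 2000))
            n_control = int(rng.integers(1, 6000))
            a = int(rng.integers(0, min(n_case, 40)))
            b = int(rng.integers(0, min(n_control, 40)))
            t = table(a, n_case, b, n_control)
            _, p_scipy = fisher_exact([[t.a, t.b], [t.c, t.d]])
            assert fisher_two_sided(t) == pytest.approx(p_scipy, rel=1e-6)

    def test_label_swap_symmetry(self, rng):
        # swapping case/control together with carrier/non-carrier labels
        # transposes the table twice; p must be invariant
        for _ in range(50):
            t = table(int(rng.integers(0, 20)), 50, int(rng.integers(0, 30)), 80)
            swapped = ContingencyTable(a=t.c, c=t.a, b=t.d, d=t.b)
            assert fisher_two_sided(t) == pytest.approx(
                fisher_two_sided(swapped), rel=1e-9
            )

    def test_monotone_toward_tail_at_fixed_margins(self):
        # margins: 10 carriers over 50 cases / 100 controls; moving carrier
        # mass into cases beyond the expectation shrinks p monotonically
        expected_a = 10 * 50 / 150
        ps = [
            fisher_two_sided(ContingencyTable(a=a, c=50 - a, b=10 - a, d=100 - (10 - a)))
            for a in range(int(np.ceil(expected_a)), 11)
        ]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestSampleOddsRatio:
    def test_published_counts_reproduce_printed_ors(self):
        orr, degen = sample_odds_ratio(table(4, 1542, 1, 5755))
        assert round(orr, 2) == 14.96 and not degen
        orr, _ = sample_odds_ratio(table(2, 1544, 2, 5762))
        assert round(orr, 2) == 3.74

    def test_equal_proportions_give_one(self):
        orr, degen = sample_odds_ratio(table(5, 50, 10, 100))
        assert orr == pytest.approx(1.0) and not degen

    def test_control_free_carrier_is_infinite(self):
        orr, degen = sample_odds_ratio(table(3, 100, 0, 200))
        assert math.isinf(orr) and not degen

    def test_case_free_carrier_is_zero(self):
        orr, degen = sample_odds_ratio(table(0, 100, 3, 200))
        assert orr == 0.0 and not degen

    def test_no_carriers_flagged_degenerate(self):
        orr, degen = sample_odds_ratio(table(0, 10, 0, 10))
        assert orr == 1.0 and degen

    def test_all_carriers_flagged_degenerate(self):
        _, degen = sample_odds_ratio(table(10, 10, 5, 10))
        assert degen


class TestStudyTableReproduction:
    def test_all_reproducible_rows_match(self):
        df = recompute_statistics()
        # every printed OR except the single discordant row
        assert (~df["or_match"] & ~df["discordant_or"]).sum() == 0
        assert df["discordant_or"].sum() == 1
        # every printed p with a known sidedness
        known = df["p_sided"] != "none"
        assert df.loc[known, "p_match"].all()
        assert (~known).sum() == 2

    def test_table_shape(self):
        df = study_regions()
        assert len(df) == 56
        assert (df["case_carriers"] <= df["n_case"]).all()


def planted_matrix(statuses, chromosome="2"):
    """CarrierMatrix with one loss region and given per-sample status."""
    region = CnvRegion("cnvr1", "r0", chromosome, 100, 200, "loss", "merged")
    idx = pd.Index([f"s{i}" for i in range(len(statuses))], name="sample_id")
    status = pd.DataFrame({"cnvr1": statuses}, index=idx)
    prov = pd.DataFrame(
        {"cnvr1": ["both" if s else "" for s in statuses]}, index=idx
    )
    return CarrierMatrix([region], status, prov)


def phenotypes_for(n_cases, n_controls, sexes=None):
    n = n_cases + n_controls
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "sex": sexes if sexes is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "batch": 0,
        }
    )


class TestAssociateRegions:
    def test_planted_exact_counts_recover_published_table(self):
        # plant exactly 4 case and 1 control carriers in a 1542/5755 cohort
        statuses = [True] * 4 + [False] * 1538 + [True] + [False] * 5754
        matrix = planted_matrix(statuses)
        pheno = phenotypes_for(1542, 5755)
        res = associate_regions(matrix, pheno)
        assert len(res) == 1
        r = res[0]
        assert (r.table.a, r.table.c, r.table.b, r.table.d) == (4, 1538, 1, 5754)
        assert round(r.odds_ratio, 2) == 14.96
        assert f"{r.p_value:.2e}" == "8.26e-03"

    def test_x_region_produces_sex_strata(self):
        statuses = [True] * 2 + [False] * 98
        matrix = planted_matrix(statuses, chromosome="X")
        pheno = phenotypes_for(40, 60)
        res = associate_regions(matrix, pheno)
        strata = {r.sex_stratum for r in res}
        assert strata == {"all", "male", "female"}

    def test_all_male_x_region_flags_empty_female_stratum(self):
        statuses = [True] * 2 + [False] * 38
        matrix = planted_matrix(statuses, chromosome="X")
        pheno = phenotypes_for(20, 20, sexes=["M"] * 40)
        res = associate_regions(matrix, pheno)
        female = next(r for r in res if r.sex_stratum == "female")
        assert female.degenerate

    def test_excluded_samples_dropped_from_counts(self):
        statuses = [True] * 3 + [False] * 97
        matrix = planted_matrix(statuses)
        pheno = phenotypes_for(50, 50)
        res = associate_regions(matrix, pheno, exclude={"s0"})
        assert res[0].table.a == 2
        assert res[0].table.n_case == 49


class TestSelectForValidation:
    def make_result(self, a, n_case, b, n_control):
        matrix = planted_matrix(
            [True] * a + [False] * (n_case - a) + [True] * b + [False] * (n_control - b)
        )
        pheno = phenotypes_for(n_case, n_control)
        return associate_regions(matrix, pheno), matrix, pheno

    def test_high_or_with_enough_carriers_selected(self):
        res, m, p = self.make_result(4, 1542, 1, 5755)
        out = select_for_validation(res, matrix=m, phenotypes=p)
        assert out[0].selected_for_validation
        assert 0 < len(out[0].validation_samples) <= 6

    def test_boundary_or_exactly_two_is_inclusive(self):
        # a=2,c=98, b=1,d=98 -> OR = (2*98)/(1*98) = 2.0 exactly
        res, m, p = self.make_result(2, 100, 1, 99)
        out = select_for_validation(res, matrix=m, phenotypes=p)
        assert out[0].odds_ratio == pytest.approx(2.0)
        assert out[0].selected_for_validation

    def test_single_case_carrier_fails_and_gate(self):
        res, m, p = self.make_result(1, 100, 0, 100)
        out = select_for_validation(res, matrix=m, phenotypes=p)
        assert not out[0].selected_for_validation

    def test_or_gate_mode_admits_single_carrier(self):
        res, m, p = self.make_result(1, 100, 0, 100)
        crit = SelectionCriteria(combine="or")
        out = select_for_validation(res, crit, m, p)
        assert out[0].selected_for_validation

    def test_at_most_six_samples_listed_with_both_priority(self):
        n_case, n_control = 100, 100
        statuses = [True] * 8 + [False] * 92 + [True] * 1 + [False] * 99
        region = CnvRegion("cnvr1", "r0", "2", 100, 200, "loss", "merged")
        idx = pd.Index([f"s{i}" for i in range(200)], name="sample_id")
        status = pd.DataFrame({"cnvr1": statuses}, index=idx)
        prov_vals = []
        for i, s in enumerate(statuses):
            prov_vals.append(("both" if i % 2 == 0 else "hmm") if s else "")
        prov = pd.DataFrame({"cnvr1": prov_vals}, index=idx)
        matrix = CarrierMatrix([region], status, prov)
        pheno = phenotypes_for(n_case, n_control)
        res = associate_regions(matrix, pheno)
        out = select_for_validation(res, matrix=matrix, phenotypes=pheno)
        samples = out[0].validation_samples
        assert len(samples) == 6
        # dual-caller carriers (even indices) come first
        both = [s for s in samples if int(s[1:]) % 2 == 0]
        assert samples[: len(both)] == tuple(both)

    def test_results_frame_renders_inf_and_bonferroni(self):
        res, m, p = self.make_result(2, 100, 0, 100)
        df = results_frame(select_for_validation(res, matrix=m, phenotypes=p))
        assert df.loc[0, "odds_ratio"] == "inf"
        assert df.loc[0, "p_bonferroni"] >= df.loc[0, "p_value"]
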