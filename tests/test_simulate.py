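"""Synthetic cohort generator: panel rules, carrier draws, intensity model."""

import numpy as np
import pandas as pd
import pytest

from cnvpanel.simulate import (
    assign_carriers,
    design_panel,
    sample_phenotypes,
    simulate_cohort,
    simulate_intensities,
)
from cnvpanel.types import CohortDesign, RegionSpec

from conftest import make_specs


def spec(region_id="r", chrom="1", start=1_000_000, width=10_000, typ="loss", **kw):
    return RegionSpec(region_id, chrom, start, start + width - 1, typ, **kw)


class TestDesignPanel:
    def test_probe_counts_and_monotone_positions(self):
        panel = design_panel([spec(width=10_000)])
        assert len(panel) == 20  # 10 inside + 5 + 5 flanks
        probes = panel.probes
        assert probes["pos"].is_monotonic_increasing
        assert (probes["role"] == "inside").sum() == 10
        assert (probes["role"] == "flank").sum() == 10
        inside = probes[probes["role"] == "inside"]["pos"]
        assert inside.min() >= 1_000_000 and inside.max() <= 1_009_999

    def test_study_scale_panel(self):
        # 363 regions across the autosomes, one pseudochromosome each
        specs = [
            spec(f"cnvr{i}", str(i % 22 + 1), 1_000_000 + 400_000 * (i // 22), 60_000)
            for i in range(363)
        ]
        panel = design_panel(specs)
        assert len(panel.region_ids) == 363
        assert len(panel) >= 363 * 20

    def test_adjacent_regions_flanks_do_not_interleave(self):
        a = spec("a", start=1_000_000, width=20_000)
        b = spec("b", start=1_022_000, width=20_000)  # 2 kb gap
        panel = design_panel([a, b])
        labels = panel.probes.sort_values("pos")["region_id"].tolist()
        # label runs must be contiguous: once we leave 'a' we never return
        first_b = labels.index("b")
        assert all(lab == "a" for lab in labels[:first_b])
        assert all(lab == "b" for lab in labels[first_b:])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            design_panel([spec("a", start=100_000), spec("b", start=104_000)])

    def test_region_too_short_for_probes_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            design_panel([spec(width=5)])

    def test_telomeric_region_truncates_left_flank(self):
        panel = design_panel([spec(start=10, width=10_000)])
        probes = panel.probes
        assert (probes["pos"] >= 1).all()
        # right flank unaffected
        right = probes[probes["pos"] > 10_009]
        assert len(right) == 5

    def test_flank_window_fraction_configurable(self):
        narrow = design_panel([spec(width=40_000)], flank_fraction=0.1)
        wide = design_panel([spec(width=40_000)], flank_fraction=0.5)
        span = lambda p: p.probes["pos"].max() - p.probes["pos"].min()
        assert span(wide) > span(narrow)


class TestAssignCarriers:
    def test_zero_frequency_no_carriers(self):
        design = CohortDesign(n_cases=50, n_controls=50, rng_seed=1)
        truth = assign_carriers(design, [spec(case_carrier_freq=0, control_carrier_freq=0)])
        assert (truth.cn.to_numpy() == 2).all()

    def test_full_frequency_all_carriers(self):
        design = CohortDesign(n_cases=20, n_controls=20, rng_seed=1)
        truth = assign_carriers(
            design, [spec(case_carrier_freq=1.0, control_carrier_freq=1.0)]
        )
        assert (truth.cn.to_numpy() == 1).all()  # loss carriers at CN1

    def test_rare_frequency_counts_within_binomial_interval(self):
        # carrier frequencies of the rarest reported deletion: expectation
        # 4 case / 1 control carriers; 99.9% binomial interval check
        design = CohortDesign(n_cases=1542, n_controls=5755, rng_seed=5)
        truth = assign_carriers(
            design,
            [spec(case_carrier_freq=4 / 1542, control_carrier_freq=1 / 5755)],
        )
        pheno = sample_phenotypes(design)
        carriers = truth.cn.iloc[:, 0].to_numpy() != 2
        n_case_carriers = carriers[: design.n_cases].sum()
        n_ctrl_carriers = carriers[design.n_cases:].sum()
        assert 0 <= n_case_carriers <= 14  # P(X>14 | mean 4) < 1e-4
        assert 0 <= n_ctrl_carriers <= 9
        assert len(pheno) == 1542 + 5755

    def test_carrier_frequency_recovery_large_n(self):
        design = CohortDesign(n_cases=5000, n_controls=5000, rng_seed=9)
        truth = assign_carriers(
            design, [spec(case_carrier_freq=0.1, control_carrier_freq=0.1)]
        )
        rate = (truth.cn.to_numpy() != 2).mean()
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(rate - 0.1) < 3 * se

    def test_x_region_sex_baselines(self):
        design = CohortDesign(n_cases=200, n_controls=200, rng_seed=3)
        pheno = sample_phenotypes(design)
        truth = assign_carriers(
            design,
            [spec(chrom="X", case_carrier_freq=0.5, control_carrier_freq=0.5)],
            pheno,
        )
        cn = truth.cn.iloc[:, 0]
        males = pheno.set_index("sample_id")["sex"] == "M"
        assert set(cn[males.to_numpy()]) <= {0, 1}   # baseline 1, loss carrier 0
        assert set(cn[~males.to_numpy()]) <= {1, 2}  # baseline 2, loss carrier 1


class TestSimulateIntensities:
    def _noise_free(self, **kw):
        return CohortDesign(
            n_cases=10, n_controls=10, noise_sd_lrr=0.0, baf_noise_sd=0.0,
            batch_count=1, rng_seed=2, **kw,
        )

    def test_noise_free_cn2_gives_zero_lrr(self):
        design = self._noise_free()
        s = [spec(case_carrier_freq=0, control_carrier_freq=0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        assert np.allclose(data.lrr.to_numpy(), 0.0)

    def test_noise_free_deletion_hits_inside_probes_only(self):
        design = self._noise_free()
        s = [spec(case_carrier_freq=1.0, control_carrier_freq=1.0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        inside = panel.probes["role"].to_numpy() == "inside"
        lrr = data.lrr.to_numpy()
        assert np.allclose(lrr[:, inside], -0.66)
        assert np.allclose(lrr[:, ~inside], 0.0)  # flanks stay diploid

    def test_duplication_mean_recovers_configured_level(self):
        design = CohortDesign(n_cases=300, n_controls=300, noise_sd_lrr=0.15,
                              batch_count=1, rng_seed=4)
        s = [spec(typ="gain", case_carrier_freq=1.0, control_carrier_freq=1.0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        inside = panel.probes["role"].to_numpy() == "inside"
        vals = data.lrr.to_numpy()[:, inside]
        se = 0.15 / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.4) < 3 * se

    def test_male_x_baseline_lrr(self):
        design = self._noise_free()
        s = [spec(chrom="X", case_carrier_freq=0, control_carrier_freq=0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        males = (pheno["sex"] == "M").to_numpy()
        if males.any():
            assert np.allclose(data.lrr.to_numpy()[males], -0.66)
        if (~males).any():
            assert np.allclose(data.lrr.to_numpy()[~males], 0.0)

    def test_batch_offsets_shift_lrr(self):
        design = CohortDesign(n_cases=100, n_controls=100, noise_sd_lrr=0.0,
                              baf_noise_sd=0.0, batch_count=2,
                              batch_effect_sd=0.3, rng_seed=6)
        s = [spec(case_carrier_freq=0, control_carrier_freq=0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        by_batch = data.lrr.mean(axis=1).groupby(pheno.set_index("sample_id")["batch"]).mean()
        assert len(by_batch) == 2
        assert abs(by_batch.iloc[0] - by_batch.iloc[1]) > 0.01

    def test_unknown_copy_number_rejected(self, small_cohort):
        panel, pheno, truth, data, design, specs = small_cohort
        bad = truth.cn.copy()
        with pytest.raises(ValueError):
            bad.iloc[0, 0] = 7
            from cnvpanel.types import TruthTable

            simulate_intensities(panel, TruthTable(bad), design, pheno)

    def test_baf_respects_copy_number_clusters(self):
        design = CohortDesign(n_cases=400, n_controls=400, noise_sd_lrr=0.0,
                              baf_noise_sd=0.0, batch_count=1, rng_seed=8)
        s = [spec(typ="gain", case_carrier_freq=1.0, control_carrier_freq=1.0)]
        panel, pheno, truth, data = simulate_cohort(design, s)
        inside = panel.probes["role"].to_numpy() == "inside"
        baf = np.round(data.baf.to_numpy()[:, inside], 6)
        assert set(np.unique(baf)) <= {0.0, round(1 / 3, 6), round(2 / 3, 6), 1.0}


def test_determinism_bit_identical(small_cohort):
    panel, pheno, truth, data, design, specs = small_cohort
    panel2, pheno2, truth2, data2 = simulate_cohort(design, specs)
    pd.testing.assert_frame_equal(truth.cn, truth2.cn)
    pd.testing.assert_frame_equal(data.lrr, data2.lrr)
    pd.testing.assert_frame_equal(data.baf, data2.baf)
    pd.testing.assert_frame_equal(pheno, pheno2)
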