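import numpy as np
import pytest

from cnvpanel.simulate import simulate_cohort
from cnvpanel.types import CohortDesign, RegionSpec


def make_specs(n_regions=6, case_freq=0.10, control_freq=0.03, with_x=True,
               width=50_000, n_inside=10):
    """Alternating loss/gain regions spread over four autosomes (+ one X)."""
    specs = [
        RegionSpec(
            f"r{i}",
            str(i % 4 + 1),
            2_000_000 * (i + 1),
            2_000_000 * (i + 1) + width,
            "loss" if i % 2 else "gain",
            case_carrier_freq=case_freq,
            control_carrier_freq=control_freq,
            n_probes_inside=n_inside,
        )
        for i in range(n_regions)
    ]
    if with_x:
        specs.append(
            RegionSpec("rx", "X", 5_000_000, 5_000_000 + width, "loss",
                       case_freq, control_freq, n_probes_inside=n_inside)
        )
    return specs


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample cohort over 7 regions, reused by read-only tests."""
    design = CohortDesign(n_cases=40, n_controls=80, rng_seed=11)
    specs = make_specs()
    return simulate_cohort(design, specs) + (design, specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
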