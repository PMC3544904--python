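"""Build the study-emulating synthetic cohort.

Creates a targeted panel with one pseudochromosome per published CNV
region (carrier frequencies taken from the printed carrier counts) and
simulates LRR/BAF intensities for a cohort at one eighth of the study's
sample size.  The per-sample matrices are bulky intermediates and land
under scratch/cohort/; later drivers read them from there.
"""

from pathlib import Path

from cnvpanel import io
from cnvpanel.evaluate import study_emulation_specs
from cnvpanel.simulate import simulate_cohort
from cnvpanel.types import CohortDesign

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    specs = study_emulation_specs()
    design = CohortDesign(n_cases=193, n_controls=720, rng_seed=SEED)
    panel, phenotypes, truth, data = simulate_cohort(design, specs)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_manifest(panel, OUT / "panel.tsv")
    io.write_phenotypes(phenotypes, OUT / "phenotypes.tsv")
    io.write_truth(truth, OUT / "truth.tsv")
    io.write_intensities(data, str(OUT / "intensities"))

    n_carriers = (truth.cn != 2).to_numpy().sum()
    print(f"panel: {len(panel)} probes over {len(panel.region_ids)} pseudochromosomes")
    print(f"cohort: {design.n_cases} cases / {design.n_controls} controls, seed {SEED}")
    print(f"planted carrier events (CN != 2, incl. male X baseline): {n_carriers}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
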