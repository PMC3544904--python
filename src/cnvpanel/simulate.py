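"""Synthetic targeted-array cohorts: probe panels, carriers, LRR/BAF.

The generator emulates a custom genotyping array that tiles a set of known
CNV regions (>=10 probes inside each region, 5 on each flank) and the
case/control intensity data such an array produces: per-probe Log-R-Ratio
values drawn around copy-number-dependent means, B-allele frequencies drawn
from copy-number-dependent genotype mixtures, additive per-batch LRR
offsets, and male X hemizygosity.  Each region plus its flanks forms one
"pseudochromosome" so downstream callers never bridge unprobed gaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    LRR_MEANS,
    CohortDesign,
    IntensityDataset,
    ProbePanel,
    RegionSpec,
    TruthTable,
    baseline_copy_number,
)

__all__ = [
    "design_panel",
    "sample_phenotypes",
    "assign_carriers",
    "simulate_intensities",
    "simulate_cohort",
]


def _uniform_positions(lo: int, hi: int, n: int) -> np.ndarray:
    """n strictly increasing integer positions spread uniformly over [lo, hi]."""
    if n <= 0:
        return np.array([], dtype=np.int64)
    if hi - lo + 1 < n:
        raise ValueError(
            f"window [{lo},{hi}] too short for {n} probes at 1-bp spacing"
        )
    pos = np.unique(np.round(np.linspace(lo, hi, n)).astype(np.int64))
    # rounding can collapse neighbours; fall back to exact integer spreading
    while len(pos) < n:
        missing = n - len(pos)
        gaps = np.setdiff1d(np.arange(lo, hi + 1, dtype=np.int64), pos)
        pos = np.sort(np.concatenate([pos, gaps[:missing]]))
    return pos


def design_panel(
    region_specs: list[RegionSpec],
    rng_seed: int | None = None,
    flank_fraction: float = 0.25,
) -> ProbePanel:
    """Tile each region with uniformly spaced probes plus flanking probes.

    Each region receives ``n_probes_inside`` probes spread over
    ``[start_bp, end_bp]`` and ``n_probes_flank`` probes on each side over a
    flank window of ``flank_fraction`` times the region width (at least
    ``n_probes_flank`` bp).  Flank windows are clipped at the midpoint
    between adjacent regions so flank probes never interleave across region
    boundaries, and truncated at position 1 (telomere rule) where a left
    flank would run off the chromosome.  Flank probes carry their region's
    pseudochromosome label.  Deterministic; ``rng_seed`` is accepted for
    interface symmetry with the stochastic generators.
    """
    del rng_seed  # construction is deterministic
    by_chrom: dict[str, list[RegionSpec]] = {}
    for spec in region_specs:
        by_chrom.setdefault(spec.chromosome, []).append(spec)

    rows: list[tuple] = []
    for chrom, specs in by_chrom.items():
        specs = sorted(specs, key=lambda s: s.start_bp)
        for prev, nxt in zip(specs, specs[1:]):
            if nxt.start_bp <= prev.end_bp:
                raise ValueError(
                    f"regions {prev.region_id} and {nxt.region_id} overlap on chrom {chrom}"
                )
        for i, spec in enumerate(specs):
            flank_w = max(int(round(flank_fraction * spec.width)), spec.n_probes_flank)
            left_lo = spec.start_bp - flank_w
            left_hi = spec.start_bp - 1
            right_lo = spec.end_bp + 1
            right_hi = spec.end_bp + flank_w
            if i > 0:
                mid = (specs[i - 1].end_bp + spec.start_bp) // 2
                left_lo = max(left_lo, mid + 1)
            if i + 1 < len(specs):
                mid = (spec.end_bp + specs[i + 1].start_bp) // 2
                right_hi = min(right_hi, mid)
            left_lo = max(left_lo, 1)  # telomere truncation

            n_left = min(spec.n_probes_flank, max(left_hi - left_lo + 1, 0))
            n_right = min(spec.n_probes_flank, max(right_hi - right_lo + 1, 0))
            inside = _uniform_positions(spec.start_bp, spec.end_bp, spec.n_probes_inside)
            left = _uniform_positions(left_lo, left_hi, n_left) if n_left else np.array([], dtype=np.int64)
            right = _uniform_positions(right_lo, right_hi, n_right) if n_right else np.array([], dtype=np.int64)

            for k, p in enumerate(left):
                rows.append((f"{spec.region_id}_lf{k}", chrom, int(p), spec.region_id, "flank"))
            for k, p in enumerate(inside):
                rows.append((f"{spec.region_id}_in{k}", chrom, int(p), spec.region_id, "inside"))
            for k, p in enumerate(right):
                rows.append((f"{spec.region_id}_rf{k}", chrom, int(p), spec.region_id, "flank"))

    df = pd.DataFrame(rows, columns=list(ProbePanel.COLUMNS))
    return ProbePanel(df)


def sample_phenotypes(design: CohortDesign) -> pd.DataFrame:
    """Deterministically seeded sample sheet: status, sex, batch.

    Sample ids are ``case_0001`` / ``ctrl_0001`` style; sexes are drawn from
    the per-group male fractions and batches uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 0]))
    n = design.n_cases + design.n_controls
    width = max(4, len(str(n)))
    ids = [f"case_{i:0{width}d}" for i in range(design.n_cases)] + [
        f"ctrl_{i:0{width}d}" for i in range(design.n_controls)
    ]
    status = ["case"] * design.n_cases + ["control"] * design.n_controls
    male_p = np.concatenate(
        [
            np.full(design.n_cases, design.male_fraction_cases),
            np.full(design.n_controls, design.male_fraction_controls),
        ]
    )
    sex = np.where(rng.random(n) < male_p, "M", "F")
    batch = rng.integers(0, design.batch_count, size=n)
    return pd.DataFrame(
        {"sample_id": ids, "status": status, "sex": sex, "batch": batch}
    )


def _carrier_copy_number(cnv_type: str, chromosome: str, sex: str) -> int:
    base = baseline_copy_number(chromosome, sex)
    return base - 1 if cnv_type == "loss" else base + 1


def assign_carriers(
    design: CohortDesign,
    specs: list[RegionSpec],
    phenotypes: pd.DataFrame | None = None,
) -> TruthTable:
    """Draw carrier status independently per sample x region.

    Each sample carries a region's CNV with its group's frequency; carriers
    get CN 1 (loss) or 3 (gain) on autosomes, shifted by the sex baseline
    on X (male baseline CN is 1).  Reproducible given ``design.rng_seed``.
    """
    if phenotypes is None:
        phenotypes = sample_phenotypes(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 1]))
    n = len(phenotypes)
    is_case = (phenotypes["status"] == "case").to_numpy()
    sexes = phenotypes["sex"].to_numpy()

    cn = np.empty((n, len(specs)), dtype=np.int64)
    for j, spec in enumerate(specs):
        freq = np.where(is_case, spec.case_carrier_freq, spec.control_carrier_freq)
        carrier = rng.random(n) < freq
        base = np.array(
            [baseline_copy_number(spec.chromosome, s) for s in sexes], dtype=np.int64
        )
        shift = -1 if spec.cnv_type == "loss" else 1
        cn[:, j] = np.where(carrier, base + shift, base)
    frame = pd.DataFrame(
        cn, index=pd.Index(phenotypes["sample_id"], name="sample_id"),
        columns=[s.region_id for s in specs],
    )
    return TruthTable(frame)


def _baf_for_copies(rng: np.random.Generator, cn: np.ndarray, p_b: np.ndarray,
                    noise_sd: float) -> np.ndarray:
    """Draw BAF for integer copy numbers with per-probe B-allele freq p_b.

    Each of the cn allele copies is B with probability p_b (Hardy-Weinberg
    at CN2); BAF = (#B / cn) + noise, truncated to [0,1].  CN0 has no
    genotype signal: BAF is uniform noise.
    """
    out = np.empty(cn.shape, dtype=float)
    zero = cn == 0
    out[zero] = rng.random(zero.sum())
    nz = ~zero
    b_copies = rng.binomial(cn[nz], p_b[nz])
    out[nz] = b_copies / cn[nz] + rng.normal(0.0, noise_sd, nz.sum())
    return np.clip(out, 0.0, 1.0)


def simulate_intensities(
    panel: ProbePanel,
    truth: TruthTable,
    design: CohortDesign,
    phenotypes: pd.DataFrame | None = None,
) -> IntensityDataset:
    """Generate LRR/BAF matrices consistent with a truth table.

    Probes inside a carried region take the carrier copy number; flank
    probes always reflect the sex baseline.  LRR ~ Normal(mean[CN] + batch
    offset, noise_sd_lrr) with batch offsets ~ Normal(0, batch_effect_sd)
    when ``batch_count > 1``.
    """
    if phenotypes is None:
        phenotypes = sample_phenotypes(design)
    pheno = phenotypes.set_index("sample_id")
    missing = set(truth.sample_ids) - set(pheno.index)
    if missing:
        raise ValueError(f"{len(missing)} truth samples lack phenotypes")
    unknown = set(truth.region_ids) - set(panel.region_ids)
    if unknown:
        raise ValueError(f"truth covers regions not in panel: {sorted(unknown)[:3]}")

    rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 2]))
    probes = panel.probes
    n_samples = len(truth.sample_ids)
    n_probes = len(probes)
    sexes = pheno.loc[truth.sample_ids, "sex"].to_numpy()
    batches = pheno.loc[truth.sample_ids, "batch"].to_numpy()

    # per-probe copy number matrix from the truth table
    cn = np.empty((n_samples, n_probes), dtype=np.int64)
    base_auto = np.full(n_samples, 2, dtype=np.int64)
    base_x = np.where(sexes == "M", 1, 2).astype(np.int64)
    region_cn = truth.cn.loc[truth.sample_ids]
    for j in range(n_probes):
        chrom = probes.at[j, "chrom"]
        base = base_x if chrom == "X" else base_auto
        if probes.at[j, "role"] == "inside":
            cn[:, j] = region_cn[probes.at[j, "region_id"]].to_numpy()
        else:
            cn[:, j] = base
    if cn.min() < 0 or cn.max() > 4:
        raise ValueError("copy number outside supported range 0..4")

    means = np.array([LRR_MEANS[k] for k in range(5)])
    lrr = means[cn]
    if design.batch_count > 1:
        offsets = rng.normal(0.0, design.batch_effect_sd, design.batch_count)
        lrr = lrr + offsets[batches][:, None]
    if design.noise_sd_lrr > 0:
        lrr = lrr + rng.normal(0.0, design.noise_sd_lrr, lrr.shape)

    p_b = rng.uniform(0.05, 0.95, n_probes)  # per-probe B allele frequency
    baf = _baf_for_copies(
        rng, cn, np.broadcast_to(p_b, cn.shape), design.baf_noise_sd
    )

    cols = pd.Index(probes["probe_id"], name="probe_id")
    idx = pd.Index(truth.sample_ids, name="sample_id")
    return IntensityDataset(
        lrr=pd.DataFrame(lrr, index=idx, columns=cols),
        baf=pd.DataFrame(baf, index=idx, columns=cols),
        phenotypes=phenotypes,
    )


def simulate_cohort(
    design: CohortDesign,
    specs: list[RegionSpec],
    flank_fraction: float = 0.25,
) -> tuple[ProbePanel, pd.DataFrame, TruthTable, IntensityDataset]:
    """Convenience wrapper: panel + phenotypes + truth + intensities."""
    panel = design_panel(specs, flank_fraction=flank_fraction)
    phenotypes = sample_phenotypes(design)
    truth = assign_carriers(design, specs, phenotypes)
    data = simulate_intensities(panel, truth, design, phenotypes)
    return panel, phenotypes, truth, data
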