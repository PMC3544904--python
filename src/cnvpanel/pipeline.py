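"""End-to-end orchestration: simulate -> preprocess -> call x2 -> consensus
-> QC -> associate -> select -> report.

``run_pipeline`` is deterministic: every random draw flows from the config
seed, writers sort and format stably, and a run manifest records the seed,
a hash of the configuration and the package version, so identical configs
produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .association import (
    associate_regions,
    manhattan_plot,
    results_frame,
    select_for_validation,
)
from .consensus import carrier_matrix, define_cnvrs, intersect_calls
from .hmm import HmmModel, call_hmm
from .preprocess import LogRatioMatrix, PcaCorrector
from .qc import filter_excessive_calls, qc_report_frame, read_exclusion_list
from .segment import SegmentationConfig, call_segments
from .simulate import simulate_cohort
from .types import (
    CallSet,
    CohortDesign,
    IntensityDataset,
    ProbePanel,
    RegionSpec,
    SelectionCriteria,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("cnvpanel")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs.

    Either ``design``+``region_specs`` (simulate a cohort) or the three
    input paths (``manifest``/``intensities_prefix``/``phenotypes``) must
    be provided.
    """

    out_dir: str = "cnvpanel_out"
    seed: int = 0
    # simulated-cohort route
    design: CohortDesign | None = None
    region_specs: list[RegionSpec] = field(default_factory=list)
    # real-data route
    manifest: str | None = None
    intensities_prefix: str | None = None
    phenotypes: str | None = None
    # stages; PCA off by default — on a targeted panel the leading PCs can
    # carry rare-CNV signal rather than batch structure (see methods note)
    pca_components: int = 0
    hmm_model: HmmModel | None = None
    hmm_min_probes: int = 3
    segmentation: SegmentationConfig | None = None
    qc_mad_k: float = 5.0
    exclusion_list: str | None = None
    selection: SelectionCriteria | None = None
    make_plot: bool = False

    def validate(self) -> None:
        simulated = self.design is not None and self.region_specs
        from_files = self.manifest and self.intensities_prefix and self.phenotypes
        if not simulated and not from_files:
            raise ValueError(
                "config needs either a simulator design with region specs "
                "or manifest/intensities/phenotypes paths"
            )
        for p in (self.manifest, self.intensities_prefix and f"{self.intensities_prefix}.lrr.tsv", self.phenotypes, self.exclusion_list):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if hasattr(o, "tolist"):
                return o.tolist()
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # hash the analysis, not its destination
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    panel: ProbePanel
    data: IntensityDataset
    hmm_calls: CallSet
    segment_calls: CallSet
    intersection_calls: CallSet
    cnvrs: list
    results: pd.DataFrame
    excluded: set[str]


def _load_inputs(config: PipelineConfig):
    if config.design is not None and config.region_specs:
        design = dataclasses.replace(config.design, rng_seed=config.seed)
        panel, phenotypes, truth, data = simulate_cohort(design, config.region_specs)
        return panel, data, truth
    panel = io.read_manifest(config.manifest)
    phenotypes = io.read_phenotypes(config.phenotypes)
    data = io.read_intensities(config.intensities_prefix, phenotypes)
    return panel, data, None


def _pca_correct_autosomes(
    data: IntensityDataset, panel: ProbePanel, n_components: int
) -> IntensityDataset:
    """Remove leading PCs from autosomal log ratios, probe means restored.

    X probes pass through uncorrected: on a mixed-sex cohort the dominant
    X-axis is sex itself and removing (or centering) it would destroy the
    hemizygous male baseline the callers rely on.
    """
    if n_components <= 0:
        return data
    auto_cols = panel.probes.loc[panel.probes["chrom"] != "X", "probe_id"]
    auto_cols = [c for c in data.lrr.columns if c in set(auto_cols)]
    if len(auto_cols) < 2 or n_components >= min(len(data.lrr), len(auto_cols)):
        log.warning("PCA correction skipped: matrix too small")
        return data
    sub = data.lrr.loc[:, auto_cols]
    corr = PcaCorrector(n_components, panel=panel).fit(sub)
    corrected = corr.transform(sub) + corr.mean_  # restore probe means
    lrr = data.lrr.copy()
    lrr.loc[:, auto_cols] = corrected
    return IntensityDataset(lrr, data.baf, data.phenotypes.reset_index())


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel, data, truth = _load_inputs(config)
    io.write_manifest(panel, out / "panel.tsv")
    io.write_phenotypes(data.phenotypes.reset_index(), out / "phenotypes.tsv")
    if truth is not None:
        io.write_truth(truth, out / "truth.tsv")

    log.info("preprocess: PCA batch correction (%d components)", config.pca_components)
    data = _pca_correct_autosomes(data, panel, config.pca_components)
    lrr_out = LogRatioMatrix(data.lrr, "pca_corrected" if config.pca_components > 0 else "raw")
    with open(out / "lrr.tsv", "w") as fh:
        fh.write(f"# provenance: {lrr_out.provenance}\n")
        data.lrr.to_csv(fh, sep="\t", float_format="%.6g")

    log.info("calling: HMM")
    seg_cfg = config.segmentation or SegmentationConfig(rng_seed=config.seed)
    hmm_calls = call_hmm(data, panel, config.hmm_model, config.hmm_min_probes)
    log.info("calling: segmentation")
    seg_calls = call_segments(data, panel, seg_cfg)
    inter, hmm_only, seg_only = intersect_calls(hmm_calls, seg_calls, panel)
    for cs, name in (
        (hmm_calls, "calls_hmm"),
        (seg_calls, "calls_segment"),
        (inter, "calls_intersection"),
        (hmm_only, "calls_hmm_only"),
        (seg_only, "calls_segment_only"),
    ):
        io.write_calls(cs, out / f"{name}.tsv")

    log.info("consensus: CNVR definition and carrier matrix")
    union_calls = CallSet(
        "mixed",
        pd.concat([hmm_calls.calls, seg_calls.calls, inter.calls], ignore_index=True)
        if (len(hmm_calls.calls) or len(seg_calls.calls))
        else hmm_calls.calls,
    )
    cnvrs = define_cnvrs(union_calls, panel)
    io.write_cnvrs(cnvrs, out / "cnvrs.tsv")

    sample_ids = data.sample_ids
    matrix = carrier_matrix(cnvrs, [hmm_calls, seg_calls, inter], panel, sample_ids=sample_ids)
    io.write_carrier_matrix(matrix, out / "carrier_matrix.tsv")

    log.info("QC")
    reports = filter_excessive_calls(
        [hmm_calls, seg_calls], sample_ids, k=config.qc_mad_k, data=data
    )
    qc_report_frame(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    excluded = {r.sample_id for r in reports if r.excluded}
    if config.exclusion_list:
        excluded |= read_exclusion_list(config.exclusion_list)

    log.info("association (%d regions, %d excluded samples)", len(cnvrs), len(excluded))
    pheno = data.phenotypes.reset_index()
    results = associate_regions(matrix, pheno, exclude=excluded)
    results = select_for_validation(results, config.selection, matrix, pheno)
    res_df = results_frame(results)
    res_df.to_csv(out / "association.tsv", sep="\t", index=False, float_format="%.6g")
    res_df[res_df["selected"]].to_csv(
        out / "selection.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if config.make_plot:
        manhattan_plot(results, str(out / "manhattan.png"))

    manifest = {
        "package": "cnvpanel",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "n_samples": len(sample_ids),
        "n_excluded": len(excluded),
        "n_cnvrs": len(cnvrs),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return PipelineResult(
        out_dir=out,
        panel=panel,
        data=data,
        hmm_calls=hmm_calls,
        segment_calls=seg_calls,
        intersection_calls=inter,
        cnvrs=cnvrs,
        results=res_df,
        excluded=excluded,
    )
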