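"""Shared domain types for the targeted-array CNV pipeline.

Coordinate conventions: probe positions and all on-disk coordinates are
1-based (inclusive intervals, as printed in CNV tables); every in-memory
interval is 0-based half-open ``[start, end)``.  Conversion happens only at
I/O boundaries (:mod:`cnvpanel.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X",)

LOSS = "loss"
GAIN = "gain"
NEUTRAL = "neutral"

#: Canonical per-copy-number Log-R-Ratio means (CN 0..4).  These are the
#: widely used cluster positions for Illumina-style arrays; CN2 is 0 by
#: construction of the log ratio.
LRR_MEANS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.4, 4: 0.68}


def baseline_copy_number(chromosome: str, sex: str) -> int:
    """Expected copy number of a non-carrier: 2 everywhere except male X."""
    if chromosome == "X" and sex == "M":
        return 1
    return 2


@dataclass(frozen=True)
class RegionSpec:
    """A targeted CNV region (CNVR) to be tiled with probes.

    ``start_bp``/``end_bp`` are 1-based inclusive, matching the printed
    table convention.  ``case_carrier_freq``/``control_carrier_freq`` are the
    per-sample probabilities of carrying the variant in each group.
    """

    region_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    cnv_type: str  # loss | gain
    case_carrier_freq: float = 0.0
    control_carrier_freq: float = 0.0
    n_probes_inside: int = 10
    n_probes_flank: int = 5

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.region_id}: start_bp > end_bp")
        if self.cnv_type not in (LOSS, GAIN):
            raise ValueError(f"{self.region_id}: cnv_type must be loss|gain")
        for f in (self.case_carrier_freq, self.control_carrier_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.region_id}: carrier freq outside [0,1]")
        if self.n_probes_inside < 1 or self.n_probes_flank < 0:
            raise ValueError(f"{self.region_id}: bad probe counts")

    @property
    def width(self) -> int:
        return self.end_bp - self.start_bp + 1


class ProbePanel:
    """Ordered probes grouped into pseudochromosomes (one per CNVR).

    Wraps a DataFrame with columns ``probe_id, chrom, pos, region_id, role``
    where ``role`` is ``inside`` or ``flank`` and ``pos`` is 1-based.
    Probes are kept sorted by (chrom, pos); each pseudochromosome's probes
    are contiguous in genomic order by construction.
    """

    COLUMNS = ("probe_id", "chrom", "pos", "region_id", "role")

    def __init__(self, probes: pd.DataFrame):
        missing = set(self.COLUMNS) - set(probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns {sorted(missing)}")
        df = probes.loc[:, list(self.COLUMNS)].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df = df.sort_values(
            ["chrom", "pos", "probe_id"], kind="mergesort"
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if sub["pos"].duplicated().any():
                raise ValueError(f"duplicate probe positions on chrom {chrom}")
        if df["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in panel")
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def region_ids(self) -> list[str]:
        """Pseudochromosome labels in canonical (chrom, first-pos) order."""
        first = self.probes.groupby("region_id", sort=False).head(1)
        first = first.sort_values(["chrom", "pos"], kind="mergesort")
        return first["region_id"].tolist()

    def region_probes(self, region_id: str) -> pd.DataFrame:
        sub = self.probes[self.probes["region_id"] == region_id]
        if sub.empty:
            raise KeyError(f"no probes for region {region_id!r}")
        return sub

    def region_chromosome(self, region_id: str) -> str:
        return str(self.region_probes(region_id)["chrom"].iloc[0])


@dataclass(frozen=True)
class CohortDesign:
    """Sample-level design of a simulated case/control cohort.

    Defaults mirror the targeted replication study design (3,000 cases vs
    6,000 controls, ~72%/67% male); construct with smaller counts for desk
    scale.  All randomness derives from ``rng_seed``.
    """

    n_cases: int = 3000
    n_controls: int = 6000
    male_fraction_cases: float = 0.717
    male_fraction_controls: float = 0.665
    batch_count: int = 2
    noise_sd_lrr: float = 0.15
    baf_noise_sd: float = 0.03
    batch_effect_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort counts must be positive")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")
        if self.noise_sd_lrr < 0 or self.baf_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


class TruthTable:
    """Ground-truth integer copy number per sample x region.

    Stored as a samples x regions integer matrix; ``to_frame`` yields the
    long (sample_id, region_id, true_copy_number) form used on disk.
    """

    def __init__(self, cn: pd.DataFrame):
        if not np.issubdtype(np.asarray(cn).dtype, np.integer):
            raise ValueError("copy numbers must be integers")
        if ((cn < 0) | (cn > 4)).any().any():
            raise ValueError("copy numbers outside 0..4")
        self.cn = cn
        self.cn.index.name = "sample_id"
        self.cn.columns.name = "region_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cn.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.cn.columns)

    def to_frame(self) -> pd.DataFrame:
        long = self.cn.stack().rename("true_copy_number").reset_index()
        long.columns = ["sample_id", "region_id", "true_copy_number"]
        return long

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TruthTable":
        cn = frame.pivot(
            index="sample_id", columns="region_id", values="true_copy_number"
        )
        if cn.isna().any().any():
            raise ValueError("truth table is not a full sample x region grid")
        return cls(cn.astype(np.int64))


class IntensityDataset:
    """Per-sample, per-probe LRR and BAF plus sample phenotypes.

    ``lrr`` and ``baf`` are samples x probes DataFrames sharing index and
    columns; ``phenotypes`` has columns sample_id, status (case|control),
    sex (M|F), batch.
    """

    def __init__(self, lrr: pd.DataFrame, baf: pd.DataFrame, phenotypes: pd.DataFrame):
        if not lrr.index.equals(baf.index) or not lrr.columns.equals(baf.columns):
            raise ValueError("LRR and BAF matrices are not aligned")
        pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes
        missing = set(lrr.index) - set(pheno.index)
        if missing:
            raise ValueError(f"{len(missing)} samples lack phenotypes")
        bad = set(pheno["status"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown status values {sorted(bad)}")
        bad = set(pheno["sex"]) - {"M", "F"}
        if bad:
            raise ValueError(f"unknown sex values {sorted(bad)}")
        self.lrr = lrr
        self.baf = baf
        self.phenotypes = pheno.loc[lrr.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lrr.index)

    def sex_of(self, sample_id: str) -> str:
        return str(self.phenotypes.loc[sample_id, "sex"])


#: Column layout shared by every call table in the package.  ``start``/``end``
#: are 0-based half-open; ``region_id`` is the pseudochromosome the call was
#: decoded in.
CALL_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "region_id",
    "type",
    "n_probes",
    "caller",
    "mean_lrr",
)


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "region_id": pd.Series(dtype=str),
            "type": pd.Series(dtype=str),
            "n_probes": pd.Series(dtype=np.int64),
            "caller": pd.Series(dtype=str),
            "mean_lrr": pd.Series(dtype=float),
        }
    )


@dataclass
class CallSet:
    """All CNV calls from one caller (or the dual-caller intersection)."""

    caller: str
    calls: pd.DataFrame = field(default_factory=empty_calls)

    def __post_init__(self) -> None:
        missing = set(CALL_COLUMNS) - set(self.calls.columns)
        if missing:
            raise ValueError(f"call table missing columns {sorted(missing)}")
        df = self.calls.loc[:, list(CALL_COLUMNS)].copy()
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("call with end <= start")
            bad = set(df["type"]) - {LOSS, GAIN}
            if bad:
                raise ValueError(f"unknown call types {sorted(bad)}")
        self.calls = df.sort_values(
            ["sample_id", "chrom", "start", "end", "type"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class CnvRegion:
    """A shared CNV region derived from overlapping calls (per type)."""

    cnvr_id: str
    region_id: str  # pseudochromosome it lives in
    chromosome: str
    start: int  # 0-based half-open
    end: int
    type: str  # loss | gain
    source: str  # hmm_only | segment_only | intersection | ...
    n_carriers: int = 0


class CarrierMatrix:
    """Boolean carrier status per sample x CNVR, split by type.

    ``status`` maps cnvr_id -> boolean Series over samples; ``provenance``
    maps cnvr_id -> string Series over samples with values in
    {"", "hmm", "segment", "both"} recording which caller(s) support each
    carrier.
    """

    def __init__(
        self,
        regions: list[CnvRegion],
        status: pd.DataFrame,
        provenance: pd.DataFrame,
    ):
        if list(status.columns) != [r.cnvr_id for r in regions]:
            raise ValueError("status columns do not match region list")
        if not status.index.equals(provenance.index) or not status.columns.equals(
            provenance.columns
        ):
            raise ValueError("status and provenance are not aligned")
        both = provenance.values == "both"
        if (both & ~status.values).any():
            raise ValueError("intersection-supported carrier marked non-carrier")
        self.regions = list(regions)
        self.status = status.astype(bool)
        self.provenance = provenance

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.index)

    def region(self, cnvr_id: str) -> CnvRegion:
        for r in self.regions:
            if r.cnvr_id == cnvr_id:
                return r
        raise KeyError(cnvr_id)


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier/non-carrier by case/control counts.

    a = case carriers, c = case non-carriers, b = control carriers,
    d = control non-carriers.
    """

    a: int
    c: int
    b: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n_case == 0 or self.n_control == 0:
            raise ValueError("empty case or control margin")

    @property
    def n_case(self) -> int:
        return self.a + self.c

    @property
    def n_control(self) -> int:
        return self.b + self.d


@dataclass
class AssociationResult:
    region_id: str  # cnvr id
    type: str
    table: ContingencyTable
    odds_ratio: float  # may be inf; degenerate tables flagged
    p_value: float
    sex_stratum: str = "all"  # all | male | female
    chromosome: str = ""
    degenerate: bool = False
    selected_for_validation: bool = False
    validation_samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionCriteria:
    """Gate for choosing regions to confirm by quantitative PCR."""

    min_odds_ratio: float = 2.0  # inclusive
    min_case_carriers: int = 2
    max_validation_samples: int = 6
    combine: str = "and"  # and | or

    def __post_init__(self) -> None:
        if self.min_odds_ratio <= 0 or self.min_case_carriers <= 0:
            raise ValueError("criteria must be positive")
        if self.max_validation_samples <= 0:
            raise ValueError("max_validation_samples must be positive")
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")


@dataclass
class SampleQcReport:
    sample_id: str
    n_calls_hmm: int
    n_calls_segment: int
    lrr_sd: float
    excluded: bool
    exclusion_reason: str  # excessive_calls | intensity_noise | none

    def __post_init__(self) -> None:
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with reason")
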