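"""Tab-separated readers/writers for every pipeline artifact.

All on-disk coordinates are 1-based inclusive (the printed-table
convention); BED-like call files additionally carry the 0-based ``start0``
column per the BED standard, and headers name both conventions.  Writers
sort rows and format floats stably so identical inputs produce
byte-identical files.  Readers raise :class:`FormatError` naming the file,
line and field on malformed input.
"""

from __future__ import annotations

import pandas as pd

from .types import (
    CALL_COLUMNS,
    CallSet,
    CnvRegion,
    IntensityDataset,
    ProbePanel,
    TruthTable,
)

__all__ = [
    "FormatError",
    "write_manifest", "read_manifest",
    "write_phenotypes", "read_phenotypes",
    "write_intensities", "read_intensities",
    "write_truth", "read_truth",
    "write_calls", "read_calls",
    "write_cnvrs", "read_cnvrs",
    "write_carrier_matrix",
]

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    def __init__(self, path: str, line: int | None, field: str, message: str):
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}, field {field!r}: {message}")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(path, 1, missing[0], "missing required column")


# --- probe manifest -------------------------------------------------------

def write_manifest(panel: ProbePanel, path: str) -> None:
    df = panel.probes.copy()
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ProbePanel.COLUMNS, path)
    bad = df.index[df["pos"] <= 0]
    if len(bad):
        raise FormatError(path, int(bad[0]) + 2, "pos", "positions are 1-based (> 0)")
    bad = df.index[~df["role"].isin(["inside", "flank"])]
    if len(bad):
        raise FormatError(path, int(bad[0]) + 2, "role", "must be inside|flank")
    return ProbePanel(df)


# --- phenotypes -----------------------------------------------------------

def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    cols = ["sample_id", "status", "sex", "batch"]
    phenotypes.loc[:, cols].sort_values("sample_id").to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "status", "sex", "batch"), path)
    if df.empty:
        raise FormatError(path, None, "sample_id", "phenotype file has no samples")
    bad = df.index[~df["status"].isin(["case", "control"])]
    if len(bad):
        raise FormatError(path, int(bad[0]) + 2, "status", "must be case|control")
    bad = df.index[~df["sex"].isin(["M", "F"])]
    if len(bad):
        raise FormatError(path, int(bad[0]) + 2, "sex", "must be M|F")
    return df


# --- intensity matrices ---------------------------------------------------

def write_intensities(data: IntensityDataset, prefix: str) -> None:
    """Write <prefix>.lrr.tsv and <prefix>.baf.tsv (samples x probes)."""
    data.lrr.to_csv(f"{prefix}.lrr.tsv", sep="\t", float_format=_FLOAT_FMT)
    data.baf.to_csv(f"{prefix}.baf.tsv", sep="\t", float_format=_FLOAT_FMT)


def read_intensities(prefix: str, phenotypes: pd.DataFrame) -> IntensityDataset:
    lrr = pd.read_csv(f"{prefix}.lrr.tsv", sep="\t", index_col="sample_id")
    baf = pd.read_csv(f"{prefix}.baf.tsv", sep="\t", index_col="sample_id")
    return IntensityDataset(lrr, baf, phenotypes)


# --- truth table ----------------------------------------------------------

def write_truth(truth: TruthTable, path: str) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> TruthTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "region_id", "true_copy_number"), path)
    return TruthTable.from_frame(df)


# --- CNV calls (BED-like) -------------------------------------------------

def write_calls(callset: CallSet, path: str) -> None:
    """BED-like TSV: start0 is 0-based (BED), start_bp/end_bp 1-based inclusive."""
    df = callset.calls.copy()
    df["start0"] = df["start"]
    df["start_bp"] = df["start"] + 1
    df["end_bp"] = df["end"]
    cols = [
        "chrom", "start0", "end_bp", "start_bp", "sample_id", "region_id",
        "type", "n_probes", "caller", "mean_lrr",
    ]
    df.loc[:, cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_calls(path: str) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(
        df, ("chrom", "start0", "end_bp", "sample_id", "type", "caller"), path
    )
    bad = df.index[df["end_bp"] <= df["start0"]]
    if len(bad):
        raise FormatError(path, int(bad[0]) + 2, "end_bp", "interval is empty")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom": df["chrom"],
            "start": df["start0"],
            "end": df["end_bp"],
            "region_id": df["region_id"],
            "type": df["type"],
            "n_probes": df["n_probes"],
            "caller": df["caller"],
            "mean_lrr": df["mean_lrr"],
        }
    )
    callers = set(df["caller"].unique())
    label = callers.pop() if len(callers) == 1 else "mixed"
    return CallSet(label, out.loc[:, list(CALL_COLUMNS)])


# --- CNV regions ----------------------------------------------------------

def write_cnvrs(cnvrs: list[CnvRegion], path: str) -> None:
    df = pd.DataFrame(
        {
            "cnvr_id": [r.cnvr_id for r in cnvrs],
            "region_id": [r.region_id for r in cnvrs],
            "chrom": [r.chromosome for r in cnvrs],
            "start0": [r.start for r in cnvrs],
            "end_bp": [r.end for r in cnvrs],
            "start_bp": [r.start + 1 for r in cnvrs],
            "type": [r.type for r in cnvrs],
            "source": [r.source for r in cnvrs],
            "n_carriers": [r.n_carriers for r in cnvrs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cnvrs(path: str) -> list[CnvRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ("cnvr_id", "region_id", "chrom", "start0", "end_bp", "type"), path)
    return [
        CnvRegion(
            cnvr_id=str(r.cnvr_id),
            region_id=str(r.region_id),
            chromosome=str(r.chrom),
            start=int(r.start0),
            end=int(r.end_bp),
            type=str(r.type),
            source=str(getattr(r, "source", "merged")),
            n_carriers=int(getattr(r, "n_carriers", 0)),
        )
        for r in df.itertuples(index=False)
    ]


# --- carrier matrix -------------------------------------------------------

def write_carrier_matrix(matrix, path: str) -> None:
    df = matrix.status.astype(int).copy()
    df.sort_index().to_csv(path, sep="\t")
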