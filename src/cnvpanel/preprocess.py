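"""Intensity preprocessing: quantile normalization, log ratios, PCA batch correction.

The discovery-style pipeline is: quantile-normalize per-allele intensities
across the cohort, form log2 ratios of total intensity against the per-probe
population median, then remove the leading principal components of the
sample x probe log-ratio matrix to strip batch structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ProbePanel

__all__ = [
    "AlleleIntensityMatrix",
    "LogRatioMatrix",
    "quantile_normalize",
    "compute_log_ratio",
    "PcaCorrector",
    "pca_batch_correct",
]


@dataclass
class AlleleIntensityMatrix:
    """Non-negative A/B allele intensities, samples x probes."""

    a: pd.DataFrame
    b: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.a.index.equals(self.b.index) or not self.a.columns.equals(self.b.columns):
            raise ValueError("A and B channels are not aligned")
        for name, df in (("A", self.a), ("B", self.b)):
            vals = df.to_numpy()
            if not np.isfinite(vals).all():
                raise ValueError(f"{name} channel contains non-finite values")
            if (vals < 0).any():
                raise ValueError(f"{name} channel contains negative intensities")


@dataclass
class LogRatioMatrix:
    """samples x probes log2 ratios with correction provenance."""

    values: pd.DataFrame
    provenance: str = "raw"  # raw | pca_corrected


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Map every row of x onto the across-row mean order statistics.

    Ties within a row receive the average of the reference values their
    ranks span (standard quantile normalization).
    """
    ref = np.sort(x, axis=1).mean(axis=0)  # reference distribution
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        ranks = rankdata(x[i], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[i] = 0.5 * (ref[lo] + ref[hi])
    return out


def quantile_normalize(raw: AlleleIntensityMatrix) -> AlleleIntensityMatrix:
    """Quantile-normalize each channel across samples.

    Every sample's values (within a channel) are replaced by the
    across-sample mean order statistic of matching rank, so all samples
    share one distribution while within-sample rank order is preserved.
    With a single sample this is the identity (with a warning).
    """
    if len(raw.a) < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return AlleleIntensityMatrix(raw.a.copy(), raw.b.copy())
    a = _quantile_normalize_array(raw.a.to_numpy(dtype=float))
    b = _quantile_normalize_array(raw.b.to_numpy(dtype=float))
    return AlleleIntensityMatrix(
        pd.DataFrame(a, index=raw.a.index, columns=raw.a.columns),
        pd.DataFrame(b, index=raw.b.index, columns=raw.b.columns),
    )


def compute_log_ratio(
    norm: AlleleIntensityMatrix,
    reference_median: np.ndarray | pd.Series | None = None,
    zero_floor: float = -10.0,
) -> LogRatioMatrix:
    """log2 of per-sample total intensity over the per-probe reference median.

    ``reference_median`` defaults to the across-sample median of A+B per
    probe (the population reference).  Zero totals are floored at
    ``zero_floor`` rather than -inf.
    """
    total = norm.a.to_numpy(dtype=float) + norm.b.to_numpy(dtype=float)
    if reference_median is None:
        ref = np.median(total, axis=0)
    else:
        ref = np.asarray(reference_median, dtype=float)
    if (ref <= 0).any():
        raise ValueError("reference medians must be strictly positive")
    with np.errstate(divide="ignore"):
        lr = np.log2(total / ref)
    n_zero = int((total == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-intensity cells floored at {zero_floor}")
        lr = np.where(total == 0, zero_floor, lr)
    return LogRatioMatrix(
        pd.DataFrame(lr, index=norm.a.index, columns=norm.a.columns), "raw"
    )


class PcaCorrector:
    """Remove leading principal components from a log-ratio matrix.

    Components are computed on the probe-mean-centered samples x probes
    matrix by SVD.  A component whose squared probe-loading mass
    concentrates beyond ``protect_fraction`` on a single pseudochromosome is
    left in place: such an axis is a shared CNV, not a batch effect, and
    regressing it out would erase signal.

    ``transform`` projects data onto the orthogonal complement of the
    retained (removed) components, so applying it twice equals applying it
    once.
    """

    def __init__(
        self,
        n_components: int = 2,
        panel: ProbePanel | None = None,
        protect_fraction: float = 0.5,
    ):
        self.n_components = int(n_components)
        self.panel = panel
        self.protect_fraction = float(protect_fraction)
        self.mean_: np.ndarray | None = None
        self.components_: np.ndarray | None = None  # (k, n_probes)
        self.skipped_components_: list[int] = []

    def fit(self, values: pd.DataFrame) -> "PcaCorrector":
        x = values.to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("log ratios contain non-finite values")
        if self.n_components >= min(x.shape):
            raise ValueError("n_components must be < min(n_samples, n_probes)")
        self.mean_ = x.mean(axis=0)
        if self.n_components <= 0:
            self.components_ = np.empty((0, x.shape[1]))
            return self
        xc = x - self.mean_
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        keep: list[np.ndarray] = []
        region_ids = None
        if self.panel is not None:
            lookup = self.panel.probes.set_index("probe_id")["region_id"]
            region_ids = lookup.reindex(values.columns).to_numpy()
        i = 0
        while len(keep) < self.n_components and i < vt.shape[0]:
            v = vt[i]
            if region_ids is not None and self._is_cnv_like(v, region_ids):
                self.skipped_components_.append(i)
            else:
                keep.append(v)
            i += 1
        self.components_ = np.array(keep) if keep else np.empty((0, x.shape[1]))
        return self

    def _is_cnv_like(self, loading: np.ndarray, region_ids: np.ndarray) -> bool:
        sq = loading**2
        mass = pd.Series(sq).groupby(region_ids).sum()
        return bool(mass.max() > self.protect_fraction * sq.sum())

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        """Center the input by its own probe means, then project out the
        removed components.  Centering by the input (rather than the stored
        fit means) makes the correction idempotent."""
        if self.mean_ is None or self.components_ is None:
            raise RuntimeError("corrector is not fitted")
        x = values.to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        if len(self.components_):
            xc = xc - (xc @ self.components_.T) @ self.components_
        return pd.DataFrame(xc, index=values.index, columns=values.columns)


def pca_batch_correct(
    lrr: LogRatioMatrix,
    n_components: int = 2,
    panel: ProbePanel | None = None,
    protect_fraction: float = 0.5,
) -> LogRatioMatrix:
    """Fit-and-apply PCA batch correction.

    ``n_components <= 0`` returns the probe-mean-centered matrix unchanged
    otherwise (identity correction).
    """
    corr = PcaCorrector(max(n_components, 0), panel, protect_fraction).fit(lrr.values)
    return LogRatioMatrix(corr.transform(lrr.values), "pca_corrected")
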