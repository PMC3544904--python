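"""Permutation-gated optimal univariate segmentation (second CNV caller).

Per sample and per pseudochromosome the log-ratio vector is partitioned
into mean-homogeneous segments.  For each candidate segment count K up to
``max_segments`` the RSS-optimal K-segmentation is computed by dynamic
programming; the largest K whose adjacent segments *all* differ
significantly under a pairwise permutation test (p < threshold) is
accepted, else the vector stays unsplit.  Testing boundaries in their
final configuration, rather than gating greedy binary splits one at a
time, matters on targeted panels: a CNV sits in the middle of its
pseudochromosome, and no single binary split of flank|CNV|flank can reach
p < 0.001 at panel-scale marker counts.

The pairwise test enumerates all assignments of the pooled values to the
two sides exactly whenever the combination count is small (the common case
for 20-marker pseudochromosomes), falling back to Monte-Carlo permutations
with the add-one estimator otherwise.

Two parameter profiles are bundled: ``replication`` (no moving window, at
most 5 segments per pseudochromosome, minimum segment of 1 marker,
p < 0.001) for targeted panels, and ``discovery`` (5,000-marker windows,
at most 20 segments per window, minimum segment of 10 markers, p < 0.001)
for genome-wide scans.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .types import (
    CALL_COLUMNS,
    CallSet,
    IntensityDataset,
    ProbePanel,
    baseline_copy_number,
    empty_calls,
)

__all__ = [
    "SegmentationConfig",
    "Segment",
    "group_pseudochromosomes",
    "permutation_split_pvalue",
    "segment_univariate",
    "classify_segments",
    "call_segments",
]

#: LRR of the male X baseline (CN1) relative to the diploid zero point.
_MALE_X_BASELINE_LRR = -0.66


@dataclass(frozen=True)
class SegmentationConfig:
    profile: str = "replication"  # replication | discovery
    moving_window_markers: int | None = None  # discovery: 5000
    max_segments: int = 5  # per pseudochromosome (discovery: 20 per window)
    min_segment_markers: int = 1  # discovery: 10
    permutation_p_threshold: float = 0.001
    n_permutations: int = 1999
    exact_enumeration_cap: int = 20000  # max combinations enumerated exactly
    loss_threshold: float = -0.3
    gain_threshold: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.permutation_p_threshold < 1:
            raise ValueError("permutation_p_threshold must be in (0,1)")
        if self.max_segments < 1 or self.min_segment_markers < 1:
            raise ValueError("max_segments and min_segment_markers must be >= 1")
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 0 < gain_threshold")

    @classmethod
    def discovery(cls, **kw) -> "SegmentationConfig":
        kw.setdefault("moving_window_markers", 5000)
        kw.setdefault("max_segments", 20)
        kw.setdefault("min_segment_markers", 10)
        return cls(profile="discovery", **kw)


@dataclass
class Segment:
    """Half-open marker-index run [first, last) with its fitted mean."""

    first: int
    last: int
    mean: float
    klass: str = "neutral"  # loss | gain | neutral
    region_id: str = ""

    @property
    def n_markers(self) -> int:
        return self.last - self.first


def group_pseudochromosomes(panel: ProbePanel) -> dict[str, pd.DataFrame]:
    """Ordered marker groups, one per CNVR (inside + flank probes, genomic order).

    Segmentation is run within a group only, so no call is ever influenced
    by data points across the unprobed gap between targeted regions.
    """
    groups: dict[str, pd.DataFrame] = {}
    for region_id in panel.region_ids:
        probes = panel.region_probes(region_id).reset_index(drop=True)
        if probes.empty:
            warnings.warn(f"region {region_id} has no probes; omitted")
            continue
        groups[region_id] = probes
    return groups


@lru_cache(maxsize=512)
def _combo_matrix(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.int64)


def permutation_split_pvalue(
    left: np.ndarray,
    right: np.ndarray,
    n_permutations: int = 1999,
    rng: np.random.Generator | None = None,
    exact_cap: int = 20000,
) -> float:
    """Two-sample permutation p-value for |mean(left) - mean(right)|.

    Pooled values are redistributed between the two sides with sizes
    preserved.  When the number of distinct assignments C(n, n_left) is at
    most ``exact_cap`` the p-value is computed by full enumeration
    (#extreme / #assignments); otherwise by ``n_permutations`` random
    shuffles with the add-one estimator, which keeps the estimate strictly
    positive.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) == 0 or len(right) == 0:
        raise ValueError("both sides must be non-empty")
    pooled = np.concatenate([left, right])
    n, k = len(pooled), len(left)
    observed = abs(left.mean() - right.mean())
    if math.comb(n, k) <= exact_cap:
        combos = _combo_matrix(n, k)
        sums = pooled[combos].sum(axis=1)
        mean_l = sums / k
        mean_r = (pooled.sum() - sums) / (n - k)
        extreme = np.abs(mean_l - mean_r) >= observed - 1e-12
        return float(extreme.mean())
    rng = rng or np.random.default_rng()
    perms = rng.permuted(np.broadcast_to(pooled, (n_permutations, n)), axis=1)
    mean_l = perms[:, :k].mean(axis=1)
    mean_r = perms[:, k:].mean(axis=1)
    extreme = np.abs(mean_l - mean_r) >= observed - 1e-12
    return (1 + int(extreme.sum())) / (n_permutations + 1)


def _best_split(values: np.ndarray, min_size: int) -> tuple[int, float]:
    """(breakpoint, RSS reduction) of the RSS-optimal single split.

    The RSS reduction of splitting at k equals n_l*n_r/n*(mean_l-mean_r)^2;
    returns (-1, 0) when no split satisfies the minimum child size.
    """
    n = len(values)
    if n < 2 * min_size:
        return -1, 0.0
    cs = np.cumsum(values)
    k = np.arange(min_size, n - min_size + 1)
    mean_l = cs[k - 1] / k
    mean_r = (cs[-1] - cs[k - 1]) / (n - k)
    gain = k * (n - k) / n * (mean_l - mean_r) ** 2
    i = int(np.argmax(gain))  # leftmost maximizer on exact ties
    return int(k[i]), float(gain[i])


def _max_stat_split_pvalue(
    values: np.ndarray,
    min_size: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the maximally selected single split.

    The observed statistic is the RSS reduction of the best breakpoint;
    each permutation reshuffles the values and re-finds its own best
    breakpoint, so the selection of the split is built into the null and
    the test holds its nominal level on homogeneous data.
    """
    _, observed = _best_split(values, min_size)
    if observed <= 0.0:
        return 1.0
    n = len(values)
    perms = rng.permuted(np.broadcast_to(values, (n_permutations, n)), axis=1)
    cs = np.cumsum(perms, axis=1)
    k = np.arange(min_size, n - min_size + 1)
    mean_l = cs[:, k - 1] / k
    mean_r = (cs[:, -1:] - cs[:, k - 1]) / (n - k)
    gains = (k * (n - k) / n) * (mean_l - mean_r) ** 2
    extreme = gains.max(axis=1) >= observed - 1e-12
    return (1 + int(extreme.sum())) / (n_permutations + 1)


def _dp_segmentations(
    values: np.ndarray, k_max: int, min_size: int
) -> dict[int, list[int]]:
    """RSS-optimal boundaries for every segment count 1..k_max.

    Classic partition DP over prefix sums; returns, per K, the boundary
    list [0, b_1, ..., n].  O(k_max * n^2) with vectorized inner minimum.
    """
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values * values)])

    def sse_vec(i: np.ndarray, j: int) -> np.ndarray:
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    k_max = min(k_max, n // min_size)
    cost = np.full((k_max + 1, n + 1), np.inf)
    arg = np.zeros((k_max + 1, n + 1), dtype=np.int64)
    idx = np.arange(n + 1)
    for j in range(min_size, n + 1):
        cost[1, j] = sse_vec(np.array([0]), j)[0]
    for k in range(2, k_max + 1):
        for j in range(k * min_size, n + 1):
            i = idx[(k - 1) * min_size : j - min_size + 1]
            c = cost[k - 1, i] + sse_vec(i, j)
            b = int(np.argmin(c))  # leftmost minimizer on ties
            cost[k, j] = c[b]
            arg[k, j] = i[b]
    out: dict[int, list[int]] = {}
    for k in range(1, k_max + 1):
        if not np.isfinite(cost[k, n]):
            continue
        bounds = [n]
        j = n
        for kk in range(k, 1, -1):
            j = int(arg[kk, j])
            bounds.append(j)
        bounds.append(0)
        out[k] = sorted(set(bounds))
    return out


def _segment_block(
    values: np.ndarray,
    config: SegmentationConfig,
    rng: np.random.Generator,
    offset: int = 0,
) -> list[Segment]:
    """Segment one marker block: DP-optimal splits, permutation-validated.

    Accepts the largest segment count whose boundaries all test
    significant; a homogeneous block stays one segment.  A two-segment
    solution is gated by the maximally-selected-split permutation test
    (the single DP breakpoint is the best of all candidates, and the naive
    pairwise test on it would be anti-conservative); three or more
    segments are gated by pairwise tests between every adjacent pair,
    which is where the power to isolate a CNV flanked by diploid probes
    comes from.
    """
    candidates = _dp_segmentations(values, config.max_segments, config.min_segment_markers)
    chosen = [0, len(values)]
    for k in sorted(candidates, reverse=True):
        bounds = candidates[k]
        if len(bounds) - 1 == 1:
            continue
        if len(bounds) - 1 == 2:
            p = _max_stat_split_pvalue(
                values, config.min_segment_markers, config.n_permutations, rng
            )
            if p < config.permutation_p_threshold:
                chosen = bounds
                break
            continue
        ok = True
        for i in range(1, len(bounds) - 1):
            p = permutation_split_pvalue(
                values[bounds[i - 1] : bounds[i]],
                values[bounds[i] : bounds[i + 1]],
                config.n_permutations,
                rng,
                config.exact_enumeration_cap,
            )
            if p >= config.permutation_p_threshold:
                ok = False
                break
        if ok:
            chosen = bounds
            break
    return [
        Segment(
            offset + chosen[i],
            offset + chosen[i + 1],
            float(values[chosen[i] : chosen[i + 1]].mean()),
        )
        for i in range(len(chosen) - 1)
    ]


def segment_univariate(
    values: np.ndarray,
    config: SegmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[Segment]:
    """Segment one log-ratio vector into mean-homogeneous runs.

    Deterministic given ``config.rng_seed`` (or a caller-provided
    generator).  A constant vector yields a single segment.  With the
    discovery profile the vector is processed in consecutive windows of
    ``moving_window_markers`` markers, each allowed ``max_segments``
    segments.
    """
    config = config or SegmentationConfig()
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty value vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    rng = rng or np.random.default_rng(config.rng_seed)
    window = config.moving_window_markers or len(values)
    out: list[Segment] = []
    for lo in range(0, len(values), window):
        out.extend(_segment_block(values[lo : lo + window], config, rng, offset=lo))
    return out


def classify_segments(
    segments: list[Segment],
    loss_threshold: float = -0.3,
    gain_threshold: float = 0.3,
    sex: str = "F",
    chromosome: str = "1",
) -> list[Segment]:
    """Label segments loss/gain/neutral from their mean log ratio.

    Thresholds are inclusive (a mean exactly at a threshold is called
    non-neutral).  On male X the comparison is made relative to the CN1
    baseline log ratio, i.e. thresholds shift down by 0.66.
    """
    shift = (
        _MALE_X_BASELINE_LRR
        if (chromosome == "X" and baseline_copy_number(chromosome, sex) == 1)
        else 0.0
    )
    out = []
    for seg in segments:
        rel = seg.mean - shift
        if rel <= loss_threshold:
            klass = "loss"
        elif rel >= gain_threshold:
            klass = "gain"
        else:
            klass = "neutral"
        out.append(Segment(seg.first, seg.last, seg.mean, klass, seg.region_id))
    return out


def call_segments(
    data: IntensityDataset,
    panel: ProbePanel,
    config: SegmentationConfig | None = None,
    min_probes: int = 1,
) -> CallSet:
    """Run univariate segmentation per sample per pseudochromosome.

    Non-neutral classified segments with at least ``min_probes`` markers
    become calls (the replication profile allows single-marker segments).
    """
    config = config or SegmentationConfig()
    rng = np.random.default_rng(config.rng_seed)
    groups = group_pseudochromosomes(panel)
    lrr_all = data.lrr.to_numpy(dtype=float)
    col_index = {p: k for k, p in enumerate(data.lrr.columns)}
    sexes = data.phenotypes["sex"].to_numpy()

    rows = []
    for region_id, probes in groups.items():
        cols = np.array([col_index[p] for p in probes["probe_id"]])
        pos = probes["pos"].to_numpy()
        chrom = str(probes["chrom"].iloc[0])
        for si, sample_id in enumerate(data.sample_ids):
            values = lrr_all[si, cols]
            segs = segment_univariate(values, config, rng)
            segs = classify_segments(
                segs, config.loss_threshold, config.gain_threshold,
                sexes[si], chrom,
            )
            for seg in segs:
                if seg.klass == "neutral" or seg.n_markers < min_probes:
                    continue
                rows.append(
                    (
                        sample_id,
                        chrom,
                        int(pos[seg.first]) - 1,
                        int(pos[seg.last - 1]),
                        region_id,
                        seg.klass,
                        seg.n_markers,
                        "segment",
                        seg.mean,
                    )
                )
    calls = (
        pd.DataFrame(rows, columns=list(CALL_COLUMNS)) if rows else empty_calls()
    )
    return CallSet("segment", calls)
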