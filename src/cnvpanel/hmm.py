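"""Hidden-Markov CNV caller: joint LRR/BAF Viterbi decoding of CN 0-4.

One of the two independent callers in the pipeline.  States are integer
copy numbers 0..4.  LRR emissions are Gaussians around per-state cluster
means; BAF emissions are mixtures over the genotypes a state admits (e.g.
CN3 heterozygotes cluster at 1/3 and 2/3), with a uniform component for
CN0 where there is no genotype signal and a small uniform floor everywhere
for robustness to outliers.  Transitions are distance-dependent:

    p_stay(d) = 1 - (1 - rho) * min(d / d_ref, 1)

so state persistence decays with inter-probe distance; the leave mass is
split over the other states in proportion to the initial distribution.
Each pseudochromosome is decoded independently, so calls can never bridge
the unprobed gaps between targeted regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import (
    CALL_COLUMNS,
    LRR_MEANS,
    CallSet,
    IntensityDataset,
    ProbePanel,
    baseline_copy_number,
    empty_calls,
)

__all__ = ["HmmModel", "viterbi_decode", "path_to_calls", "call_hmm",
           "enumerate_best_path"]

N_STATES = 5


def _baf_mixture(cn: int) -> tuple[np.ndarray, np.ndarray]:
    """(cluster means, weights) for the BAF mixture of a copy-number state.

    Genotype weights assume B-allele frequency 1/2 (binomial over cn
    copies); the decoder does not know per-probe allele frequencies and a
    symmetric prior loses little for segmentation purposes.
    """
    if cn == 0:
        return np.array([]), np.array([])
    k = np.arange(cn + 1)
    from scipy.stats import binom

    return k / cn, binom.pmf(k, cn, 0.5)


@dataclass
class HmmModel:
    """Emission/transition parameters of the 5-state copy-number HMM."""

    lrr_means: np.ndarray = field(
        default_factory=lambda: np.array([LRR_MEANS[k] for k in range(5)])
    )
    lrr_sd: float = 0.25
    baf_sd: float = 0.05
    baf_uniform_floor: float = 0.01
    rho: float = 0.999
    d_ref: float = 100_000.0
    initial: np.ndarray = field(
        default_factory=lambda: np.array([0.002, 0.018, 0.96, 0.018, 0.002])
    )

    def __post_init__(self) -> None:
        self.lrr_means = np.asarray(self.lrr_means, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("emission sds must be positive")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0,1)")

    def for_baseline(self, baseline_cn: int) -> "HmmModel":
        """Copy of the model with the prior mass peak moved to ``baseline_cn``.

        Used on male X, where the expected non-carrier state is CN1.
        """
        init = np.full(N_STATES, (1 - 0.96) / (N_STATES - 1))
        init[baseline_cn] = 0.96
        return HmmModel(
            lrr_means=self.lrr_means.copy(),
            lrr_sd=self.lrr_sd,
            baf_sd=self.baf_sd,
            baf_uniform_floor=self.baf_uniform_floor,
            rho=self.rho,
            d_ref=self.d_ref,
            initial=init,
        )

    # --- emissions -------------------------------------------------------
    def log_emission(self, lrr: np.ndarray, baf: np.ndarray) -> np.ndarray:
        """(n_probes, n_states) log emission densities; NaN probes masked."""
        lrr = np.asarray(lrr, dtype=float)
        baf = np.asarray(baf, dtype=float)
        n = len(lrr)
        out = np.zeros((n, N_STATES))
        lrr_ok = np.isfinite(lrr)
        baf_ok = np.isfinite(baf)
        for s in range(N_STATES):
            ll = np.zeros(n)
            ll[lrr_ok] = norm.logpdf(lrr[lrr_ok], self.lrr_means[s], self.lrr_sd)
            lb = np.zeros(n)
            means, weights = _baf_mixture(s)
            if len(means) == 0:
                dens = np.ones(baf_ok.sum())  # CN0: BAF uninformative, uniform
            else:
                comp = norm.pdf(baf[baf_ok, None], means[None, :], self.baf_sd)
                dens = comp @ weights
            lb[baf_ok] = np.log(
                (1 - self.baf_uniform_floor) * dens + self.baf_uniform_floor
            )
            out[:, s] = ll + lb
        return out

    # --- transitions -----------------------------------------------------
    def log_transition(self, distance: float) -> np.ndarray:
        """(n_states, n_states) log transition matrix for one probe gap."""
        cache = self.__dict__.setdefault("_trans_cache", {})
        if distance in cache:
            return cache[distance]
        p_stay = 1.0 - (1.0 - self.rho) * min(max(distance, 0.0) / self.d_ref, 1.0)
        trans = np.empty((N_STATES, N_STATES))
        for s in range(N_STATES):
            leave = self.initial.copy()
            leave[s] = 0.0
            total = leave.sum()
            trans[s] = (1.0 - p_stay) * leave / total
            trans[s, s] = p_stay
        with np.errstate(divide="ignore"):
            out = np.log(trans)
        cache[distance] = out
        return out


def _tie_break_argmax(scores: np.ndarray, prefer: int = 2) -> int:
    """Index of max score; exact ties resolved toward ``prefer``, then to
    the state nearest it (lower CN first)."""
    best = scores.max()
    candidates = np.flatnonzero(scores == best)
    if prefer in candidates:
        return prefer
    return int(candidates[np.argmin(np.abs(candidates - prefer))])


def viterbi_decode(
    model: HmmModel,
    lrr: np.ndarray,
    baf: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Maximum-a-posteriori joint copy-number path (log-domain Viterbi).

    Non-finite LRR/BAF entries are treated as uninformative (masked) rather
    than rejected.  Exact score ties break toward CN2.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    positions = np.asarray(positions)
    if not (len(lrr) == len(baf) == len(positions)) or len(lrr) == 0:
        raise ValueError("lrr, baf, positions must be equal length >= 1")
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")

    log_e = model.log_emission(lrr, baf)
    n = len(lrr)
    with np.errstate(divide="ignore"):
        score = np.log(model.initial) + log_e[0]
    back = np.zeros((n, N_STATES), dtype=np.int8)
    states = np.arange(N_STATES)
    for t in range(1, n):
        log_t = model.log_transition(float(positions[t] - positions[t - 1]))
        cand = score[:, None] + log_t  # (from, to)
        bt = np.argmax(cand, axis=0)
        best = cand[bt, states]
        tied = (cand == best).sum(axis=0) > 1
        if tied.any():  # exact ties are rare with continuous emissions
            for s in np.flatnonzero(tied):
                bt[s] = _tie_break_argmax(cand[:, s])
        back[t] = bt
        score = best + log_e[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = _tie_break_argmax(score)
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_score(model: HmmModel, lrr, baf, positions, path) -> float:
    """Joint log score of an arbitrary state path (for oracle comparisons)."""
    log_e = model.log_emission(np.asarray(lrr, float), np.asarray(baf, float))
    positions = np.asarray(positions)
    with np.errstate(divide="ignore"):
        s = float(np.log(model.initial[path[0]]) + log_e[0, path[0]])
    for t in range(1, len(path)):
        log_t = model.log_transition(float(positions[t] - positions[t - 1]))
        s += float(log_t[path[t - 1], path[t]] + log_e[t, path[t]])
    return s


def enumerate_best_path(
    model: HmmModel, lrr, baf, positions, return_path: bool = True
):
    """Exhaustive search over all 5**n state paths.

    Independent oracle for :func:`viterbi_decode`.  With ``return_path``
    the full path table is enumerated via ``itertools.product`` (practical
    to n ~ 8); without it, all path scores are still enumerated but only
    the running maximum is kept, allowing n = 12 within memory bounds.
    """
    n = len(lrr)
    if return_path:
        if n > 8:
            raise ValueError("full path enumeration limited to n <= 8")
        log_e = model.log_emission(np.asarray(lrr, float), np.asarray(baf, float))
        log_ts = [
            model.log_transition(float(positions[t] - positions[t - 1]))
            for t in range(1, n)
        ]
        with np.errstate(divide="ignore"):
            log_init = np.log(model.initial)
        best, best_path = -np.inf, None
        for path in itertools.product(range(N_STATES), repeat=n):
            s = log_init[path[0]] + log_e[0, path[0]]
            for t in range(1, n):
                s += log_ts[t - 1][path[t - 1], path[t]] + log_e[t, path[t]]
            if s > best:
                best, best_path = s, path
        return best, np.array(best_path)

    if n > 12:
        raise ValueError("score enumeration limited to n <= 12")
    log_e = model.log_emission(np.asarray(lrr, float), np.asarray(baf, float))
    positions = np.asarray(positions)
    with np.errstate(divide="ignore"):
        scores = np.log(model.initial) + log_e[0]  # one entry per path prefix
    last = np.arange(N_STATES)
    for t in range(1, n):
        log_t = model.log_transition(float(positions[t] - positions[t - 1]))
        if t == n - 1 and len(scores) * N_STATES > 50_000_000:
            # final extension: fold the max over chunks instead of storing
            best = -np.inf
            for lo in range(0, len(scores), 5_000_000):
                chunk = scores[lo : lo + 5_000_000, None] + log_t[last[lo : lo + 5_000_000]] + log_e[t]
                best = max(best, float(chunk.max()))
            return best, None
        scores = (scores[:, None] + log_t[last] + log_e[t]).ravel()
        last = np.tile(np.arange(N_STATES), len(last))
    return float(scores.max()), None


def path_to_calls(
    path: np.ndarray,
    probes: pd.DataFrame,
    sex: str,
    sample_id: str = "",
    min_probes: int = 3,
    masked: np.ndarray | None = None,
    mean_lrr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convert a decoded state path into loss/gain calls.

    Maximal runs of states off the sex-specific baseline become calls
    (typed by the sign of the deviation); runs shorter than ``min_probes``
    are dropped, and same-type runs separated by a single masked probe are
    merged first.  Coordinates span the first/last probe of the run,
    0-based half-open.
    """
    path = np.asarray(path)
    if len(path) != len(probes):
        raise ValueError("path and probe table length mismatch")
    chrom = str(probes["chrom"].iloc[0])
    region_id = str(probes["region_id"].iloc[0])
    base = baseline_copy_number(chrom, sex)
    typ = np.where(path < base, "loss", np.where(path > base, "gain", "neutral"))
    if masked is not None:
        masked = np.asarray(masked, dtype=bool)
        # a single masked probe between two same-type runs joins them
        for i in range(1, len(typ) - 1):
            if masked[i] and typ[i - 1] == typ[i + 1] != "neutral":
                typ[i] = typ[i - 1]

    rows = []
    pos = probes["pos"].to_numpy()
    i = 0
    while i < len(typ):
        j = i
        while j < len(typ) and typ[j] == typ[i]:
            j += 1
        if typ[i] != "neutral" and j - i >= min_probes:
            if mean_lrr is not None:
                mlrr = float(np.nanmean(mean_lrr[i:j]))
            else:
                mlrr = float("nan")
            rows.append(
                (
                    sample_id,
                    chrom,
                    int(pos[i]) - 1,
                    int(pos[j - 1]),
                    region_id,
                    str(typ[i]),
                    j - i,
                    "hmm",
                    mlrr,
                )
            )
        i = j
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS)) if rows else empty_calls()


def call_hmm(
    data: IntensityDataset,
    panel: ProbePanel,
    model: HmmModel | None = None,
    min_probes: int = 3,
) -> CallSet:
    """Run Viterbi decoding per sample per pseudochromosome."""
    model = model or HmmModel()
    male_x_model = model.for_baseline(1)
    frames = []
    lrr_all = data.lrr.to_numpy(dtype=float)
    baf_all = data.baf.to_numpy(dtype=float)
    col_index = {p: k for k, p in enumerate(data.lrr.columns)}
    sexes = data.phenotypes["sex"].to_numpy()

    for region_id in panel.region_ids:
        probes = panel.region_probes(region_id).reset_index(drop=True)
        cols = np.array([col_index[p] for p in probes["probe_id"]])
        positions = probes["pos"].to_numpy()
        chrom = str(probes["chrom"].iloc[0])
        for si, sample_id in enumerate(data.sample_ids):
            sex = sexes[si]
            m = male_x_model if (chrom == "X" and sex == "M") else model
            lrr = lrr_all[si, cols]
            baf = baf_all[si, cols]
            path = viterbi_decode(m, lrr, baf, positions)
            masked = ~(np.isfinite(lrr) & np.isfinite(baf))
            calls = path_to_calls(
                path, probes, sex, sample_id, min_probes, masked, mean_lrr=lrr
            )
            if len(calls):
                frames.append(calls)
    if frames:
        return CallSet("hmm", pd.concat(frames, ignore_index=True))
    return CallSet("hmm")
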