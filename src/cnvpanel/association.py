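"""Case/control CNV association: exact Fisher tests, odds ratios, selection.

Each CNV region is tested per type (copy-number loss vs. no loss, gain vs.
no gain) with a two-sided Fisher exact test on the carriers/non-carriers x
case/control table.  X-linked regions are additionally tested within each
sex stratum.  The sample odds ratio (a*d)/(b*c) is reported as a risk
indicator, infinite when carriers occur only in cases.  Regions are
flagged for wet-lab validation when the odds ratio is at least 2.0 and at
least two cases carry the variant, and up to six case carriers are listed
per flagged region, preferring samples supported by both callers.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import (
    AssociationResult,
    CarrierMatrix,
    ContingencyTable,
    SelectionCriteria,
)

__all__ = [
    "fisher_two_sided",
    "sample_odds_ratio",
    "associate_regions",
    "select_for_validation",
    "results_frame",
]

#: Relative tolerance when comparing point hypergeometric probabilities;
#: guards against log-gamma rounding dropping tables that are exactly as
#: probable as the observed one.
_REL_TOL = 1e-7


def fisher_two_sided(t: ContingencyTable) -> float:
    """Exact two-sided Fisher p-value (point-probability method).

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed table's
    (within relative tolerance 1e-7).  Computed in log-gamma space via the
    hypergeometric log-pmf.  A table with no carriers anywhere has p = 1.
    """
    m = t.a + t.b  # carrier margin
    if m == 0 or m == t.n_case + t.n_control:
        return 1.0
    n_total = t.n_case + t.n_control
    lo = max(0, m - t.n_control)
    hi = min(m, t.n_case)
    support = np.arange(lo, hi + 1)
    # log C(n_case, k) + log C(n_control, m-k) - log C(n_total, m)
    k = support
    logpmf = (
        gammaln(t.n_case + 1) - gammaln(k + 1) - gammaln(t.n_case - k + 1)
        + gammaln(t.n_control + 1) - gammaln(m - k + 1) - gammaln(t.n_control - m + k + 1)
        - (gammaln(n_total + 1) - gammaln(m + 1) - gammaln(n_total - m + 1))
    )
    obs = logpmf[t.a - lo]
    keep = logpmf <= obs + math.log1p(_REL_TOL)
    p = float(np.exp(logpmf[keep]).sum())
    return min(p, 1.0)


def sample_odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    """(odds ratio, degenerate flag) for a carriers-by-status table.

    (a/c)/(b/d); infinite when carriers occur only in cases; 0 when only in
    controls; 1.0 with the degenerate flag when there are no carriers at
    all or a margin of non-carriers is empty.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a == 0 and b == 0:
        return 1.0, True
    if c == 0 or d == 0:  # a non-carrier margin is empty
        value = math.inf if b * c == 0 else (a * d) / (b * c)
        return value, True
    if b == 0:
        return math.inf, False
    if a == 0:
        return 0.0, False
    return (a * d) / (b * c), False


def _result(
    cnvr_id: str,
    typ: str,
    chromosome: str,
    carriers: np.ndarray,
    is_case: np.ndarray,
    stratum: str,
) -> AssociationResult:
    a = int((carriers & is_case).sum())
    b = int((carriers & ~is_case).sum())
    c = int((~carriers & is_case).sum())
    d = int((~carriers & ~is_case).sum())
    if a + c == 0 or b + d == 0:
        # empty stratum (e.g. no females genotyped for an X region)
        return AssociationResult(
            region_id=cnvr_id,
            type=typ,
            table=ContingencyTable(max(a, 0), max(c, 1), max(b, 0), max(d, 1)),
            odds_ratio=1.0,
            p_value=1.0,
            sex_stratum=stratum,
            chromosome=chromosome,
            degenerate=True,
        )
    table = ContingencyTable(a, c, b, d)
    orr, degen = sample_odds_ratio(table)
    return AssociationResult(
        region_id=cnvr_id,
        type=typ,
        table=table,
        odds_ratio=orr,
        p_value=fisher_two_sided(table),
        sex_stratum=stratum,
        chromosome=chromosome,
        degenerate=degen,
    )


def associate_regions(
    matrix: CarrierMatrix,
    phenotypes: pd.DataFrame,
    exclude: set[str] | None = None,
) -> list[AssociationResult]:
    """Fisher test + odds ratio per CNVR and type.

    Autosomal regions use all (non-excluded) samples; X regions produce the
    combined result plus male-only and female-only strata.  Samples in
    ``exclude`` (QC failures, relatives) are dropped before counting.
    """
    pheno = (
        phenotypes.set_index("sample_id")
        if "sample_id" in phenotypes.columns
        else phenotypes
    )
    samples = [s for s in matrix.sample_ids if not (exclude and s in exclude)]
    missing = [s for s in samples if s not in pheno.index]
    if missing:
        raise ValueError(f"{len(missing)} samples lack phenotype rows")
    pheno = pheno.loc[samples]
    is_case = (pheno["status"] == "case").to_numpy()
    is_male = (pheno["sex"] == "M").to_numpy()

    results: list[AssociationResult] = []
    for region in matrix.regions:
        carriers = matrix.status.loc[samples, region.cnvr_id].to_numpy()
        results.append(
            _result(region.cnvr_id, region.type, region.chromosome,
                    carriers, is_case, "all")
        )
        if region.chromosome == "X":
            for label, mask in (("male", is_male), ("female", ~is_male)):
                results.append(
                    _result(
                        region.cnvr_id,
                        region.type,
                        region.chromosome,
                        carriers[mask],
                        is_case[mask],
                        label,
                    )
                )
    return results


def select_for_validation(
    results: list[AssociationResult],
    criteria: SelectionCriteria | None = None,
    matrix: CarrierMatrix | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """Flag regions meeting the validation gate; list samples to assay.

    The default gate is the conjunction odds_ratio >= 2.0 (inclusive) AND
    case carriers >= 2 (``criteria.combine="or"`` switches to the
    disjunction).  When the carrier matrix and phenotypes are given, up to
    ``max_validation_samples`` case carriers are listed per flagged region,
    prioritizing carriers supported by both callers, then by sample id for
    determinism.  Only combined-sex results are flagged (strata inherit the
    counts but are informational).
    """
    criteria = criteria or SelectionCriteria()
    pheno = None
    if phenotypes is not None:
        pheno = (
            phenotypes.set_index("sample_id")
            if "sample_id" in phenotypes.columns
            else phenotypes
        )
    for res in results:
        if res.sex_stratum != "all":
            continue
        hits_or = (not res.degenerate or res.table.a > 0) and (
            res.odds_ratio >= criteria.min_odds_ratio
        )
        hits_rare = res.table.a >= criteria.min_case_carriers
        res.selected_for_validation = (
            (hits_or and hits_rare) if criteria.combine == "and" else (hits_or or hits_rare)
        )
        if not res.selected_for_validation or matrix is None or pheno is None:
            continue
        status = matrix.status[res.region_id]
        prov = matrix.provenance[res.region_id]
        carriers = [
            s
            for s in status.index[status]
            if s in pheno.index and pheno.loc[s, "status"] == "case"
        ]
        carriers.sort(key=lambda s: (0 if prov[s] == "both" else 1, s))
        res.validation_samples = tuple(carriers[: criteria.max_validation_samples])
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flat results table mirroring the published column order.

    Infinite odds ratios are rendered as "inf"; a Bonferroni-corrected
    column is included for convenience but plays no role in selection.
    """
    n_tests = sum(1 for r in results if r.sex_stratum == "all") or 1
    rows = []
    for r in results:
        rows.append(
            {
                "region_id": r.region_id,
                "chromosome": r.chromosome,
                "type": r.type,
                "sex_stratum": r.sex_stratum,
                "total_cases": r.table.n_case,
                "total_controls": r.table.n_control,
                "odds_ratio": "inf" if math.isinf(r.odds_ratio) else round(r.odds_ratio, 6),
                "p_value": r.p_value,
                "p_bonferroni": min(r.p_value * n_tests, 1.0),
                "case_carriers": r.table.a,
                "control_carriers": r.table.b,
                "degenerate": r.degenerate,
                "selected": r.selected_for_validation,
                "validation_samples": ",".join(r.validation_samples),
            }
        )
    return pd.DataFrame(rows)


def manhattan_plot(results: list[AssociationResult], path: str) -> None:
    """Region-index vs -log10(p) plot with alternating chromosome colors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = [r for r in results if r.sex_stratum == "all"]
    if not res:
        warnings.warn("no results to plot")
        return
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r.chromosome for r in res))}
    xs = np.arange(len(res))
    ys = [-math.log10(max(r.p_value, 1e-300)) for r in res]
    colors = ["tab:red" if chrom_order[r.chromosome] % 2 else "tab:blue" for r in res]
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(xs, ys, s=12, c=colors)
    ax.set_xlabel("CNV region index")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
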