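"""Published contingency counts for the 56 reported CNV regions.

The replication study reported, per CNV region, the usable case/control
totals, carrier counts, a sample odds ratio and a Fisher p-value.  Those
printed counts are inputs here: :func:`recompute_statistics` rebuilds every
2x2 table and recomputes the statistics with this package, which is both a
regression surface for :mod:`cnvpanel.association` and a worked example.

Flags carried per row (from cross-checking the printed statistics against
the counts):

* ``or_printed`` — printed odds ratio; matches (a*d)/(b*c) to 2 d.p. for
  every row except ``discordant_or`` rows, where the printed value cannot
  be derived from the printed counts.
* ``p_sided`` — ``two`` when the printed p-value is the two-sided
  point-probability Fisher p of the counts, ``one`` when it matches the
  one-sided (enrichment) p instead, ``none`` when it matches neither.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import hypergeom

from .association import fisher_two_sided, sample_odds_ratio
from .types import ContingencyTable

__all__ = ["study_regions", "recompute_statistics"]

# columns: row_id, cytoband, coords, type, n_case, n_control, a (case
# carriers), b (control carriers), or_printed, p_printed, p_sided,
# discordant_or
_ROWS = [
    # --- regions discovered in the high-risk families / sequence SNVs ---
    ("fam_1q21.1_dup", "1q21.1", "chr1:145703115-145736438", "gain", 1542, 5754, 9, 10, 3.37, 9.60e-03, "two", False),
    ("fam_1q41_del", "1q41", "chr1:215854466-215861792", "loss", 1540, 5754, 22, 39, 2.12, 5.02e-03, "one", False),
    ("fam_2p16.3_del", "2p16.3", "chr2:51266798-51339236", "loss", 1542, 5755, 4, 1, 14.96, 8.26e-03, "two", False),
    ("fam_3q26.31_dup", "3q26.31", "chr3:172591359-172604675", "gain", 1540, 5754, 1, 1, 3.74, 2.11e-01, "none", False),
    ("fam_4q35.2_del", "4q35.2", "chr4:189084240-189117031", "loss", 1544, 5762, 2, 2, 3.74, 1.98e-01, "two", False),
    ("fam_6p24.3_del", "6p24.3", "chr6:7461346-7470321", "loss", 1544, 5762, 1, 0, math.inf, 2.11e-01, "two", False),
    ("fam_6q11.1_dup", "6q11.1", "chr6:62426827-62472074", "gain", 1544, 5762, 2, 2, 3.74, 1.98e-01, "two", False),
    ("fam_6q24.3_del", "6q24.3", "chr6:147577803-147684318", "loss", 1533, 5751, 1, 0, math.inf, 2.10e-01, "two", False),
    ("fam_7p22.1_dup", "7p22.1", "chr7:6870635-6871412", "gain", 1544, 5762, 2, 1, 7.47, 1.15e-01, "two", False),
    ("seq_7q21.3_del", "7q21.3", "chr7:93070811-93116320", "loss", 1544, 5762, 2, 0, math.inf, 4.46e-02, "two", False),
    ("fam_9p21.1_del_a", "9p21.1", "chr9:28207468-28348133", "loss", 1544, 5761, 4, 4, 3.74, 6.72e-02, "two", False),
    ("fam_9p21.1_del_b", "9p21.1", "chr9:28354180-28354967", "loss", 1544, 5762, 1, 1, 3.73, 3.78e-01, "two", False),
    ("fam_10q23.1_del", "10q23.1", "chr10:83886963-83888343", "loss", 1505, 5640, 7, 7, 3.76, 1.54e-02, "two", False),
    ("fam_10q23.31_dup", "10q23.31", "chr10:92262627-92298079", "gain", 1544, 5761, 2, 1, 7.47, 1.15e-01, "two", False),
    ("fam_12q23.2_dup", "12q23.2", "chr12:102095178-102108946", "gain", 1544, 5762, 2, 1, 7.47, 1.15e-01, "two", False),
    ("fam_13q13.3_del", "13q13.3", "chr13:40089105-40090197", "loss", 1544, 5761, 1, 0, math.inf, 2.11e-01, "two", False),
    ("seq_14q32.2_dup", "14q32.2", "chr14:100705631-100828134", "gain", 1544, 5762, 5, 2, 9.36, 5.99e-03, "two", False),
    ("seq_14q32.31_dup_a", "14q32.31", "chr14:102018946-102026138", "gain", 1544, 5762, 60, 50, 4.62, 1.01e-14, "two", False),
    ("seq_14q32.31_del", "14q32.31", "chr14:102729881-102749930", "loss", 1544, 5762, 2, 1, 7.47, 1.15e-01, "two", False),
    ("seq_14q32.31_dup_b", "14q32.31", "chr14:102973910-102975572", "gain", 1544, 5762, 136, 142, 3.82, 8.29e-26, "one", False),
    ("seq_15q11.2-q13.1_dup", "15q11.2-q13.1", "chr15:25690465-28513763", "gain", 1544, 5762, 11, 1, 41.05, 1.82e-08, "none", True),
    ("seq_15q13.2-q13.3_del", "15q13.2-15q13.3", "chr15:31092983-31369123", "loss", 1543, 5761, 2, 0, math.inf, 4.46e-02, "two", False),
    ("seq_15q13.3_dup", "15q13.3", "chr15:31776648-31822910", "gain", 1544, 5762, 21, 18, 4.40, 6.91e-06, "two", False),
    ("seq_20q11.22_dup", "20q11.22", "chr20:32210931-32441302", "gain", 1544, 5762, 8, 11, 2.72, 3.16e-02, "one", False),
    # --- literature-reported regions -----------------------------------
    ("lit_1q21.1_dup", "1q21.1", "chr1:146656292-146707824", "gain", 1543, 5761, 2, 1, 7.48, 1.15e-01, "two", False),
    ("lit_2p24.3_del", "2p24.3", "chr2:13203874-13209245", "loss", 1544, 5761, 1, 0, math.inf, 2.11e-01, "two", False),
    ("lit_2p21_dup", "2p21", "chr2:45489954-45492582", "gain", 1541, 5756, 2, 0, math.inf, 4.46e-02, "two", False),
    ("lit_2p16.3_del", "2p16.3", "chr2:51237767-51245359", "loss", 1544, 5762, 4, 0, math.inf, 1.99e-03, "two", False),
    ("lit_2p15_dup", "2p15", "chr2:62230970-62367720", "gain", 1543, 5762, 1, 0, math.inf, 2.11e-01, "two", False),
    ("lit_2q14.1_del", "2q14.1", "chr2:115133493-115140263", "loss", 1543, 5759, 2, 1, 7.47, 1.15e-01, "two", False),
    ("lit_3p26.3_del", "3p26.3", "chr3:1937796-1941004", "loss", 1544, 5760, 3, 2, 5.60, 6.70e-02, "two", False),
    ("lit_3p14.1_del", "3p14.1", "chr3:67657429-68962928", "loss", 1544, 5762, 1, 0, math.inf, 2.11e-01, "two", False),
    ("lit_4q13.3_dup", "4q13.3", "chr4:73766964-73816870", "gain", 1544, 5760, 1, 0, math.inf, 2.11e-01, "two", False),
    ("lit_4q33_del", "4q33", "chr4:171366005-171471530", "loss", 1543, 5761, 2, 0, math.inf, 4.46e-02, "two", False),
    ("lit_5q23.1_dup", "5q23.1", "chr5:118527524-118589485", "gain", 1541, 5760, 2, 2, 3.74, 1.98e-01, "two", False),
    ("lit_6p21.2_del", "6p21.2", "chr6:39069291-39072241", "loss", 1544, 5759, 12, 19, 2.37, 1.93e-02, "one", False),
    ("lit_8q11.23_dup", "8q11.23", "chr8:54855680-54912001", "gain", 1544, 5762, 1, 0, math.inf, 2.11e-01, "two", False),
    ("lit_10q11.22_dup", "10q11.22", "chr10:49370090-49471091", "gain", 1528, 5750, 2, 2, 3.77, 1.96e-01, "two", False),
    ("lit_10q11.23_dup", "10q11.23", "chr10:50884949-50943185", "gain", 1542, 5760, 2, 2, 3.74, 1.98e-01, "two", False),
    ("lit_12q13.13_del", "12q13.13", "chr12:53177144-53180552", "loss", 1544, 5762, 2, 0, math.inf, 4.46e-02, "two", False),
    ("lit_15q11.1_dup", "15q11.1", "chr15:20192970-20197164", "gain", 1515, 5632, 4, 3, 4.97, 4.06e-02, "two", False),
    ("lit_15q11.2_del", "15q11.2", "chr15:25099351-25102073", "loss", 1540, 5761, 3, 3, 3.75, 1.13e-01, "two", False),
    ("lit_15q11.2_dup_a", "15q11.2", "chr15:25099351-25102073", "gain", 1541, 5759, 12, 1, 45.19, 7.93e-08, "two", False),
    ("lit_15q11.2_dup_b", "15q11.2", "chr15:25579767-25581658", "gain", 1540, 5761, 8, 0, math.inf, 3.86e-06, "two", False),
    ("lit_15q11.2_dup_c", "15q11.2", "chr15:25582882-25662988", "gain", 1540, 5762, 8, 1, 30.08, 2.82e-05, "two", False),
    ("lit_16p12.2_dup", "16p12.2", "chr16:21958486-22172866", "gain", 1544, 5761, 2, 0, math.inf, 4.47e-02, "two", False),
    ("lit_16p11.2_del", "16p11.2", "chr16:29664753-30177298", "loss", 1544, 5761, 2, 1, 7.47, 1.15e-01, "two", False),
    ("lit_16q23.3_dup", "16q23.3", "chr16:82423855-82445055", "gain", 1542, 5758, 2, 0, math.inf, 4.46e-02, "two", False),
    ("lit_17p12_dup_a", "17p12", "chr17:14132271-14133349", "gain", 1544, 5762, 3, 7, 1.60, 3.57e-01, "one", False),
    ("lit_17p12_del_a", "17p12", "chr17:14132271-15282708", "loss", 1544, 5761, 3, 2, 5.61, 6.70e-02, "two", False),
    ("lit_17p12_dup_b", "17p12", "chr17:14952999-15053648", "gain", 1543, 5760, 2, 2, 3.74, 1.98e-01, "two", False),
    ("lit_17p12_del_b", "17p12", "chr17:15283960-15287134", "loss", 1544, 5761, 3, 3, 3.74, 1.13e-01, "two", False),
    ("lit_20p12.3_dup", "20p12.3", "chr20:8162278-8313229", "gain", 1544, 5761, 2, 2, 3.73, 1.98e-01, "two", False),
    ("lit_Xp21.2_dup", "Xp21.2", "chrX:29944502-29987870", "gain", 1544, 5760, 2, 0, math.inf, 4.47e-02, "two", False),
    ("lit_Xq27.2_del", "Xq27.2", "chrX:140329633-140348506", "loss", 1544, 5762, 4, 2, 7.48, 2.06e-02, "two", False),
    ("lit_Xq28_del", "Xq28", "chrX:148882559-148886166", "loss", 1540, 5754, 2, 0, math.inf, 4.46e-02, "two", False),
]

_COLUMNS = [
    "row_id", "cytoband", "coords", "type", "n_case", "n_control",
    "case_carriers", "control_carriers", "or_printed", "p_printed",
    "p_sided", "discordant_or",
]


def study_regions() -> pd.DataFrame:
    """The published per-region counts and statistics as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def _fisher_one_sided_greater(t: ContingencyTable) -> float:
    """One-sided (case-enrichment) Fisher p, for the rows printed that way."""
    m = t.a + t.b
    n_total = t.n_case + t.n_control
    return float(hypergeom.sf(t.a - 1, n_total, m, t.n_case))


def recompute_statistics() -> pd.DataFrame:
    """Rebuild each published 2x2 table and recompute OR and Fisher p.

    Adds ``or_recomputed``, ``p_two_sided``, ``p_one_sided`` and agreement
    columns: ``or_match`` (2 d.p. against the printed OR) and ``p_match``
    (3 significant figures against the printed p, using the sidedness the
    row was printed with; rows flagged ``p_sided == "none"`` never match).
    """
    df = study_regions()
    recomputed = []
    for row in df.itertuples(index=False):
        t = ContingencyTable(
            a=row.case_carriers,
            c=row.n_case - row.case_carriers,
            b=row.control_carriers,
            d=row.n_control - row.control_carriers,
        )
        orr, _ = sample_odds_ratio(t)
        p2 = fisher_two_sided(t)
        p1 = _fisher_one_sided_greater(t)
        if row.p_sided == "two":
            p_cmp = p2
        elif row.p_sided == "one":
            p_cmp = p1
        else:
            p_cmp = float("nan")
        or_match = (
            math.isinf(orr) and math.isinf(row.or_printed)
        ) or (
            not math.isinf(orr)
            and not math.isinf(row.or_printed)
            and round(orr, 2) == round(row.or_printed, 2)
        )
        p_match = (not math.isnan(p_cmp)) and (
            f"{p_cmp:.2e}" == f"{row.p_printed:.2e}"
        )
        recomputed.append((orr, p2, p1, or_match, p_match))
    extra = pd.DataFrame(
        recomputed,
        columns=["or_recomputed", "p_two_sided", "p_one_sided", "or_match", "p_match"],
    )
    return pd.concat([df, extra], axis=1)
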