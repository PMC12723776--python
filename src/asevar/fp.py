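"""Screening for false-positive-prone genes.

A gene repeatedly called a dosage outlier across many samples of a reference
cohort is more likely mis-modeled (e.g. imprinted, mapping-biased) than
repeatedly biologically aberrant.  The screen computes, per gene, the exact
binomial (Clopper–Pearson) confidence interval on its cohort-wide outlier
rate and flags genes whose lower bound exceeds a threshold rate (default 1%);
flagged genes form an exclusion list for subsequent outlier testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta, binomtest

__all__ = ["clopper_pearson", "screen_fp_genes", "exclusion_list"]

FP_RATE_THRESHOLD = 0.01


def clopper_pearson(k: int, m: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided CI for a binomial proportion with k successes in m trials.

    Bounds invert the binomial tails via beta quantiles:
    ``low = BetaQ(alpha/2; k, m-k+1)`` (0 when k = 0) and
    ``high = BetaQ(1-alpha/2; k+1, m-k)`` (1 when k = m).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= k <= m:
        raise ValueError("k must be in [0, m]")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, m - k + 1))
    high = 1.0 if k == m else float(beta.ppf(1.0 - alpha / 2.0, k + 1, m - k))
    return low, high


def screen_fp_genes(
    dot_results: pd.DataFrame,
    threshold: float = FP_RATE_THRESHOLD,
    level: float = 0.95,
) -> pd.DataFrame:
    """Flag genes whose outlier-rate lower confidence bound exceeds ``threshold``.

    Parameters
    ----------
    dot_results : DataFrame
        Cohort-wide outlier test results (``gene_id``, ``tested``,
        ``outlier`` columns; one row per sample-gene).

    Returns
    -------
    DataFrame
        One row per gene tested in >= 1 sample: tested count ``m``, outlier
        count ``k``, rate, Clopper–Pearson bounds, a two-sided binomial-test
        p-value against the threshold rate (informational), and the flag
        ``cp_low > threshold``.
    """
    columns = ["gene_id", "m", "k", "rate", "cp_low", "cp_high", "binom_p", "flagged"]
    if dot_results.empty:
        return pd.DataFrame(columns=columns)
    tested = dot_results[dot_results["tested"].astype(bool)]
    rows = []
    for gene, grp in tested.groupby("gene_id", sort=False):
        m = int(len(grp))
        k = int(grp["outlier"].sum())
        low, high = clopper_pearson(k, m, level)
        rows.append(
            {
                "gene_id": gene,
                "m": m,
                "k": k,
                "rate": k / m,
                "cp_low": low,
                "cp_high": high,
                "binom_p": binomtest(k, m, threshold).pvalue,
                "flagged": low > threshold,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def exclusion_list(fp_table: pd.DataFrame) -> list[str]:
    """Gene ids flagged as false-positive prone, in table order."""
    return fp_table.loc[fp_table["flagged"], "gene_id"].tolist()
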