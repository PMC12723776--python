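"""Dosage outlier test (DOT) on haplotype-level ASE.

For one sample, each gene with sufficient coverage is tested for allelic
imbalance beyond what the population's regulatory variability predicts: the
null is the symmetric binomial-logit-normal law BLN(n = a + b, mu = 0,
sigma = reference sd_g), the p-value the doubled smaller tail, and p-values
are Benjamini–Hochberg adjusted within the sample over the tested genes of
the FDR gene universe (conventionally protein-coding + lncRNA).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bln import DEFAULT_QUAD_ORDER, _two_sided_p_arrays
from .containers import GeneUniverse, HaplotypeCountMatrix

__all__ = ["bh_adjust", "dot_sample", "dot_cohort"]

MIN_COVERAGE = 10
ALPHA = 0.05

RESULT_COLUMNS = [
    "sample_id",
    "gene_id",
    "a_count",
    "b_count",
    "total",
    "ref_sd_g",
    "p_value",
    "q_value",
    "tested",
    "outlier",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _reference_series(vg_reference: pd.DataFrame) -> pd.Series:
    if "gene_id" in vg_reference.columns:
        ref = vg_reference.set_index("gene_id")["sd_g"]
    else:
        ref = vg_reference["sd_g"]
    if ref.index.has_duplicates:
        raise ValueError("vg_reference has duplicate gene_ids")
    return ref.astype(float)


def dot_sample(
    sample_counts: pd.DataFrame,
    vg_reference: pd.DataFrame,
    gene_universe: GeneUniverse | set,
    sample_id: str = "",
    min_coverage: int = MIN_COVERAGE,
    alpha: float = ALPHA,
    exclude: set | None = None,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> pd.DataFrame:
    """Outlier-test every gene of one sample.

    Parameters
    ----------
    sample_counts : DataFrame
        Columns ``gene_id``, ``a_count``, ``b_count`` (one row per gene).
    vg_reference : DataFrame
        Reference table with ``gene_id`` and ``sd_g`` columns (the SD of the
        latent log allelic fold change; convert external variance-convention
        tables on load).
    gene_universe : GeneUniverse or set
        Genes over which FDR is controlled.
    exclude : set, optional
        False-positive-prone genes to leave untested.

    Returns
    -------
    DataFrame
        One row per input gene.  ``tested`` is true iff total >= min_coverage,
        a reference sd_g exists, the gene is in the universe, and it is not
        excluded; p/q-values are NaN for untested genes.
    """
    ref = _reference_series(vg_reference)
    universe = gene_universe.gene_ids if isinstance(gene_universe, GeneUniverse) else set(gene_universe)
    exclude = exclude or set()

    df = sample_counts[["gene_id", "a_count", "b_count"]].copy()
    df["sample_id"] = sample_id
    df["total"] = df["a_count"] + df["b_count"]
    df["ref_sd_g"] = df["gene_id"].map(ref)
    df["tested"] = (
        (df["total"] >= min_coverage)
        & df["ref_sd_g"].notna()
        & df["gene_id"].isin(universe)
        & ~df["gene_id"].isin(exclude)
    )
    df["p_value"] = np.nan
    df["q_value"] = np.nan

    tested = df[df["tested"]]
    if tested.empty:
        warnings.warn(f"sample {sample_id!r}: no testable genes", stacklevel=2)
    # group by reference sd_g so each tail integral is vectorized over genes
    for sd, grp in tested.groupby("ref_sd_g", sort=True):
        p = _two_sided_p_arrays(
            grp["a_count"].to_numpy(float), grp["total"].to_numpy(float), 0.0, float(sd), quad_order
        )
        df.loc[grp.index, "p_value"] = p
    mask = df["tested"].to_numpy()
    if mask.any():
        df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    df["outlier"] = df["tested"] & (df["q_value"] <= alpha)
    return df[RESULT_COLUMNS].reset_index(drop=True)


def dot_cohort(
    counts: HaplotypeCountMatrix,
    vg_reference: pd.DataFrame,
    gene_universe: GeneUniverse | set,
    min_coverage: int = MIN_COVERAGE,
    alpha: float = ALPHA,
    exclude: set | None = None,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the outlier test independently on every sample of a cohort.

    Returns ``(results, summary)``: the concatenated per-sample result
    tables, and one summary row per sample with the number of tested genes,
    outliers, and the positivity rate (outliers / tested).
    """
    tables = []
    summary_rows = []
    for sample in counts.sample_ids:
        sc = pd.DataFrame(
            {
                "gene_id": counts.gene_ids,
                "a_count": counts.a[sample].to_numpy(),
                "b_count": counts.b[sample].to_numpy(),
            }
        ).dropna(subset=["a_count"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dot_sample(
                sc,
                vg_reference,
                gene_universe,
                sample_id=sample,
                min_coverage=min_coverage,
                alpha=alpha,
                exclude=exclude,
                quad_order=quad_order,
            )
        tables.append(res)
        n_tested = int(res["tested"].sum())
        n_out = int(res["outlier"].sum())
        summary_rows.append(
            {
                "sample_id": sample,
                "n_tested": n_tested,
                "n_outliers": n_out,
                "positivity_rate": n_out / n_tested if n_tested else np.nan,
            }
        )
    results = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=RESULT_COLUMNS)
    summary = pd.DataFrame(summary_rows, columns=["sample_id", "n_tested", "n_outliers", "positivity_rate"])
    return results, summary
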