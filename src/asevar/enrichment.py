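"""Rare-variant enrichment among dosage outliers.

Joins per-(individual, gene) outlier calls to precomputed rare-variant
carrier annotations (consequence-class resolved; MAF filtering and the gene
window are upstream) and quantifies enrichment as a relative risk: the ratio
of rare-variant carrier rates between outlier and non-outlier pairs, with a
Katz log-normal confidence interval.  Results can be stratified by variant
consequence class and by outlier significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentResult",
    "build_pairs",
    "relative_risk",
    "enrichment_by_significance",
]

VARIANT_COLUMNS = ["individual_id", "gene_id", "consequence_class", "carries_rare"]
Z975 = 1.959963984540054


@dataclass
class EnrichmentResult:
    """2x2 outlier-by-carrier contingency summary for one stratum."""

    stratum: str
    a: int  # outlier, carrier
    b: int  # outlier, non-carrier
    c: int  # non-outlier, carrier
    d: int  # non-outlier, non-carrier
    rr: float
    ci_low: float
    ci_high: float
    odds_ratio: float
    haldane: bool  # +0.5 continuity correction applied to all cells


def _validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if variants.duplicated(["individual_id", "gene_id", "consequence_class"]).any():
        raise ValueError("variant table has duplicate (individual, gene, class) records")
    return variants


def build_pairs(
    dot_results: pd.DataFrame,
    variants: pd.DataFrame,
    restrict_to_outlier_genes: bool = True,
) -> pd.DataFrame:
    """Tested (individual, gene) pairs labeled by outlier status and per-class
    carrier status.

    Pairs are restricted to genes that are an outlier in at least one
    individual when ``restrict_to_outlier_genes`` (the default, matching the
    enrichment protocol); a pair with no variant record is a non-carrier in
    every class (closed-world default).
    """
    variants = _validate_variants(variants)
    tested = dot_results[dot_results["tested"]][
        ["sample_id", "gene_id", "p_value", "q_value", "outlier"]
    ].rename(columns={"sample_id": "individual_id"})
    if restrict_to_outlier_genes:
        keep_genes = set(tested.loc[tested["outlier"], "gene_id"])
        tested = tested[tested["gene_id"].isin(keep_genes)]
    pairs = tested.copy()

    var_ind = set(variants["individual_id"])
    if var_ind and not tested.empty and var_ind.isdisjoint(set(tested["individual_id"])):
        raise ValueError(
            f"variant and outlier tables share no individuals "
            f"(first unmatched: {sorted(var_ind)[0]!r})"
        )

    carriers = variants[variants["carries_rare"].astype(bool)]
    wide = (
        carriers.assign(flag=True)
        .pivot_table(
            index=["individual_id", "gene_id"],
            columns="consequence_class",
            values="flag",
            aggfunc="any",
            fill_value=False,
        )
        .add_prefix("carrier_")
        .reset_index()
    )
    pairs = pairs.merge(wide, on=["individual_id", "gene_id"], how="left")
    for col in pairs.columns:
        if col.startswith("carrier_"):
            pairs[col] = pairs[col].astype("boolean").fillna(False).astype(bool)
    classes = sorted(variants["consequence_class"].unique())
    for cls in classes:
        if f"carrier_{cls}" not in pairs.columns:
            pairs[f"carrier_{cls}"] = False
    pairs["carrier_any"] = (
        pairs[[c for c in pairs.columns if c.startswith("carrier_")]].any(axis=1)
        if classes
        else False
    )
    return pairs.reset_index(drop=True)


def relative_risk(pairs: pd.DataFrame, stratum: str = "any") -> EnrichmentResult | None:
    """Relative risk of rare-variant carriage in outlier vs non-outlier pairs.

    ``rr = (a/(a+b)) / (c/(c+d))`` from the 2x2 table of the given
    consequence-class stratum, with Katz CI
    ``exp(log rr +/- 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``.  Any zero
    cell triggers a Haldane–Anscombe +0.5 on all four cells (recorded in the
    result).  Returns None (with a warning) for an empty stratum.
    """
    col = f"carrier_{stratum}" if stratum != "any" else "carrier_any"
    if col not in pairs.columns:
        raise ValueError(f"no carrier column for stratum {stratum!r}")
    out = pairs["outlier"].to_numpy(bool)
    car = pairs[col].to_numpy(bool)
    a = int(np.sum(out & car))
    b = int(np.sum(out & ~car))
    c = int(np.sum(~out & car))
    d = int(np.sum(~out & ~car))
    if a + b == 0 or c + d == 0:
        warnings.warn(f"stratum {stratum!r}: empty outlier or non-outlier margin; skipped", stacklevel=2)
        return None
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if haldane else (a, b, c, d)
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se = np.sqrt(1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd))
    odds = (aa / bb) / (cc / dd)
    return EnrichmentResult(
        stratum=stratum,
        a=a,
        b=b,
        c=c,
        d=d,
        rr=float(rr),
        ci_low=float(rr * np.exp(-Z975 * se)),
        ci_high=float(rr * np.exp(Z975 * se)),
        odds_ratio=float(odds),
        haldane=haldane,
    )


def enrichment_by_significance(
    pairs: pd.DataFrame,
    thresholds,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Relative risk per (q-value threshold, consequence class).

    Outlier labels are recomputed at each threshold (``q <= t``) over the
    same tested pairs, so pairs outlying at a stricter threshold are a subset
    of those at a looser one.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        warnings.warn("thresholds were not sorted; sorting ascending", stacklevel=2)
        thresholds = sorted(thresholds)
    if strata is None:
        strata = sorted(
            c.removeprefix("carrier_") for c in pairs.columns if c.startswith("carrier_")
        )
    rows = []
    for t in thresholds:
        relabeled = pairs.copy()
        relabeled["outlier"] = relabeled["q_value"] <= t
        for stratum in strata:
            res = relative_risk(relabeled, stratum)
            if res is None:
                continue
            rows.append(
                {
                    "threshold": t,
                    "stratum": res.stratum,
                    "a": res.a,
                    "b": res.b,
                    "c": res.c,
                    "d": res.d,
                    "rr": res.rr,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "odds_ratio": res.odds_ratio,
                    "haldane": res.haldane,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "stratum",
            "a",
            "b",
            "c",
            "d",
            "rr",
            "ci_low",
            "ci_high",
            "odds_ratio",
            "haldane",
        ],
    )
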