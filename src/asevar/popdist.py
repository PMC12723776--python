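"""Cross-population comparison of regulatory-variance estimates.

Two complementary views: (1) a similarity matrix over populations, where each
pair is scored by the fraction of common genes whose sd_g 95% confidence
intervals overlap (1 = complete overlap, 0 = none; D = 1 - S is the distance
fed to hierarchical clustering); and (2) the cross-population outlier-rate
matrix, testing each population's ASE against every population's reference
V^G table and recording the median per-sample outlier count, with
fold-increase relative to the ancestry-matched diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import GeneUniverse, HaplotypeCountMatrix
from .dot import ALPHA, MIN_COVERAGE, dot_cohort

__all__ = ["SimilarityMatrix", "ci_overlap_similarity", "cross_population_dot"]


@dataclass
class SimilarityMatrix:
    """CI-overlap similarity S (and distance D = 1 - S) between populations."""

    population_ids: list[str]
    S: pd.DataFrame
    n_common_genes: int

    @property
    def D(self) -> pd.DataFrame:
        return 1.0 - self.S

    def cluster(self, method: str = "average") -> np.ndarray:
        """Hierarchical clustering linkage of D (visualization aid only)."""
        return linkage(squareform(self.D.to_numpy(), checks=False), method=method)


def _indexed(table: pd.DataFrame) -> pd.DataFrame:
    t = table.set_index("gene_id") if "gene_id" in table.columns else table
    return t[["ci_low", "ci_high"]].astype(float)


def ci_overlap_similarity(vgs: dict[str, pd.DataFrame]) -> SimilarityMatrix:
    """Pairwise CI-overlap fraction over the populations' common genes.

    For populations p, q: ``S[p, q]`` is the fraction of common genes whose
    [ci_low, ci_high] intervals intersect (closed intervals — touching
    endpoints overlap).
    """
    if len(vgs) < 2:
        raise ValueError("need at least 2 populations")
    pops = list(vgs)
    tables = {p: _indexed(vgs[p]) for p in pops}
    common = tables[pops[0]].index
    for p in pops[1:]:
        common = common.intersection(tables[p].index)
    if len(common) == 0:
        raise ValueError("populations share no common genes")
    lows = np.stack([tables[p].loc[common, "ci_low"].to_numpy() for p in pops])
    highs = np.stack([tables[p].loc[common, "ci_high"].to_numpy() for p in pops])
    k = len(pops)
    S = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            overlap = (lows[i] <= highs[j]) & (lows[j] <= highs[i])
            S[i, j] = S[j, i] = overlap.mean()
    frame = pd.DataFrame(S, index=pops, columns=pops)
    return SimilarityMatrix(population_ids=pops, S=frame, n_common_genes=len(common))


def cross_population_dot(
    ase_by_pop: dict[str, HaplotypeCountMatrix],
    vgs: dict[str, pd.DataFrame],
    gene_universe: GeneUniverse | set,
    min_coverage: int = MIN_COVERAGE,
    alpha: float = ALPHA,
    exclude: set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median per-sample outlier counts for every (test pop, reference pop) cell.

    Returns ``(medians, fold_increase)`` DataFrames, rows = test population
    (ASE source), columns = reference population (V^G source).  Fold increase
    is each cell divided by its row's matched diagonal cell; cells with a
    missing reference are NaN.
    """
    test_pops = list(ase_by_pop)
    ref_pops = list(vgs)
    med = pd.DataFrame(np.nan, index=test_pops, columns=ref_pops, dtype=float)
    for t in test_pops:
        for r in ref_pops:
            _, summary = dot_cohort(
                ase_by_pop[t],
                vgs[r],
                gene_universe,
                min_coverage=min_coverage,
                alpha=alpha,
                exclude=exclude,
            )
            med.loc[t, r] = float(summary["n_outliers"].median())
    fold = med.copy()
    for t in test_pops:
        base = med.loc[t, t] if t in ref_pops else np.nan
        fold.loc[t] = med.loc[t] / base if base and not np.isnan(base) else np.nan
        if t in ref_pops and not np.isnan(base):
            fold.loc[t, t] = 1.0  # matched diagonal, by construction (also when base = 0)
    return med, fold
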