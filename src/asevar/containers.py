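"""Core in-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HaplotypeCountMatrix", "GeneUniverse"]


@dataclass
class HaplotypeCountMatrix:
    """Gene x sample paired haplotype read counts.

    ``a`` and ``b`` are float DataFrames (genes as index, samples as columns)
    holding non-negative integers, with NaN marking entries missing in both
    haplotypes.  ``total = a + b`` is the coverage every downstream filter
    uses.
    """

    a: pd.DataFrame
    b: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.a.index.equals(self.b.index) or not self.a.columns.equals(self.b.columns):
            raise ValueError("a and b count matrices must share genes and samples")
        if self.a.index.has_duplicates or self.a.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        av, bv = self.a.to_numpy(dtype=float), self.b.to_numpy(dtype=float)
        if np.any(np.isnan(av) != np.isnan(bv)):
            raise ValueError("a and b entries must be missing together")
        with np.errstate(invalid="ignore"):
            if np.any(av < 0) or np.any(bv < 0):
                raise ValueError("haplotype counts must be non-negative")
            if np.any(av[~np.isnan(av)] % 1 != 0) or np.any(bv[~np.isnan(bv)] % 1 != 0):
                raise ValueError("haplotype counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.a.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.a.columns)

    @property
    def n_genes(self) -> int:
        return self.a.shape[0]

    @property
    def n_samples(self) -> int:
        return self.a.shape[1]

    def totals(self) -> pd.DataFrame:
        return self.a + self.b

    @classmethod
    def from_arrays(cls, gene_ids, sample_ids, a_counts, b_counts) -> "HaplotypeCountMatrix":
        idx = pd.Index(gene_ids, name="gene_id")
        cols = pd.Index(sample_ids, name="sample_id")
        return cls(
            pd.DataFrame(np.asarray(a_counts, dtype=float), index=idx, columns=cols),
            pd.DataFrame(np.asarray(b_counts, dtype=float), index=idx, columns=cols),
        )

    def strip_gene_versions(self) -> "HaplotypeCountMatrix":
        """Return a copy with Ensembl-style '.NN' version suffixes removed."""
        stripped = self.a.index.str.replace(r"\.\d+$", "", regex=True)
        a = self.a.copy()
        b = self.b.copy()
        a.index = stripped
        b.index = stripped
        return HaplotypeCountMatrix(a, b)


@dataclass
class GeneUniverse:
    """Set of gene ids over which FDR correction is performed, with optional
    biotype labels (e.g. protein_coding, lncRNA)."""

    gene_ids: set = field(default_factory=set)
    biotypes: dict = field(default_factory=dict)  # gene_id -> biotype, optional

    def __post_init__(self) -> None:
        self.gene_ids = set(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)
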