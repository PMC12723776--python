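"""Synthetic populations of haplotype-level ASE with known ground truth.

The generator embodies the package's own generative law so every downstream
module is testable without external data: per gene g, a regulatory SD
``sd_g(g)`` is drawn from a configurable law; per individual i, the latent
log allelic fold change ``delta ~ Normal(0, sd_g^2)``, the total coverage
from a coverage law (log-uniform on [30, 3000] by default — spanning the
eligibility threshold through deep coverage), and the haplotype-A count
``a ~ Binomial(total, logistic(delta))``.  Planted outliers replace delta
with a fixed large effect (random sign — haplotype labels are arbitrary) or
force complete monoallelic expression.  A companion generator fabricates
rare-variant carrier tables with a configurable carrier-rate uplift among
planted outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import HaplotypeCountMatrix

__all__ = ["SimConfig", "simulate_population", "simulate_variant_table"]


@dataclass
class SimConfig:
    """Configuration of one synthetic ASE population.

    Attributes
    ----------
    seed : int
        Seed for all randomness; identical configs give identical outputs.
    n_genes, n_individuals : int
        Cohort dimensions.
    sd_g_law : tuple
        ``("fixed", value)``, ``("grid", [values])`` (cycled across genes), or
        ``("lognormal", mean_log, sd_log)`` across genes.
    coverage_law : tuple
        ``("loguniform", min_total, max_total)`` or
        ``("negbin", mean, dispersion)`` (totals clipped to >= 1).
    outlier_fraction : float
        Fraction of (gene, individual) cells planted as outliers.
    outlier_effect : float or "monoallelic"
        Planted |log allelic fold change| (sign randomized), or complete
        monoallelic expression (a = total or 0).
    variant_classes : dict
        class name -> (base carrier rate, carrier rate given planted outlier).
    """

    seed: int = 0
    n_genes: int = 100
    n_individuals: int = 300
    sd_g_law: tuple = ("fixed", 0.2)
    coverage_law: tuple = ("loguniform", 30, 3000)
    outlier_fraction: float = 0.0
    outlier_effect: float | str = "monoallelic"
    variant_classes: dict = field(
        default_factory=lambda: {"splice_donor": (0.01, 0.5), "missense": (0.05, 0.3)}
    )

    def validate(self) -> None:
        bad = []
        if self.n_genes < 1 or self.n_individuals < 1:
            bad.append("n_genes/n_individuals must be >= 1")
        if self.sd_g_law[0] not in ("fixed", "grid", "lognormal"):
            bad.append(f"unknown sd_g_law {self.sd_g_law[0]!r}")
        if self.coverage_law[0] not in ("loguniform", "negbin"):
            bad.append(f"unknown coverage_law {self.coverage_law[0]!r}")
        if not 0 <= self.outlier_fraction <= 1:
            bad.append("outlier_fraction must be in [0, 1]")
        if self.outlier_effect != "monoallelic" and not np.isfinite(self.outlier_effect):
            bad.append("outlier_effect must be finite or 'monoallelic'")
        for cls, (p0, p1) in self.variant_classes.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                bad.append(f"variant class {cls!r}: rates must be in [0, 1]")
        if bad:
            raise ValueError("invalid SimConfig: " + "; ".join(bad))


def _draw_sd_g(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.sd_g_law[0]
    if kind == "fixed":
        return np.full(cfg.n_genes, float(cfg.sd_g_law[1]))
    if kind == "grid":
        vals = np.asarray(cfg.sd_g_law[1], dtype=float)
        return vals[np.arange(cfg.n_genes) % len(vals)]
    mean_log, sd_log = cfg.sd_g_law[1], cfg.sd_g_law[2]
    return np.exp(rng.normal(mean_log, sd_log, size=cfg.n_genes))


def _draw_totals(cfg: SimConfig, rng: np.random.Generator, shape) -> np.ndarray:
    kind = cfg.coverage_law[0]
    if kind == "loguniform":
        lo, hi = cfg.coverage_law[1], cfg.coverage_law[2]
        return np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=shape))).astype(int)
    mean, disp = cfg.coverage_law[1], cfg.coverage_law[2]
    p = disp / (disp + mean)
    return np.maximum(rng.negative_binomial(disp, p, size=shape), 1)


def simulate_population(config: SimConfig) -> tuple[HaplotypeCountMatrix, pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns the count matrix and a truth table with one row per
    (gene, individual): true sd_g, latent delta, total, and planted flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{idx:05d}" for idx in range(config.n_genes)]
    samples = [f"S{idx:04d}" for idx in range(config.n_individuals)]
    sd_g = _draw_sd_g(config, rng)
    shape = (config.n_genes, config.n_individuals)
    totals = _draw_totals(config, rng, shape)
    delta = rng.normal(0.0, sd_g[:, None], size=shape)
    planted = rng.random(shape) < config.outlier_fraction
    signs = rng.choice([-1.0, 1.0], size=shape)
    monoallelic = config.outlier_effect == "monoallelic"
    if not monoallelic:
        delta = np.where(planted, signs * float(config.outlier_effect), delta)
    a = rng.binomial(totals, expit(delta))
    if monoallelic:
        a = np.where(planted, np.where(signs > 0, totals, 0), a)
    b = totals - a
    counts = HaplotypeCountMatrix.from_arrays(genes, samples, a, b)
    truth = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, config.n_individuals),
            "sample_id": np.tile(samples, config.n_genes),
            "true_sd_g": np.repeat(sd_g, config.n_individuals),
            "delta": delta.ravel(),
            "total": totals.ravel(),
            "planted_outlier": planted.ravel(),
        }
    )
    return counts, truth


def simulate_variant_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fabricate a rare-variant carrier table aligned to a truth table.

    Per consequence class, each (individual, gene) pair carries a rare
    variant with the class's base rate, or the elevated rate if the pair was
    a planted outlier.  Only carrier records are materialized (absent rows
    mean non-carrier downstream).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA5E)))
    rows = []
    planted = truth["planted_outlier"].to_numpy(bool)
    for cls, (p0, p1) in sorted(config.variant_classes.items()):
        rate = np.where(planted, p1, p0)
        carries = rng.random(len(truth)) < rate
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": truth["sample_id"].to_numpy(),
                    "gene_id": truth["gene_id"].to_numpy(),
                    "consequence_class": cls,
                    "carries_rare": carries,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return table[table["carries_rare"]].reset_index(drop=True)
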