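"""Synthetic inbred-panel data with controlled genetic architecture.

Emulates the shape of a reference-panel transcriptomic study: ~200 fully
inbred lines, thousands of genes with co-expression structure, line-mean
phenotypes whose broad-sense heritability

    H2m = sigma_G^2 / (sigma_G^2 + sigma_E^2 / f)

is raised towards ~0.8 by averaging the trait over f individuals per line.
Expression correlation comes from a latent-factor model; trait architectures
range from dense (every gene causal) to sparse to gene-set-enriched (all
causal genes inside one designated GO term).

Effect sizes act on the *standardized* expression scale so the target
heritability is architecture-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ExpressionMatrix,
    GeneSetCollection,
    Phenotype,
    standardize,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_expression",
    "simulate_trait",
    "simulate_genesets",
    "simulate_dataset",
    "line_mean_heritability",
]

ARCHITECTURES = ("dense", "sparse", "go_enriched")


def line_mean_heritability(sigma_G2: float, sigma_E2: float, f: int) -> float:
    """Broad-sense heritability of line means: sG2 / (sG2 + sE2/f)."""
    if f < 1:
        raise ValueError("f must be a positive integer")
    return sigma_G2 / (sigma_G2 + sigma_E2 / f)


@dataclass
class SimulationConfig:
    """Study-condition knobs for one synthetic sex/trait dataset.

    ``target_H2m`` may be given directly or implied by (sigma_G2, sigma_E2, f);
    supplying both inconsistently is an error.
    """

    n_lines: int = 200
    n_genes: int = 2000
    n_factors: int = 10
    architecture: str = "dense"
    n_causal: int | None = None
    target_H2m: float | None = 0.8
    sigma_G2: float | None = None
    sigma_E2: float | None = None
    f: int = 25
    causal_term: str | None = None
    noise_sd: float = 1.0  # idiosyncratic expression noise on top of factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.n_lines <= 0 or self.n_genes <= 0:
            raise ValueError("nonpositive dimensions")
        if self.n_factors < 0 or self.n_factors >= min(self.n_lines, self.n_genes):
            raise ValueError("need 0 <= n_factors < min(n_lines, n_genes)")
        if self.sigma_G2 is not None and self.sigma_E2 is not None:
            implied = line_mean_heritability(self.sigma_G2, self.sigma_E2, self.f)
            if self.target_H2m is None:
                self.target_H2m = implied
            elif abs(self.target_H2m - implied) > 1e-8:
                raise ValueError(
                    f"target_H2m={self.target_H2m} inconsistent with "
                    f"sigma_G2/(sigma_G2+sigma_E2/f)={implied}"
                )
        if self.target_H2m is None:
            raise ValueError("target_H2m (or sigma_G2, sigma_E2, f) required")
        if not 0 <= self.target_H2m < 1:
            raise ValueError("target_H2m must lie in [0, 1) (1 is degenerate)")
        if self.architecture in ("sparse", "go_enriched"):
            if self.n_causal is None:
                self.n_causal = 10
            if self.n_causal > self.n_genes:
                raise ValueError("n_causal > n_genes")


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    phenotype: Phenotype
    genesets: GeneSetCollection | None
    true_effects: np.ndarray  # per gene, trait units per SD of expression
    true_genetic_values: np.ndarray
    realized_H2m: float
    config: SimulationConfig = field(repr=False, default=None)


def simulate_expression(cfg: SimulationConfig) -> ExpressionMatrix:
    """Latent-factor expression: X = L F^T + noise, L and F standard normal.

    With k = 0 the genes are mutually independent Gaussian noise. Determinism:
    the same config (including seed) yields a bit-identical matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_lines, cfg.n_genes, cfg.n_factors
    X = rng.normal(0.0, cfg.noise_sd, size=(n, m))
    if k > 0:
        # normalize the factor component to unit variance per gene so the
        # shared (co-expression) share is ~50% at the default noise_sd=1;
        # unnormalized k-factor loadings would give k/(k+1) shared variance,
        # i.e. near-total co-expression, which no expression panel shows
        L = rng.normal(size=(n, k))
        F = rng.normal(size=(m, k))
        X = L @ F.T / np.sqrt(k) + X
    line_ids = [f"line_{i:04d}" for i in range(n)]
    gene_ids = [f"gene_{j:05d}" for j in range(m)]
    return ExpressionMatrix(X, line_ids, gene_ids)


def _draw_effects(
    cfg: SimulationConfig, gene_ids: list[str], genesets: GeneSetCollection | None, rng
) -> np.ndarray:
    m = len(gene_ids)
    beta = np.zeros(m)
    if cfg.target_H2m == 0:
        return beta
    if cfg.architecture == "dense":
        causal = np.arange(m)
    elif cfg.architecture == "sparse":
        causal = rng.choice(m, size=cfg.n_causal, replace=False)
    else:  # go_enriched: causal genes drawn from the designated term
        if genesets is None or cfg.causal_term not in genesets:
            raise ValueError("go_enriched requires causal_term present in genesets")
        members = genesets[cfg.causal_term]
        idx = [gene_ids.index(g) for g in members]
        if len(idx) < cfg.n_causal:
            raise ValueError("causal_term smaller than n_causal")
        causal = rng.choice(np.array(idx), size=cfg.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, 1.0, size=len(causal))
    return beta


def simulate_trait(
    expr: ExpressionMatrix,
    cfg: SimulationConfig,
    genesets: GeneSetCollection | None = None,
) -> SimulatedDataset:
    """Draw effects, genetic values g = W beta and line-mean noise.

    The residual (line-mean) variance sigma_E^2/f is set so that
    Var(g) / (Var(g) + sigma_E^2/f) equals ``target_H2m``; the realized value
    (from the actually drawn noise) is recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    W = standardize(expr)
    beta = _draw_effects(cfg, W.gene_ids, genesets, rng)
    g = W.values @ beta
    n = expr.n_lines
    h2 = cfg.target_H2m
    if h2 == 0 or np.var(g, ddof=1) == 0:
        sigma_line = cfg.sigma_E2 / cfg.f if cfg.sigma_E2 is not None else 1.0
        g = np.zeros(n)
        beta = np.zeros_like(beta)
    else:
        var_g = np.var(g, ddof=1)
        sigma_line = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma_line), size=n)
    y = g + e
    var_g = np.var(g, ddof=1)
    var_e = np.var(e, ddof=1)
    realized = var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0
    # map effects back to the full gene list (zero for excluded genes)
    full_beta = np.zeros(expr.n_genes)
    kept = {g_id: j for j, g_id in enumerate(W.gene_ids)}
    for j, g_id in enumerate(expr.gene_ids):
        if g_id in kept:
            full_beta[j] = beta[kept[g_id]]
    return SimulatedDataset(
        expression=expr,
        phenotype=Phenotype(y, expr.line_ids),
        genesets=genesets,
        true_effects=full_beta,
        true_genetic_values=g,
        realized_H2m=float(realized),
        config=cfg,
    )


def simulate_genesets(
    gene_ids: list[str],
    n_terms: int = 100,
    size_range: tuple[int, int] = (5, 50),
    causal_genes: list[str] | None = None,
    causal_term: str = "GO:CAUSAL",
    seed: int = 0,
    min_size: int = 5,
) -> GeneSetCollection:
    """Random-membership gene sets, optionally one term holding the causal genes.

    The designated term contains all ``causal_genes`` padded with random
    non-causal genes up to a size drawn from ``size_range``.
    """
    lo, hi = size_range
    if lo < min_size:
        raise ValueError("size_range minimum below min_size")
    if hi > len(gene_ids):
        raise ValueError("size_range maximum exceeds number of genes")
    rng = np.random.default_rng(seed)
    genes = np.array(gene_ids)
    sets: dict[str, list[str]] = {}
    if causal_genes is not None:
        size = max(len(causal_genes), int(rng.integers(lo, hi + 1)))
        pool = np.array([g for g in gene_ids if g not in set(causal_genes)])
        pad = rng.choice(pool, size=size - len(causal_genes), replace=False)
        members = list(causal_genes) + list(pad)
        sets[causal_term] = members
    n_random = n_terms - len(sets)
    for t in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"GO:{t:07d}"] = list(members)
    return GeneSetCollection(sets, min_size=min_size)


def simulate_dataset(cfg: SimulationConfig, n_terms: int = 100,
                     size_range: tuple[int, int] = (5, 50)) -> SimulatedDataset:
    """One-call generator: expression, gene sets and trait under ``cfg``.

    For ``go_enriched`` the causal genes are placed in a designated term
    (named by ``cfg.causal_term``, default ``GO:CAUSAL``).
    """
    expr = simulate_expression(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    genesets = None
    if cfg.architecture == "go_enriched":
        term = cfg.causal_term or "GO:CAUSAL"
        causal = list(rng.choice(expr.gene_ids, size=cfg.n_causal, replace=False))
        genesets = simulate_genesets(
            expr.gene_ids, n_terms=n_terms, size_range=size_range,
            causal_genes=causal, causal_term=term, seed=cfg.seed + 1,
        )
        cfg.causal_term = term
    else:
        genesets = simulate_genesets(
            expr.gene_ids, n_terms=n_terms, size_range=size_range, seed=cfg.seed + 1
        )
    return simulate_trait(expr, cfg, genesets)


def simulate_sex_pair(
    cfg_female: SimulationConfig,
    cfg_male: SimulationConfig,
    rho: float = 1.0,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two sex-specific datasets whose causal effects correlate at ``rho``.

    rho = 1 models a trait with no genetic variation in sexual dimorphism
    (startle-like); rho < 1 lets the sexes have partly distinct architectures
    (starvation-like). Expression matrices are independent draws.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    female = simulate_dataset(cfg_female)
    male_expr = simulate_expression(cfg_male)
    rng = np.random.default_rng(np.random.SeedSequence([cfg_male.seed, 29]))
    Wm = standardize(male_expr)
    # correlate male effects with the female draw on the shared gene index range
    beta_f = female.true_effects
    m = min(len(beta_f), male_expr.n_genes)
    fresh = rng.normal(size=male_expr.n_genes)
    beta_m = np.zeros(male_expr.n_genes)
    scale_f = np.std(beta_f[:m]) or 1.0
    beta_m[:m] = rho * beta_f[:m] / scale_f + np.sqrt(1 - rho**2) * fresh[:m]
    g = Wm.values @ beta_m[[male_expr.gene_ids.index(g) for g in Wm.gene_ids]]
    h2 = cfg_male.target_H2m
    var_g = np.var(g, ddof=1)
    sigma_line = var_g * (1 - h2) / h2 if h2 > 0 and var_g > 0 else 1.0
    e = rng.normal(0, np.sqrt(sigma_line), size=male_expr.n_lines)
    y = g + e
    var_e = np.var(e, ddof=1)
    male = SimulatedDataset(
        expression=male_expr,
        phenotype=Phenotype(y, male_expr.line_ids),
        genesets=female.genesets,
        true_effects=beta_m,
        true_genetic_values=g,
        realized_H2m=float(var_g / (var_g + var_e)),
        config=cfg_male,
    )
    return female, male
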