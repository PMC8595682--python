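"""Overall detection power: expression probability x significance power.

A gene is detected when it is both called expressed in the planned experiment
and statistically significant; the two probabilities are conditionally
independent given the gene's expression mean, so detection power is their
product and the study-level power is the mean over all prior genes.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    CellTypeContext,
    DesignPoint,
    EffectSizePrior,
    EQTLSimConfig,
    ExpressionPrior,
    ExpressionThreshold,
    GenePower,
    PowerResult,
)
from .expression import (
    dispersion_from_mean,
    expected_expressed_genes,
    gene_expression_probability,
    mean_umi_from_reads,
    mixture_at_depth,
    rank_to_mean,
)
from .significance import (
    DispersionLookup,
    bonferroni_alpha,
    eqtl_power,
    fdr_alpha,
    nb_de_power,
)

logger = logging.getLogger(__name__)

__all__ = [
    "overall_detection_power",
    "eqtl_population_threshold",
    "optimize_expression_threshold",
]

#: mean transcript length assumed for non-prior genes in length-normalized mode
DEFAULT_GENE_LENGTH = 5000.0

#: independent SNPs per gene assumed in a genome-wide cis eQTL scan
DEFAULT_INDEP_SNPS = 10


def eqtl_population_threshold(maf: float) -> float:
    """Across-individual fraction 2*maf*(1-maf): expression at least in
    heterozygotes."""
    if not 0 < maf <= 0.5:
        raise ValueError("minor allele frequency must lie in (0, 0.5]")
    return 2.0 * maf * (1.0 - maf)


def _de_significance_power(
    mu_prime: np.ndarray,
    phi_prime: np.ndarray,
    log2fc: np.ndarray,
    n_s: int,
    group_ratio: float,
    alpha: float,
    de_method: int,
) -> np.ndarray:
    n1 = int(np.floor(n_s / (1.0 + group_ratio)))
    if n1 < 1:
        raise ValueError("control group is empty; increase n_s or lower group_ratio")
    theta_eff = (n_s - n1) / n1
    powers = np.zeros(mu_prime.shape)
    pos = mu_prime > 0
    if pos.any():
        powers[pos] = nb_de_power(
            n1, theta_eff, mu_prime[pos], phi_prime[pos], log2fc[pos], alpha, method=de_method
        )
    return powers


def _eqtl_significance_power(
    mu_prime: np.ndarray,
    r2: np.ndarray,
    n_s: int,
    alpha: float,
    sim_config: EQTLSimConfig,
    lookup: Optional[DispersionLookup],
    rng: np.random.Generator,
) -> np.ndarray:
    powers = np.zeros(mu_prime.shape)
    for i, (mu, eff) in enumerate(zip(mu_prime, r2)):
        if mu <= 0:
            continue
        powers[i] = eqtl_power(
            n_s, float(eff), alpha, float(mu), config=sim_config, lookup=lookup, rng=rng
        )
    return powers


def overall_detection_power(
    prior: ExpressionPrior,
    effects: EffectSizePrior,
    ctx: CellTypeContext,
    design: DesignPoint,
    threshold: ExpressionThreshold,
    mt: str = "fdr",
    alpha: float = 0.05,
    n_indep_snps: int = DEFAULT_INDEP_SNPS,
    de_method: int = 3,
    sim_config: Optional[EQTLSimConfig] = None,
    dispersion_lookup: Optional[DispersionLookup] = None,
    default_gene_length: float = DEFAULT_GENE_LENGTH,
) -> PowerResult:
    """Overall power of a design to detect the prior DE/eQTL genes.

    Computes the expected number of expressed genes over ranks 1..G, derives
    the adjusted significance threshold (Bonferroni on E(E) * SNPs for
    'fwer', analytic FDR inversion for 'fdr'), maps each prior gene's rank to
    its per-cell mean and pseudobulk law, and averages expression probability
    times significance power over the prior genes.
    """
    if len(effects) == 0:
        raise ValueError("effect-size prior is empty")
    if mt not in ("fwer", "fdr"):
        raise ValueError("mt must be 'fwer' or 'fdr'")
    if threshold.length_normalized and prior.technology != "read-plate-smartseq2":
        raise ValueError("length-normalized thresholds require a Smart-seq2 prior")
    n_cs = max(float(np.floor(ctx.n_cs)), 1.0)
    if ctx.n_cs < 1:
        raise ValueError("fewer than one expected cell of the target type per sample")
    n_s = design.n_s
    sim_config = sim_config or EQTLSimConfig()
    rng = np.random.default_rng(sim_config.seed)

    mean_len = default_gene_length if threshold.length_normalized else None
    expected_e, _ = expected_expressed_genes(
        prior, n_cs, n_s, ctx.r_m, threshold, gene_length=mean_len
    )

    if prior.technology == "read-plate-smartseq2":
        depth_param = ctx.r_m
    else:
        depth_param = mean_umi_from_reads(prior, ctx.r_m)
    mixture = mixture_at_depth(prior, depth_param)
    ranks = effects.ranks
    if np.any(ranks > prior.n_genes):
        raise ValueError("effect prior contains ranks beyond the prior's gene count")
    mu = np.atleast_1d(rank_to_mean(mixture, ranks, prior.n_genes))
    phi = np.ones_like(mu)
    pos = mu > 0
    if pos.any():
        phi[pos] = dispersion_from_mean(prior, mu[pos], read_depth=ctx.r_m)

    lengths = np.array(
        [rec.gene_length if rec.gene_length is not None else default_gene_length
         for rec in effects.records]
    )
    p_expressed = np.zeros(mu.shape)
    for i in range(mu.size):
        if mu[i] > 0:
            p_expressed[i] = gene_expression_probability(
                mu[i], phi[i], n_cs, n_s, threshold,
                gene_length=lengths[i] if threshold.length_normalized else None,
            )
    expected_e_prior = float(p_expressed.sum())

    mu_prime = n_cs * mu
    phi_prime = phi / n_cs
    effects_arr = effects.effects

    def sig_power(a: float) -> np.ndarray:
        if effects.kind == "de":
            return _de_significance_power(
                mu_prime, phi_prime, effects_arr, n_s, design.group_ratio, a, de_method
            )
        return _eqtl_significance_power(
            mu_prime, effects_arr, n_s, a, sim_config, dispersion_lookup,
            np.random.default_rng(sim_config.seed),
        )

    m0 = None
    r1 = None
    if mt == "fwer":
        snps = n_indep_snps if effects.kind == "eqtl" else 1
        adj_alpha = bonferroni_alpha(expected_e, snps, alpha=alpha)
    else:
        m0 = expected_e - expected_e_prior
        adj_alpha = fdr_alpha(
            lambda a: p_expressed * sig_power(a), expected_e, expected_e_prior, target_fdr=alpha
        )

    powers = sig_power(adj_alpha)
    if mt == "fdr":
        r1 = float(np.sum(p_expressed * powers))
    per_gene = [
        GenePower(
            rank=int(rank),
            expression_probability=float(pe),
            significance_power=float(ps),
        )
        for rank, pe, ps in zip(ranks, p_expressed, powers)
    ]
    return PowerResult(
        per_gene=per_gene,
        expected_expressed=expected_e,
        expected_expressed_prior=expected_e_prior,
        adjusted_alpha=adj_alpha,
        m0=m0,
        expected_significant_prior=r1,
    )


def optimize_expression_threshold(
    candidate_counts: Sequence[int],
    prior: ExpressionPrior,
    effects: EffectSizePrior,
    ctx: CellTypeContext,
    design: DesignPoint,
    base_threshold: ExpressionThreshold,
    mt: str = "fdr",
    alpha: float = 0.05,
    **kwargs,
) -> tuple[int, list[tuple[int, float]]]:
    """Exhaustively evaluate count thresholds; return the argmax and the table.

    Ties are broken toward the larger (more conservative) threshold.
    """
    if not candidate_counts:
        raise ValueError("no candidate thresholds given")
    table: list[tuple[int, float]] = []
    for n in candidate_counts:
        threshold = ExpressionThreshold(
            mode=base_threshold.mode,
            min_count=int(n),
            individual_fraction=base_threshold.individual_fraction,
            min_individuals=base_threshold.min_individuals,
            length_normalized=base_threshold.length_normalized,
        )
        result = overall_detection_power(
            prior, effects, ctx, design, threshold, mt=mt, alpha=alpha, **kwargs
        )
        table.append((int(n), result.overall_power))
    best = max(table, key=lambda item: (item[1], item[0]))
    return best[0], table
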