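"""Expression probabilities for a planned design.

Given a fitted :class:`~scpower.data_model.ExpressionPrior`, instantiate the
gamma mixture at the planned read depth, map expression ranks to per-cell NB
means, and compute per-gene probabilities of passing the expressed-gene
threshold together with the expected number of expressed genes.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import (
    ExpressionPrior,
    ExpressionThreshold,
    GammaMixture,
    P1_FLOOR,
)

__all__ = [
    "mean_umi_from_reads",
    "reads_from_mean_umi",
    "mixture_at_depth",
    "rank_to_mean",
    "dispersion_from_mean",
    "gene_expression_probability",
    "expected_expressed_genes",
    "nb_cdf",
]

MIN_DISPERSION = 1e-8


def nb_cdf(n, mu, phi):
    """Negative binomial CDF at n for mean mu and dispersion phi (= 1/size).

    Evaluated through the regularized incomplete beta function (scipy's
    nbinom), stable for large pseudobulk means; phi below the Poisson clamp
    falls back to the Poisson CDF.
    """
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    poisson_limit = phi < MIN_DISPERSION
    size = 1.0 / np.where(poisson_limit, 1.0, phi)
    p = size / (size + mu)
    out = np.where(
        poisson_limit,
        stats.poisson.cdf(n, mu),
        stats.nbinom.cdf(n, size, p),
    )
    return out


def mean_umi_from_reads(prior: ExpressionPrior, mapped_reads: float) -> float:
    """Invert mapped_reads = b0 + b1 * ln(mean UMI); floors the result at 1."""
    curve = prior.read_umi_curve
    if curve is None:
        raise ValueError("prior has no read->UMI curve")
    if curve.slope <= 0:
        raise ValueError("invalid read->UMI curve: slope must be > 0")
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    umi = float(np.exp((mapped_reads - curve.intercept) / curve.slope))
    if umi < 1.0:
        warnings.warn("read depth implies mean UMI < 1; flooring at 1")
        return 1.0
    return umi


def reads_from_mean_umi(prior: ExpressionPrior, mean_umi: float) -> float:
    curve = prior.read_umi_curve
    if curve is None:
        raise ValueError("prior has no read->UMI curve")
    return float(curve(np.log(mean_umi)))


def mixture_at_depth(prior: ExpressionPrior, mean_umi: float) -> GammaMixture:
    """Evaluate the depth curves at a mean UMI count (read depth for Smart-seq2)."""
    if mean_umi < 1 and prior.technology != "read-plate-smartseq2":
        raise ValueError("mean_umi must be >= 1")
    cc = prior.component_curves
    values = {name: float(cc[name](mean_umi)) for name in ("mean1", "sd1", "mean2", "sd2")}
    for name, val in values.items():
        if val <= 0:
            raise ValueError(
                f"component curve {name!r} evaluates to {val:.4g} at depth {mean_umi:.4g}: "
                "outside the fitted range"
            )
    p1 = max(float(cc["p1"](mean_umi)), P1_FLOOR)
    p3 = prior.p3_const
    p2 = 1.0 - p1 - p3
    if p2 < 0:
        raise ValueError(f"p1 ({p1:.3f}) + p3 ({p3:.3f}) exceed 1 at depth {mean_umi:.4g}")
    shape1 = values["mean1"] ** 2 / values["sd1"] ** 2
    rate1 = values["mean1"] / values["sd1"] ** 2
    shape2 = values["mean2"] ** 2 / values["sd2"] ** 2
    rate2 = values["mean2"] / values["sd2"] ** 2
    return GammaMixture(
        p1=p1, p2=p2, p3=p3,
        shape1=shape1, rate1=rate1, shape2=shape2, rate2=rate2,
    )


def rank_to_mean(mixture: GammaMixture, rank, n_genes: int):
    """Per-cell NB mean of the gene at an expression rank (1 = most expressed).

    Ranks map to the quantile 1 - (rank - 0.5)/G of the uncensored mixture;
    quantiles falling into the zero mass yield mu = 0.
    """
    rank_arr = np.atleast_1d(np.asarray(rank))
    if np.any(rank_arr < 1) or np.any(rank_arr > n_genes):
        raise ValueError(f"ranks must lie in [1, {n_genes}]")
    q = 1.0 - (rank_arr - 0.5) / n_genes
    mu = mixture.quantile(q)
    mu = np.atleast_1d(np.asarray(mu))
    return mu if np.ndim(rank) else float(mu[0])


def dispersion_from_mean(prior: ExpressionPrior, mu, read_depth: Optional[float] = None):
    """Dispersion trend phi = a0 + a1/mu, clamped below at 1e-8."""
    a0, a1 = prior.dispersion_trend.coefficients(read_depth)
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu_arr <= 0):
        raise ValueError("dispersion trend undefined at mu <= 0")
    phi = np.maximum(a0 + a1 / mu_arr, MIN_DISPERSION)
    return phi if np.ndim(mu) else float(phi[0])


def _required_individuals(threshold: ExpressionThreshold, n_s: int) -> int:
    """Smallest number of passing individuals that counts as 'expressed'."""
    if threshold.min_individuals is not None:
        return int(threshold.min_individuals)
    # strictly more than k percent of the individuals
    return int(np.floor(threshold.individual_fraction * n_s)) + 1


def _count_threshold(threshold: ExpressionThreshold, gene_length: Optional[float]) -> int:
    if not threshold.length_normalized:
        return threshold.min_count
    if gene_length is None:
        raise ValueError("length-normalized threshold requires gene_length")
    return int(np.ceil(threshold.min_count * gene_length / 1000.0))


def gene_expression_probability(
    mu,
    phi,
    n_cs: float,
    n_s: int,
    threshold: ExpressionThreshold,
    gene_length: Optional[float] = None,
):
    """P(gene is called expressed) for per-cell NB law (mu, phi).

    Pseudobulk-count mode: the per-individual sum over n_cs cells follows
    NB(n_cs*mu, phi/n_cs); one individual passes when the sum exceeds the
    count threshold, and the gene is expressed when enough individuals pass
    (binomial across individuals). Nonzero-cells mode replaces the
    per-individual criterion by >= min_count cells with a nonzero count.
    """
    if n_cs < 1:
        raise ValueError("n_cs must be >= 1")
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    phi_arr = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), mu_arr.shape)
    n = _count_threshold(threshold, gene_length)

    p_is = np.zeros(mu_arr.shape)
    pos = mu_arr > 0
    if pos.any():
        if threshold.mode == "pseudobulk-count":
            mu_prime = n_cs * mu_arr[pos]
            phi_prime = phi_arr[pos] / n_cs
            p_is[pos] = 1.0 - nb_cdf(n, mu_prime, phi_prime)
        else:
            p_cell = 1.0 - nb_cdf(0, mu_arr[pos], phi_arr[pos])
            m = max(n, 1)
            p_is[pos] = stats.binom.sf(m - 1, int(np.floor(n_cs)), p_cell)

    min_ind = _required_individuals(threshold, n_s)
    prob = stats.binom.sf(min_ind - 1, n_s, p_is)
    prob = np.where(pos, prob, 0.0)
    return prob if np.ndim(mu) else float(prob[0])


def expected_expressed_genes(
    prior: ExpressionPrior,
    n_cs: float,
    n_s: int,
    mapped_read_depth: float,
    threshold: ExpressionThreshold,
    gene_length: Optional[float] = None,
) -> tuple[float, np.ndarray]:
    """Expected number of expressed genes E(E) and per-rank probabilities.

    Evaluates ranks 1..G of the prior's mixture at the given mapped read
    depth; returns (sum, per-rank probability vector).
    """
    if prior.technology == "read-plate-smartseq2":
        depth_param = mapped_read_depth
    else:
        depth_param = mean_umi_from_reads(prior, mapped_read_depth)
    mixture = mixture_at_depth(prior, depth_param)
    ranks = np.arange(1, prior.n_genes + 1)
    mu = rank_to_mean(mixture, ranks, prior.n_genes)
    probs = np.zeros(prior.n_genes)
    pos = mu > 0
    if pos.any():
        phi = dispersion_from_mean(prior, mu[pos], read_depth=mapped_read_depth)
        probs[pos] = gene_expression_probability(
            mu[pos], phi, n_cs, n_s, threshold, gene_length=gene_length
        )
    return float(probs.sum()), probs
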