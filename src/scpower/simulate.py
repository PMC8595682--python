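"""Synthetic fixtures: effect-size priors, pilot counts and Monte-Carlo oracles.

Everything here is a pure function of its parameters and a seed, so test
fixtures and acceptance checks are fully reproducible without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import (
    EffectRecord,
    EffectSizePrior,
    ExpressionThreshold,
    GammaMixture,
    PilotCounts,
)

__all__ = [
    "simulate_de_priors",
    "simulate_eqtl_priors",
    "simulate_pilot_counts",
    "simulate_nb_counts",
    "mc_power_oracle",
    "OracleEstimate",
]


def simulate_de_priors(
    n_genes: int = 250,
    lfc_mean: float = 2.0,
    lfc_sd: float = 1.0,
    rank_max: int = 10_000,
    seed: Optional[int] = None,
) -> EffectSizePrior:
    """Simulated DE prior: normal log fold changes with random sign, ranks
    uniform without replacement over 1..rank_max."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > rank_max:
        raise ValueError("cannot draw more unique ranks than rank_max")
    rng = np.random.default_rng(seed)
    magnitudes = rng.normal(lfc_mean, lfc_sd, size=n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    ranks = rng.choice(rank_max, size=n_genes, replace=False) + 1
    records = [
        EffectRecord(rank=int(r), effect=float(s * m))
        for r, s, m in zip(ranks, signs, magnitudes)
    ]
    return EffectSizePrior(kind="de", records=records)


def simulate_eqtl_priors(
    n_genes: int = 2000,
    z_mean: float = 0.5,
    z_sd: float = 0.2,
    rank_max: int = 10_000,
    seed: Optional[int] = None,
) -> EffectSizePrior:
    """Simulated eQTL prior: R = tanh(Z) with Z normal truncated below at its
    mean (inverse Fisher transform), recorded as R^2."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > rank_max:
        raise ValueError("cannot draw more unique ranks than rank_max")
    rng = np.random.default_rng(seed)
    z = np.empty(n_genes)
    filled = 0
    while filled < n_genes:  # rejection sampling, acceptance 0.5
        draw = rng.normal(z_mean, z_sd, size=2 * (n_genes - filled))
        draw = draw[draw >= z_mean]
        take = min(draw.size, n_genes - filled)
        z[filled : filled + take] = draw[:take]
        filled += take
    r2 = np.tanh(z) ** 2
    ranks = rng.choice(rank_max, size=n_genes, replace=False) + 1
    records = [EffectRecord(rank=int(r), effect=float(e)) for r, e in zip(ranks, r2)]
    return EffectSizePrior(kind="eqtl", records=records)


def simulate_nb_counts(
    mu: np.ndarray, phi: np.ndarray, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """(genes x n_cells) i.i.d. NB draws; phi below 1e-8 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.zeros((mu.size, n_cells), dtype=np.int64)
    pos = mu > 0
    if not pos.any():
        return out
    mu_p = mu[pos][:, None]
    phi_p = phi[pos][:, None]
    poisson_like = phi_p < 1e-8
    size = 1.0 / np.where(poisson_like, 1.0, phi_p)
    p = size / (size + mu_p)
    draws = np.where(
        poisson_like,
        rng.poisson(np.broadcast_to(mu_p, (mu_p.size, n_cells))),
        rng.negative_binomial(
            np.broadcast_to(size, (mu_p.size, n_cells)),
            np.broadcast_to(p, (mu_p.size, n_cells)),
        ),
    )
    out[pos] = draws
    return out


def simulate_pilot_counts(
    mixture: GammaMixture,
    dispersion_trend: tuple[float, float],
    n_genes: int,
    n_cells: int,
    n_samples: int = 1,
    seed: Optional[int] = None,
    cell_type: str = "simulated",
) -> tuple[PilotCounts, np.ndarray]:
    """Pilot counts drawn from the generative model, with ground-truth means.

    Per-gene means come from the mixture (zeros for the zero component and
    censored mass), dispersions from phi(mu) = a0 + a1/mu, counts are i.i.d.
    NB per cell and cells are assigned round-robin to samples.
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        counts = PilotCounts(
            matrix=np.zeros((0, n_cells), dtype=np.int64),
            gene_ids=[],
            cell_ids=[f"cell_{j}" for j in range(n_cells)],
            sample_ids=[f"sample_{j % n_samples}" for j in range(n_cells)],
            cell_types=[cell_type] * n_cells,
        )
        return counts, np.zeros(0)
    means = mixture.sample_means(n_genes, rng)
    a0, a1 = dispersion_trend
    phi = np.ones(n_genes)
    pos = means > 0
    phi[pos] = np.maximum(a0 + a1 / means[pos], 1e-8)
    matrix = simulate_nb_counts(means, phi, n_cells, rng)
    counts = PilotCounts(
        matrix=matrix,
        gene_ids=[f"gene_{i}" for i in range(n_genes)],
        cell_ids=[f"cell_{j}" for j in range(n_cells)],
        sample_ids=[f"sample_{j % n_samples}" for j in range(n_cells)],
        cell_types=[cell_type] * n_cells,
    )
    return counts, means


@dataclass(frozen=True)
class OracleEstimate:
    """Monte-Carlo estimate with its binomial / empirical standard error."""

    estimate: float
    se: float
    reps: int


def _de_oracle(scenario: dict, reps: int, rng: np.random.Generator) -> OracleEstimate:
    """Rejection rate of the NB two-rate Wald test on two simulated groups.

    The test statistic is ln(m2/m1) over its standard error estimated under
    the constrained null (both groups at the pooled mean, known dispersion) -
    the test whose power the analytic variant-3 formula approximates.
    Repetitions with an all-zero group never reject.
    """
    n1 = int(scenario["n1"])
    theta = float(scenario.get("group_ratio", 1.0))
    n2 = int(scenario.get("n2", round(theta * n1)))
    mu0 = float(scenario["mu0"])
    phi = float(scenario["phi"])
    rho = 2.0 ** float(scenario["log2fc"])
    alpha = float(scenario.get("alpha", 0.05))

    size = 1.0 / phi
    x1 = rng.negative_binomial(size, size / (size + mu0), size=(reps, n1))
    x2 = rng.negative_binomial(size, size / (size + rho * mu0), size=(reps, n2))
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ok = (m1 > 0) & (m2 > 0)
    m_bar = (n1 * m1 + n2 * m2) / (n1 + n2)
    b1 = np.zeros(reps)
    var = np.full(reps, np.inf)
    b1[ok] = np.log(m2[ok] / m1[ok])
    var[ok] = (1.0 / m_bar[ok] + phi) * (1.0 / n1 + 1.0 / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    reject = np.abs(b1) / np.sqrt(var) > z
    p_hat = reject.mean()
    return OracleEstimate(float(p_hat), math.sqrt(p_hat * (1 - p_hat) / reps), reps)


def _eqtl_oracle(scenario: dict, reps: int, rng: np.random.Generator) -> OracleEstimate:
    """Rejection rate of the slope t-test in a Gaussian regression with a
    normal covariate, effect fixed by R^2."""
    n_s = int(scenario["n_s"])
    r2 = float(scenario["r2"])
    alpha = float(scenario.get("alpha", 0.05))
    beta = math.sqrt(r2)
    sigma = math.sqrt(1.0 - r2)
    x = rng.normal(size=(reps, n_s))
    y = beta * x + sigma * rng.normal(size=(reps, n_s))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    ss_x = np.sum(xc**2, axis=1)
    slope = np.sum(xc * yc, axis=1) / ss_x
    resid = yc - slope[:, None] * xc
    df = n_s - 2
    se = np.sqrt(np.sum(resid**2, axis=1) / df / ss_x)
    pvals = 2 * stats.t.sf(np.abs(slope) / se, df)
    p_hat = float(np.mean(pvals < alpha))
    return OracleEstimate(p_hat, math.sqrt(p_hat * (1 - p_hat) / reps), reps)


def _expression_oracle(scenario: dict, reps: int, rng: np.random.Generator) -> OracleEstimate:
    """Empirical number of genes passing the expression threshold.

    Each repetition draws fresh gene means from the mixture, simulates cell
    counts for every individual, forms pseudobulks and counts passing genes.
    Returns the mean count over repetitions and its empirical standard error.
    """
    mixture: GammaMixture = scenario["mixture"]
    a0, a1 = scenario["dispersion_trend"]
    n_genes = int(scenario["n_genes"])
    n_cs = int(scenario["n_cs"])
    n_s = int(scenario["n_s"])
    threshold: ExpressionThreshold = scenario["threshold"]
    if threshold.min_individuals is not None:
        min_ind = threshold.min_individuals
    else:
        min_ind = int(np.floor(threshold.individual_fraction * n_s)) + 1

    counts_passing = np.empty(reps)
    for rep in range(reps):
        means = mixture.sample_means(n_genes, rng)
        phi = np.ones(n_genes)
        pos = means > 0
        phi[pos] = np.maximum(a0 + a1 / means[pos], 1e-8)
        passing_per_gene = np.zeros(n_genes, dtype=int)
        for _s in range(n_s):
            cells = simulate_nb_counts(means, phi, n_cs, rng)
            if threshold.mode == "pseudobulk-count":
                ok = cells.sum(axis=1) > threshold.min_count
            else:
                ok = (cells > 0).sum(axis=1) >= max(threshold.min_count, 1)
            passing_per_gene += ok
        counts_passing[rep] = int(np.sum(passing_per_gene >= min_ind))
    est = float(counts_passing.mean())
    se = float(counts_passing.std(ddof=1) / math.sqrt(reps)) if reps > 1 else float("inf")
    return OracleEstimate(est, se, reps)


def mc_power_oracle(
    mode: str, scenario: dict, reps: int, seed: Optional[int] = None
) -> OracleEstimate:
    """Monte-Carlo oracle for DE power, eQTL power or expressed-gene counts."""
    if mode in ("de", "eqtl") and reps < 100:
        raise ValueError("power oracles need at least 100 repetitions")
    rng = np.random.default_rng(seed)
    if mode == "de":
        return _de_oracle(scenario, reps, rng)
    if mode == "eqtl":
        return _eqtl_oracle(scenario, reps, rng)
    if mode == "expression":
        return _expression_oracle(scenario, reps, rng)
    raise ValueError("mode must be 'de', 'eqtl' or 'expression'")
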