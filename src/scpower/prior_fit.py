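"""Fitting the expression prior from pilot count data.

Pipeline: per-cell size factors -> per-gene NB mean/dispersion for one cell
type -> mean-dispersion trend phi(mu) = a0 + a1/mu -> censored gamma mixture
over gene means -> linear depth curves tying mixture parameters, UMI counts
and read depth together into an :class:`~scpower.data_model.ExpressionPrior`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .data_model import (
    DispersionTrend,
    ExpressionPrior,
    GammaMixture,
    GeneNBFit,
    LinearCurve,
    PilotCounts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_size_factors",
    "fit_gene_nb",
    "fit_dispersion_trend",
    "fit_gamma_mixture",
    "DepthObservation",
    "fit_depth_curves",
]

MIN_DISPERSION = 1e-8
MIN_CELLS_PER_TYPE = 50


def estimate_size_factors(counts, method: str = "median-ratio") -> np.ndarray:
    """Per-cell size factors with geometric mean 1.

    'median-ratio' is the classic median-of-ratios estimator against the
    per-gene geometric mean over all cells and requires at least one gene
    with positive counts in every cell. 'poscounts' builds the reference
    from the geometric mean over positive entries only, suitable for sparse
    data.
    """
    matrix = counts.matrix if isinstance(counts, PilotCounts) else np.asarray(counts)
    matrix = matrix.astype(float)
    n_genes, n_cells = matrix.shape
    if n_cells < 2:
        raise ValueError("size factor estimation needs at least 2 cells")

    if method == "median-ratio":
        all_positive = np.all(matrix > 0, axis=1)
        if not all_positive.any():
            raise ValueError(
                "median-ratio requires a gene with positive counts in every cell; "
                "use method='poscounts'"
            )
        sub = matrix[all_positive]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    elif method == "poscounts":
        with np.errstate(divide="ignore"):
            log_mat = np.where(matrix > 0, np.log(matrix), 0.0)
        n_pos = (matrix > 0).sum(axis=1)
        usable = n_pos > 0
        log_ref = np.full(n_genes, -np.inf)
        log_ref[usable] = log_mat[usable].sum(axis=1) / n_pos[usable]
        factors = np.empty(n_cells)
        for j in range(n_cells):
            sel = usable & (matrix[:, j] > 0)
            if not sel.any():
                raise ValueError(f"cell {j} has no positive counts; cannot normalize")
            factors[j] = np.exp(np.median(np.log(matrix[sel, j]) - log_ref[sel]))
    else:
        raise ValueError("method must be 'median-ratio' or 'poscounts'")

    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def fit_gene_nb(
    counts: PilotCounts,
    cell_type: str,
    size_factors: Optional[np.ndarray] = None,
    min_cells: int = MIN_CELLS_PER_TYPE,
    normalization: str = "median-ratio",
) -> tuple[list[GeneNBFit], tuple[float, float]]:
    """Per-gene NB fits for one cell type plus the dispersion trend (a0, a1).

    Means and dispersions are method-of-moments estimates on size-factor
    normalized counts; genes with nonpositive dispersion estimates are
    clamped to ``MIN_DISPERSION`` and excluded from the trend fit.
    """
    sub = counts.subset_cell_type(cell_type)
    if sub.n_cells < min_cells:
        raise ValueError(
            f"cell type {cell_type!r} has {sub.n_cells} cells, fewer than the "
            f"floor of {min_cells}; skipping"
        )
    if size_factors is None:
        size_factors = estimate_size_factors(sub, method=normalization)
    norm = sub.matrix / size_factors[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (var - mu) / mu**2
    trend_ok = np.isfinite(phi_raw) & (phi_raw > 0) & (mu > 0)
    phi = np.where(trend_ok, phi_raw, MIN_DISPERSION)
    fits = [
        GeneNBFit(gene_id=g, mu=float(m), phi=float(p))
        for g, m, p in zip(sub.gene_ids, mu, phi)
    ]
    if trend_ok.sum() >= 2:
        trend = fit_dispersion_trend(mu[trend_ok], phi_raw[trend_ok])
    else:
        warnings.warn("too few overdispersed genes for a trend fit; constant fallback")
        fallback = float(phi_raw[trend_ok][0]) if trend_ok.any() else MIN_DISPERSION
        trend = (fallback, 0.0)
    return fits, trend


def fit_dispersion_trend(mu: np.ndarray, phi: np.ndarray, n_iter: int = 4) -> tuple[float, float]:
    """Fit phi = a0 + a1/mu with residual trimming (top/bottom 5%)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    keep = (mu > 0) & np.isfinite(phi) & (phi > 0)
    mu, phi = mu[keep], phi[keep]
    if mu.size < 2:
        raise ValueError("need at least 2 genes with positive mean and dispersion")
    x = 1.0 / mu
    sel = np.ones(mu.size, dtype=bool)
    a0 = a1 = 0.0
    for _ in range(n_iter):
        design = np.column_stack([np.ones(sel.sum()), x[sel]])
        coef, *_ = np.linalg.lstsq(design, phi[sel], rcond=None)
        a0, a1 = coef
        resid = phi - (a0 + a1 * x)
        lo, hi = np.quantile(resid[sel], [0.05, 0.95])
        new_sel = (resid >= lo) & (resid <= hi)
        if new_sel.sum() < 2 or np.array_equal(new_sel, sel):
            break
        sel = new_sel
    return float(a0), float(a1)


# --- censored gamma mixture ---------------------------------------------------


def _censored_gamma_negloglik(params, stats_pos, w0, censor):
    """Negative expected log-likelihood of one censored gamma component.

    ``stats_pos`` = (sum of weights, weighted sum of ln x, weighted sum of x)
    over uncensored observations, ``w0`` the weight attributed to censored
    mass below ``censor``.
    """
    log_shape, log_rate = params
    shape, rate = math.exp(log_shape), math.exp(log_rate)
    w_sum, s_logx, s_x = stats_pos
    ll = w_sum * (shape * math.log(rate) - math.lgamma(shape)) + (shape - 1) * s_logx - rate * s_x
    if w0 > 0:
        cdf_c = stats.gamma.cdf(censor, a=shape, scale=1.0 / rate)
        ll += w0 * math.log(max(cdf_c, 1e-300))
    return -ll


def _component_loglik(x, shape, rate):
    return stats.gamma.logpdf(x, a=shape, scale=1.0 / rate)


def _mixture_observed_loglik(x_pos, n_zero, p1, p2, p3, sh1, ra1, sh2, ra2, censor):
    """Observed-data log-likelihood: zeros are structural or censored gamma mass."""
    zero_mass = (
        p1
        + p2 * stats.gamma.cdf(censor, a=sh1, scale=1.0 / ra1)
        + p3 * stats.gamma.cdf(censor, a=sh2, scale=1.0 / ra2)
    )
    ll = n_zero * math.log(max(zero_mass, 1e-300)) if n_zero else 0.0
    if x_pos.size:
        dens = p2 * np.exp(_component_loglik(x_pos, sh1, ra1)) + p3 * np.exp(
            _component_loglik(x_pos, sh2, ra2)
        )
        ll += float(np.sum(np.log(np.maximum(dens, 1e-300))))
    return ll


def _moment_gamma(x, w=None):
    if w is None:
        m = float(np.mean(x))
        v = float(np.var(x))
    else:
        w = w / w.sum()
        m = float(np.sum(w * x))
        v = float(np.sum(w * (x - m) ** 2))
    v = max(v, 1e-12)
    m = max(m, 1e-12)
    return max(m * m / v, 1e-3), max(m / v, 1e-6)


def fit_gamma_mixture(
    gene_means: np.ndarray,
    n_cells: int,
    max_iter: int = 300,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
) -> GammaMixture:
    """ML fit of {structural zero, censored gamma 1, censored gamma 2}.

    Zeros in ``gene_means`` are attributed between the structural-zero
    component and gamma mass censored below 1/n_cells. EM runs over the
    component labels; each M-step solves a small weighted censored-gamma ML
    problem, so the observed log-likelihood is non-decreasing (guarded:
    a failed component update keeps the previous parameters). The fit with
    the best BIC over moment-based initialization plus random restarts wins.
    """
    x = np.asarray(gene_means, dtype=float)
    if np.any(x < 0):
        raise ValueError("gene means must be non-negative")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    censor = 1.0 / n_cells
    x_pos = x[x >= censor]
    # positive-but-below-censor values cannot arise from counts; treat as censored
    n_zero = int(x.size - x_pos.size)

    if x_pos.size == 0:
        mix = GammaMixture(1.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, censor_point=censor, converged=False)
        warnings.warn("all gene means are zero/censored; degenerate mixture (p1=1)")
        return mix

    rng = np.random.default_rng(seed)
    inits = [
        _initial_params(x_pos, n_zero, x.size, split_quantile=0.9),
        _single_component_params(x_pos, n_zero, x.size),
    ]
    for _ in range(n_restarts - 1):
        q = rng.uniform(0.7, 0.97)
        init = _initial_params(x_pos, n_zero, x.size, split_quantile=q)
        inits.append(_perturb(init, rng))

    best = None
    best_ll = -np.inf
    for init in inits:
        fit, ll = _run_em(x_pos, n_zero, x.size, censor, init, max_iter, tol)
        if ll > best_ll:
            best, best_ll = fit, ll
    return best


def _initial_params(x_pos, n_zero, n_total, split_quantile):
    split = np.quantile(x_pos, split_quantile)
    low = x_pos[x_pos <= split]
    high = x_pos[x_pos > split]
    if high.size < 2:
        high = x_pos[x_pos >= np.max(x_pos)] * np.array([0.9, 1.1])
    sh1, ra1 = _moment_gamma(low)
    sh2, ra2 = _moment_gamma(high)
    p1 = max(n_zero / n_total, 1e-3)
    rest = 1.0 - p1
    p3 = rest * high.size / max(x_pos.size, 1)
    p2 = rest - p3
    return [p1, p2, p3, sh1, ra1, sh2, ra2]


def _single_component_params(x_pos, n_zero, n_total):
    """Near-degenerate start: one gamma carries the mass, a faint wide second.

    Wins the restart competition when the data holds no high-expression
    outlier component."""
    sh, ra = _moment_gamma(x_pos)
    p1 = max(n_zero / n_total, 1e-3)
    p3 = 0.005
    return [p1, 1.0 - p1 - p3, p3, sh, ra, sh, ra / 20.0]


def _perturb(init, rng):
    p1, p2, p3, sh1, ra1, sh2, ra2 = init
    jitter = lambda v: v * rng.uniform(0.7, 1.3)
    p = np.abs([p1, p2, p3] * rng.uniform(0.8, 1.2, size=3))
    p = p / p.sum()
    return [p[0], p[1], p[2], jitter(sh1), jitter(ra1), jitter(sh2), jitter(ra2)]


def _run_em(x_pos, n_zero, n_total, censor, init, max_iter, tol):
    p1, p2, p3, sh1, ra1, sh2, ra2 = init
    log_x = np.log(np.maximum(x_pos, 1e-300))
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step: responsibilities for positive observations ...
        d1 = p2 * np.exp(_component_loglik(x_pos, sh1, ra1))
        d2 = p3 * np.exp(_component_loglik(x_pos, sh2, ra2))
        denom = np.maximum(d1 + d2, 1e-300)
        r1 = d1 / denom
        r2 = d2 / denom
        # ... and for zeros (structural vs censored gamma mass)
        c1 = stats.gamma.cdf(censor, a=sh1, scale=1.0 / ra1)
        c2 = stats.gamma.cdf(censor, a=sh2, scale=1.0 / ra2)
        z_denom = max(p1 + p2 * c1 + p3 * c2, 1e-300)
        z_struct = n_zero * p1 / z_denom
        z_g1 = n_zero * p2 * c1 / z_denom
        z_g2 = n_zero * p3 * c2 / z_denom

        # M-step: weights
        w1_tot = float(r1.sum()) + z_g1
        w2_tot = float(r2.sum()) + z_g2
        p1 = z_struct / n_total
        p2 = w1_tot / n_total
        p3 = w2_tot / n_total

        # M-step: component parameters (guarded numerical ML)
        sh1, ra1 = _update_component(x_pos, r1, log_x, z_g1, censor, sh1, ra1)
        sh2, ra2 = _update_component(x_pos, r2, log_x, z_g2, censor, sh2, ra2)
        if (sh1 / ra1) > (sh2 / ra2):  # keep component 2 the high-mean one
            sh1, ra1, sh2, ra2 = sh2, ra2, sh1, ra1
            p2, p3 = p3, p2

        ll = _mixture_observed_loglik(x_pos, n_zero, p1, p2, p3, sh1, ra1, sh2, ra2, censor)
        if ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = ll >= ll_prev - 1e-9
            ll_prev = max(ll, ll_prev)
            break
        ll_prev = ll
    mix = GammaMixture(
        p1=p1,
        p2=p2,
        p3=p3,
        shape1=sh1,
        rate1=ra1,
        shape2=sh2,
        rate2=ra2,
        censor_point=censor,
        converged=converged,
    )
    return mix, ll_prev


def _update_component(x_pos, resp, log_x, w0, censor, shape, rate):
    w_sum = float(resp.sum())
    if w_sum + w0 < 1e-10:
        return shape, rate
    stats_pos = (w_sum, float(np.sum(resp * log_x)), float(np.sum(resp * x_pos)))
    x0 = np.log([shape, rate])
    current = _censored_gamma_negloglik(x0, stats_pos, w0, censor)
    res = optimize.minimize(
        _censored_gamma_negloglik,
        x0,
        args=(stats_pos, w0, censor),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
    )
    if res.fun < current:  # only accept improvements (keeps EM monotone)
        shape, rate = np.exp(res.x)
    return float(shape), float(rate)


# --- depth curves -------------------------------------------------------------


@dataclass
class DepthObservation:
    """One (sub)sampled sequencing run summarized for the depth curves."""

    label: str
    mean_mapped_reads: float
    mean_umi: float
    mixture: GammaMixture
    dispersion_fit: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mean_umi > self.mean_mapped_reads + 1e-9:
            raise ValueError("mean UMI count cannot exceed mean mapped reads")


def _ols_line(x: np.ndarray, y: np.ndarray) -> LinearCurve:
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearCurve(intercept=float(coef[0]), slope=float(coef[1]))


def fit_depth_curves(
    observations: Sequence[DepthObservation],
    cell_type: str = "",
    technology: str = "umi-droplet-10x",
    n_genes: int = 21_000,
) -> ExpressionPrior:
    """Combine per-depth mixture fits into a depth-parameterized prior.

    Gamma component means/sds and the raw p1 weight are regressed linearly on
    the mean UMI count (on the read depth for Smart-seq2); p3 becomes the
    median over observations; mapped reads are regressed on ln(mean UMI);
    dispersion-trend coefficients are averaged (Smart-seq2: fitted linearly
    against the read depth). A single observation degenerates to constant
    curves with a warning.
    """
    if not observations:
        raise ValueError("need at least one depth observation")
    obs = sorted(observations, key=lambda o: o.mean_umi)
    umi = np.array([o.mean_umi for o in obs])
    reads = np.array([o.mean_mapped_reads for o in obs])
    predictor = reads if technology == "read-plate-smartseq2" else umi

    def line(values) -> LinearCurve:
        values = np.asarray(values, dtype=float)
        if len(obs) == 1:
            warnings.warn("single depth observation: curves degenerate to constants")
            return LinearCurve(intercept=float(values[0]), slope=0.0)
        return _ols_line(predictor, values)

    curves = {
        "mean1": line([o.mixture.mean1 for o in obs]),
        "sd1": line([o.mixture.sd1 for o in obs]),
        "mean2": line([o.mixture.mean2 for o in obs]),
        "sd2": line([o.mixture.sd2 for o in obs]),
        "p1": line([o.mixture.p1 for o in obs]),
    }
    p3_const = float(np.median([o.mixture.p3 for o in obs]))

    if len(obs) == 1:
        read_umi = LinearCurve(intercept=float(reads[0]), slope=0.0)
    else:
        read_umi = _ols_line(np.log(umi), reads)

    a0s = np.array([o.dispersion_fit[0] for o in obs])
    a1s = np.array([o.dispersion_fit[1] for o in obs])
    if technology == "read-plate-smartseq2" and len(obs) > 1:
        trend = DispersionTrend(a0_curve=_ols_line(reads, a0s), a1_curve=_ols_line(reads, a1s))
    else:
        trend = DispersionTrend(a0=float(np.mean(a0s)), a1=float(np.mean(a1s)))

    return ExpressionPrior(
        cell_type=cell_type,
        technology=technology,  # type: ignore[arg-type]
        component_curves=curves,
        p3_const=min(max(p3_const, 0.0), 1.0 - 1e-9),
        dispersion_trend=trend,
        read_umi_curve=read_umi,
        n_genes=n_genes,
        depth_range=(float(reads.min()), float(reads.max())),
    )
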