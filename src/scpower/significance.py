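"""Per-gene significance power and multiple-testing adjustment.

DE power uses the analytic two-rate negative binomial framework (Wald test of
the log rate ratio, three null-variance variants, variant 3 the default).
eQTL power uses the noncentral F distribution for well-expressed genes and a
discrete count simulation for low pseudobulk means. Adjusted thresholds come
from Bonferroni (FWER) or an analytic FDR inversion.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Optional

import numpy as np
from scipy import optimize, special, stats

from .data_model import EQTLSimConfig, beta_to_r2  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "nb_de_power",
    "beta_to_r2",
    "eqtl_power_analytic",
    "eqtl_power_simulated",
    "eqtl_power",
    "bonferroni_alpha",
    "fdr_alpha",
    "FDRNoSolutionError",
    "DispersionLookup",
    "log1p_sd",
    "dispersion_for_log_sd",
]


def nb_de_power(n1, group_ratio, mu0, phi, log2fc, alpha, method: int = 3):
    """Analytic power of the two-sided NB test of the rate ratio.

    ``n1`` is the control-group size, ``group_ratio`` the ratio n2/n1, ``mu0``
    the control pseudobulk mean, ``phi`` the shared pseudobulk dispersion and
    ``log2fc`` the log2 fold change (ratio rho = 2**log2fc). The null
    variance follows the selected variant: 1 evaluates both groups at mu0,
    2 and 3 at the weighted average / constrained-null mean (identical for a
    unity null ratio). Vectorized over mu0 and log2fc.
    """
    if np.any(np.asarray(group_ratio) <= 0):
        raise ValueError("group_ratio must be > 0")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    n1 = np.asarray(n1, dtype=float)
    theta = np.asarray(group_ratio, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu0 <= 0):
        raise ValueError("mu0 must be > 0")
    rho = np.power(2.0, np.asarray(log2fc, dtype=float))

    v1 = (1.0 / mu0 + phi) + (1.0 / (rho * mu0) + phi) / theta
    if method == 1:
        v0 = (1.0 / mu0 + phi) * (1.0 + 1.0 / theta)
    else:
        mu_bar = mu0 * (1.0 + theta * rho) / (1.0 + theta)
        v0 = (1.0 / mu_bar + phi) * (1.0 + 1.0 / theta)

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = np.abs(np.log(rho)) * np.sqrt(n1 / v1)
    shift = z * np.sqrt(v0 / v1)
    power = stats.norm.cdf(delta - shift) + stats.norm.cdf(-delta - shift)
    power = np.clip(power, alpha * 1e-3, 1.0)
    return power if power.ndim else float(power)


def eqtl_power_analytic(n_s, r2, alpha):
    """Noncentral-F power of a single-SNP association test.

    Numerator df 1, denominator df n_s - 2, effect size f2 = R^2/(1-R^2),
    noncentrality f2 * n_s. Vectorized over r2.
    """
    n_s = int(n_s)
    if n_s < 4:
        raise ValueError("n_s must be >= 4 for the F-test")
    r2_arr = np.asarray(r2, dtype=float)
    if np.any((r2_arr < 0) | (r2_arr >= 1)):
        raise ValueError("R^2 must lie in [0, 1)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    u, v = 1, n_s - 2
    f2 = r2_arr / (1.0 - r2_arr)
    lam = f2 * (u + v + 1)
    crit = stats.f.isf(alpha, u, v)
    power = np.where(lam > 0, stats.ncf.sf(crit, u, v, lam), alpha)
    return power if power.ndim else float(power)


# --- dispersion matching for the count simulation -----------------------------

_MAX_PMF_TERMS = 150_000


def log1p_sd(mu: float, phi: float) -> float:
    """Standard deviation of ln(X+1) for X ~ NB(mu, phi), by pmf summation.

    The sum is truncated at the 1 - 1e-9 quantile; when that would exceed the
    term cap, the gamma-limit closed form sqrt(psi'(1/phi)) is used instead.
    """
    if mu <= 0:
        return 0.0
    if phi < 1e-8:
        kmax = int(stats.poisson.ppf(1 - 1e-9, mu)) + 1
        k = np.arange(kmax + 1)
        pmf = stats.poisson.pmf(k, mu)
    else:
        size = 1.0 / phi
        p = size / (size + mu)
        kmax = int(stats.nbinom.ppf(1 - 1e-9, size, p)) + 1
        if kmax > _MAX_PMF_TERMS:
            return float(np.sqrt(special.polygamma(1, 1.0 / phi)))
        k = np.arange(kmax + 1)
        pmf = stats.nbinom.pmf(k, size, p)
    log_k = np.log1p(k)
    m1 = float(np.sum(pmf * log_k))
    m2 = float(np.sum(pmf * log_k**2))
    return math.sqrt(max(m2 - m1 * m1, 0.0))


_PHI_GRID = np.geomspace(1e-4, 20.0, 36)


def dispersion_for_log_sd(mu: float, target_sd: float) -> float:
    """Dispersion phi making sd(ln(X+1)) match ``target_sd``; clamped when
    the target is unreachable at the given mean."""
    sds = np.array([log1p_sd(mu, phi) for phi in _PHI_GRID])
    diffs = sds - target_sd
    sign_change = np.flatnonzero(np.diff(np.sign(diffs)) != 0)
    if sign_change.size:
        i = sign_change[0]
        phi = optimize.brentq(
            lambda lp: log1p_sd(mu, math.exp(lp)) - target_sd,
            math.log(_PHI_GRID[i]),
            math.log(_PHI_GRID[i + 1]),
            xtol=1e-8,
        )
        return float(math.exp(phi))
    # unreachable target: return the best grid point (boundary clamp)
    return float(_PHI_GRID[int(np.argmin(np.abs(diffs)))])


class DispersionLookup:
    """Bilinear-interpolated table (ln mu x target sd) -> ln phi.

    Built once per process by root-finding on a modest grid; queries outside
    the grid clamp to its edges. Mirrors the 'precalculated for a range of
    parameter combinations' shortcut of the original tool.
    """

    def __init__(
        self,
        mu_grid: Optional[np.ndarray] = None,
        sd_grid: Optional[np.ndarray] = None,
    ) -> None:
        self.mu_grid = np.geomspace(0.005, 3000.0, 28) if mu_grid is None else np.asarray(mu_grid)
        self.sd_grid = np.linspace(0.35, 1.25, 10) if sd_grid is None else np.asarray(sd_grid)
        self._table: Optional[np.ndarray] = None

    def _build(self) -> None:
        table = np.empty((self.mu_grid.size, self.sd_grid.size))
        for i, mu in enumerate(self.mu_grid):
            for j, sd in enumerate(self.sd_grid):
                table[i, j] = math.log(dispersion_for_log_sd(float(mu), float(sd)))
        self._table = table

    def __call__(self, mu, target_sd):
        if self._table is None:
            logger.info("building dispersion lookup table (one-off)")
            self._build()
        mu = np.asarray(mu, dtype=float)
        sd = np.broadcast_to(np.asarray(target_sd, dtype=float), mu.shape).copy()
        lx = np.clip(np.log(mu), np.log(self.mu_grid[0]), np.log(self.mu_grid[-1]))
        ly = np.clip(sd, self.sd_grid[0], self.sd_grid[-1])
        gx = np.log(self.mu_grid)
        i = np.clip(np.searchsorted(gx, lx) - 1, 0, gx.size - 2)
        j = np.clip(np.searchsorted(self.sd_grid, ly) - 1, 0, self.sd_grid.size - 2)
        tx = (lx - gx[i]) / (gx[i + 1] - gx[i])
        ty = (ly - self.sd_grid[j]) / (self.sd_grid[j + 1] - self.sd_grid[j])
        t = self._table
        val = (
            t[i, j] * (1 - tx) * (1 - ty)
            + t[i + 1, j] * tx * (1 - ty)
            + t[i, j + 1] * (1 - tx) * ty
            + t[i + 1, j + 1] * tx * ty
        )
        return np.exp(val)


_DEFAULT_LOOKUP = DispersionLookup()


def _hwe_genotypes(n_s: int, f_a: float) -> np.ndarray:
    """Deterministic genotype vector with largest-remainder expected counts."""
    probs = np.array([f_a**2, 2 * f_a * (1 - f_a), (1 - f_a) ** 2])
    raw = probs * n_s
    counts = np.floor(raw).astype(int)
    rem = n_s - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    return np.repeat(np.arange(3), counts)


def eqtl_power_simulated(
    n_s: int,
    r2: float,
    alpha: float,
    mu_c: float,
    config: Optional[EQTLSimConfig] = None,
    lookup: Optional[DispersionLookup] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Simulation-based eQTL power for low pseudobulk means.

    Per repetition: draw an allele frequency, build a Hardy-Weinberg genotype
    vector, pick beta = sqrt(R^2 / (2 f_a (1-f_a))) and residual sd
    sqrt(1-R^2), draw NB counts with per-genotype mean exp(ln mu_c + beta*g)
    and dispersion matched so that sd(ln(X+1)) equals the residual sd, then
    test the slope of ln(x+1) ~ g. Power is the fraction of repetitions with
    p < alpha.
    """
    if mu_c <= 0:
        raise ValueError("mu_c must be > 0")
    config = config or EQTLSimConfig()
    lookup = lookup or _DEFAULT_LOOKUP
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not 0 <= r2 < 1:
        raise ValueError("R^2 must lie in [0, 1)")
    sigma_hat = math.sqrt(1.0 - r2)
    n_hits = 0
    tcrit_df = n_s - 2
    for _ in range(config.n_reps):
        for _attempt in range(100):
            f_a = rng.uniform(config.maf_low, config.maf_high)
            g = _hwe_genotypes(n_s, f_a)
            if np.ptp(g) > 0:
                break
            logger.debug("all-identical genotype vector redrawn (f_a=%.3f)", f_a)
        else:  # pragma: no cover - cannot happen for n_s >= 3 in the maf range
            raise RuntimeError("could not draw a polymorphic genotype vector")
        beta = math.sqrt(r2 / (2 * f_a * (1 - f_a))) if r2 > 0 else 0.0
        mu_g = np.exp(math.log(mu_c) + beta * g)
        phi_g = lookup(mu_g, sigma_hat)
        size = 1.0 / phi_g
        x = rng.negative_binomial(size, size / (size + mu_g))
        y = np.log1p(x)
        # OLS slope t-test of y ~ g
        gc = g - g.mean()
        ss_g = float(np.sum(gc * gc))
        slope = float(np.sum(gc * y)) / ss_g
        resid = y - y.mean() - slope * gc
        sigma2 = float(np.sum(resid**2)) / tcrit_df
        se = math.sqrt(max(sigma2 / ss_g, 1e-300))
        pval = 2 * stats.t.sf(abs(slope) / se, tcrit_df)
        if pval < alpha:
            n_hits += 1
    return n_hits / config.n_reps


def eqtl_power(
    n_s: int,
    r2: float,
    alpha: float,
    mu_c: float,
    config: Optional[EQTLSimConfig] = None,
    lookup: Optional[DispersionLookup] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Dispatch: count simulation below the mean switch (default 5), else F-test."""
    config = config or EQTLSimConfig()
    if mu_c < config.mean_switch:
        return eqtl_power_simulated(n_s, r2, alpha, mu_c, config=config, lookup=lookup, rng=rng)
    return eqtl_power_analytic(n_s, r2, alpha)


def bonferroni_alpha(expected_tests: float, n_indep_snps: int = 1, alpha: float = 0.05) -> float:
    """Family-wise adjusted threshold alpha / (expected tests * independent SNPs)."""
    if expected_tests <= 0:
        raise ValueError("expected_tests must be > 0")
    if n_indep_snps < 1:
        raise ValueError("n_indep_snps must be >= 1")
    return alpha / (expected_tests * n_indep_snps)


class FDRNoSolutionError(RuntimeError):
    """Raised when no raw threshold can produce any expected discovery."""


def fdr_alpha(
    prior_gene_powers: Callable[[float], np.ndarray],
    expected_expressed: float,
    expected_expressed_prior: float,
    target_fdr: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Invert FDR(a') = m0 a' / (m0 a' + r1(a')) for the raw threshold a'.

    ``prior_gene_powers(a')`` returns the per-prior-gene expected discovery
    probabilities (expression probability times power at a'); their sum is
    r1(a'). m0 = E(E) - E(E_prior) counts the expected expressed non-prior
    genes. Solved by bisection on ln(a') over [1e-12, 1].
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    if expected_expressed_prior > expected_expressed + 1e-9:
        raise ValueError("E(E_prior) cannot exceed E(E)")
    m0 = expected_expressed - expected_expressed_prior
    if m0 <= 0:
        logger.info("m0 = 0: every expressed gene is a prior gene; returning target_fdr")
        return target_fdr

    def fdr_at(log_a: float) -> float:
        a = math.exp(log_a)
        r1 = float(np.sum(prior_gene_powers(a)))
        return m0 * a / (m0 * a + r1) if r1 > 0 else 1.0

    r1_max = float(np.sum(prior_gene_powers(1.0)))
    if r1_max <= 0:
        raise FDRNoSolutionError("prior-gene powers are zero everywhere; FDR has no solution")
    lo, hi = math.log(1e-12), 0.0
    if fdr_at(hi) < target_fdr:
        logger.info("FDR below target even at a'=1; returning 1")
        return 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = fdr_at(mid)
        if abs(val - target_fdr) < tol:
            return math.exp(mid)
        if val < target_fdr:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))
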