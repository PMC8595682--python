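"""Shared domain types for the power-analysis framework.

The central objects are :class:`ExpressionPrior` (the fitted, depth-aware
description of a cell type's expression distribution), :class:`EffectSizePrior`
(ranked DE / eQTL effect sizes from a reference study or simulation) and
:class:`DesignPoint` (samples x cells x reads). Everything is a plain
dataclass with eager validation so that malformed inputs fail at construction
time rather than deep inside a power calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PilotCounts",
    "DesignPoint",
    "CellTypeContext",
    "GeneNBFit",
    "PseudobulkLaw",
    "GammaMixture",
    "LinearCurve",
    "DispersionTrend",
    "ExpressionPrior",
    "EffectRecord",
    "EffectSizePrior",
    "ExpressionThreshold",
    "CostModel",
    "GenePower",
    "PowerResult",
    "EQTLSimConfig",
    "beta_to_r2",
]

Technology = Literal["umi-droplet-10x", "umi-droplet-dropseq", "read-plate-smartseq2"]

#: genes considered when mapping expression ranks to mixture quantiles
DEFAULT_N_GENES = 21_000


@dataclass
class PilotCounts:
    """Pilot count matrix (genes x cells) with per-cell annotations."""

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    sample_ids: list[str]
    cell_types: list[str]
    batches: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n_genes, n_cells = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        for name, values in (
            ("cell_ids", self.cell_ids),
            ("sample_ids", self.sample_ids),
            ("cell_types", self.cell_types),
        ):
            if len(values) != n_cells:
                raise ValueError(f"{name} length {len(values)} != matrix columns {n_cells}")
        if self.batches is not None and len(self.batches) != n_cells:
            raise ValueError("batches length does not match matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if np.any(self.matrix < 0) or not np.allclose(self.matrix, np.round(self.matrix)):
            raise ValueError("non-count value: matrix must contain non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset_cell_type(self, cell_type: str) -> "PilotCounts":
        """Return the cells of a single cell type (gene order preserved)."""
        mask = np.array([ct == cell_type for ct in self.cell_types])
        if not mask.any():
            raise ValueError(f"no cells of type {cell_type!r}")
        idx = np.flatnonzero(mask)
        return PilotCounts(
            matrix=self.matrix[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            cell_types=[self.cell_types[i] for i in idx],
            batches=None if self.batches is None else [self.batches[i] for i in idx],
        )


@dataclass(frozen=True)
class DesignPoint:
    """A candidate experimental design: samples, cells per sample, reads per cell."""

    n_s: int
    n_c: int
    r: float
    group_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_s < 1:
            raise ValueError("n_s must be >= 1")
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.group_ratio <= 0:
            raise ValueError("group_ratio must be > 0")


@dataclass(frozen=True)
class CellTypeContext:
    """Doublet/mapping-adjusted quantities for one cell type inside a design."""

    cell_type: str
    f_c: float
    n_u: float
    n_cs: float
    r_s: float
    r_m: float
    doublet_rate: float = 0.0
    n_sl: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.f_c <= 1:
            raise ValueError("f_c must be in (0, 1]")
        if self.n_u < 0 or self.n_cs < 0:
            raise ValueError("cell numbers must be non-negative")
        if self.r_m > self.r_s + 1e-9:
            raise ValueError("mapped read depth cannot exceed singlet read depth")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must be in [0, 1]")


@dataclass(frozen=True)
class GeneNBFit:
    """Per-gene negative binomial fit (per-cell mean and dispersion)."""

    gene_id: str
    mu: float
    phi: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0 (use the Poisson clamp 1e-8)")


@dataclass(frozen=True)
class PseudobulkLaw:
    """NB law of the per-individual sum of n_cs i.i.d. NB(mu, phi) cell counts."""

    mu_prime: float
    phi_prime: float
    p_is: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_is <= 1:
            raise ValueError("p_is must be a probability")

    @classmethod
    def from_cell_law(cls, mu: float, phi: float, n_cs: float, p_is: float = 0.0) -> "PseudobulkLaw":
        return cls(mu_prime=n_cs * mu, phi_prime=phi / n_cs, p_is=p_is)


@dataclass
class GammaMixture:
    """Zero component + two (left-censored) gamma components over gene means.

    ``shape``/``rate`` follow the density s^r x^(r-1) e^(-sx) / Gamma(r), so a
    component has mean shape/rate and sd sqrt(shape)/rate.
    """

    p1: float
    p2: float
    p3: float
    shape1: float
    rate1: float
    shape2: float
    rate2: float
    censor_point: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        weights = np.array([self.p1, self.p2, self.p3], dtype=float)
        if np.any(weights < -1e-12):
            raise ValueError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {weights.sum()}, expected 1")
        for name in ("shape1", "rate1", "shape2", "rate2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.censor_point < 0:
            raise ValueError("censor_point must be >= 0")

    # --- uncensored mixture law (zero mass + two gammas) ---------------

    @property
    def mean1(self) -> float:
        return self.shape1 / self.rate1

    @property
    def mean2(self) -> float:
        return self.shape2 / self.rate2

    @property
    def sd1(self) -> float:
        return math.sqrt(self.shape1) / self.rate1

    @property
    def sd2(self) -> float:
        return math.sqrt(self.shape2) / self.rate2

    def mean(self) -> float:
        return self.p2 * self.mean1 + self.p3 * self.mean2

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = (
            self.p1
            + self.p2 * stats.gamma.cdf(x, a=self.shape1, scale=1.0 / self.rate1)
            + self.p3 * stats.gamma.cdf(x, a=self.shape2, scale=1.0 / self.rate2)
        )
        return np.where(x < 0, 0.0, out)

    def quantile(self, q):
        """Quantile of the uncensored mixture; values in the zero mass map to 0."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        out = np.zeros_like(q)
        pos = q > self.p1
        if pos.any():
            hi = max(
                stats.gamma.ppf(0.999999, a=self.shape1, scale=1.0 / self.rate1),
                stats.gamma.ppf(0.999999, a=self.shape2, scale=1.0 / self.rate2),
                1.0,
            )
            lo = np.zeros(pos.sum())
            hi_arr = np.full(pos.sum(), hi)
            target = q[pos]
            for _ in range(80):  # bisection: |hi-lo| shrinks by 2^-80
                mid = 0.5 * (lo + hi_arr)
                below = self.cdf(mid) < target
                lo = np.where(below, mid, lo)
                hi_arr = np.where(below, hi_arr, mid)
            out[pos] = 0.5 * (lo + hi_arr)
        return out if out.shape != (1,) else float(out[0])

    def sample_means(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw gene means; censored draws (below censor_point) return 0."""
        comp = rng.choice(3, size=n, p=[self.p1, self.p2, self.p3])
        means = np.zeros(n)
        for k, (shape, rate) in enumerate(
            [(self.shape1, self.rate1), (self.shape2, self.rate2)], start=1
        ):
            mask = comp == k
            means[mask] = rng.gamma(shape, 1.0 / rate, size=mask.sum())
        if self.censor_point > 0:
            means[means < self.censor_point] = 0.0
        return means


@dataclass(frozen=True)
class LinearCurve:
    """y = intercept + slope * x."""

    intercept: float
    slope: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class DispersionTrend:
    """phi(mu) = a0 + a1 / mu, optionally with depth-dependent coefficients.

    For UMI technologies a0/a1 are constants (averaged over subsampled runs);
    for Smart-seq2 they vary linearly with the read depth.
    """

    a0: Optional[float] = None
    a1: Optional[float] = None
    a0_curve: Optional[LinearCurve] = None
    a1_curve: Optional[LinearCurve] = None

    def __post_init__(self) -> None:
        constant = self.a0 is not None and self.a1 is not None
        depth = self.a0_curve is not None and self.a1_curve is not None
        if not (constant or depth):
            raise ValueError("dispersion trend needs (a0, a1) or depth curves")

    def coefficients(self, read_depth: Optional[float] = None) -> tuple[float, float]:
        if self.a0 is not None and self.a1 is not None:
            return float(self.a0), float(self.a1)
        if read_depth is None:
            raise ValueError("depth-dependent dispersion trend requires a read depth")
        return float(self.a0_curve(read_depth)), float(self.a1_curve(read_depth))


#: floor applied to the zero-component weight when evaluating the p1 line
P1_FLOOR = 0.01


@dataclass
class ExpressionPrior:
    """Fitted, depth-parameterized expression model of one cell type.

    ``component_curves`` maps {'mean1','sd1','mean2','sd2','p1'} to linear
    curves in the mean UMI count per cell (for Smart-seq2, in the read depth).
    ``read_umi_curve`` gives mapped reads = b0 + b1 * ln(mean UMI).
    """

    cell_type: str
    technology: Technology
    component_curves: dict[str, LinearCurve]
    p3_const: float
    dispersion_trend: DispersionTrend
    read_umi_curve: Optional[LinearCurve] = None
    n_genes: int = DEFAULT_N_GENES
    depth_range: Optional[tuple[float, float]] = None

    REQUIRED_CURVES = ("mean1", "sd1", "mean2", "sd2", "p1")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED_CURVES if k not in self.component_curves]
        if missing:
            raise ValueError(f"missing component curves: {missing}")
        if not 0 <= self.p3_const < 1:
            raise ValueError("p3_const must be in [0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class EffectRecord:
    """One prior gene: expression rank plus effect size."""

    rank: int
    effect: float
    gene_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.gene_length is not None and self.gene_length <= 0:
            raise ValueError("gene_length must be > 0")


def beta_to_r2(beta: float, se: float, n: float) -> float:
    """R^2 of a single-predictor regression from (beta, se, study size).

    t = beta / se;  R^2 = t^2 / (n - 2 + t^2).
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError("study sample size must exceed 2")
    t = beta / se
    return t * t / (n - 2 + t * t)


@dataclass
class EffectSizePrior:
    """Ranked effect sizes (log2 fold changes for DE, R^2 for eQTL)."""

    kind: Literal["de", "eqtl"]
    records: list[EffectRecord]
    source_sample_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("de", "eqtl"):
            raise ValueError("kind must be 'de' or 'eqtl'")
        self.records = sorted(self.records, key=lambda rec: rec.rank)
        if self.kind == "eqtl":
            for rec in self.records:
                if not 0 <= rec.effect < 1:
                    raise ValueError(f"eQTL R^2 {rec.effect} outside [0, 1)")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ranks(self) -> np.ndarray:
        return np.array([rec.rank for rec in self.records])

    @property
    def effects(self) -> np.ndarray:
        return np.array([rec.effect for rec in self.records])


@dataclass(frozen=True)
class ExpressionThreshold:
    """Definition of an 'expressed' gene.

    A gene passes in one individual when its pseudobulk sum exceeds
    ``min_count`` (mode 'pseudobulk-count') or when at least ``min_count``
    cells show a nonzero count (mode 'nonzero-cells'); it is called expressed
    when it passes in more than ``individual_fraction`` of the individuals
    (or in at least ``min_individuals`` of them, if given).
    """

    mode: Literal["pseudobulk-count", "nonzero-cells"] = "pseudobulk-count"
    min_count: int = 0
    individual_fraction: Optional[float] = 0.5
    min_individuals: Optional[int] = None
    length_normalized: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("pseudobulk-count", "nonzero-cells"):
            raise ValueError("unknown threshold mode")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.min_individuals is None:
            if self.individual_fraction is None:
                raise ValueError("need individual_fraction or min_individuals")
            if not 0 <= self.individual_fraction < 1:
                raise ValueError("individual_fraction must lie in [0, 1)")
        elif self.min_individuals < 1:
            raise ValueError("min_individuals must be >= 1")


@dataclass(frozen=True)
class CostModel:
    """Library-preparation and sequencing cost structure.

    10x mode uses kit/lane pricing with an overloading-dependent doublet rate;
    Drop-seq / Smart-seq2 use a per-cell library cost and a constant doublet
    rate.
    """

    kit_cost: float = 5_600.0
    lanes_per_kit: int = 6
    flowcell_cost: float = 14_032.0
    reads_per_flowcell: float = 4.1e9
    cells_loaded_per_lane: int = 20_000
    doublet_slope: Optional[float] = 7.67e-6
    doublet_rate_constant: Optional[float] = None
    doublet_read_factor: float = 1.8
    mapping_efficiency: float = 0.8
    per_cell_library_cost: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("kit_cost", "flowcell_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reads_per_flowcell <= 0:
            raise ValueError("reads_per_flowcell must be > 0")
        if not 0 < self.mapping_efficiency <= 1:
            raise ValueError("mapping_efficiency must be in (0, 1]")
        if self.doublet_read_factor < 1:
            raise ValueError("doublet_read_factor must be >= 1")
        if self.doublet_slope is None and self.doublet_rate_constant is None:
            raise ValueError("need doublet_slope or doublet_rate_constant")

    @property
    def uses_overloading(self) -> bool:
        return self.doublet_rate_constant is None


@dataclass(frozen=True)
class GenePower:
    """Detection-power decomposition for one prior gene."""

    rank: int
    expression_probability: float
    significance_power: float

    @property
    def detection_power(self) -> float:
        return self.expression_probability * self.significance_power


@dataclass
class PowerResult:
    """Aggregate power of one design for one effect-size prior."""

    per_gene: list[GenePower]
    expected_expressed: float
    expected_expressed_prior: float
    adjusted_alpha: float
    m0: Optional[float] = None
    expected_significant_prior: Optional[float] = None

    def __post_init__(self) -> None:
        for gp in self.per_gene:
            for p in (gp.expression_probability, gp.significance_power):
                if not -1e-12 <= p <= 1 + 1e-12:
                    raise ValueError("probabilities must lie in [0, 1]")

    @property
    def overall_power(self) -> float:
        if not self.per_gene:
            return float("nan")
        return float(np.mean([gp.detection_power for gp in self.per_gene]))

    @property
    def mean_expression_probability(self) -> float:
        return float(np.mean([gp.expression_probability for gp in self.per_gene]))

    @property
    def mean_significance_power(self) -> float:
        return float(np.mean([gp.significance_power for gp in self.per_gene]))


@dataclass(frozen=True)
class EQTLSimConfig:
    """Settings of the discrete (low-mean) eQTL power simulation."""

    n_reps: int = 100
    maf_low: float = 0.1
    maf_high: float = 0.9
    mean_switch: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.maf_low < self.maf_high < 1:
            raise ValueError("need 0 < maf_low < maf_high < 1")
        if self.mean_switch <= 0:
            raise ValueError("mean_switch must be > 0")
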