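"""Cost model, doublet adjustment, rare-cell detection and budget optimization.

Ties together the per-design adjustments (overloading doublets, effective
read depth, mapping efficiency), the kit/flowcell cost structure and a grid
search over two of (samples, cells per sample, reads per cell) with the third
derived from a fixed budget.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CellTypeContext,
    CostModel,
    DesignPoint,
    EffectSizePrior,
    ExpressionPrior,
    ExpressionThreshold,
)
from .detection import overall_detection_power

logger = logging.getLogger(__name__)

__all__ = [
    "DoubletAdjustment",
    "doublet_adjust",
    "make_cell_type_context",
    "experiment_cost",
    "sample_size_for_budget",
    "celltype_detection_probability",
    "min_cells_for_detection",
    "optimize_design",
]


@dataclass(frozen=True)
class DoubletAdjustment:
    """Doublet/overloading consequences of loading n_c cells per sample."""

    doublet_rate: float
    n_u: float
    r_s: float
    r_m: float
    n_sl: Optional[int]


def doublet_adjust(n_c: int, cost_model: CostModel, r: float) -> DoubletAdjustment:
    """Usable cells and effective read depths after doublet removal.

    Overloading mode (10x): d = slope * n_c * n_sl with n_sl =
    floor(cells_loaded_per_lane / n_c); constant mode uses the configured
    rate. Doublets soak up ``doublet_read_factor`` times the singlet reads,
    so r_s = r*n_c / (n_u + f_d*(n_c - n_u)), and mapping leaves
    r_m = mapping_efficiency * r_s.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    if r <= 0:
        raise ValueError("r must be > 0")
    if cost_model.uses_overloading:
        n_sl = int(cost_model.cells_loaded_per_lane // n_c)
        if n_sl == 0:
            raise ValueError("cells per sample exceed lane capacity")
        d = min(cost_model.doublet_slope * n_c * n_sl, 1.0)
    else:
        n_sl = None
        d = cost_model.doublet_rate_constant
    n_u = (1.0 - d) * n_c
    r_s = r * n_c / (n_u + cost_model.doublet_read_factor * (n_c - n_u))
    r_m = cost_model.mapping_efficiency * r_s
    return DoubletAdjustment(doublet_rate=d, n_u=n_u, r_s=r_s, r_m=r_m, n_sl=n_sl)


def make_cell_type_context(
    design: DesignPoint,
    f_c: float,
    cost_model: CostModel,
    cell_type: str = "",
) -> CellTypeContext:
    """Apply the doublet model to a design for one target cell type.

    The expected number of target-type cells per sample is f_c * n_u rounded
    down; a value below 1 flags the design as infeasible.
    """
    adj = doublet_adjust(design.n_c, cost_model, design.r)
    n_cs = math.floor(f_c * adj.n_u)
    if n_cs < 1:
        raise ValueError(
            f"design yields {f_c * adj.n_u:.2f} cells of the target type per sample "
            "(fewer than 1); infeasible"
        )
    return CellTypeContext(
        cell_type=cell_type,
        f_c=f_c,
        n_u=adj.n_u,
        n_cs=float(n_cs),
        r_s=adj.r_s,
        r_m=adj.r_m,
        doublet_rate=adj.doublet_rate,
        n_sl=adj.n_sl,
    )


def experiment_cost(design: DesignPoint, cost_model: CostModel) -> float:
    """Total cost: library preparation (kits or per cell) plus sequencing."""
    if design.n_s == 0:
        return 0.0
    seq_cost = (
        math.ceil(design.n_s * design.n_c * design.r / cost_model.reads_per_flowcell)
        * cost_model.flowcell_cost
    )
    if cost_model.per_cell_library_cost is not None:
        lib_cost = cost_model.per_cell_library_cost * design.n_s * design.n_c
    else:
        n_sl = int(cost_model.cells_loaded_per_lane // design.n_c)
        if n_sl == 0:
            raise ValueError("cells per sample exceed lane capacity")
        lib_cost = (
            math.ceil(design.n_s / (cost_model.lanes_per_kit * n_sl)) * cost_model.kit_cost
        )
    return lib_cost + seq_cost


def sample_size_for_budget(budget: float, n_c: int, r: float, cost_model: CostModel) -> int:
    """Largest sample size affordable at (n_c, r), ceiling-free cost model."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    per_sample = _per_sample_cost(n_c, r, cost_model)
    return int(budget // per_sample)


def _per_sample_cost(n_c: int, r: float, cost_model: CostModel) -> float:
    seq = n_c * r * cost_model.flowcell_cost / cost_model.reads_per_flowcell
    if cost_model.per_cell_library_cost is not None:
        lib = cost_model.per_cell_library_cost * n_c
    else:
        n_sl = int(cost_model.cells_loaded_per_lane // n_c)
        if n_sl == 0:
            raise ValueError("cells per sample exceed lane capacity")
        lib = cost_model.kit_cost / (cost_model.lanes_per_kit * n_sl)
    per_sample = lib + seq
    if per_sample <= 0:
        raise ValueError("per-sample cost must be > 0")
    return per_sample


def reads_for_budget(budget: float, n_s: int, n_c: int, cost_model: CostModel) -> float:
    """Read depth affordable at (n_s, n_c), ceiling-free cost model."""
    if cost_model.per_cell_library_cost is not None:
        lib = cost_model.per_cell_library_cost * n_c
    else:
        n_sl = int(cost_model.cells_loaded_per_lane // n_c)
        if n_sl == 0:
            raise ValueError("cells per sample exceed lane capacity")
        lib = cost_model.kit_cost / (cost_model.lanes_per_kit * n_sl)
    remaining = budget / n_s - lib
    if remaining <= 0:
        return 0.0
    return remaining * cost_model.reads_per_flowcell / (n_c * cost_model.flowcell_cost)


def celltype_detection_probability(
    n_c: int, n_cs_target: int, f_c: float, n_s: int = 1
) -> float:
    """Probability that every individual yields >= n_cs_target cells of a type.

    Per individual this is the NB CDF of failures before the n_cs_target-th
    success at success probability f_c, evaluated at n_c - n_cs_target; across
    individuals the probability is raised to n_s.
    """
    if n_cs_target < 1:
        raise ValueError("n_cs_target must be >= 1")
    if not 0 < f_c <= 1:
        raise ValueError("f_c must be in (0, 1]")
    if n_cs_target > n_c:
        return 0.0
    single = float(stats.nbinom.cdf(n_c - n_cs_target, n_cs_target, f_c))
    return single**n_s


def min_cells_for_detection(
    f_c: float, n_cs_target: int, n_s: int, target_prob: float
) -> int:
    """Smallest n_c whose detection probability reaches target_prob."""
    if not 0 < target_prob < 1:
        raise ValueError("target_prob must be in (0, 1)")
    lo = n_cs_target
    if celltype_detection_probability(lo, n_cs_target, f_c, n_s) >= target_prob:
        return lo
    hi = max(2 * lo, 2)
    while celltype_detection_probability(hi, n_cs_target, f_c, n_s) < target_prob:
        lo = hi
        hi *= 2
        if hi > 10**9:
            raise RuntimeError("no feasible cell number below 1e9")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if celltype_detection_probability(mid, n_cs_target, f_c, n_s) >= target_prob:
            hi = mid
        else:
            lo = mid
    assert celltype_detection_probability(hi, n_cs_target, f_c, n_s) >= target_prob
    assert celltype_detection_probability(hi - 1, n_cs_target, f_c, n_s) < target_prob
    return hi


def optimize_design(
    budget: float,
    prior: ExpressionPrior,
    effects: EffectSizePrior,
    f_c: float,
    threshold: ExpressionThreshold,
    cost_model: CostModel,
    cells_grid: Optional[Sequence[int]] = None,
    reads_grid: Optional[Sequence[float]] = None,
    samples_grid: Optional[Sequence[int]] = None,
    mt: str = "fdr",
    alpha: float = 0.05,
    group_ratio: float = 1.0,
    min_samples: int = 2,
    **power_kwargs,
) -> pd.DataFrame:
    """Grid search of designs under a fixed budget.

    Two of the three parameters are gridded (cells x reads, or samples x
    cells) and the third is derived from the ceiling-free cost model. Each
    feasible point is doublet-adjusted and scored by overall detection power.
    The returned table is sorted by power (ties: larger n_s, then lower r);
    the first row is the optimum.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    points: list[tuple[int, int, float]] = []
    if cells_grid is not None and reads_grid is not None and samples_grid is None:
        for n_c in cells_grid:
            for r in reads_grid:
                try:
                    n_s = sample_size_for_budget(budget, int(n_c), float(r), cost_model)
                except ValueError:
                    continue
                points.append((n_s, int(n_c), float(r)))
    elif samples_grid is not None and cells_grid is not None and reads_grid is None:
        for n_s in samples_grid:
            for n_c in cells_grid:
                try:
                    r = reads_for_budget(budget, int(n_s), int(n_c), cost_model)
                except ValueError:
                    continue
                points.append((int(n_s), int(n_c), r))
    else:
        raise ValueError("grid exactly two parameters: (cells, reads) or (samples, cells)")

    rows = []
    for n_s, n_c, r in points:
        if n_s < min_samples or r <= 0:
            continue
        design = DesignPoint(n_s=n_s, n_c=n_c, r=r, group_ratio=group_ratio)
        try:
            ctx = make_cell_type_context(design, f_c, cost_model, cell_type=prior.cell_type)
            result = overall_detection_power(
                prior, effects, ctx, design, threshold, mt=mt, alpha=alpha, **power_kwargs
            )
        except ValueError as exc:
            logger.debug("skipping infeasible design %s: %s", (n_s, n_c, r), exc)
            continue
        rows.append(
            {
                "n_s": n_s,
                "n_c": n_c,
                "r": r,
                "n_cs": ctx.n_cs,
                "r_m": ctx.r_m,
                "doublet_rate": ctx.doublet_rate,
                "expected_expressed": result.expected_expressed,
                "adjusted_alpha": result.adjusted_alpha,
                "expression_probability": result.mean_expression_probability,
                "significance_power": result.mean_significance_power,
                "overall_power": result.overall_power,
            }
        )
    if not rows:
        raise ValueError("no feasible design in the grid under this budget")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["overall_power", "n_s", "r"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table
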