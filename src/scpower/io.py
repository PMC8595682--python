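"""Readers and writers for count matrices, annotations and priors.

Count matrices come as Matrix Market (genes x cells, the layout written by
common single-cell pipelines) or as dense TSV with gene ids in the first
column and cell ids in the header. Fitted expression priors are serialized to
a small, schema-versioned JSON document so they stay human-diffable.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data_model import (
    DispersionTrend,
    EffectRecord,
    EffectSizePrior,
    ExpressionPrior,
    LinearCurve,
    PilotCounts,
    beta_to_r2,
)

logger = logging.getLogger(__name__)

PRIOR_SCHEMA_VERSION = 1

__all__ = [
    "load_pilot_counts",
    "load_effect_prior",
    "save_effect_prior",
    "save_prior",
    "load_prior",
]


def _read_matrix(path: Union[str, Path]) -> tuple[np.ndarray, Optional[list[str]], Optional[list[str]]]:
    """Return (matrix, gene_ids or None, cell_ids or None)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        return np.asarray(mat), None, None
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns]


def load_pilot_counts(
    matrix_path: Union[str, Path],
    annotation_path: Union[str, Path],
    orientation: Literal["auto", "genes-by-cells", "cells-by-genes"] = "auto",
    barcodes_path: Optional[Union[str, Path]] = None,
) -> PilotCounts:
    """Load a pilot count matrix plus its cell annotation table.

    The annotation TSV must provide columns ``cell_id``, ``sample_id`` and
    ``cell_type`` (optionally ``batch``). Matrix Market files carry no ids:
    columns are matched to a barcodes file when given, otherwise they are
    named ``cell_0 .. cell_{n-1}`` in file order. Cells missing from the
    annotation are dropped with a logged warning; annotation rows without a
    matching matrix column raise an error.
    """
    matrix, gene_ids, cell_ids = _read_matrix(matrix_path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "cell_type"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must contain columns {sorted(required)}")
    if ann["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in annotation")

    if orientation == "cells-by-genes":
        matrix = matrix.T
        gene_ids, cell_ids = cell_ids, gene_ids
    elif orientation == "auto" and cell_ids is None:
        # MTX carries no labels: orient so that columns can cover the annotation
        n_ann = len(ann)
        if matrix.shape[1] < n_ann <= matrix.shape[0]:
            matrix = matrix.T

    if barcodes_path is not None:
        cell_ids = [l.strip() for l in Path(barcodes_path).read_text().splitlines() if l.strip()]
        if len(cell_ids) != matrix.shape[1]:
            raise ValueError("barcodes file length does not match matrix columns")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(matrix.shape[1])]
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(matrix.shape[0])]

    ann = ann.set_index("cell_id")
    unknown = set(ann.index) - set(cell_ids)
    if unknown:
        raise ValueError(f"annotation rows without a matrix column: {sorted(unknown)[:5]}")
    keep = [i for i, cid in enumerate(cell_ids) if cid in ann.index]
    n_dropped = matrix.shape[1] - len(keep)
    if n_dropped:
        logger.warning("dropping %d cells absent from the annotation", n_dropped)
        warnings.warn(f"dropped {n_dropped} cells absent from the annotation")
    if not keep:
        raise ValueError("no matrix column matches the annotation")

    kept_ids = [cell_ids[i] for i in keep]
    ann = ann.loc[kept_ids]
    if np.any(matrix < 0) or not np.allclose(matrix, np.round(matrix)):
        raise ValueError("non-count value: matrix must contain non-negative integers")
    return PilotCounts(
        matrix=matrix[:, keep].astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=kept_ids,
        sample_ids=ann["sample_id"].tolist(),
        cell_types=ann["cell_type"].tolist(),
        batches=ann["batch"].tolist() if "batch" in ann.columns else None,
    )


def load_effect_prior(path: Union[str, Path], kind: Literal["de", "eqtl"]) -> EffectSizePrior:
    """Load a ranked effect-size table (TSV with header).

    DE tables need columns ``rank`` and ``log2fc``; eQTL tables either ``r2``
    or the triple ``beta``, ``se``, ``n`` (converted via t = beta/se,
    R^2 = t^2/(n-2+t^2)). An optional ``gene_length`` column is carried along.
    """
    df = pd.read_csv(path, sep="\t")
    if "rank" not in df.columns:
        raise ValueError("effect prior table must have a 'rank' column")
    source_n: Optional[int] = None
    if kind == "de":
        if "log2fc" not in df.columns:
            raise ValueError("DE prior requires a 'log2fc' column")
        effects = df["log2fc"].astype(float)
    elif kind == "eqtl":
        if "r2" in df.columns:
            effects = df["r2"].astype(float)
        elif {"beta", "se", "n"}.issubset(df.columns):
            effects = pd.Series(
                [beta_to_r2(b, s, n) for b, s, n in zip(df["beta"], df["se"], df["n"])],
                index=df.index,
            )
            source_n = int(df["n"].iloc[0])
        else:
            raise ValueError("eQTL prior requires 'r2' or ('beta','se','n') columns")
    else:
        raise ValueError("kind must be 'de' or 'eqtl'")
    lengths = df["gene_length"] if "gene_length" in df.columns else None
    records = [
        EffectRecord(
            rank=int(row_rank),
            effect=float(eff),
            gene_length=None if lengths is None else float(lengths.iloc[i]),
        )
        for i, (row_rank, eff) in enumerate(zip(df["rank"], effects))
    ]
    return EffectSizePrior(kind=kind, records=records, source_sample_size=source_n)


def save_effect_prior(prior: EffectSizePrior, path: Union[str, Path]) -> None:
    effect_col = "log2fc" if prior.kind == "de" else "r2"
    rows = {"rank": [r.rank for r in prior.records], effect_col: [r.effect for r in prior.records]}
    if any(r.gene_length is not None for r in prior.records):
        rows["gene_length"] = [r.gene_length for r in prior.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- expression prior JSON (schema version 1) --------------------------------


def _curve_to_json(curve: Optional[LinearCurve]):
    if curve is None:
        return None
    return {"intercept": curve.intercept, "slope": curve.slope}


def _curve_from_json(obj) -> Optional[LinearCurve]:
    if obj is None:
        return None
    return LinearCurve(intercept=float(obj["intercept"]), slope=float(obj["slope"]))


def save_prior(prior: ExpressionPrior, path: Union[str, Path]) -> None:
    """Serialize a fitted expression prior to versioned JSON."""
    trend = prior.dispersion_trend
    doc = {
        "schema_version": PRIOR_SCHEMA_VERSION,
        "cell_type": prior.cell_type,
        "technology": prior.technology,
        "component_curves": {k: _curve_to_json(v) for k, v in prior.component_curves.items()},
        "p3_const": prior.p3_const,
        "dispersion_trend": {
            "a0": trend.a0,
            "a1": trend.a1,
            "a0_curve": _curve_to_json(trend.a0_curve),
            "a1_curve": _curve_to_json(trend.a1_curve),
        },
        "read_umi_curve": _curve_to_json(prior.read_umi_curve),
        "n_genes": prior.n_genes,
        "depth_range": list(prior.depth_range) if prior.depth_range else None,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_prior(path: Union[str, Path]) -> ExpressionPrior:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != PRIOR_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported prior schema version {version!r} (expected {PRIOR_SCHEMA_VERSION})"
        )
    missing = [
        k
        for k in ("cell_type", "technology", "component_curves", "p3_const", "dispersion_trend")
        if k not in doc
    ]
    if missing:
        raise ValueError(f"prior file missing fields: {missing}")
    trend = doc["dispersion_trend"]
    return ExpressionPrior(
        cell_type=doc["cell_type"],
        technology=doc["technology"],
        component_curves={k: _curve_from_json(v) for k, v in doc["component_curves"].items()},
        p3_const=float(doc["p3_const"]),
        dispersion_trend=DispersionTrend(
            a0=trend.get("a0"),
            a1=trend.get("a1"),
            a0_curve=_curve_from_json(trend.get("a0_curve")),
            a1_curve=_curve_from_json(trend.get("a1_curve")),
        ),
        read_umi_curve=_curve_from_json(doc.get("read_umi_curve")),
        n_genes=int(doc.get("n_genes", 21_000)),
        depth_range=tuple(doc["depth_range"]) if doc.get("depth_range") else None,
    )
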