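"""Prevalence filtering, FPKM conversion and log transformation.

These steps precede every analysis stage: transcripts kept for analysis
must be expressed (value above a threshold, default strictly > 0) in at
least a minimum fraction of cells (default 5%, boundary inclusive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_low_prevalence(
    m: ExpressionMatrix,
    min_frac: float = 0.05,
    expressed_threshold: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes expressed in at least ``min_frac`` of cells.

    A gene is kept iff ``(#cells with value > expressed_threshold) /
    n_cells >= min_frac`` — the boundary is inclusive. Cells and gene
    order are untouched.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    frac = (m.values > expressed_threshold).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError(
            "no gene passes the prevalence filter; review min_frac "
            f"({min_frac}) and expressed_threshold ({expressed_threshold})"
        )
    kept_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    logger.info("prevalence filter kept %d/%d genes", len(kept_ids), m.n_genes)
    return ExpressionMatrix(m.values[keep], kept_ids, m.cell_ids, m.unit, dict(m.meta))


def counts_to_fpkm(counts: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Convert raw counts to FPKM using annotated transcript lengths.

    ``FPKM_gc = counts_gc / ((length_bp_g / 1e3) * (total counts of cell c / 1e6))``.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    missing = [g for g in counts.gene_ids if g not in ann.index]
    if missing:
        raise KeyError(f"genes without annotated length: {missing[:10]}"
                       + (" ..." if len(missing) > 10 else ""))
    lengths_kb = ann.loc[counts.gene_ids, "length_bp"].to_numpy(dtype=float) / 1e3
    totals = counts.values.sum(axis=0)
    if np.any(totals == 0):
        zero_cells = [c for c, t in zip(counts.cell_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total counts: {zero_cells[:10]}")
    fpkm = counts.values / (lengths_kb[:, None] * (totals[None, :] / 1e6))
    return ExpressionMatrix(fpkm, counts.gene_ids, counts.cell_ids, "fpkm", dict(counts.meta))


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) variance stabilization; keeps zeros at zero."""
    if m.unit != "fpkm":
        raise ValueError(f"expected an fpkm matrix, got unit {m.unit!r}")
    return ExpressionMatrix(
        np.log2(m.values + 1.0), m.gene_ids, m.cell_ids, "log2fpkm", dict(m.meta)
    )
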