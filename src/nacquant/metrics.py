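"""Evaluation metrics comparing a program count matrix to a truth matrix.

Given a truth matrix ``G_s`` (entries ``y_ij``) and a program matrix ``G_p``
(entries ``ŷ_ij``) over n cells × m genes:

* ``RMSE = sqrt( (1/nm) Σ_ij (y_ij − ŷ_ij)² )``
* ``FPR`` — fraction of *all* nm entries with ``y_ij = 0`` and ``ŷ_ij > 0``
* ``FNR`` — fraction of *all* nm entries with ``y_ij > 0`` and ``ŷ_ij = 0``
  (denominator is the full matrix size, not the classical rate denominators)
* ``r_i`` — per-cell Pearson correlation over all m genes
* ``ρ*_i`` — per-cell Spearman correlation over the gene pairs with
  ``(y_ij, ŷ_ij) ≠ (0, 0)`` (zeros common to both matrices cannot be ranked
  against each other and are excluded); a strict variant restricted to genes
  nonzero in *both* matrices is available behind ``spearman_mode``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .count import CountMatrix
from .errors import ValidationError


@dataclass
class MetricsReport:
    rmse: float
    fpr: float
    fnr: float
    pearson: np.ndarray  # per cell, NaN where undefined
    spearman: np.ndarray  # per cell, NaN where undefined
    n_cells: int
    n_genes: int

    @property
    def median_pearson(self) -> float:
        return float(np.nanmedian(self.pearson)) if np.any(~np.isnan(self.pearson)) else math.nan

    @property
    def median_spearman(self) -> float:
        return (
            float(np.nanmedian(self.spearman)) if np.any(~np.isnan(self.spearman)) else math.nan
        )

    @property
    def n_pearson_undefined(self) -> int:
        return int(np.isnan(self.pearson).sum())

    @property
    def n_spearman_undefined(self) -> int:
        return int(np.isnan(self.spearman).sum())

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "median_pearson": self.median_pearson,
            "median_spearman": self.median_spearman,
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_pearson_undefined": self.n_pearson_undefined,
            "n_spearman_undefined": self.n_spearman_undefined,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def evaluate(
    truth: CountMatrix,
    pred: CountMatrix,
    *,
    spearman_mode: str = "nonzero-pair",
) -> MetricsReport:
    """Compute RMSE/FPR/FNR and per-cell correlations of ``pred`` vs ``truth``.

    The two matrices must carry the same barcode and gene label sets; they
    are aligned by label, not position.  ``spearman_mode`` selects which gene
    pairs enter ρ*: ``"nonzero-pair"`` (default) drops pairs equal to (0, 0);
    ``"both-nonzero"`` keeps only genes nonzero in both matrices.
    """
    if spearman_mode not in ("nonzero-pair", "both-nonzero"):
        raise ValidationError(f"unknown spearman_mode {spearman_mode!r}")
    if set(truth.barcodes) != set(pred.barcodes) or set(truth.genes) != set(pred.genes):
        raise ValidationError(
            "matrices carry different label sets; align the prediction first "
            "(CountMatrix.align_to)"
        )
    pred = pred.align_to(truth.barcodes, truth.genes)
    y, yhat = truth.values, pred.values
    n, m = y.shape
    diff = y - yhat
    rmse = float(np.sqrt(np.mean(diff**2)))
    fpr = float(np.mean((y == 0) & (yhat > 0)))
    fnr = float(np.mean((y > 0) & (yhat == 0)))
    pearson = np.empty(n)
    spearman = np.empty(n)
    for i in range(n):
        pearson[i] = _pearson(y[i], yhat[i])
        if spearman_mode == "nonzero-pair":
            keep = ~((y[i] == 0) & (yhat[i] == 0))
        else:
            keep = (y[i] != 0) & (yhat[i] != 0)
        spearman[i] = _spearman(y[i][keep], yhat[i][keep])
    return MetricsReport(rmse, fpr, fnr, pearson, spearman, n, m)


def top_barcodes(matrix: CountMatrix, n_top: int) -> list[str]:
    """The ``n_top`` barcodes with the highest total UMI count.

    Ties at the cutoff are broken lexicographically by barcode.  Asking for
    more barcodes than exist returns all of them.
    """
    if n_top < 1:
        raise ValidationError(f"n_top must be >= 1, got {n_top}")
    totals = matrix.total_per_barcode()
    ranked = sorted(totals, key=lambda b: (-totals[b], b))
    if n_top > len(ranked):
        import warnings

        warnings.warn(
            f"requested {n_top} barcodes but only {len(ranked)} exist", stacklevel=2
        )
    return ranked[:n_top]
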