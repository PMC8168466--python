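"""Differential-expression gate between case and control samples.

Genes are called differentially expressed when |log fold change| exceeds
the configured cut-off (default 2, strict inequality) AND the
Benjamini-Hochberg adjusted p-value is below alpha (default 0.05).  The
fold change is the difference of group means, which is a log2 fold change
when — as the pipeline assumes — expression values are already on a log
scale.  The location test is Welch's two-sample t; the screen treats DE
purely as a gate for the gene lists entering the correlation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("com6ar")


@dataclass(frozen=True)
class DeResult:
    gene: str
    log_fc: float
    p_raw: float
    p_adj: float
    is_de: bool
    direction: str  # "up" | "down" | "none"


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def differential_expression(em: ExpressionMatrix,
                            lfc_min: float = 2.0,
                            alpha: float = 0.05) -> list[DeResult]:
    """Welch t + BH over all genes; both groups need >= 2 samples.

    Genes with zero variance in both groups get p_raw = 1 (logged); genes
    with missing values are dropped beforehand via ``drop_missing``.
    """
    em = em.drop_missing()
    case, ctrl = em.split_groups()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError(f"need >= 2 samples per group, got "
                         f"{case.shape[1]} case / {ctrl.shape[1]} control")
    a = case.to_numpy()
    b = ctrl.to_numpy()
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p_raw = np.asarray(t_res.pvalue, dtype=float)

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        logger.warning("%d gene(s) with zero variance in both groups; "
                       "p set to 1", int(degenerate.sum()))
        p_raw[degenerate] = 1.0
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)

    p_adj = bh_adjust(p_raw)
    out: list[DeResult] = []
    for g, lfc, pr, pa in zip(em.gene_ids, log_fc, p_raw, p_adj):
        is_de = bool(abs(lfc) > lfc_min and pa < alpha)
        direction = "none"
        if is_de:
            direction = "up" if lfc > 0 else "down"
        out.append(DeResult(gene=g, log_fc=float(lfc), p_raw=float(pr),
                            p_adj=float(pa), is_de=is_de, direction=direction))
    return out


def de_gate(results: list[DeResult], genes: list[str]) -> list[str]:
    """Restrict a gene list to its differentially expressed members,
    preserving order.  Genes absent from the DE results are dropped."""
    de = {r.gene for r in results if r.is_de}
    return [g for g in genes if g in de]
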