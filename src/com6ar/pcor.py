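"""Partial correlation of candidate genes with m6A regulators.

The statistical core of the package.  For gene expression vectors x (a
regulator, from set M) and y (a candidate, from G) and a control matrix D
(the diabetes gene set), the partial correlation rho is the Pearson
correlation of the residuals of x and y after least-squares regression on
D (with intercept).  Its null distribution is tested with

    t = rho * sqrt(n - k - 2) / sqrt(1 - rho^2),   df = n - k - 2,

where n is the number of samples and k the number of control variables
actually regressed out.  For a single control variable the first-order
recursion (r_xy - r_xZ r_yZ) / sqrt((1 - r_xZ^2)(1 - r_yZ^2)) gives the
same number; both forms are exposed and must agree.

Conventions fixed here: sample standard deviation (ddof=1) for the
flat-expression filter; intercept always included in residualizing
regressions; rho clipped to [-1, 1] only within 1e-12; zero residual
variance raises rather than silently returning 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

logger = logging.getLogger("com6ar")

_CLIP_TOL = 1e-12
_VAR_TOL = 1e-12


class InsufficientDfError(ValueError):
    """n - k - 2 < 1: no degrees of freedom left for the test."""


class UndefinedCorrelationError(ValueError):
    """A residual has (numerically) zero variance; rho is undefined."""


@dataclass(frozen=True)
class PcorResult:
    """One (candidate gene, regulator) pair."""

    gene: str
    regulator: str
    rho: float
    t_stat: float
    n: int
    k: int
    df: int
    p: float
    p_adj: float | None = None


# ---------------------------------------------------------------------------
# elementwise operations
# ---------------------------------------------------------------------------

def _as_control_matrix(D, n: int) -> np.ndarray:
    if D is None:
        return np.empty((0, n))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.size == 0:
        return np.empty((0, n))
    if D.shape[1] != n:
        raise ValueError(f"control matrix has {D.shape[1]} samples, "
                         f"expected {n}")
    return D


def _residualize(Y: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y after regression on D rows + intercept."""
    n = Y.shape[1]
    A = np.column_stack([np.ones(n), D.T])
    coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    return Y - (A @ coef).T


def _clip_rho(r: float) -> float:
    if abs(r) > 1.0:
        if abs(r) > 1.0 + _CLIP_TOL:
            raise FloatingPointError(f"correlation {r} outside [-1, 1]")
        r = float(np.clip(r, -1.0, 1.0))
    return r


def pcor_residual(x: Sequence[float], y: Sequence[float],
                  D=None) -> float:
    """Partial correlation of x and y given control rows D (k x n).

    D may be None or empty, in which case this is plain Pearson
    correlation.  Requires n > k + 2 and nonzero residual variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    D = _as_control_matrix(D, n)
    k = D.shape[0]
    if n <= k + 2:
        raise InsufficientDfError(f"n={n} <= k+2={k + 2}")
    R = _residualize(np.vstack([x, y]), D)
    rx, ry = R[0], R[1]
    scale = max(float(np.var(x)), float(np.var(y)), 1.0)
    if np.var(rx) <= _VAR_TOL * scale or np.var(ry) <= _VAR_TOL * scale:
        raise UndefinedCorrelationError(
            "residual variance is zero; x or y is fully explained by the "
            "control set")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean())
              / np.sqrt(np.dot(rx - rx.mean(), rx - rx.mean())
                        * np.dot(ry - ry.mean(), ry - ry.mean())))
    return _clip_rho(r)


def pcor_first_order(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from three plain correlations."""
    for name, v in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    if abs(r_xz) == 1.0 or abs(r_yz) == 1.0:
        raise ZeroDivisionError("|r_xz| = 1 or |r_yz| = 1: denominator is 0")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    return _clip_rho(float(r))


def pcor_test(rho: float, n: int, k: int) -> tuple[float, int, float]:
    """t statistic, degrees of freedom and two-sided p for a partial
    correlation computed from n samples with k control variables."""
    df = n - k - 2
    if df < 1:
        raise InsufficientDfError(f"df = n-k-2 = {df} < 1")
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| = {abs(rho)} >= 1: t statistic is infinite")
    t = rho * np.sqrt(df) / np.sqrt(1.0 - rho ** 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# matrix-level operations
# ---------------------------------------------------------------------------

def sd_filter(em: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Drop flat genes: sample SD (ddof=1) <= threshold, inclusive."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sds = em.data.std(axis=1, ddof=1)
    keep = sds > threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("sd_filter: removed %d flat gene(s) (SD <= %g)",
                    dropped, threshold)
    if not keep.any():
        logger.warning("sd_filter removed every gene")
    return ExpressionMatrix(em.data.loc[keep], em.groups) if keep.any() \
        else _empty_like(em)


def _empty_like(em: ExpressionMatrix) -> ExpressionMatrix:
    # bypass the no-empty-matrix invariant deliberately: an all-filtered
    # matrix is a legal (logged) outcome of sd_filter
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.data = em.data.iloc[0:0]
    out.groups = em.groups
    return out


def _standardized_residuals(values: np.ndarray, D: np.ndarray,
                            names: Sequence[str]) -> np.ndarray:
    R = _residualize(values, D)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R * R).sum(axis=1))
    scale = np.maximum(values.var(axis=1), 1.0)
    bad = norms * norms <= _VAR_TOL * scale * values.shape[1]
    if bad.any():
        offenders = [names[i] for i in np.flatnonzero(bad)]
        raise UndefinedCorrelationError(
            f"zero residual variance for: {', '.join(offenders)}")
    return R / norms[:, None]


def pcor_screen(em: ExpressionMatrix,
                regulators: Sequence[str],
                controls: Sequence[str],
                adjust: str | None = None) -> list[PcorResult]:
    """Partial correlation of every candidate gene with every regulator,
    controlling for the full control-gene matrix.

    Candidates are all genes not in the regulator or control sets,
    in matrix order.  ``adjust='bh'`` fills p_adj by Benjamini-Hochberg
    over all pairs; by default p_adj is left unset (the screen's
    significance rule is the unadjusted p < alpha).
    """
    missing = [g for g in list(regulators) + list(controls)
               if g not in em.data.index]
    if missing:
        raise KeyError("regulator/control genes absent from matrix: "
                       + ", ".join(sorted(set(missing))))
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    reg_set, ctl_set = set(regulators), set(controls)
    candidates = [g for g in em.gene_ids if g not in reg_set and g not in ctl_set]
    if not candidates or not regulators:
        return []
    n = em.n_samples
    k = len(controls)
    if n <= k + 2:
        raise InsufficientDfError(f"n={n} <= k+2={k + 2}")
    D = em.data.loc[list(controls)].to_numpy() if k else np.empty((0, n))
    cand_vals = em.data.loc[candidates].to_numpy()
    reg_vals = em.data.loc[list(regulators)].to_numpy()
    Rc = _standardized_residuals(cand_vals, D, candidates)
    Rm = _standardized_residuals(reg_vals, D, list(regulators))
    corr = np.clip(Rc @ Rm.T, -1.0, 1.0)

    df = n - k - 2
    with np.errstate(divide="ignore"):
        tmat = corr * np.sqrt(df) / np.sqrt(1.0 - corr ** 2)
    pmat = 2.0 * stats.t.sf(np.abs(tmat), df)
    pmat = np.minimum(pmat, 1.0)

    results = [PcorResult(gene=g, regulator=m, rho=float(corr[i, j]),
                          t_stat=float(tmat[i, j]), n=n, k=k, df=df,
                          p=float(pmat[i, j]))
               for i, g in enumerate(candidates)
               for j, m in enumerate(regulators)]
    if adjust == "bh":
        padj = bh_adjust(np.array([r.p for r in results]))
        results = [replace(r, p_adj=float(a)) for r, a in zip(results, padj)]
    return results


def pearson_matrix(em: ExpressionMatrix) -> "pd.DataFrame":
    """Plain Pearson correlation among the matrix's genes (used for the
    regulator-regulator analysis).  Symmetric with unit diagonal."""
    import pandas as pd

    if em.n_genes < 2:
        raise ValueError("need >= 2 genes for a correlation matrix")
    values = em.values()
    sds = values.std(axis=1, ddof=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        names = [em.gene_ids[i] for i in flat]
        raise ValueError(f"zero-variance gene(s): {', '.join(names)}")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=em.gene_ids, columns=em.gene_ids)
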