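"""Measured-genotype (MG) mixed-model association tests for pedigrees.

The model for the trait vector within the pedigree sample is

    y = X beta + g + e,   g ~ N(0, 2 Phi sigma_g^2),   e ~ N(0, sigma_e^2 I)

where Phi is the kinship matrix (block-diagonal by family), sigma_g^2 the
polygenic variance and sigma_e^2 the residual variance. Collapsed gene
predictors (CA, CP, WS, bivariate CMC1) enter as fixed effects and are
tested by a likelihood-ratio chi-square with 1 or 2 df, re-estimating the
variance components under both the null and the full model. Unlike the
unrelated-sample WS test, significance in families uses the tabulated 1-df
chi-square p-value (no permutation); the variable-threshold test is
structurally excluded because maximizing over thresholds would invalidate
the tabulated reference.

Fitting parameterizes the covariance as ``sigma_t^2 [(1-h) I + h 2Phi]``
with total variance ``sigma_t^2`` and heritability fraction
``h = sigma_g^2 / sigma_t^2 in [0, 1)``. After one eigendecomposition
``2 Phi = U L U^T`` (phenotype- and genotype-free, cached across genes and
replicates), the fixed effects and sigma_t^2 are closed-form given h, and h
is maximized by bounded one-dimensional search, checking the h = 0 boundary
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .assoc_unrelated import AssocResult, _as_values, _variant_column
from .core_types import GenotypeMatrix, GeneSet, KinshipMatrix, maf_array

__all__ = [
    "MixedModelFit",
    "KinshipEigen",
    "kinship_eigen",
    "fit_mg",
    "fit_mg_null",
    "test_mg",
    "test_sm_family",
]

_H_TOL = 1e-8
_H_MAX = 1.0 - 1e-9


@dataclass
class MixedModelFit:
    """ML fit of the measured-genotype mixed model."""

    params: np.ndarray  # fixed effects: intercept first
    sigma_g2: float
    sigma_e2: float
    heritability: float
    loglik: float


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of 2*Phi for one pedigree sample."""

    ids: list
    eigvec: np.ndarray  # U, columns are eigenvectors
    eigval: np.ndarray  # L, eigenvalues of 2*Phi (all >= 0 up to rounding)


def kinship_eigen(kinship: KinshipMatrix) -> KinshipEigen:
    """Eigendecomposition of 2*Phi; do this once per pedigree sample."""
    lam, U = np.linalg.eigh(2.0 * kinship.values)
    if lam.min() < -1e-8:
        raise ValueError(
            f"2*Phi is not positive semi-definite (min eigenvalue {lam.min():.3g})"
        )
    return KinshipEigen(list(kinship.ids), U, np.maximum(lam, 0.0))


def _profile_nll(h: float, yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray) -> float:
    n = len(yr)
    d = (1.0 - h) + h * lam
    w = 1.0 / d
    Xw = Xr * w[:, None]
    try:
        beta = np.linalg.solve(Xw.T @ Xr, Xw.T @ yr)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Xw.T @ Xr, Xw.T @ yr, rcond=None)
    r = yr - Xr @ beta
    rss = float((r * r) @ w)
    sigma2 = max(rss / n, np.finfo(float).tiny)
    loglik = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + np.log(d).sum())
    return -loglik


def _fit_given_h(h: float, yr, Xr, lam) -> MixedModelFit:
    n = len(yr)
    d = (1.0 - h) + h * lam
    w = 1.0 / d
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xw.T @ Xr, Xw.T @ yr)
    r = yr - Xr @ beta
    sigma_t2 = max(float((r * r) @ w) / n, np.finfo(float).tiny)
    loglik = -0.5 * (n * (np.log(2 * np.pi * sigma_t2) + 1.0) + np.log(d).sum())
    return MixedModelFit(
        params=beta,
        sigma_g2=h * sigma_t2,
        sigma_e2=(1.0 - h) * sigma_t2,
        heritability=h,
        loglik=loglik,
    )


def fit_mg(y, eig: KinshipEigen, design: np.ndarray | None = None) -> MixedModelFit:
    """ML fit of y = mu + [design] + g + e with cov(g) = 2 Phi sigma_g^2.

    ``design`` holds zero or more fixed-effect columns beyond the
    intercept. Variance components are profiled: bounded search over the
    heritability fraction h with the h = 0 boundary checked explicitly, so
    an unstructured sample pins sigma_g^2 to zero.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if design is None or np.size(design) == 0:
        X = np.ones((n, 1))
    else:
        design = np.atleast_2d(np.asarray(design, dtype=float))
        if design.shape[0] != n:
            design = design.T
        X = np.column_stack([np.ones(n), design])
    yr = eig.eigvec.T @ y
    Xr = eig.eigvec.T @ X
    lam = eig.eigval

    res = optimize.minimize_scalar(
        _profile_nll,
        bounds=(0.0, _H_MAX),
        args=(yr, Xr, lam),
        method="bounded",
        options={"xatol": _H_TOL},
    )
    h_best, nll_best = float(res.x), float(res.fun)
    nll_zero = _profile_nll(0.0, yr, Xr, lam)
    if nll_zero <= nll_best:
        h_best = 0.0
    fit = _fit_given_h(h_best, yr, Xr, lam)
    if not np.isfinite(fit.loglik):
        raise RuntimeError("mixed-model likelihood did not evaluate finitely")
    return fit


def fit_mg_null(y, eig: KinshipEigen) -> MixedModelFit:
    """Null (intercept-only) measured-genotype fit."""
    return fit_mg(_as_values(y), eig)


def test_mg(
    y,
    eig: KinshipEigen,
    design: np.ndarray,
    df: int,
    gene: str = "",
    method: str = "MG",
) -> AssocResult:
    """LRT of collapsed predictor column(s) in the MG mixed model.

    Both the null and the full model re-estimate (sigma_g^2, sigma_e^2);
    the statistic 2*(l_full - l_null) is referred to chi-square with the
    stated df.
    """
    yv = _as_values(y)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != len(yv):
        design = design.T
    keep = design.std(axis=0) > 0
    if not keep.any():
        return AssocResult.not_applicable(gene, method, "constant predictor")
    design = design[:, keep]
    df = min(df, design.shape[1])
    full = fit_mg(yv, eig, design)
    null = fit_mg(yv, eig)
    statistic = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return AssocResult(gene, method, float(statistic), int(df), p)


def test_sm_family(
    y,
    eig: KinshipEigen,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    alpha: float = 0.05,
) -> AssocResult:
    """Single-marker MG tests with a gene-level Bonferroni decision.

    Variants monomorphic within the family sample are excluded, reducing
    J_G accordingly; the reported gene p is ``min(1, J_G * min_p)``.
    """
    sub = matrix.subset(variants=geneset[gene])
    yv = _as_values(y, matrix)
    m = maf_array(sub)
    poly = np.flatnonzero(np.isfinite(m) & (m > 0))
    if poly.size == 0:
        return AssocResult.not_applicable(gene, "SM", "no polymorphic variant in families")
    stats_j, p_j = [], []
    for j in poly:
        res = test_mg(yv, eig, _variant_column(sub.counts[:, j])[:, None], df=1,
                      gene=gene, method="SM")
        if res.status == "ok":
            stats_j.append(res.statistic)
            p_j.append(res.p)
    if not stats_j:
        return AssocResult.not_applicable(gene, "SM", "no testable variant")
    j_g = len(stats_j)
    gene_p = min(1.0, j_g * min(p_j))
    return AssocResult(gene, "SM", float(max(stats_j)), 1, gene_p,
                       note=f"J_G={j_g}, Bonferroni at alpha={alpha}")
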