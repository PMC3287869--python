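"""Gene-level association tests for unrelated samples.

All tests regress a quantitative trait on gene-derived predictors:

* :func:`test_cast` — 1-df likelihood-ratio test (LRT) on a CA or CP
  collapsed variable at a fixed frequency threshold (labels CA1/CA5/CP1/CP5
  for thresholds 1% and 5%).
* :func:`test_cmc` — combined multivariate and collapsing LRTs:
  CMC1 (2 df: rare-collapsed + low-frequency-collapsed, variants above 5%
  dropped), CMC2 ((k+1) df: rare-collapsed + each 1-5% variant
  individually), CMC3 ((k+1) df: rare-collapsed + every maf >= 1% variant
  individually).
* :func:`test_sm` — per-variant 1-df LRTs with a gene-level Bonferroni
  decision (min p <= alpha / J_G).
* :func:`test_vt` — variable threshold: CP collapse at every observed MAF
  cutoff, take the largest absolute regression z-score, assess by
  permutation.
* :func:`test_ws` — weighted-sum burden z-score over all gene variants,
  assessed by permutation.

LRTs use Gaussian maximum likelihood (not REML): with residual sums of
squares ``RSS0`` (null, intercept only) and ``RSS1`` (full model), the
statistic is ``N log(RSS0 / RSS1)`` and is referred to a chi-square with the
model's degrees of freedom. Permutation p-values use the add-one estimator
``(1 + #{stat_b >= observed}) / (B + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .collapsing import (
    NoEligibleVariants,
    collapse_ca,
    collapse_cp,
    collapse_ws,
    vt_thresholds,
    ws_weights,
)
from .core_types import GenotypeMatrix, GeneSet, Phenotype, maf_array

__all__ = [
    "AssocResult",
    "RegressionFit",
    "lrt_linear",
    "test_cast",
    "test_cmc",
    "test_sm",
    "test_vt",
    "test_ws",
    "permutation_p",
    "zscore_simple",
]

# Relative floor on the ML residual variance; keeps the LRT finite when the
# full model interpolates the phenotype exactly.
_SIGMA2_REL_FLOOR = 1e-12


@dataclass
class AssocResult:
    """One gene-level test result."""

    gene: str
    method: str
    statistic: float | None
    df: int | None
    p: float | None
    n_permutations: int | None = None
    status: str = "ok"  # ok | n/a
    note: str = ""

    @classmethod
    def not_applicable(cls, gene: str, method: str, note: str = "") -> "AssocResult":
        return cls(gene, method, None, None, None, status="n/a", note=note)


@dataclass
class RegressionFit:
    """Gaussian ML fit summary of y = X beta + e."""

    params: np.ndarray
    sigma2: float
    loglik: float


def _as_values(y, matrix: GenotypeMatrix | None = None) -> np.ndarray:
    if isinstance(y, Phenotype):
        if matrix is not None:
            return y.aligned_to(matrix)
        return np.asarray(y.values, dtype=float)
    return np.asarray(y, dtype=float)


def _ml_loglik(n: int, rss: float, var_y: float) -> float:
    sigma2 = max(rss / n, _SIGMA2_REL_FLOOR * max(var_y, np.finfo(float).tiny))
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _ols_fit(y: np.ndarray, design: np.ndarray) -> RegressionFit:
    """ML Gaussian fit with intercept; pinv handles rank deficiency."""
    X = np.column_stack([np.ones(len(y)), design]) if design.size else np.ones((len(y), 1))
    res = sm.OLS(y, X).fit()
    var_y = float(np.var(y))
    return RegressionFit(np.asarray(res.params), max(res.ssr / len(y), 0.0),
                         _ml_loglik(len(y), res.ssr, var_y))


def lrt_linear(
    y,
    design: np.ndarray,
    df: int | None = None,
    gene: str = "",
    method: str = "LRT",
) -> AssocResult:
    """Likelihood-ratio test of y on predictor column(s) plus intercept.

    The null model is intercept-only. Aliased (linearly dependent) predictor
    columns reduce the effective degrees of freedom, with a warning.
    Constant predictors yield an "n/a" result.
    """
    y = _as_values(y)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != len(y):
        design = design.T
    keep = design.std(axis=0) > 0
    if not keep.any():
        return AssocResult.not_applicable(gene, method, "constant predictor")
    design = design[:, keep]
    n, k = design.shape
    if n <= k + 1:
        raise ValueError("need more samples than predictors plus intercept")
    X = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(X)
    df_eff = rank - 1
    if df is None:
        df = k
    if df_eff < df:
        warnings.warn(
            f"{gene or 'design'}: {df - df_eff} aliased predictor column(s) "
            f"dropped; df reduced to {df_eff}",
            stacklevel=2,
        )
        df = df_eff
    if df < 1:
        return AssocResult.not_applicable(gene, method, "no identifiable predictor")
    full = _ols_fit(y, design)
    null = _ols_fit(y, np.empty((n, 0)))
    statistic = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return AssocResult(gene, method, float(statistic), int(df), p)


# ---------------------------------------------------------------------------
# Collapsing tests
# ---------------------------------------------------------------------------

def _gene_sub(matrix: GenotypeMatrix, geneset: GeneSet, gene: str) -> GenotypeMatrix:
    return matrix.subset(variants=geneset[gene])


def _method_label(strategy: str, t_maf: float) -> str:
    pct = 100 * t_maf
    return f"{strategy}{pct:g}"


def test_cast(
    y,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    strategy: str = "CP",
    t_maf: float = 0.05,
    mafs: np.ndarray | None = None,
) -> AssocResult:
    """CA/CP collapsing followed by a 1-df LRT."""
    if strategy not in ("CA", "CP"):
        raise ValueError("strategy must be 'CA' or 'CP'")
    label = _method_label(strategy, t_maf)
    sub = _gene_sub(matrix, geneset, gene)
    yv = _as_values(y, matrix)
    collapse = collapse_ca if strategy == "CA" else collapse_cp
    try:
        collapsed = collapse(sub, t_maf, mafs=mafs)
    except NoEligibleVariants as exc:
        return AssocResult.not_applicable(gene, label, str(exc))
    return lrt_linear(yv, collapsed.values[:, None], df=1, gene=gene, method=label)


def _variant_column(col: np.ndarray) -> np.ndarray:
    """Regression coding of a raw count column; missing -> column mean."""
    if np.isnan(col).any():
        fill = np.nanmean(col) if not np.isnan(col).all() else 0.0
        col = np.where(np.isnan(col), fill, col)
    return col


def test_cmc(
    y,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    variant: str = "CMC1",
    mafs: np.ndarray | None = None,
) -> AssocResult:
    """Combined multivariate and collapsing LRT (CMC1 / CMC2 / CMC3).

    The rare group (maf < 1%) is CA-collapsed in every flavour. CMC1 also
    CA-collapses the 1-5% group (2 df); CMC2 includes each 1-5% variant
    individually; CMC3 includes every maf >= 1% variant individually with no
    upper frequency cap. Empty groups are dropped with matching df
    reduction; a gene where every group is empty returns "n/a".
    """
    if variant not in ("CMC1", "CMC2", "CMC3"):
        raise ValueError("variant must be CMC1, CMC2 or CMC3")
    sub = _gene_sub(matrix, geneset, gene)
    yv = _as_values(y, matrix)
    m = maf_array(sub) if mafs is None else np.asarray(mafs, dtype=float)
    rare = np.isfinite(m) & (m > 0) & (m < 0.01)
    if variant == "CMC3":
        individual = np.isfinite(m) & (m >= 0.01)
    else:
        individual = np.isfinite(m) & (m >= 0.01) & (m <= 0.05)

    columns: list[np.ndarray] = []
    if rare.any():
        rare_carrier = np.nan_to_num(sub.counts[:, rare], nan=0.0) >= 1
        columns.append(rare_carrier.any(axis=1).astype(float))
    if variant == "CMC1":
        if individual.any():
            mid_carrier = np.nan_to_num(sub.counts[:, individual], nan=0.0) >= 1
            columns.append(mid_carrier.any(axis=1).astype(float))
    else:
        for j in np.flatnonzero(individual):
            columns.append(_variant_column(sub.counts[:, j]))
    if not columns:
        return AssocResult.not_applicable(gene, variant, "all predictor groups empty")
    design = np.column_stack(columns)
    return lrt_linear(yv, design, df=design.shape[1], gene=gene, method=variant)


def test_sm(
    y,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    alpha: float = 0.05,
    mafs: np.ndarray | None = None,
) -> AssocResult:
    """Single-marker test with a gene-level Bonferroni decision.

    Every polymorphic variant gets its own 1-df LRT; the gene statistic is
    the largest LRT and the reported gene p-value is ``min(1, J_G * min_p)``
    so that ``gene p <= alpha`` reproduces the ``min_p <= alpha / J_G``
    rule.
    """
    sub = _gene_sub(matrix, geneset, gene)
    yv = _as_values(y, matrix)
    m = maf_array(sub) if mafs is None else np.asarray(mafs, dtype=float)
    poly = np.flatnonzero(np.isfinite(m) & (m > 0))
    if poly.size == 0:
        return AssocResult.not_applicable(gene, "SM", "no polymorphic variant")
    stats_j, p_j = [], []
    for j in poly:
        res = lrt_linear(yv, _variant_column(sub.counts[:, j])[:, None], df=1,
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


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def zscore_simple(y: np.ndarray, c: np.ndarray) -> float:
    """OLS slope z-score (slope / standard error) of y on c with intercept."""
    n = len(y)
    xc = c - c.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return 0.0
    beta = float(xc @ yc) / sxx
    rss = float(yc @ yc) - beta * beta * sxx
    if rss <= 0:
        return np.inf if beta >= 0 else -np.inf
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta / se


def permutation_p(
    observed: float,
    stat_fn: Callable[[np.ndarray], float],
    y: np.ndarray,
    n_permutations: int,
    seed,
) -> float:
    """Add-one permutation p-value: (1 + #{stat_b >= observed}) / (B + 1).

    Permutations shuffle phenotype values against the fixed genotypes.
    ``seed`` may be an int, a sequence of ints, or a Generator.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    count = 0
    for _ in range(n_permutations):
        if stat_fn(rng.permutation(y)) >= observed:
            count += 1
    return (1 + count) / (n_permutations + 1)


def test_ws(
    y,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    n_permutations: int = 1000,
    seed=0,
) -> AssocResult:
    """Weighted-sum burden test with permutation significance.

    The gene score is the absolute regression z-score of the trait on the
    weighted-sum collapsed variable over *all* gene variants (threshold
    0.5). The Madsen-Browning weights are phenotype-free, so they are
    computed once and reused across permutations.
    """
    sub = _gene_sub(matrix, geneset, gene)
    yv = _as_values(y, matrix)
    weights = ws_weights(sub)
    collapsed = collapse_ws(sub, weights)
    c = collapsed.values
    if c.std() == 0:
        return AssocResult.not_applicable(gene, "WS", "constant burden score")
    observed = abs(zscore_simple(yv, c))
    p = permutation_p(observed, lambda yp: abs(zscore_simple(yp, c)),
                      yv, n_permutations, seed)
    return AssocResult(gene, "WS", float(observed), None, p,
                       n_permutations=n_permutations)


def test_vt(
    y,
    matrix: GenotypeMatrix,
    geneset: GeneSet,
    gene: str,
    n_permutations: int = 1000,
    seed=0,
    mafs: np.ndarray | None = None,
) -> AssocResult:
    """Variable-threshold test: max |z| over all observed MAF cutoffs.

    For each distinct MAF value t in the gene, the CP collapsed variable at
    threshold t is regressed on the trait; the statistic is the largest
    absolute z-score and its significance is assessed by permutation,
    recomputing the maximum for every shuffled phenotype.
    """
    sub = _gene_sub(matrix, geneset, gene)
    yv = _as_values(y, matrix)
    m = maf_array(sub) if mafs is None else np.asarray(mafs, dtype=float)
    try:
        thresholds = vt_thresholds(sub, mafs=m)
    except NoEligibleVariants as exc:
        return AssocResult.not_applicable(gene, "VT", str(exc))
    cols = [collapse_cp(sub, float(t), mafs=m).values for t in thresholds]
    C = np.column_stack(cols)
    usable = C.std(axis=0) > 0
    if not usable.any():
        return AssocResult.not_applicable(gene, "VT", "constant at every threshold")
    C = C[:, usable]

    # Precompute centered predictors so each permutation costs O(N * T).
    Cc = C - C.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Cc, Cc)
    n = len(yv)

    def zmax(yp: np.ndarray) -> float:
        yc = yp - yp.mean()
        syy = float(yc @ yc)
        sxy = yc @ Cc
        beta = sxy / sxx
        rss = syy - beta * beta * sxx
        rss = np.maximum(rss, np.finfo(float).tiny)
        z = beta / np.sqrt(rss / (n - 2) / sxx)
        return float(np.abs(z).max())

    observed = zmax(yv)
    p = permutation_p(observed, zmax, yv, n_permutations, seed)
    return AssocResult(gene, "VT", float(observed), None, p,
                       n_permutations=n_permutations)
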