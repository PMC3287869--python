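"""Population-stratification adjustment by genotype principal components.

Subpopulations that differ in both allele frequencies and trait means
inflate single-marker association tests. The adjustment here follows the
Eigenstrat recipe: compute principal components of the *common*-variant
genotype matrix (default: variants with MAF >= 5%), each variant column
centered at twice its allele frequency and scaled by ``sqrt(2 p (1 - p))``,
then replace the phenotype by its residual from an OLS regression on the
top components. All gene tests then run on the residualized phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_types import GenotypeMatrix, maf_array

__all__ = ["PcAdjustment", "compute_pcs", "residualize"]


@dataclass
class PcAdjustment:
    """Principal-component scores and loadings from common variants."""

    n_components: int
    scores: np.ndarray  # (N, k), zero mean per component
    loadings: np.ndarray  # (J_used, k)
    variants: list  # variants that passed the frequency filter


def compute_pcs(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    k: int = 5,
) -> PcAdjustment:
    """Top-k genotype principal components from variants with maf >= maf_min.

    Missing genotypes are mean-imputed per variant before standardization.
    Each component's sign is fixed so that its largest-magnitude loading is
    positive, making the output bit-reproducible.
    """
    if k == 0:
        return PcAdjustment(0, np.zeros((matrix.n_samples, 0)),
                            np.zeros((0, 0)), [])
    mafs = maf_array(matrix)
    keep = np.flatnonzero(np.isfinite(mafs) & (mafs >= maf_min))
    if keep.size < k:
        raise ValueError(
            f"only {keep.size} variants with maf >= {maf_min}; need at least {k}"
        )
    G = matrix.counts[:, keep]
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    p = G.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = (G - 2.0 * p) / denom
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:k].T  # (J, k)
    # sign convention: largest-magnitude loading positive per component
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    scores = U[:, :k] * S[:k] * signs
    loadings = loadings * signs
    scores = scores - scores.mean(axis=0)
    variants = [matrix.variants[j] for j in keep]
    return PcAdjustment(k, scores, loadings, variants)


def residualize(y: np.ndarray, adjustment: PcAdjustment | np.ndarray) -> np.ndarray:
    """Residual of y regressed (OLS, with intercept) on the PC scores.

    With zero components this is the identity; the returned residuals are
    orthogonal to every retained score column.
    """
    scores = adjustment.scores if isinstance(adjustment, PcAdjustment) else np.asarray(adjustment)
    y = np.asarray(y, dtype=float)
    if scores.size == 0:
        return y.copy()
    X = np.column_stack([np.ones(len(y)), scores])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("aliased PC score columns in residualization", stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
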