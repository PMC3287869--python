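"""Per-gene collapsing operators.

Each operator maps a gene's genotype submatrix to one per-sample scalar:

* **CA** (collapsing absence/presence) — indicator that the individual
  carries at least one minor allele at any rare variant in the gene.
* **CP** (collapsing proportion) — fraction of the gene's rare variants at
  which the individual carries at least one minor allele.
* **WS** (weighted sum) — sum of minor-allele counts over *all* variants in
  the gene, each divided by a Madsen-Browning-style weight so that rarer
  variants contribute more.

"Rare" means minor allele frequency at most ``t_maf`` (inclusive) and
strictly positive: monomorphic variants never enter a collapsing set.
Missing genotypes count as non-carrier in CA/CP and contribute zero to WS
by default ("zero" policy); WS additionally supports per-variant mean
imputation ("mean").

:func:`vt_thresholds` enumerates the frequency cutoffs used by the
variable-threshold test: every distinct MAF observed in the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import GenotypeMatrix, maf_array

__all__ = [
    "CollapsedVariable",
    "WsWeights",
    "NoEligibleVariants",
    "eligible_mask",
    "collapse_ca",
    "collapse_cp",
    "ws_weights",
    "collapse_ws",
    "vt_thresholds",
]


class NoEligibleVariants(ValueError):
    """No polymorphic variant passes the frequency threshold.

    Association drivers translate this into an "n/a" result rather than a
    failure, mirroring how genes with no testable variants are reported.
    """


@dataclass
class CollapsedVariable:
    """Per-sample collapsed scalar with provenance."""

    values: np.ndarray  # length N
    method: str  # CA | CP | WS
    t_maf: float
    variants: list  # variant ids included

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WsWeights:
    """Per-variant weights w_j and the frequency estimates q_j behind them."""

    variants: list
    weights: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("weights must be strictly positive")


def eligible_mask(mafs: np.ndarray, t_maf: float) -> np.ndarray:
    """Variants with 0 < maf <= t_maf (NaN-MAF variants excluded)."""
    mafs = np.asarray(mafs, dtype=float)
    with np.errstate(invalid="ignore"):
        return (mafs > 0) & (mafs <= t_maf)


def _carrier_matrix(counts: np.ndarray) -> np.ndarray:
    """0/1 carrier indicators; missing genotypes are non-carriers."""
    with np.errstate(invalid="ignore"):
        return np.where(np.nan_to_num(counts, nan=0.0) >= 1, 1.0, 0.0)


def _eligible_submatrix(
    sub: GenotypeMatrix, t_maf: float, mafs: np.ndarray | None
) -> tuple[np.ndarray, list]:
    if not 0 < t_maf <= 0.5:
        raise ValueError(f"t_maf must lie in (0, 0.5], got {t_maf}")
    if mafs is None:
        mafs = maf_array(sub)
    mask = eligible_mask(np.asarray(mafs), t_maf)
    if not mask.any():
        raise NoEligibleVariants(
            f"no polymorphic variant with maf <= {t_maf} in the gene"
        )
    variants = [v for v, m in zip(sub.variants, mask) if m]
    return sub.counts[:, mask], variants


def collapse_ca(
    sub: GenotypeMatrix,
    t_maf: float,
    mafs: np.ndarray | None = None,
) -> CollapsedVariable:
    """CA indicator: 1 if the sample carries any eligible minor allele."""
    counts, variants = _eligible_submatrix(sub, t_maf, mafs)
    values = _carrier_matrix(counts).max(axis=1)
    return CollapsedVariable(values, "CA", t_maf, variants)


def collapse_cp(
    sub: GenotypeMatrix,
    t_maf: float,
    mafs: np.ndarray | None = None,
) -> CollapsedVariable:
    """CP proportion: fraction of eligible variants carried."""
    counts, variants = _eligible_submatrix(sub, t_maf, mafs)
    values = _carrier_matrix(counts).mean(axis=1)
    return CollapsedVariable(values, "CP", t_maf, variants)


def ws_weights(sub: GenotypeMatrix, pheno=None) -> WsWeights:
    """Madsen-Browning weights for every variant in the gene.

    ``w_j = sqrt(n_j q_j (1 - q_j))`` with the add-one smoothed frequency
    ``q_j = (m_j + 1) / (2 n_j + 2)``, where ``n_j`` is the number of
    non-missing genotypes and ``m_j`` the minor-allele count at variant j.
    The frequency is estimated from the whole sample, so the weights do not
    depend on the phenotype (``pheno`` is accepted for signature symmetry
    and ignored).
    """
    counts = sub.counts
    n = np.sum(~np.isnan(counts), axis=0)
    m = np.nansum(counts, axis=0)
    q = (m + 1.0) / (2.0 * n + 2.0)
    w = np.sqrt(n * q * (1.0 - q))
    return WsWeights(list(sub.variants), w, q)


def collapse_ws(
    sub: GenotypeMatrix,
    weights: WsWeights,
    missing: str = "zero",
) -> CollapsedVariable:
    """Weighted-sum burden: C_i = sum_j x_ij / w_j over all gene variants."""
    if weights.variants != sub.variants:
        raise ValueError("weights do not match the submatrix variants")
    counts = sub.counts
    if missing == "zero":
        x = np.nan_to_num(counts, nan=0.0)
    elif missing == "mean":
        col_mean = np.nanmean(np.where(np.isnan(counts).all(axis=0), 0.0, counts), axis=0)
        x = np.where(np.isnan(counts), col_mean, counts)
    else:
        raise ValueError("missing policy must be 'zero' or 'mean'")
    values = x @ (1.0 / weights.weights)
    return CollapsedVariable(values, "WS", 0.5, list(sub.variants))


def vt_thresholds(
    sub: GenotypeMatrix,
    mafs: np.ndarray | None = None,
) -> np.ndarray:
    """Sorted distinct MAFs of the gene's polymorphic variants.

    Each value t defines the eligible set {j : maf_j <= t}; successive
    thresholds therefore yield strictly growing sets.
    """
    if mafs is None:
        mafs = maf_array(sub)
    mafs = np.asarray(mafs, dtype=float)
    poly = mafs[np.isfinite(mafs) & (mafs > 0)]
    if poly.size == 0:
        raise NoEligibleVariants("no polymorphic variant in the gene")
    return np.unique(poly)
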