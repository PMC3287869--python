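"""Shared domain types for gene-level rare-variant association testing.

The analysis unit throughout the package is a gene ``G`` containing ``J_G``
variants. Genotypes are coded as minor-allele counts in ``{0, 1, 2}``
(``NaN`` for missing), so that every burden/collapsing operator downstream
can reason about "carrying at least one minor allele" without caring about
strand or REF/ALT conventions. :func:`minor_allele_orient` establishes that
convention; :func:`compute_maf` and :func:`maf_array` report allele
frequencies under it.

Pedigree support is limited to what the measured-genotype mixed model needs:
a validated family structure and the kinship matrix derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "VariantStats",
    "GeneSet",
    "Phenotype",
    "Pedigree",
    "KinshipMatrix",
    "UndefinedMAFError",
    "PedigreeError",
    "compute_maf",
    "maf_array",
    "minor_allele_orient",
    "kinship_from_pedigree",
]


class UndefinedMAFError(ValueError):
    """All genotypes missing at a variant: its MAF is undefined."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, ...)."""


@dataclass(frozen=True)
class VariantStats:
    """Per-variant summary: minor allele frequency and call count."""

    variant: str
    maf: float
    n_called: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if self.n_called < 0:
            raise ValueError("n_called must be non-negative")


class GenotypeMatrix:
    """Sample x variant matrix of minor-allele counts.

    Parameters
    ----------
    samples
        Unique sample identifiers (rows).
    variants
        Unique variant identifiers (columns).
    counts
        ``(N, J)`` array with entries in ``{0, 1, 2}`` or ``NaN`` (missing).
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.variants = list(variants)
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant identifiers must be unique")
        observed = counts[~np.isnan(counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")
        self.counts = counts
        self._variant_index = {v: j for j, v in enumerate(self.variants)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant: str) -> int:
        try:
            return self._variant_index[variant]
        except KeyError:
            raise KeyError(f"unknown variant {variant!r}") from None

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=int)

    def column(self, variant: str) -> np.ndarray:
        return self.counts[:, self.variant_index(variant)]

    def subset(
        self,
        variants: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Submatrix restricted to the given variants and/or samples."""
        rows = (
            slice(None)
            if samples is None
            else self.sample_indices(samples)
        )
        if variants is None:
            cols = slice(None)
            new_variants = self.variants
        else:
            cols = np.array([self.variant_index(v) for v in variants], dtype=int)
            new_variants = list(variants)
        new_samples = self.samples if samples is None else list(samples)
        sub = self.counts[rows]
        sub = sub[:, cols] if not isinstance(cols, slice) else sub
        return GenotypeMatrix(new_samples, new_variants, sub.copy())


class GeneSet(Mapping[str, list]):
    """Mapping gene name -> ordered list of variant identifiers."""

    def __init__(self, genes: Mapping[str, Sequence[str]], matrix: GenotypeMatrix | None = None):
        cleaned: dict[str, list[str]] = {}
        for gene, variants in genes.items():
            seen: dict[str, None] = {}
            for v in variants:
                seen.setdefault(v, None)
            ordered = list(seen)
            if not ordered:
                raise ValueError(f"gene {gene!r} has no variants")
            if matrix is not None:
                missing = [v for v in ordered if v not in matrix._variant_index]
                if missing:
                    raise ValueError(
                        f"gene {gene!r} references unknown variants: {missing[:5]}"
                    )
            cleaned[gene] = ordered
        self._genes = cleaned

    def __getitem__(self, gene: str) -> list:
        return list(self._genes[gene])

    def __iter__(self):
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)


@dataclass
class Phenotype:
    """Quantitative phenotype keyed by sample identifier."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.samples):
            raise ValueError("phenotype values must be 1-D, one per sample")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")

    @classmethod
    def from_series(cls, series: pd.Series) -> "Phenotype":
        return cls(list(series.index), series.to_numpy(dtype=float))

    def aligned_to(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Values reordered to the matrix's sample order."""
        lookup = dict(zip(self.samples, self.values))
        try:
            return np.array([lookup[s] for s in matrix.samples], dtype=float)
        except KeyError as exc:
            raise KeyError(f"phenotype missing for sample {exc.args[0]!r}") from None


@dataclass
class Pedigree:
    """FAM-style pedigree: family, individual, father, mother, sex.

    ``father``/``mother`` are ``None`` for founders. Individual identifiers
    must be globally unique; parents must belong to the same family and no
    individual may be its own ancestor.
    """

    records: pd.DataFrame  # columns: fid, iid, father, mother, sex
    _topo: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        req = ["fid", "iid", "father", "mother", "sex"]
        if list(self.records.columns[:5]) != req:
            raise PedigreeError(f"pedigree needs columns {req}")
        df = self.records
        if df["iid"].duplicated().any():
            raise PedigreeError("individual identifiers must be globally unique")
        fam_of = dict(zip(df["iid"], df["fid"]))
        for _, row in df.iterrows():
            for parent in (row["father"], row["mother"]):
                if parent is None:
                    continue
                if parent not in fam_of:
                    raise PedigreeError(
                        f"parent {parent!r} of {row['iid']!r} not in pedigree"
                    )
                if fam_of[parent] != row["fid"]:
                    raise PedigreeError(
                        f"parent {parent!r} of {row['iid']!r} is in a different family"
                    )
        self._topo = self._topological_order()

    def _topological_order(self) -> list:
        children: dict[str, list[str]] = {i: [] for i in self.records["iid"]}
        indeg = {i: 0 for i in children}
        for _, row in self.records.iterrows():
            for parent in (row["father"], row["mother"]):
                if parent is not None:
                    children[parent].append(row["iid"])
                    indeg[row["iid"]] += 1
        order, queue = [], [i for i, d in indeg.items() if d == 0]
        while queue:
            node = queue.pop()
            order.append(node)
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(indeg):
            raise PedigreeError("pedigree contains a cycle")
        return order

    @property
    def ids(self) -> list:
        return list(self.records["iid"])

    @property
    def founder_mask(self) -> np.ndarray:
        return np.array(
            [f is None and m is None for f, m in zip(self.records["father"], self.records["mother"])]
        )

    @property
    def topological_order(self) -> list:
        """Individual ids ordered so parents precede children."""
        return list(self._topo)


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients phi, block-diagonal by family."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_maf(
    matrix: GenotypeMatrix,
    variant: str,
    subset: Sequence[str] | None = None,
) -> VariantStats:
    """Minor allele frequency of one variant, optionally within a subset.

    If the counted allele's frequency exceeds 0.5 the complementary (minor)
    frequency is reported, consistent with :func:`minor_allele_orient`.
    """
    col = matrix.column(variant)
    if subset is not None:
        col = col[matrix.sample_indices(subset)]
    called = col[~np.isnan(col)]
    if called.size == 0:
        raise UndefinedMAFError(f"all genotypes missing at {variant!r}")
    freq = called.sum() / (2 * called.size)
    return VariantStats(variant, min(freq, 1.0 - freq), int(called.size))


def maf_array(
    matrix: GenotypeMatrix,
    subset: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-variant minor allele frequencies (NaN where all calls missing)."""
    counts = matrix.counts
    if subset is not None:
        counts = counts[matrix.sample_indices(subset)]
    n_called = np.sum(~np.isnan(counts), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(counts, axis=0) / (2 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    return np.minimum(freq, 1.0 - freq)


def minor_allele_orient(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, list]:
    """Re-orient counts so that the counted allele is the minor one.

    Variants whose counted-allele frequency exceeds 0.5 in the full sample
    have their counts complemented (``2 - count``). Frequency exactly 0.5
    keeps the input orientation. Returns the oriented matrix and the list of
    flipped variant identifiers.
    """
    counts = matrix.counts.copy()
    n_called = np.sum(~np.isnan(counts), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(counts, axis=0) / (2 * n_called)
    flip = (n_called > 0) & (freq > 0.5)
    counts[:, flip] = 2.0 - counts[:, flip]
    flipped = [v for v, f in zip(matrix.variants, flip) if f]
    return GenotypeMatrix(matrix.samples, matrix.variants, counts), flipped


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the standard recursive (tabular) algorithm.

    Founders are assumed unrelated and non-inbred: phi(f, f) = 1/2 and
    phi(f, g) = 0 between distinct founders. For a non-founder ``a`` with
    parents ``p`` and ``q`` processed before it,
    ``phi(a, b) = (phi(p, b) + phi(q, b)) / 2`` for previously processed
    ``b`` and ``phi(a, a) = 1/2 + phi(p, q) / 2``.
    """
    ids = ped.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    parents = {
        row["iid"]: (row["father"], row["mother"])
        for _, row in ped.records.iterrows()
    }
    done: list[str] = []
    for a in ped.topological_order:
        ia = idx[a]
        pa, ma = parents[a]
        if pa is None and ma is None:
            phi[ia, ia] = 0.5
        else:
            contrib_self = 0.0
            if pa is not None and ma is not None:
                contrib_self = phi[idx[pa], idx[ma]]
            phi[ia, ia] = 0.5 + 0.5 * contrib_self
            for b in done:
                ib = idx[b]
                val = 0.0
                if pa is not None:
                    val += 0.5 * phi[idx[pa], ib]
                if ma is not None:
                    val += 0.5 * phi[idx[ma], ib]
                phi[ia, ib] = phi[ib, ia] = val
        done.append(a)
    return KinshipMatrix(ids, phi)
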