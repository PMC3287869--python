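"""Synthetic genotype/phenotype generator and replicate evaluation engine.

The generator emulates the evaluation design used throughout the package's
validation: genotypes are drawn once and held fixed while phenotypes are
regenerated independently in every replicate, and type-I error or power is
the proportion of replicates in which a gene test rejects at the nominal
level (alpha = 5% by default, 200 replicates by default).

Two sample designs are supported:

* **unrelated** — N individuals, optionally split into subpopulations whose
  variant frequencies diverge by a Balding-Nichols F_ST and whose trait
  means may differ (the stratified-null scenario);
* **family** — three-generation pedigrees of eight members (grandparental
  couple, two of their children with married-in spouses, two
  grandchildren). Founder genotypes are drawn from the population
  frequencies and transmitted by Mendelian gene dropping; phenotypes
  include a polygenic component with covariance ``2 Phi sigma_g^2``.

Per-variant minor allele frequencies are drawn log-uniformly from a
configurable spectrum (default 0.0007-0.165, the range spanned by rare
causal exome variants). Causal effects are expressed in residual standard
deviations per minor allele. Within-gene allele correlation is available
through a Gaussian-copula knob on haplotype draws (default off).

Randomness is fully deterministic: one master seed, with per-replicate
child streams derived from ``(seed, replicate_index)`` so replicates are
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc_family, assoc_unrelated
from .core_types import (
    GenotypeMatrix,
    GeneSet,
    KinshipMatrix,
    Pedigree,
    Phenotype,
    kinship_from_pedigree,
    minor_allele_orient,
)
from .collapsing import collapse_ca, collapse_cp, collapse_ws, ws_weights, NoEligibleVariants

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "EvalReport",
    "simulate_genotypes",
    "simulate_phenotype",
    "evaluate",
    "UNRELATED_METHODS",
    "FAMILY_METHODS",
]

UNRELATED_METHODS = ("CA1", "CA5", "CP1", "CP5", "VT", "WS", "CMC1", "CMC2", "CMC3", "SM")
FAMILY_METHODS = ("CA1", "CA5", "CP1", "CP5", "WS", "CMC1", "SM")


@dataclass
class SimConfig:
    """Study-design parameters for the replicate engine.

    Defaults describe a single homogeneous population of 500 unrelated
    individuals, one gene of 20 variants, no causal effects (a null
    design), 200 replicates and genotypes fixed across replicates.
    """

    n_samples: int = 500
    n_genes: int = 1
    variants_per_gene: int = 20
    maf_range: tuple = (0.0007, 0.165)
    family_mode: bool = False
    n_families: int = 150
    n_populations: int = 1
    fst: float = 0.0
    pop_offsets: Sequence[float] | None = None  # trait-mean shift per population
    causal_effects: Mapping[str, object] = field(default_factory=dict)
    causal_t_maf: float = 0.05  # scalar effects apply to variants with maf <= this
    heritability: float = 0.0  # polygenic variance fraction (family mode)
    ld_rho: float = 0.0  # within-gene haplotype correlation (Gaussian copula)
    n_replicates: int = 200
    alpha: float = 0.05
    n_permutations: int = 1000
    fixed_genotypes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must lie in [0, 1)")
        if self.pop_offsets is not None and len(self.pop_offsets) != self.n_populations:
            raise ValueError("pop_offsets length must equal n_populations")


@dataclass
class SimulatedDataset:
    """Genotypes plus the bookkeeping the tests and phenotype model need."""

    matrix: GenotypeMatrix
    geneset: GeneSet
    populations: np.ndarray  # population index per sample
    true_mafs: np.ndarray  # ancestral per-variant frequencies
    pedigree: Pedigree | None = None
    kinship: KinshipMatrix | None = None


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    n = config.n_genes * config.variants_per_gene
    if lo == hi:
        return np.full(n, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def _population_freqs(
    mafs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-population frequencies; Balding-Nichols divergence when fst > 0."""
    K = config.n_populations
    if K == 1 or config.fst == 0.0:
        return np.tile(mafs, (K, 1))
    F = config.fst
    a = mafs * (1.0 - F) / F
    b = (1.0 - mafs) * (1.0 - F) / F
    freqs = rng.beta(a, b, size=(K, len(mafs)))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def _draw_haplotypes(
    freqs: np.ndarray, n_haplotypes: int, rng: np.random.Generator, ld_rho: float,
    variants_per_gene: int,
) -> np.ndarray:
    """(n_haplotypes, J) 0/1 allele draws, optionally gene-block correlated."""
    J = len(freqs)
    if ld_rho == 0.0:
        return (rng.random((n_haplotypes, J)) < freqs).astype(float)
    # Gaussian copula with exchangeable within-gene correlation.
    out = np.empty((n_haplotypes, J))
    thresh = stats.norm.ppf(freqs)
    for start in range(0, J, variants_per_gene):
        stop = min(start + variants_per_gene, J)
        width = stop - start
        shared = rng.standard_normal((n_haplotypes, 1))
        indiv = rng.standard_normal((n_haplotypes, width))
        z = np.sqrt(ld_rho) * shared + np.sqrt(1.0 - ld_rho) * indiv
        out[:, start:stop] = (z < thresh[start:stop]).astype(float)
    return out


def _three_generation_family(k: int) -> list[tuple]:
    """(fid, iid, father, mother, sex) rows for one 8-member family."""
    f = f"F{k}"
    i = lambda name: f"{f}_{name}"
    return [
        (f, i("gp1"), None, None, 1),
        (f, i("gp2"), None, None, 2),
        (f, i("sp1"), None, None, 2),
        (f, i("sp2"), None, None, 1),
        (f, i("c1"), i("gp1"), i("gp2"), 1),
        (f, i("c2"), i("gp1"), i("gp2"), 2),
        (f, i("g1"), i("c1"), i("sp1"), 1),
        (f, i("g2"), i("sp2"), i("c2"), 2),
    ]


def _gene_names(config: SimConfig) -> list[str]:
    return [f"GENE{g + 1}" for g in range(config.n_genes)]


def _variant_names(config: SimConfig) -> list[str]:
    names = []
    for g in range(config.n_genes):
        names += [f"GENE{g + 1}:V{j + 1}" for j in range(config.variants_per_gene)]
    return names


def _seed_key(seed) -> list:
    """Normalize a seed (int or sequence of ints) to a list of ints."""
    if np.isscalar(seed):
        return [int(seed)]
    return [int(s) for s in seed]


def simulate_genotypes(config: SimConfig, seed: int | None = None) -> SimulatedDataset:
    """Draw the genotype matrix (and pedigree, in family mode).

    Unrelated mode: each sample's count at variant j is Binomial(2, p_j)
    with p_j the sample's population frequency. Family mode: founder
    haplotypes are drawn from the population frequencies and offspring
    haplotypes by Mendelian gene dropping (one allele from each parent,
    independently per variant).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([*_seed_key(seed), 0])
    mafs = _draw_mafs(config, rng)
    variants = _variant_names(config)
    genes = {
        g: variants[gi * config.variants_per_gene:(gi + 1) * config.variants_per_gene]
        for gi, g in enumerate(_gene_names(config))
    }

    if not config.family_mode:
        freqs = _population_freqs(mafs, config, rng)
        pops = np.repeat(np.arange(config.n_populations),
                         -(-config.n_samples // config.n_populations))[: config.n_samples]
        counts = np.empty((config.n_samples, len(mafs)))
        for pop in range(config.n_populations):
            rows = np.flatnonzero(pops == pop)
            hap_a = _draw_haplotypes(freqs[pop], len(rows), rng, config.ld_rho,
                                     config.variants_per_gene)
            hap_b = _draw_haplotypes(freqs[pop], len(rows), rng, config.ld_rho,
                                     config.variants_per_gene)
            counts[rows] = hap_a + hap_b
        samples = [f"S{i + 1}" for i in range(config.n_samples)]
        matrix, _ = minor_allele_orient(GenotypeMatrix(samples, variants, counts))
        geneset = GeneSet(genes, matrix)
        return SimulatedDataset(matrix, geneset, pops, mafs)

    rows: list[tuple] = []
    for k in range(config.n_families):
        rows += _three_generation_family(k + 1)
    ped = Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]))
    ids = ped.ids
    idx = {iid: i for i, iid in enumerate(ids)}
    parents = dict(zip(ped.records["iid"],
                       zip(ped.records["father"], ped.records["mother"])))
    J = len(mafs)
    hap = np.empty((len(ids), 2, J))
    founders = [iid for iid, fm in parents.items() if fm == (None, None)]
    fh = _draw_haplotypes(mafs, 2 * len(founders), rng, config.ld_rho,
                          config.variants_per_gene)
    for f_i, iid in enumerate(founders):
        hap[idx[iid], 0] = fh[2 * f_i]
        hap[idx[iid], 1] = fh[2 * f_i + 1]
    for iid in ped.topological_order:
        fa, mo = parents[iid]
        if fa is None and mo is None:
            continue
        pick_f = rng.integers(0, 2, size=J)
        pick_m = rng.integers(0, 2, size=J)
        hap[idx[iid], 0] = hap[idx[fa], pick_f, np.arange(J)]
        hap[idx[iid], 1] = hap[idx[mo], pick_m, np.arange(J)]
    counts = hap.sum(axis=1)
    matrix, _ = minor_allele_orient(GenotypeMatrix(ids, variants, counts))
    geneset = GeneSet(genes, matrix)
    kinship = kinship_from_pedigree(ped)
    pops = np.zeros(len(ids), dtype=int)
    return SimulatedDataset(matrix, geneset, pops, mafs,
                            pedigree=ped, kinship=kinship)


# ---------------------------------------------------------------------------
# Phenotype generation
# ---------------------------------------------------------------------------

def _effect_vector(dataset: SimulatedDataset, config: SimConfig) -> np.ndarray:
    """Per-variant effect sizes aligned to the matrix columns."""
    beta = np.zeros(dataset.matrix.n_variants)
    vindex = {v: j for j, v in enumerate(dataset.matrix.variants)}
    for gene, eff in config.causal_effects.items():
        gene_variants = dataset.geneset[gene]
        cols = np.array([vindex[v] for v in gene_variants])
        if np.isscalar(eff):
            causal = dataset.true_mafs[cols] <= config.causal_t_maf
            beta[cols[causal]] = float(eff)
        else:
            eff = np.asarray(eff, dtype=float)
            if len(eff) != len(cols):
                raise ValueError(f"effect vector for {gene} has wrong length")
            beta[cols] = eff
    return beta


def _polygenic_chol(dataset: SimulatedDataset) -> np.ndarray:
    """Cholesky factor of 2*Phi, cached on the dataset object."""
    chol = getattr(dataset, "_polygenic_chol", None)
    if chol is None:
        A = 2.0 * dataset.kinship.values
        chol = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
        dataset._polygenic_chol = chol
    return chol


def simulate_phenotype(
    dataset: SimulatedDataset,
    config: SimConfig,
    replicate_index: int,
    seed: int | None = None,
) -> Phenotype:
    """One phenotype replicate.

    ``y_i = offset(pop_i) + sum_c beta_c x_ic + g_i + e_i`` with
    ``g ~ N(0, 2 Phi sigma_g^2)`` in family mode (``sigma_g^2`` equals the
    configured heritability, ``sigma_e^2 = 1 - sigma_g^2``) and
    ``e ~ N(0, sigma_e^2)``; unrelated mode has ``sigma_e^2 = 1``. The RNG
    stream is derived from ``(seed, 1 + replicate_index)``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([*_seed_key(seed), 1 + replicate_index])
    n = dataset.matrix.n_samples
    beta = _effect_vector(dataset, config)
    x = np.nan_to_num(dataset.matrix.counts, nan=0.0)
    y = x @ beta
    if config.pop_offsets is not None:
        y = y + np.asarray(config.pop_offsets)[dataset.populations]
    if config.family_mode and config.heritability > 0:
        g = _polygenic_chol(dataset) @ rng.standard_normal(n)
        y = y + np.sqrt(config.heritability) * g
        y = y + np.sqrt(1.0 - config.heritability) * rng.standard_normal(n)
    else:
        y = y + rng.standard_normal(n)
    return Phenotype(list(dataset.matrix.samples), y)


# ---------------------------------------------------------------------------
# Replicate evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per gene x method empirical rejection rates with exact binomial CIs."""

    table: pd.DataFrame  # gene, method, rate, n_ok, n_na, ci_low, ci_high
    alpha: float
    n_replicates: int

    def rate(self, gene: str, method: str) -> float:
        sel = self.table[(self.table.gene == gene) & (self.table.method == method)]
        if sel.empty:
            raise KeyError(f"no cell for ({gene}, {method})")
        return float(sel.rate.iloc[0])


def _clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple:
    if n == 0:
        return (0.0, 1.0)
    a = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(a / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - a / 2, x + 1, n - x))
    return lo, hi


def _run_method_unrelated(method, y, dataset, config, perm_seed, maf_cache, gene_list):
    au = assoc_unrelated
    if method in ("CA1", "CA5", "CP1", "CP5"):
        strategy, t = method[:2], 0.01 if method.endswith("1") else 0.05
        return {
            g: au.test_cast(y, dataset.matrix, dataset.geneset, g, strategy, t,
                            mafs=maf_cache[g])
            for g in gene_list
        }
    if method in ("CMC1", "CMC2", "CMC3"):
        return {
            g: au.test_cmc(y, dataset.matrix, dataset.geneset, g, method,
                           mafs=maf_cache[g])
            for g in gene_list
        }
    if method == "SM":
        return {
            g: au.test_sm(y, dataset.matrix, dataset.geneset, g, config.alpha,
                          mafs=maf_cache[g])
            for g in gene_list
        }
    if method == "WS":
        return {
            g: au.test_ws(y, dataset.matrix, dataset.geneset, g,
                          config.n_permutations, seed=perm_seed + [hash_gene(g)])
            for g in gene_list
        }
    if method == "VT":
        return {
            g: au.test_vt(y, dataset.matrix, dataset.geneset, g,
                          config.n_permutations, seed=perm_seed + [hash_gene(g)],
                          mafs=maf_cache[g])
            for g in gene_list
        }
    raise ValueError(f"unknown method {method!r}")


def hash_gene(gene: str) -> int:
    """Stable small-integer stream tag for a gene name."""
    return sum((i + 1) * ord(ch) for i, ch in enumerate(gene)) % 100003


def _family_design(dataset, gene, method, maf_cache):
    sub = dataset.matrix.subset(variants=dataset.geneset[gene])
    m = maf_cache[gene]
    if method in ("CA1", "CA5", "CP1", "CP5"):
        t = 0.01 if method.endswith("1") else 0.05
        collapse = collapse_ca if method.startswith("CA") else collapse_cp
        return collapse(sub, t, mafs=m).values[:, None], 1
    if method == "WS":
        return collapse_ws(sub, ws_weights(sub)).values[:, None], 1
    if method == "CMC1":
        cols = []
        rare_mask = np.isfinite(m) & (m > 0) & (m < 0.01)
        mid_mask = np.isfinite(m) & (m >= 0.01) & (m <= 0.05)
        for mask in (rare_mask, mid_mask):
            if mask.any():
                carrier = np.nan_to_num(sub.counts[:, mask], nan=0.0) >= 1
                cols.append(carrier.any(axis=1).astype(float))
        if not cols:
            raise NoEligibleVariants("all CMC1 groups empty")
        return np.column_stack(cols), len(cols)
    raise ValueError(f"method {method!r} not available in family mode")


def _run_method_family(method, y, dataset, config, eig, maf_cache, gene_list=None):
    if gene_list is None:
        gene_list = list(dataset.geneset)
    af = assoc_family
    if method == "VT":
        raise ValueError(
            "the variable-threshold test is not defined for family samples: "
            "maximizing over thresholds invalidates the tabulated mixed-model LRT"
        )
    if method == "SM":
        return {
            g: af.test_sm_family(y, eig, dataset.matrix, dataset.geneset, g,
                                 config.alpha)
            for g in gene_list
        }
    out = {}
    for g in gene_list:
        try:
            design, df = _family_design(dataset, g, method, maf_cache)
        except NoEligibleVariants as exc:
            out[g] = assoc_unrelated.AssocResult.not_applicable(g, method, str(exc))
            continue
        out[g] = af.test_mg(y, eig, design, df, gene=g, method=method)
    return out


def evaluate(
    config: SimConfig,
    methods: Sequence[str],
    alpha: float | None = None,
    seed: int | None = None,
    adjust_pcs: int = 0,
    pc_maf_min: float = 0.05,
    genes: Sequence[str] | None = None,
) -> EvalReport:
    """Run the requested tests over all replicates and tabulate rates.

    The empirical rate per (gene, method) cell is the proportion of
    successful replicates with gene-level p <= alpha (for SM the Bonferroni
    rule, which the adjusted gene p reproduces exactly). With
    ``adjust_pcs > 0`` the phenotype is residualized on that many genotype
    principal components (from variants with maf >= ``pc_maf_min``) before
    testing, as in the stratification-adjusted analyses. ``genes`` limits
    testing to a subset of genes (PCs still use the full matrix).
    """
    from .stratification import compute_pcs, residualize

    alpha = config.alpha if alpha is None else alpha
    seed = config.seed if seed is None else seed
    for m in methods:
        valid = FAMILY_METHODS if config.family_mode else UNRELATED_METHODS
        if m not in valid:
            raise ValueError(f"method {m!r} not available for this design")

    dataset = simulate_genotypes(config, seed) if config.fixed_genotypes else None
    eig = None
    adjustment = None
    maf_cache = None

    def prepare(ds):
        from .core_types import maf_array
        gene_list = list(ds.geneset) if genes is None else list(genes)
        cache = {g: maf_array(ds.matrix.subset(variants=ds.geneset[g]))
                 for g in gene_list}
        e = assoc_family.kinship_eigen(ds.kinship) if config.family_mode else None
        adj = compute_pcs(ds.matrix, pc_maf_min, adjust_pcs) if adjust_pcs else None
        return gene_list, cache, e, adj

    gene_list = None
    if dataset is not None:
        gene_list, maf_cache, eig, adjustment = prepare(dataset)

    hits: dict[tuple, int] = {}
    n_ok: dict[tuple, int] = {}
    n_na: dict[tuple, int] = {}
    for rep in range(config.n_replicates):
        if dataset is None:
            ds = simulate_genotypes(config, [*_seed_key(seed), 50000 + rep])
            glist, cache, e, adj = prepare(ds)
        else:
            ds, glist, cache, e, adj = dataset, gene_list, maf_cache, eig, adjustment
        pheno = simulate_phenotype(ds, config, rep, seed)
        y = pheno.values
        if adj is not None:
            y = residualize(y, adj)
        for method in methods:
            if config.family_mode:
                results = _run_method_family(method, y, ds, config, e, cache, glist)
            else:
                results = _run_method_unrelated(
                    method, y, ds, config, [*_seed_key(seed), 1 + rep, 999], cache, glist
                )
            for g, res in results.items():
                key = (g, method)
                if res.status != "ok":
                    n_na[key] = n_na.get(key, 0) + 1
                    continue
                n_ok[key] = n_ok.get(key, 0) + 1
                if res.p <= alpha:
                    hits[key] = hits.get(key, 0) + 1

    rows = []
    for g in (gene_list if gene_list is not None else glist):
        for method in methods:
            key = (g, method)
            ok = n_ok.get(key, 0)
            x = hits.get(key, 0)
            rate = x / ok if ok else np.nan
            lo, hi = _clopper_pearson(x, ok)
            rows.append((g, method, rate, ok, n_na.get(key, 0), lo, hi))
    table = pd.DataFrame(
        rows, columns=["gene", "method", "rate", "n_ok", "n_na", "ci_low", "ci_high"]
    )
    return EvalReport(table, alpha, config.n_replicates)
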