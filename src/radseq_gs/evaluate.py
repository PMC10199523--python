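"""Single-trait single-step GBLUP evaluation and ranking comparisons.

The animal model is y = Xb + Zu + e with u ~ N(0, H sigma2_u), where H
merges pedigree relationships (A, tabular method) with genomic
relationships of the genotyped subset (G, VanRaden method 1).  The mixed
model equations

    [X'X   X'Z        ] [b]   [X'y]
    [Z'X   Z'Z + Hinv*lambda] [u] = [Z'y],   lambda = sigma2_e / sigma2_u,

are solved directly (desk scale).  Variance components are inputs, not
estimated.  Three evaluation scenarios mirror a breeding programme
validating imputed RADseq genotypes: Full_HD (all phenotypes and
genotypes), Ancestry_true (parent-generation phenotypes, true candidate
genotypes) and Ancestry_imputed (same, but candidates carry imputed
genotypes); scenarios are compared by Spearman rank correlations over the
top-K candidates and over the breeders (parents with >= 10 offspring), and
by Pearson correlation against the Full_HD reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .qc import GenotypeMatrix
from .simulate import UNKNOWN_PARENT


# ------------------------------------------------------------- small pieces
def derive_esc(L: float, a: float, b: float):
    """Eggshell colour from Minolta L*, a*, b*: ESC = 100 - (L* - a* - b*)."""
    return 100 - (np.asarray(L) - np.asarray(a) - np.asarray(b))


def heterozygote_call_probability(n_reads: int) -> float:
    """Probability that n reads from a heterozygote show both alleles:
    1 - 2/2^n (each read is a fair draw between the two alleles)."""
    if n_reads < 1:
        raise ValueError("need at least one read")
    return 1 - 2 / 2**n_reads


# -------------------------------------------------------------- relationship
def _pedigree_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    row_of = {ind: i for i, ind in enumerate(pedigree["id"])}
    n = len(pedigree)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i, rec in enumerate(pedigree.itertuples(index=False)):
        for arr, parent in ((sire, rec.sire), (dam, rec.dam)):
            if parent != UNKNOWN_PARENT:
                j = row_of.get(parent)
                if j is None:
                    raise ValueError(f"parent {parent} of {rec.id} not in pedigree")
                if j >= i:
                    raise ValueError("pedigree must list parents before offspring")
                arr[i] = j
    return sire, dam


def build_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Additive (numerator) relationship matrix by the tabular method."""
    sire, dam = _pedigree_indices(pedigree)
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def build_A_inverse(pedigree: pd.DataFrame, method: str = "henderson") -> np.ndarray:
    """A^-1 either by direct inversion or by Henderson's rules with exact
    Mendelian-sampling variances (valid with inbreeding)."""
    if method == "direct":
        return np.linalg.inv(build_A(pedigree))
    if method != "henderson":
        raise ValueError("method must be 'henderson' or 'direct'")
    sire, dam = _pedigree_indices(pedigree)
    A = build_A(pedigree)  # for Mendelian-sampling variances
    n = len(pedigree)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        d_i = A[i, i]
        if s >= 0:
            d_i -= 0.25 * A[s, s]
        if d >= 0:
            d_i -= 0.25 * A[d, d]
        if s >= 0 and d >= 0:
            d_i -= 0.5 * A[s, d]
        w = 1.0 / d_i
        idx = [(i, 1.0)]
        if s >= 0:
            idx.append((s, -0.5))
        if d >= 0:
            idx.append((d, -0.5))
        for j, cj in idx:
            for k, ck in idx:
                Ainv[j, k] += w * cj * ck
    return Ainv


def build_G(codes: np.ndarray, allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = M M' / (2 sum p_j (1-p_j)) with M the column-centred dosage matrix
    (code - 2 p_j).  Codes must be complete (post-imputation).
    """
    codes = np.asarray(codes, dtype=float)
    if (codes < 0).any():
        raise ValueError("missing codes not allowed; impute first")
    p = codes.mean(axis=0) / 2 if allele_freqs is None else np.asarray(allele_freqs)
    denom = 2 * np.sum(p * (1 - p))
    if denom == 0:
        raise ValueError("all markers monomorphic: G denominator is zero")
    M = codes - 2 * p
    return M @ M.T / denom


def build_Hinv(
    Ainv: np.ndarray,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    blend: float = 0.05,
    tau: float = 1.0,
    omega: float = 1.0,
) -> np.ndarray:
    """Single-step H^-1: A^-1 plus the genotyped-block correction
    tau*(blended G)^-1 - omega*A22^-1, with G blended as
    (1-blend)*G + blend*A22 for invertibility."""
    Gb = (1 - blend) * G + blend * A22
    try:
        Gb_inv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "blended G is singular; raise the blend proportion"
        ) from err
    A22_inv = np.linalg.inv(A22)
    Hinv = Ainv.copy()
    ix = np.ix_(genotyped_idx, genotyped_idx)
    Hinv[ix] += tau * Gb_inv - omega * A22_inv
    return Hinv


# --------------------------------------------------------------------- MME
def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    Hinv: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's mixed model equations; returns (b, u).

    A rank-deficient fixed block is handled by zeroing dependent columns
    (QR pivot) and logging a warning.
    """
    import warnings

    if lam <= 0:
        raise ValueError("lambda must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = np.arange(X.shape[1])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy column selection by pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"fixed-effect design rank-deficient; columns {sorted(set(range(X.shape[1])) - set(keep))} constrained to zero"
        )
    Xk = X[:, keep]
    XtX = Xk.T @ Xk
    XtZ = Xk.T @ Z
    ZtZ = Z.T @ Z
    lhs = np.block([[XtX, XtZ], [XtZ.T, ZtZ + Hinv * lam]])
    rhs = np.concatenate([Xk.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    b = np.zeros(X.shape[1])
    b[keep] = sol[: Xk.shape[1]]
    u = sol[Xk.shape[1] :]
    return b, u


# ---------------------------------------------------------------- scenarios
@dataclass(frozen=True)
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be > 0")

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_u


def _design(
    pedigree: pd.DataFrame, records: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse repeated measures to individual means and build y, X
    (intercept + batch dummies, first level dropped), Z (obs -> pedigree)."""
    collapsed = (
        records.groupby("individual")
        .agg(value=("value", "mean"), batch=("batch", "first"))
        .reset_index()
    )
    y = collapsed["value"].to_numpy(dtype=float)
    batches = sorted(records["batch"].unique())
    X = np.ones((len(collapsed), 1 + max(len(batches) - 1, 0)))
    for j, lev in enumerate(batches[1:]):
        X[:, 1 + j] = (collapsed["batch"] == lev).to_numpy(dtype=float)
    row_of = {ind: i for i, ind in enumerate(pedigree["id"])}
    Z = np.zeros((len(collapsed), len(pedigree)))
    for obs_i, ind in enumerate(collapsed["individual"]):
        Z[obs_i, row_of[ind]] = 1.0
    return y, X, Z


def evaluate_trait(
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    varcomp: VarianceComponents,
    genotyped: GenotypeMatrix | None = None,
    phenotyped_generations: tuple | None = None,
    Ainv: np.ndarray | None = None,
    A: np.ndarray | None = None,
    blend: float = 0.05,
) -> pd.Series:
    """GEBV for every pedigree individual from one scenario's data.

    ``genotyped`` supplies the (complete) genotypes entering G; without it
    the model is plain pedigree BLUP.
    """
    records = phenotypes[phenotypes["trait"] == trait]
    if phenotyped_generations is not None:
        records = records[records["generation"].isin(phenotyped_generations)]
    if records.empty:
        raise ValueError(f"no phenotype records for trait {trait}")
    y, X, Z = _design(pedigree, records)
    if A is None:
        A = build_A(pedigree)
    if Ainv is None:
        Ainv = np.linalg.inv(A)
    if genotyped is not None and genotyped.n_individuals > 0:
        row_of = {ind: i for i, ind in enumerate(pedigree["id"])}
        missing = [i for i in genotyped.individuals if i not in row_of]
        if missing:
            raise ValueError(f"genotyped individuals not in pedigree: {missing[:5]}")
        gidx = np.array([row_of[i] for i in genotyped.individuals])
        A22 = A[np.ix_(gidx, gidx)]
        G = build_G(genotyped.codes)
        Hinv = build_Hinv(Ainv, A22, G, gidx, blend=blend)
    else:
        Hinv = Ainv
    _, u = solve_mme(y, X, Z, Hinv, varcomp.lam)
    return pd.Series(u, index=pedigree["id"].to_numpy(), name=trait)


SCENARIOS = ("Full_HD", "Ancestry_true", "Ancestry_imputed")


def run_scenarios(
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame,
    hd_true: GenotypeMatrix,
    hd_imputed_candidates: GenotypeMatrix,
    varcomps: dict[str, VarianceComponents],
    candidate_generation: int = 1,
    blend: float = 0.05,
) -> pd.DataFrame:
    """GEBV table over the three standard scenarios x traits.

    Full_HD: all phenotypes, true HD genotypes of everyone in ``hd_true``.
    Ancestry_true: ancestor-generation phenotypes only; true HD genotypes of
    generations 0..candidate_generation.
    Ancestry_imputed: same phenotypes; candidates' genotypes replaced by the
    imputed matrix.  Variance components are shared across scenarios.
    """
    ped = pedigree
    gens = dict(zip(ped["id"], ped["generation"]))
    A = build_A(ped)
    Ainv = np.linalg.inv(A)
    anc_gens = tuple(range(candidate_generation))

    def subset(gm: GenotypeMatrix, keep_ids: set) -> GenotypeMatrix:
        mask = np.array([i in keep_ids for i in gm.individuals])
        return GenotypeMatrix(
            [i for i, k in zip(gm.individuals, mask) if k], gm.markers, gm.codes[mask]
        )

    upto = {i for i, g in gens.items() if g <= candidate_generation}
    anc_only = {i for i, g in gens.items() if g < candidate_generation}
    cand = {i for i, g in gens.items() if g == candidate_generation}
    true_upto = subset(hd_true, upto)
    imp_mask = np.array([i in cand for i in hd_imputed_candidates.individuals])
    imputed_cand = GenotypeMatrix(
        [i for i, k in zip(hd_imputed_candidates.individuals, imp_mask) if k],
        hd_imputed_candidates.markers,
        hd_imputed_candidates.codes[imp_mask],
    )
    anc_true = subset(hd_true, anc_only)
    mixed = GenotypeMatrix(
        list(anc_true.individuals) + list(imputed_cand.individuals),
        hd_true.markers,
        np.vstack([anc_true.codes, imputed_cand.codes]),
    )
    scenario_data = {
        "Full_HD": (hd_true, None),
        "Ancestry_true": (true_upto, anc_gens),
        "Ancestry_imputed": (mixed, anc_gens),
    }
    rows = []
    for trait, vc in varcomps.items():
        for scen, (gm, pgens) in scenario_data.items():
            gebv = evaluate_trait(
                ped,
                phenotypes,
                trait,
                vc,
                genotyped=gm,
                phenotyped_generations=pgens,
                Ainv=Ainv,
                A=A,
                blend=blend,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "scenario": scen,
                        "trait": trait,
                        "individual": gebv.index,
                        "gebv": gebv.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------------ ranking
@dataclass
class RankComparison:
    spearman_topK: float
    spearman_breeders: float
    n_retained_in_topK: int
    pearson_relative_accuracy: float
    K: int
    min_offspring: int
    n_breeders: int
    se_topK: float | None = None
    se_breeders: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def offspring_counts(pedigree: pd.DataFrame) -> pd.Series:
    """Number of offspring per individual (as sire or dam)."""
    counts = pd.concat([pedigree["sire"], pedigree["dam"]]).value_counts()
    return counts.drop(UNKNOWN_PARENT, errors="ignore")


def rank_comparison(
    gebv_a: pd.Series,
    gebv_b: pd.Series,
    pedigree: pd.DataFrame,
    K: int = 150,
    min_offspring: int = 10,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> RankComparison:
    """Ranking agreement between two GEBV vectors over a shared candidate set.

    Spearman over the top-K of ``gebv_a`` (the reference ranking); Spearman
    over the breeder subset (>= min_offspring offspring in the pedigree);
    count of top-K(a) individuals also in top-K(b); Pearson over the breeder
    subset as the relative-accuracy measure (meaningful when ``gebv_a`` is
    the Full_HD reference).  Optional bootstrap standard errors.
    """
    common = gebv_a.index.intersection(gebv_b.index)
    if K > len(common):
        raise ValueError(f"K={K} exceeds the {len(common)} shared candidates")
    a = gebv_a.loc[common]
    b = gebv_b.loc[common]
    top_a = a.sort_values(ascending=False).index[:K]
    top_b = b.sort_values(ascending=False).index[:K]
    rho_top = float(spearmanr(a.loc[top_a], b.loc[top_a]).statistic)
    n_retained = len(set(top_a) & set(top_b))
    counts = offspring_counts(pedigree)
    breeders = [i for i in common if counts.get(i, 0) >= min_offspring]
    if len(breeders) >= 2:
        rho_br = float(spearmanr(a.loc[breeders], b.loc[breeders]).statistic)
        pear = float(pearsonr(a.loc[breeders], b.loc[breeders]).statistic)
    else:
        rho_br = float("nan")
        pear = float("nan")
    se_top = se_br = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)

        def boot_se(x: np.ndarray, y: np.ndarray) -> float:
            stats = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, len(x), size=len(x))
                if np.unique(x[idx]).size < 2 or np.unique(y[idx]).size < 2:
                    continue
                stats.append(spearmanr(x[idx], y[idx]).statistic)
            return float(np.std(stats, ddof=1)) if len(stats) > 1 else float("nan")

        se_top = boot_se(a.loc[top_a].to_numpy(), b.loc[top_a].to_numpy())
        if len(breeders) >= 2:
            se_br = boot_se(a.loc[breeders].to_numpy(), b.loc[breeders].to_numpy())
    return RankComparison(
        spearman_topK=rho_top,
        spearman_breeders=rho_br,
        n_retained_in_topK=n_retained,
        pearson_relative_accuracy=pear,
        K=K,
        min_offspring=min_offspring,
        n_breeders=len(breeders),
        se_topK=se_top,
        se_breeders=se_br,
    )
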