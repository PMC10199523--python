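"""Genotype quality control.

Reproduces the successive-step QC chain commonly applied to SNP-array data
before genomic evaluation: individual call rate, monomorphic-marker removal,
minor allele frequency, SNP call rate, Hardy-Weinberg equilibrium (exact
test), location-based exclusion, and a parent-offspring Mendelian
consistency check.  Allele frequencies are recomputed after every removal
step, so the chain is order-dependent by design and idempotent on its own
output.

Genotype codes count alternate alleles: 0, 1, 2, with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of allele-dosage codes.

    ``codes`` is int8 with values {0, 1, 2, -1(missing)}; rows follow
    ``individuals``, columns follow the ``markers`` table (marker_id, chrom,
    pos, ref, alt).
    """

    individuals: list
    markers: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        ids = [i for i, m in zip(self.individuals, mask) if m]
        return GenotypeMatrix(ids, self.markers.copy(), self.codes[mask])

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals),
            self.markers[mask].reset_index(drop=True),
            self.codes[:, mask],
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing codes."""
        obs = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, self.codes, 0).sum(axis=0) / (2 * obs.sum(axis=0))
        return np.where(obs.any(axis=0), p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1 - p)

    def genotype_counts(self) -> np.ndarray:
        """(n_markers, 3) counts of codes 0/1/2 over non-missing."""
        return np.stack([(self.codes == g).sum(axis=0) for g in (0, 1, 2)], axis=1)


@dataclass
class QCReport:
    """Ordered record of removals per QC step."""

    steps: list = field(default_factory=list)
    initial_markers: int = 0
    initial_individuals: int = 0
    final_markers: int = 0
    final_individuals: int = 0

    def add(self, step: str, n_removed: int, unit: str, threshold) -> None:
        self.steps.append(
            {"step": step, "n_removed": int(n_removed), "unit": unit, "threshold": threshold}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


# ----------------------------------------------------------------- filters
def filter_individual_call_rate(gm: GenotypeMatrix, threshold: float = 0.95):
    """Remove individuals whose non-missing fraction is strictly below
    ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    rate = (gm.codes != MISSING).mean(axis=1)
    keep = rate >= threshold
    if not keep.any():
        raise ValueError("individual call-rate filter removed every individual")
    entry = {
        "step": "Individual call rate",
        "n_removed": int((~keep).sum()),
        "unit": "individuals",
        "threshold": f"< {threshold:g}",
    }
    return gm.subset_individuals(keep), entry


def filter_maf(gm: GenotypeMatrix, min_maf: float):
    """Remove markers with minor allele frequency strictly below ``min_maf``
    (computed on non-missing codes of currently retained individuals)."""
    maf = gm.maf()
    keep = ~(maf < min_maf)  # NaN (all-missing) markers kept here
    entry = {
        "step": "MAF",
        "n_removed": int((~keep).sum()),
        "unit": "markers",
        "threshold": f"< {min_maf:g}",
    }
    return gm.subset_markers(keep), entry


def filter_snp_call_rate(gm: GenotypeMatrix, threshold: float = 0.95):
    """Remove markers whose non-missing fraction across individuals is
    strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    rate = (gm.codes != MISSING).mean(axis=0)
    keep = rate >= threshold
    entry = {
        "step": "SNP call rate",
        "n_removed": int((~keep).sum()),
        "unit": "markers",
        "threshold": f"< {threshold:g}",
    }
    return gm.subset_markers(keep), entry


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count is

        P(h) = n! / (nAA! h! naa!) * 2^h * nA! na! / (2n)!

    and the p-value sums P over all outcomes no more probable than the
    observed one.  Zero total returns 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_A, 2 * n - n_A)

    def logp(h: int) -> float:
        homr = (n_rare - h) // 2
        homc = n - h - homr
        return (
            gammaln(n + 1)
            - gammaln(homr + 1)
            - gammaln(h + 1)
            - gammaln(homc + 1)
            + h * np.log(2)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    lp = np.array([logp(int(h)) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square HWE test (alternative flavour)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def filter_hwe(gm: GenotypeMatrix, alpha: float = 1e-4, method: str = "exact"):
    """Remove markers with HWE test p-value strictly below ``alpha``."""
    test = {"exact": hwe_exact_test, "chi2": hwe_chi2_test}[method]
    counts = gm.genotype_counts()
    pvals = np.array([test(a, h, b) for a, h, b in counts])
    keep = pvals >= alpha
    entry = {
        "step": "Hardy-Weinberg equilibrium",
        "n_removed": int((~keep).sum()),
        "unit": "markers",
        "threshold": f"P < {alpha:g}",
    }
    return gm.subset_markers(keep), entry


def filter_by_location(
    gm: GenotypeMatrix,
    excluded_chroms: list[str] | tuple = (),
    drop_unplaced: bool = True,
    unplaced_labels: tuple = ("unknown", "un", "na", ""),
):
    """Remove markers on excluded chromosomes or without a placement."""
    chrom = gm.markers["chrom"].astype(str)
    bad = chrom.isin([str(c) for c in excluded_chroms])
    if drop_unplaced:
        bad |= chrom.str.lower().isin(unplaced_labels) | gm.markers["chrom"].isna()
    entry = {
        "step": "Location (unplaced / excluded chromosomes)",
        "n_removed": int(bad.sum()),
        "unit": "markers",
        "threshold": ",".join(map(str, excluded_chroms)) or "-",
    }
    return gm.subset_markers(~bad.to_numpy()), entry


def mendel_check(gm: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Opposing-homozygote conflicts per genotyped parent-offspring pair.

    A conflict is parent code 0 with offspring code 2 (or vice versa) at a
    marker where both are non-missing.  Reporting only; removal policy is
    left to the caller.
    """
    idx = {ind: i for i, ind in enumerate(gm.individuals)}
    rows = []
    for rec in pedigree.itertuples(index=False):
        if rec.id not in idx:
            continue
        off = gm.codes[idx[rec.id]]
        for parent in (rec.sire, rec.dam):
            if parent == 0 or parent not in idx:
                continue
            par = gm.codes[idx[parent]]
            both = (off != MISSING) & (par != MISSING)
            conflicts = int(
                (((off == 0) & (par == 2)) | ((off == 2) & (par == 0)))[both].sum()
            )
            rows.append({"offspring": rec.id, "parent": parent, "n_conflicts": conflicts})
    return pd.DataFrame(rows, columns=["offspring", "parent", "n_conflicts"])


def qc_chain(
    gm: GenotypeMatrix,
    pedigree: pd.DataFrame | None = None,
    ind_call_rate: float = 0.95,
    min_maf: float = 0.05,
    snp_call_rate: float = 0.95,
    hwe_alpha: float = 1e-4,
    excluded_chroms: tuple = (),
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """The six-step successive QC chain plus the pedigree check.

    Order: individual call rate -> monomorphic (MAF = 0) -> MAF -> SNP call
    rate -> HWE -> location -> pedigree compatibility (report only).
    """
    report = QCReport(
        initial_markers=gm.n_markers, initial_individuals=gm.n_individuals
    )
    gm, e = filter_individual_call_rate(gm, ind_call_rate)
    report.steps.append(e)
    gm, e = filter_maf(gm, np.finfo(float).tiny)  # removes exactly MAF == 0
    e["step"] = "MAF (= 0)"
    e["threshold"] = "= 0"
    report.steps.append(e)
    gm, e = filter_maf(gm, min_maf)
    report.steps.append(e)
    gm, e = filter_snp_call_rate(gm, snp_call_rate)
    report.steps.append(e)
    gm, e = filter_hwe(gm, hwe_alpha, method=hwe_method)
    report.steps.append(e)
    gm, e = filter_by_location(gm, excluded_chroms)
    report.steps.append(e)
    if pedigree is not None:
        conflicts = mendel_check(gm, pedigree)
        n_bad = int((conflicts["n_conflicts"] > 0).sum()) if len(conflicts) else 0
        report.add("Pedigree incompatibility (reported)", 0, "individuals", f"{n_bad} pairs flagged")
    report.final_markers = gm.n_markers
    report.final_individuals = gm.n_individuals
    return gm, report
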