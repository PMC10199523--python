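"""Synthetic genomes, pedigreed populations and traits with known truth.

Every downstream stage of the pipeline (digestion, window/SNP overlap, QC,
imputation, single-step GBLUP) is exercised on data produced here, so the
generator emulates the salient features of a layer-chicken breeding
population: chromosome size classes with different GC content (micro > macro),
a multi-generation pedigree with sires reused across dams, founder
haplotypes with tunable LD decay, an HD chip panel nested in a larger
variant set, some variants planted inside restriction sites, and additive
polygenic traits with specified heritabilities.

Randomness: one master seed; each stage draws from a named substream spawned
from it, so outputs are reproducible stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import scan_sites
from .enzymes import ENZYMES, EnzymeSpec
from .genome import CHROM_TYPES, GenomeAssembly
from .qc import GenotypeMatrix

_STAGES = ("genome", "pedigree", "markers", "haplotypes", "gene_drop", "traits", "panel")


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES.index(stage)]))


# ------------------------------------------------------------- configuration
@dataclass(frozen=True)
class ChromosomePlan:
    name: str
    ctype: str  # macro | intermediate | micro | Z
    length: int
    gc: float


@dataclass(frozen=True)
class TraitPlan:
    name: str
    h2: float
    var_p: float = 1.0
    mean: float = 0.0
    n_qtl: int = 100
    n_batches: int = 3  # fixed-effect levels per generation
    batch_sd: float = 0.3  # sd of batch effects, on the phenotype scale


@dataclass(frozen=True)
class MatingPlan:
    n_sires: int = 10
    n_dams: int = 40
    offspring_per_dam: int = 5


@dataclass
class SimConfig:
    """All knobs of the synthetic study population."""

    seed: int = 0
    chromosome_plan: list = field(default_factory=list)
    n_founders: int = 100
    generations: int = 4
    mating: MatingPlan = field(default_factory=MatingPlan)
    marker_density: float = 120.0  # markers per Mb
    ld_decay_bp: float = 250_000.0  # distance at which founder r^2 ~ 0.3
    recombination_rate: float = 3e-8  # crossovers per bp per meiosis
    trait_plan: list = field(default_factory=list)
    panel_fraction: float = 0.35
    site_variant_rate: float = 0.05  # fraction of markers inside enzyme sites
    site_enzymes: tuple = ("TaqI", "PstI")

    def validate(self) -> None:
        if not self.chromosome_plan:
            raise ValueError("chromosome_plan must be non-empty")
        for cp in self.chromosome_plan:
            if cp.length <= 0:
                raise ValueError(f"chromosome {cp.name}: length must be > 0")
            if not 0 < cp.gc < 1:
                raise ValueError(f"chromosome {cp.name}: GC must be in (0,1)")
            if cp.ctype not in CHROM_TYPES:
                raise ValueError(f"chromosome {cp.name}: unknown type {cp.ctype}")
        macros = [c for c in self.chromosome_plan if c.ctype == "macro"]
        micros = [c for c in self.chromosome_plan if c.ctype == "micro"]
        if macros and micros:
            if max(c.length for c in micros) >= min(c.length for c in macros):
                raise ValueError("micro chromosomes must be shorter than macro")
            if min(c.gc for c in micros) < max(c.gc for c in macros):
                raise ValueError("configured micro GC must be >= macro GC")
        for tp in self.trait_plan:
            if not 0 < tp.h2 < 1:
                raise ValueError(f"trait {tp.name}: h2 must be in (0,1)")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if not 0 < self.panel_fraction <= 1:
            raise ValueError("panel_fraction must be in (0,1]")


def default_config(seed: int = 0) -> SimConfig:
    """Desk-scale study conditions: 8 chromosomes over the four size classes
    (~14.4 Mb total), 4 generations of 240 birds from 100 founders (16 sires
    x 48 dams, so every sire leaves >= 10 offspring), and the four
    egg-quality traits."""
    plan = [
        ChromosomePlan("chr1", "macro", 3_000_000, 0.40),
        ChromosomePlan("chr2", "macro", 2_500_000, 0.41),
        ChromosomePlan("chr6", "intermediate", 1_500_000, 0.45),
        ChromosomePlan("chr7", "intermediate", 1_200_000, 0.45),
        ChromosomePlan("chr11", "micro", 700_000, 0.52),
        ChromosomePlan("chr12", "micro", 600_000, 0.53),
        ChromosomePlan("chr13", "micro", 500_000, 0.54),
        ChromosomePlan("chrZ", "Z", 2_000_000, 0.40),
    ]
    # egg weight, eggshell colour, eggshell strength, albumen height
    traits = [
        TraitPlan("EW", 0.50, var_p=1.0, mean=60.0),
        TraitPlan("ESC", 0.35, var_p=1.0, mean=25.0),
        TraitPlan("ESS", 0.30, var_p=1.0, mean=40.0),
        TraitPlan("AH", 0.40, var_p=1.0, mean=7.0),
    ]
    return SimConfig(
        seed=seed,
        chromosome_plan=plan,
        trait_plan=traits,
        mating=MatingPlan(16, 48, 5),
        # dense discoverable-variant set (sequence-level), of which
        # panel_fraction form the HD chip
        marker_density=600.0,
    )


# ------------------------------------------------------------------- genome
def simulate_genome(config: SimConfig) -> GenomeAssembly:
    """i.i.d. bases at each chromosome's target GC; deterministic per seed."""
    config.validate()
    rng = _rng(config.seed, "genome")
    seqs, types = {}, {}
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for cp in config.chromosome_plan:
        probs = [(1 - cp.gc) / 2, cp.gc / 2, cp.gc / 2, (1 - cp.gc) / 2]
        idx = rng.choice(4, size=cp.length, p=probs)
        seqs[cp.name] = alphabet[idx].tobytes().decode()
        types[cp.name] = cp.ctype
    return GenomeAssembly(seqs, types)


# ----------------------------------------------------------------- pedigree
UNKNOWN_PARENT = 0


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Multi-generation pedigree; generation 0 founders have unknown parents
    (sentinel 0); each sire serves several dams so some parents have >= 10
    offspring (needed for breeder-subset comparisons)."""
    config.validate()
    m = config.mating
    rows = []
    next_id = 1
    gen_members: list[list[tuple[int, str]]] = []
    founders = []
    for i in range(config.n_founders):
        sex = "M" if i % 2 == 0 else "F"
        rows.append(
            {"id": next_id, "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT, "generation": 0, "sex": sex}
        )
        founders.append((next_id, sex))
        next_id += 1
    gen_members.append(founders)
    for g in range(1, config.generations):
        prev = gen_members[-1]
        males = [i for i, s in prev if s == "M"]
        females = [i for i, s in prev if s == "F"]
        if len(males) < m.n_sires or len(females) < m.n_dams:
            raise ValueError(
                f"infeasible mating plan at generation {g}: need {m.n_sires} sires "
                f"and {m.n_dams} dams, have {len(males)} males / {len(females)} females"
            )
        sires = males[: m.n_sires]
        dams = females[: m.n_dams]
        current = []
        k = 0
        for d_i, dam in enumerate(dams):
            sire = sires[d_i % m.n_sires]
            for _ in range(m.offspring_per_dam):
                sex = "M" if k % 2 == 0 else "F"
                rows.append(
                    {"id": next_id, "sire": sire, "dam": dam, "generation": g, "sex": sex}
                )
                current.append((next_id, sex))
                next_id += 1
                k += 1
        gen_members.append(current)
    return pd.DataFrame(rows)


# ------------------------------------------------- markers & founder haplotypes
def _place_markers(
    genome: GenomeAssembly, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Marker positions: mostly uniform, a configured fraction planted inside
    restriction-enzyme recognition-site matches."""
    enzymes = [ENZYMES[e] for e in config.site_enzymes]
    rows = []
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        n_markers = int(round(config.marker_density * length / 1e6))
        if n_markers > length:
            raise ValueError(f"marker density exceeds available positions on {chrom}")
        n_in_sites = int(round(config.site_variant_rate * n_markers))
        site_pos = []
        if n_in_sites:
            candidates = []
            for enz in enzymes:
                starts = scan_sites(seq, enz)
                if len(starts):
                    offs = rng.integers(0, enz.site_length, size=len(starts))
                    candidates.append(starts + offs)
            if candidates:
                pool = np.unique(np.concatenate(candidates))
                n_take = min(n_in_sites, len(pool))
                site_pos = rng.choice(pool, size=n_take, replace=False)
        n_uniform = n_markers - len(site_pos)
        # drawn in random order, so truncation after removing site positions
        # does not bias toward either chromosome end
        uni = rng.choice(length, size=min(n_uniform + len(site_pos) + 16, length), replace=False)
        uni = uni[~np.isin(uni, site_pos)][:n_uniform]
        pos0 = np.unique(np.concatenate([np.asarray(site_pos, dtype=np.int64), uni]))
        ref = np.array([seq[p] for p in pos0])
        others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        alt = np.array([others[r][rng.integers(3)] for r in ref])
        rows.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom}_{p + 1}" for p in pos0],
                    "chrom": chrom,
                    "pos": pos0 + 1,  # 1-based
                    "ref": ref,
                    "alt": alt,
                }
            )
        )
    markers = pd.concat(rows, ignore_index=True)
    return markers.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_founder_haplotypes(
    genome: GenomeAssembly, config: SimConfig
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Biallelic markers plus founder haplotypes with LD decaying in distance.

    Haplotypes use a copying process: each marker's latent uniform is copied
    from the previous marker with probability 0.3^(d / (2 * ld_decay_bp)) and
    redrawn otherwise; the allele is the indicator (latent < p_marker).  For
    equal-frequency pairs this gives r^2 ~ 0.3 at ``ld_decay_bp`` and a
    geometric decay beyond.  Alt-allele frequencies have MAF ~ U(0.05, 0.5).
    """
    config.validate()
    rng = _rng(config.seed, "markers")
    markers = _place_markers(genome, config, rng)
    hrng = _rng(config.seed, "haplotypes")
    n_hap = 2 * config.n_founders
    haplotypes: dict[str, np.ndarray] = {}
    freqs = np.empty(len(markers))
    for chrom, grp in markers.groupby("chrom", sort=False):
        m = len(grp)
        pos = grp["pos"].to_numpy()
        maf = hrng.uniform(0.05, 0.5, size=m)
        side = hrng.random(m) < 0.5
        p = np.where(side, maf, 1 - maf)
        freqs[grp.index.to_numpy()] = p
        if config.ld_decay_bp > 0:
            copy_prob = 0.3 ** (np.diff(pos) / (2 * config.ld_decay_bp))
        else:
            copy_prob = np.zeros(max(m - 1, 0))
        fresh = hrng.random((n_hap, m))
        redraw = np.ones((n_hap, m), dtype=bool)
        if m > 1:
            redraw[:, 1:] = hrng.random((n_hap, m - 1)) >= copy_prob
        cols = np.arange(m)
        last = np.maximum.accumulate(np.where(redraw, cols, -1), axis=1)
        u = fresh[np.arange(n_hap)[:, None], last]
        alleles = (u < p).astype(np.uint8)
        haplotypes[chrom] = alleles.reshape(config.n_founders, 2, m)
    markers = markers.assign(founder_freq=freqs)
    return haplotypes, markers


# ---------------------------------------------------------------- gene drop
def gene_drop(
    pedigree: pd.DataFrame,
    founder_haplotypes: dict[str, np.ndarray],
    markers: pd.DataFrame,
    recombination_rate: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Drop founder haplotypes down the pedigree with Poisson recombination.

    Each meiosis draws a Poisson(rate * chrom_length) crossover count with
    uniform positions; the transmitted gamete is a mosaic of the parent's two
    haplotypes.  Founders keep their input haplotypes.  Returns, per
    chromosome, a (n_individuals, 2, n_markers) allele array in pedigree row
    order (haplotype 0 = paternal, 1 = maternal).
    """
    if recombination_rate < 0:
        raise ValueError("recombination_rate must be >= 0")
    ids = pedigree["id"].to_numpy()
    row_of = {ind: i for i, ind in enumerate(ids)}
    for rec in pedigree.itertuples(index=False):
        for parent in (rec.sire, rec.dam):
            if parent != UNKNOWN_PARENT:
                if parent not in row_of:
                    raise ValueError(f"missing parent {parent} for {rec.id}")
                if row_of[parent] >= row_of[rec.id]:
                    raise ValueError("pedigree must list parents before offspring")
    rng = _rng(seed, "gene_drop")
    n = len(pedigree)
    out: dict[str, np.ndarray] = {}
    chrom_pos = {
        chrom: grp["pos"].to_numpy() for chrom, grp in markers.groupby("chrom", sort=False)
    }
    founder_rows = pedigree["generation"].to_numpy() == 0
    for chrom, fhap in founder_haplotypes.items():
        m = fhap.shape[2]
        pos = chrom_pos[chrom]
        length = int(pos[-1]) if m else 0
        haps = np.zeros((n, 2, m), dtype=np.uint8)
        f_idx = 0
        for i in range(n):
            if founder_rows[i]:
                haps[i] = fhap[f_idx]
                f_idx += 1
        for rec in pedigree.itertuples(index=False):
            if rec.sire == UNKNOWN_PARENT:
                continue
            i = row_of[rec.id]
            for which, parent in enumerate((rec.sire, rec.dam)):
                par = haps[row_of[parent]]
                n_cross = rng.poisson(recombination_rate * length)
                start = rng.integers(2)
                if n_cross == 0:
                    gamete = par[start]
                else:
                    cuts = np.sort(rng.uniform(0, length, size=n_cross))
                    seg = start + np.searchsorted(cuts, pos)  # segment index per marker
                    gamete = par[seg % 2, np.arange(m)]
                haps[i, which] = gamete
        out[chrom] = haps
    return out


def genotypes_from_haplotypes(
    haplotypes: dict[str, np.ndarray], markers: pd.DataFrame, individuals: list
) -> GenotypeMatrix:
    codes = np.concatenate(
        [haplotypes[chrom].sum(axis=1) for chrom in markers["chrom"].unique()], axis=1
    ).astype(np.int8)
    return GenotypeMatrix(list(individuals), markers, codes)


# ------------------------------------------------------------------- traits
def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    trait_plan: list,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive polygenic traits.

    Per trait: effects ~ N(0,1) at ``n_qtl`` random markers; the true
    breeding value (TBV) is the effect-weighted allele dosage, rescaled to
    variance h2 * var_p; the phenotype adds the trait mean, a batch effect
    (``n_batches`` hatches per generation) and a Normal residual of variance
    (1 - h2) * var_p.  Returns (phenotype records, TBV table).
    """
    rng = _rng(seed, "traits")
    n = genotypes.n_individuals
    gens = pedigree["generation"].to_numpy()
    batch = rng.integers(0, max((tp.n_batches for tp in trait_plan), default=3), size=n)
    pheno_rows = []
    tbv_cols = {}
    for tp in trait_plan:
        if not 0 < tp.h2 < 1 and tp.h2 != 1:
            raise ValueError(f"trait {tp.name}: invalid h2")
        qtl = rng.choice(genotypes.n_markers, size=min(tp.n_qtl, genotypes.n_markers), replace=False)
        effects = rng.normal(0, 1, size=len(qtl))
        raw = genotypes.codes[:, qtl].astype(float) @ effects
        sd = raw.std()
        if sd == 0:
            tbv = np.zeros(n)
        else:
            tbv = (raw - raw.mean()) / sd * np.sqrt(tp.h2 * tp.var_p)
        batch_effects = (
            rng.normal(0, tp.batch_sd, size=tp.n_batches) if tp.batch_sd > 0 else np.zeros(tp.n_batches)
        )
        resid_sd = np.sqrt((1 - tp.h2) * tp.var_p)
        resid = rng.normal(0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)
        pheno = tp.mean + batch_effects[batch % tp.n_batches] + tbv + resid
        tbv_cols[tp.name] = tbv
        pheno_rows.append(
            pd.DataFrame(
                {
                    "individual": genotypes.individuals,
                    "trait": tp.name,
                    "value": pheno,
                    "batch": batch % tp.n_batches,
                    "generation": gens,
                }
            )
        )
    phenotypes = pd.concat(pheno_rows, ignore_index=True)
    tbv_table = pd.DataFrame({"individual": genotypes.individuals, **tbv_cols})
    return phenotypes, tbv_table


# -------------------------------------------------------------------- panel
def sample_hd_panel(markers: pd.DataFrame, panel_fraction: float, seed: int = 0) -> pd.Index:
    """Seed-deterministic subset of marker ids designated 'HD chip' markers."""
    if not 0 < panel_fraction <= 1:
        raise ValueError("panel_fraction must be in (0,1]")
    rng = _rng(seed, "panel")
    n = int(round(panel_fraction * len(markers)))
    if n == 0:
        raise ValueError("panel would be empty")
    idx = np.sort(rng.choice(len(markers), size=n, replace=False))
    return pd.Index(markers["marker_id"].to_numpy()[idx])


# ------------------------------------------------------------------- bundle
@dataclass
class SimOutput:
    """Everything the pipeline needs, with ground truth."""

    config: SimConfig
    genome: GenomeAssembly
    pedigree: pd.DataFrame
    markers: pd.DataFrame
    haplotypes: dict[str, np.ndarray]  # per chrom (n, 2, m), pedigree row order
    genotypes: GenotypeMatrix
    hd_panel: pd.Index
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame


def simulate_all(config: SimConfig) -> SimOutput:
    """Run every stage: genome -> pedigree -> founder haplotypes -> gene drop
    -> genotypes -> traits -> HD panel."""
    config.validate()
    genome = simulate_genome(config)
    pedigree = simulate_pedigree(config)
    founder_haps, markers = simulate_founder_haplotypes(genome, config)
    haplotypes = gene_drop(
        pedigree, founder_haps, markers, config.recombination_rate, seed=config.seed
    )
    genotypes = genotypes_from_haplotypes(haplotypes, markers, list(pedigree["id"]))
    phenotypes, tbv = simulate_traits(genotypes, pedigree, config.trait_plan, seed=config.seed)
    panel = sample_hd_panel(markers, config.panel_fraction, seed=config.seed)
    return SimOutput(
        config=config,
        genome=genome,
        pedigree=pedigree,
        markers=markers,
        haplotypes=haplotypes,
        genotypes=genotypes,
        hd_panel=panel,
        phenotypes=phenotypes,
        true_breeding_values=tbv,
    )
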