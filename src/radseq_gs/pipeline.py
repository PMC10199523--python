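"""End-to-end workflow helpers tying the pipeline stages together.

The canonical experiment: digest the genome with an enzyme (or pair),
size-select, derive paired-end windows, intersect with the variant set and
the HD panel to get the markers a RADseq protocol would genotype, type the
selection candidates at those markers only, impute them back to HD from
the previous generation's haplotypes, score SNP-wise accuracy, and compare
breeding-value rankings between evaluations using true vs imputed HD
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import digest as dg
from .enzymes import EnzymeSpec, get_enzyme
from .evaluate import VarianceComponents, rank_comparison, run_scenarios
from .impute import AccuracyReport, build_library, impute_candidates, snpwise_accuracy
from .overlap import extract_snps_in_windows, overlap_with_panel
from .qc import GenotypeMatrix
from .simulate import SimOutput


def hd_matrix(sim: SimOutput) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Genotypes and phased haplotypes restricted to the HD panel markers."""
    mask = sim.markers["marker_id"].isin(sim.hd_panel).to_numpy()
    hd_markers = sim.markers[mask].reset_index(drop=True)
    hd_haps = {}
    col = 0
    for chrom, grp in sim.markers.groupby("chrom", sort=False):
        m = len(grp)
        hd_haps[chrom] = sim.haplotypes[chrom][:, :, mask[col : col + m]]
        col += m
    gm = GenotypeMatrix(
        list(sim.pedigree["id"]), hd_markers, sim.genotypes.codes[:, mask]
    )
    return gm, hd_haps


def digest_windows(
    sim: SimOutput,
    enzyme: str,
    enzyme2: str | None = None,
    min_bp: int = 200,
    max_bp: int = 500,
    read_length: int = 150,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Digest the simulated genome; returns (all fragments, windows, stats)."""
    e1 = get_enzyme(enzyme)
    if enzyme2 is not None:
        sites1 = dg.scan_genome(sim.genome, [e1])
        sites2 = dg.scan_genome(sim.genome, [get_enzyme(enzyme2)])
        fragments = dg.build_fragments_double(sites1, sites2)
    else:
        fragments = dg.build_fragments_single(dg.scan_genome(sim.genome, [e1]))
    selected = dg.size_select(fragments, min_bp, max_bp)
    windows = dg.make_windows(selected, read_length)
    stats = dg.fragment_stats(fragments, sim.genome, min_bp, max_bp)
    return fragments, windows, stats


def detected_panel_markers(
    sim: SimOutput, windows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(all detected markers, detected-and-on-HD-panel markers)."""
    detected = extract_snps_in_windows(sim.markers, windows)
    on_panel = detected[detected["marker_id"].isin(sim.hd_panel)].reset_index(drop=True)
    return detected, on_panel


def density_subset(hd_gm: GenotypeMatrix, fraction: float, seed: int = 0) -> pd.Index:
    """Random fraction of HD marker ids (for panel-density sweeps)."""
    rng = np.random.default_rng(seed)
    n = max(2, int(round(fraction * hd_gm.n_markers)))
    idx = np.sort(rng.choice(hd_gm.n_markers, size=n, replace=False))
    return pd.Index(hd_gm.markers["marker_id"].to_numpy()[idx])


@dataclass
class ImputationExperiment:
    typed_marker_ids: pd.Index
    imputed: GenotypeMatrix
    truth: GenotypeMatrix
    accuracy: AccuracyReport


def impute_generation(
    sim: SimOutput,
    typed_marker_ids,
    reference_generation: int = 0,
    candidate_generation: int = 1,
    window_sizes: tuple[int, ...] = (64, 32, 16, 8),
) -> ImputationExperiment:
    """Type candidates at ``typed_marker_ids`` only, impute back to HD from
    the reference generation's haplotype library, and score accuracy."""
    hd_gm, hd_haps = hd_matrix(sim)
    gens = sim.pedigree["generation"].to_numpy()
    ref_mask = gens == reference_generation
    cand_mask = gens == candidate_generation
    ref = hd_gm.subset_individuals(ref_mask)
    lib = build_library(ref, {c: h[ref_mask] for c, h in hd_haps.items()})
    typed = hd_gm.markers["marker_id"].isin(typed_marker_ids).to_numpy()
    if typed.sum() < 2:
        raise ValueError("need at least 2 typed markers on the HD panel")
    cand = GenotypeMatrix(
        [i for i, k in zip(hd_gm.individuals, cand_mask) if k],
        hd_gm.markers[typed].reset_index(drop=True),
        hd_gm.codes[cand_mask][:, typed],
    )
    imputed = impute_candidates(cand, lib, sim.pedigree, window_sizes)
    truth = hd_gm.subset_individuals(cand_mask)
    accuracy = snpwise_accuracy(truth, imputed, sim.genome.chrom_types)
    return ImputationExperiment(
        typed_marker_ids=pd.Index(typed_marker_ids),
        imputed=imputed,
        truth=truth,
        accuracy=accuracy,
    )


def default_varcomps(sim: SimOutput) -> dict[str, VarianceComponents]:
    """True simulation variance components per trait (sigma2_u = h2 var_p)."""
    return {
        tp.name: VarianceComponents(tp.h2 * tp.var_p, (1 - tp.h2) * tp.var_p)
        for tp in sim.config.trait_plan
    }


def evaluation_experiment(
    sim: SimOutput,
    imputed: GenotypeMatrix,
    varcomps: dict[str, VarianceComponents] | None = None,
    K: int = 150,
    min_offspring: int = 10,
    candidate_generation: int = 1,
) -> dict:
    """Run the three evaluation scenarios and the per-trait ranking
    comparisons (Ancestry_true vs Ancestry_imputed, and Full_HD vs
    Ancestry_imputed for the relative-accuracy Pearson)."""
    if varcomps is None:
        varcomps = default_varcomps(sim)
    hd_gm, _ = hd_matrix(sim)
    gebv = run_scenarios(
        sim.pedigree, sim.phenotypes, hd_gm, imputed, varcomps,
        candidate_generation=candidate_generation,
    )
    cand_ids = sim.pedigree.loc[
        sim.pedigree["generation"] == candidate_generation, "id"
    ]
    out = {"gebv": gebv, "per_trait": {}}
    for trait in varcomps:
        pivot = gebv[gebv["trait"] == trait].pivot(
            index="individual", columns="scenario", values="gebv"
        ).loc[cand_ids]
        rc = rank_comparison(
            pivot["Ancestry_true"], pivot["Ancestry_imputed"], sim.pedigree,
            K=K, min_offspring=min_offspring,
        )
        rc_full = rank_comparison(
            pivot["Full_HD"], pivot["Ancestry_imputed"], sim.pedigree,
            K=K, min_offspring=min_offspring,
        )
        out["per_trait"][trait] = {
            "ancestry_true_vs_imputed": rc,
            "full_hd_vs_imputed": rc_full,
        }
    return out
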