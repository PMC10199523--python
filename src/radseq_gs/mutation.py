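"""Impact of sequence variants on restriction sites and predicted fragments.

A polymorphism inside a recognition site can destroy it (the enzyme no
longer cuts, merging two fragments) and a substitution elsewhere can create
a new site (splitting a fragment).  Both perturb the predicted fragment and
SNP lists and, on real data, drive allele dropout.  This module quantifies
the perturbation by rescanning an alternate-allele-substituted genome and
rebuilding fragments from the adjusted site lists.

All alternate alleles are applied jointly before rescanning, so nearby
variants within one recognition site are evaluated together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import build_fragments_double, build_fragments_single, size_select
from .enzymes import EnzymeSpec
from .genome import GenomeAssembly
from .digest import scan_sites


@dataclass
class SiteDelta:
    """Sites destroyed/created by variants, per chromosome, for one enzyme.

    Under ``het_mode='destroy'`` (the default) a site overlapped by a
    variant whose alternate allele breaks the match is counted destroyed —
    the allele-dropout-pessimistic reading, where the alternate haplotype's
    fragments are the ones observed.  Under ``het_mode='keep'`` reference
    sites are retained (the reference haplotype still cuts) and only
    creations are counted.
    """

    enzyme: str
    destroyed: dict[str, np.ndarray] = field(default_factory=dict)
    created: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_destroyed(self) -> int:
        return int(sum(len(v) for v in self.destroyed.values()))

    @property
    def n_created(self) -> int:
        return int(sum(len(v) for v in self.created.values()))

    def inverse(self) -> "SiteDelta":
        """Swap destroyed and created (applying delta then inverse restores
        the original site list)."""
        return SiteDelta(self.enzyme, dict(self.created), dict(self.destroyed))

    def to_dict(self) -> dict:
        return {
            "enzyme": self.enzyme,
            "n_destroyed": self.n_destroyed,
            "n_created": self.n_created,
        }


def _substitute(seq: str, pos0: np.ndarray, alt: list[str]) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    arr[pos0] = [a.encode() for a in alt]
    return arr.tobytes().decode()


def apply_variants(genome: GenomeAssembly, variants: pd.DataFrame) -> GenomeAssembly:
    """Alternate-allele-substituted genome (SNVs only; homozygous-alt model).

    Non-SNV records are rejected with a warning; out-of-bounds positions
    raise.  Positions are 1-based as in VCF.
    """
    snv = (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)
    if not snv.all():
        warnings.warn(f"{int((~snv).sum())} non-SNV variants rejected")
        variants = variants[snv]
    seqs = {}
    for chrom, seq in genome.sequences.items():
        v = variants[variants["chrom"] == chrom]
        if v.empty:
            seqs[chrom] = seq
            continue
        pos0 = v["pos"].to_numpy() - 1
        if (pos0 < 0).any() or (pos0 >= len(seq)).any():
            raise IndexError(f"variant position out of bounds on {chrom}")
        seqs[chrom] = _substitute(seq, pos0, list(v["alt"]))
    return GenomeAssembly(seqs, dict(genome.chrom_types))


def site_deltas(
    genome: GenomeAssembly,
    variants: pd.DataFrame,
    enzyme: EnzymeSpec,
    het_mode: str = "destroy",
) -> SiteDelta:
    """Sites destroyed/created by the variant set for one enzyme.

    Counting is per site on the pooled variant set: a reference site that no
    longer matches on the substituted sequence is destroyed; a position that
    matches only on the substituted sequence is created.
    """
    if het_mode not in ("destroy", "keep"):
        raise ValueError("het_mode must be 'destroy' or 'keep'")
    mutated = apply_variants(genome, variants)
    delta = SiteDelta(enzyme.name)
    for chrom in genome.chroms:
        ref_sites = set(scan_sites(genome.sequences[chrom], enzyme).tolist())
        alt_sites = set(scan_sites(mutated.sequences[chrom], enzyme).tolist())
        destroyed = np.array(sorted(ref_sites - alt_sites), dtype=np.int64)
        created = np.array(sorted(alt_sites - ref_sites), dtype=np.int64)
        if het_mode == "keep":
            destroyed = destroyed[:0]
        if len(destroyed):
            delta.destroyed[chrom] = destroyed
        if len(created):
            delta.created[chrom] = created
    return delta


def _apply_delta(sites: pd.DataFrame, delta: SiteDelta) -> pd.DataFrame:
    """(reference sites - destroyed) union created, re-sorted, one enzyme."""
    mine = sites[sites["enzyme"] == delta.enzyme]
    out = []
    chroms = set(mine["chrom"]) | set(delta.created)
    for chrom in chroms:
        starts = set(mine.loc[mine["chrom"] == chrom, "start"].tolist())
        starts -= set(np.asarray(delta.destroyed.get(chrom, ())).tolist())
        starts |= set(np.asarray(delta.created.get(chrom, ())).tolist())
        out.append(
            pd.DataFrame(
                {"chrom": chrom, "start": sorted(starts), "enzyme": delta.enzyme}
            )
        )
    if not out:
        return mine.iloc[:0]
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def rebuild_fragments_with_mutations(
    reference_sites: pd.DataFrame,
    deltas: list[SiteDelta],
    size_min: int | None = None,
    size_max: int | None = None,
) -> pd.DataFrame:
    """Fragment table after applying site deltas, using the same single- or
    double-digest rules as the reference (inferred from the enzyme count)."""
    known = set(reference_sites["enzyme"].unique())
    for d in deltas:
        if d.enzyme not in known:
            raise ValueError(f"delta enzyme {d.enzyme} not among reference enzymes")
    by_enzyme = {}
    for enz in known:
        delta = next((d for d in deltas if d.enzyme == enz), SiteDelta(enz))
        by_enzyme[enz] = _apply_delta(reference_sites, delta)
    enzymes = sorted(by_enzyme)
    if len(enzymes) == 1:
        frags = build_fragments_single(by_enzyme[enzymes[0]])
    elif len(enzymes) == 2:
        frags = build_fragments_double(by_enzyme[enzymes[0]], by_enzyme[enzymes[1]])
    else:
        raise ValueError("expected sites for one or two enzymes")
    if size_min is not None or size_max is not None:
        frags = size_select(
            frags, size_min if size_min is not None else 0, size_max
            if size_max is not None else np.iinfo(np.int64).max
        )
    return frags


@dataclass
class FragmentComparison:
    """Shared/unique fragment counts between a reference prediction and a
    mutation-aware one, plus (optionally) the analogous SNP-list counts."""

    n_shared: int
    n_only_reference: int
    n_only_mutated: int
    n_shared_snps: int | None = None
    n_shared_snps_with_panel: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def compare_fragment_tables(
    reference: pd.DataFrame,
    mutated: pd.DataFrame,
    markers: pd.DataFrame | None = None,
    panel_keys: set | None = None,
    read_length: int = 150,
) -> FragmentComparison:
    """Match fragments on exact (chrom, start, end, left_enzyme, right_enzyme).

    If ``markers`` is given, the paired-end windows of each table are used to
    extract SNP lists and the shared SNP count (and, with ``panel_keys``,
    the shared-with-panel count) is reported as well.
    """
    key_cols = ["chrom", "start", "end", "left_enzyme", "right_enzyme"]
    ref_keys = set(map(tuple, reference[key_cols].itertuples(index=False)))
    mut_keys = set(map(tuple, mutated[key_cols].itertuples(index=False)))
    shared = ref_keys & mut_keys
    cmp = FragmentComparison(
        n_shared=len(shared),
        n_only_reference=len(ref_keys - mut_keys),
        n_only_mutated=len(mut_keys - ref_keys),
    )
    if markers is not None:
        from .digest import make_windows
        from .overlap import extract_snps_in_windows

        snps_ref = extract_snps_in_windows(markers, make_windows(reference, read_length))
        snps_mut = extract_snps_in_windows(markers, make_windows(mutated, read_length))
        kr = set(zip(snps_ref["chrom"], snps_ref["pos"]))
        km = set(zip(snps_mut["chrom"], snps_mut["pos"]))
        both = kr & km
        cmp.n_shared_snps = len(both)
        if panel_keys is not None:
            cmp.n_shared_snps_with_panel = len(both & set(panel_keys))
    return cmp
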