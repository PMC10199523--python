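"""Overlap of predicted sequencing windows with variants and a SNP panel.

Markers use 1-based VCF positions; windows are 0-based half-open BED
intervals, so a marker at position p falls in window [s, e) iff s < p <= e.
Marker identity for panel overlap is (chrom, pos).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genome import GenomeAssembly

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def extract_snps_in_windows(markers: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Markers covered by at least one window, each reported once.

    A marker covered by both paired-end reads of a fragment (overlapping
    windows of a short fragment) still appears once.
    """
    keep = np.zeros(len(markers), dtype=bool)
    for chrom, wgrp in windows.groupby("chrom", sort=False):
        sel = markers["chrom"] == chrom
        if not sel.any():
            continue
        s, e = _merge_intervals(
            wgrp["win_start"].to_numpy(), wgrp["win_end"].to_numpy()
        )
        flat = np.empty(2 * len(s), dtype=np.int64)
        flat[0::2], flat[1::2] = s, e
        pos0 = markers.loc[sel, "pos"].to_numpy() - 1  # 0-based
        inside = np.searchsorted(flat, pos0, side="right") % 2 == 1
        keep[np.flatnonzero(sel.to_numpy())[inside]] = True
    return markers[keep].reset_index(drop=True)


@dataclass
class OverlapReport:
    """Counts and proportion of detected SNPs shared with the chip panel."""

    n_detected: int
    n_panel: int
    n_shared: int
    proportion_shared_of_detected: float  # percent, 2 decimals
    snp_per_mb_by_type: pd.DataFrame | None = None
    inter_snp_distance_by_type: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "n_detected": self.n_detected,
            "n_panel": self.n_panel,
            "n_shared": self.n_shared,
            "proportion_shared_of_detected": self.proportion_shared_of_detected,
        }
        if self.snp_per_mb_by_type is not None:
            d["snp_per_mb_by_type"] = self.snp_per_mb_by_type.to_dict("records")
        if self.inter_snp_distance_by_type is not None:
            d["inter_snp_distance_by_type"] = self.inter_snp_distance_by_type.to_dict(
                "records"
            )
        return d


def shared_proportion(n_detected: int, n_shared: int) -> float:
    """100 * n_shared / n_detected, half-up to 2 decimals."""
    if n_detected == 0:
        return 0.0
    pct = Decimal(100 * n_shared) / Decimal(n_detected)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def overlap_with_panel(
    detected: pd.DataFrame, panel: pd.DataFrame | set
) -> OverlapReport:
    """Intersect detected markers with the chip panel by (chrom, pos).

    ``panel`` may be a marker table or a set of (chrom, pos) tuples.
    """
    det_keys = set(zip(detected["chrom"], detected["pos"]))
    if isinstance(panel, pd.DataFrame):
        panel_keys = set(zip(panel["chrom"], panel["pos"]))
    else:
        panel_keys = set(panel)
    shared = det_keys & panel_keys
    return OverlapReport(
        n_detected=len(det_keys),
        n_panel=len(panel_keys),
        n_shared=len(shared),
        proportion_shared_of_detected=shared_proportion(len(det_keys), len(shared)),
    )


def snp_density_by_type(
    markers: pd.DataFrame, genome: GenomeAssembly
) -> pd.DataFrame:
    """Per chromosome type: mean +/- sample sd (across chromosomes) of
    SNP count per Mb.  The single Z chromosome is reported with sd NaN."""
    rows = []
    for chrom in genome.chroms:
        length = genome.length(chrom)
        if length == 0:
            raise ValueError(f"zero-length chromosome {chrom}")
        n = int((markers["chrom"] == chrom).sum())
        rows.append(
            {
                "chrom": chrom,
                "type": genome.chrom_type(chrom),
                "snp_per_mb": n / (length / 1e6),
            }
        )
    per_chrom = pd.DataFrame(rows)
    per_type = (
        per_chrom.groupby("type")["snp_per_mb"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else float("nan"))
        .reset_index()
    )
    return per_type


def inter_snp_distances(
    markers: pd.DataFrame, chrom_type_map: dict[str, str]
) -> pd.DataFrame:
    """Per chromosome type: mean of per-chromosome mean consecutive-marker
    distances (kb) +/- sample sd across chromosomes.

    Chromosomes with fewer than 2 markers are skipped (nothing to difference)
    and never cross-chromosome distances are formed.
    """
    import warnings

    rows = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        if len(grp) < 2:
            warnings.warn(f"chromosome {chrom} has <2 markers; skipped")
            continue
        pos = np.sort(grp["pos"].to_numpy())
        rows.append(
            {
                "chrom": chrom,
                "type": chrom_type_map[chrom],
                "mean_distance_kb": float(np.mean(np.diff(pos)) / 1e3),
            }
        )
    per_chrom = pd.DataFrame(rows, columns=["chrom", "type", "mean_distance_kb"])
    if per_chrom.empty:
        return pd.DataFrame(columns=["type", "mean_kb", "sd_kb"])
    return (
        per_chrom.groupby("type")["mean_distance_kb"]
        .agg(
            mean_kb="mean",
            sd_kb=lambda x: x.std(ddof=1) if len(x) > 1 else float("nan"),
        )
        .reset_index()
    )


def required_fragment_count(genome_size_bp: float, ld_extent_bp: float) -> int:
    """Fragments needed for genome-wide tagging: genome size divided by the
    useful-LD extent, rounded to the nearest integer."""
    if genome_size_bp <= 0 or ld_extent_bp <= 0:
        raise ValueError("genome size and LD extent must be positive")
    return int(np.floor(genome_size_bp / ld_extent_bp + 0.5))
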