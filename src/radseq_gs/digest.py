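"""In silico restriction digestion.

Implements the genome-reduction prediction used by single-enzyme (GGRS-style)
and double-enzyme (ddRADseq-style) protocols: scan recognition sites, build
fragments between consecutive sites, select fragments by size, and derive the
two 150 bp paired-end sequencing windows per selected fragment.

Coordinate conventions
----------------------
Site positions are 0-based starts of the recognition match.  A fragment runs
from the start of its left site to the start of its right site (0-based
half-open), so ``size = end - start``; read-1 covers the first ``read_length``
bases of the fragment and read-2 the last ``read_length`` bases.  Terminal
chromosome segments (before the first site / after the last) are not
fragments: a sequenceable fragment needs an enzyme site at both ends.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .enzymes import IUPAC, EnzymeSpec
from .genome import GenomeAssembly

FRAGMENT_COLUMNS = ["chrom", "start", "end", "left_enzyme", "right_enzyme", "size"]
WINDOW_COLUMNS = ["chrom", "win_start", "win_end", "fragment_id", "read"]


def _site_regex(enzyme: EnzymeSpec) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(f"[{IUPAC[c]}]" for c in enzyme.recognition)
    return re.compile(f"(?={body})")


def scan_sites(sequence: str, enzyme: EnzymeSpec) -> np.ndarray:
    """All 0-based start positions where ``sequence`` matches the enzyme's
    recognition pattern, overlapping matches included.

    Scanning is case-insensitive; ``N`` bases never match any code.
    """
    seq = sequence.upper()
    rx = _site_regex(enzyme)
    return np.fromiter((m.start() for m in rx.finditer(seq)), dtype=np.int64)


def scan_genome(
    genome: GenomeAssembly, enzymes: list[EnzymeSpec] | tuple[EnzymeSpec, ...]
) -> pd.DataFrame:
    """Site table (chrom, start, enzyme) over all chromosomes, sorted."""
    rows = []
    for chrom, seq in genome.sequences.items():
        for enz in enzymes:
            starts = scan_sites(seq, enz)
            rows.append(
                pd.DataFrame({"chrom": chrom, "start": starts, "enzyme": enz.name})
            )
    sites = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "enzyme"]
    )
    return sites.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def build_fragments_single(sites: pd.DataFrame) -> pd.DataFrame:
    """Fragments between consecutive sites of one enzyme: k sites -> k-1
    fragments per chromosome."""
    out = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        starts = np.sort(grp["start"].to_numpy())
        if len(starts) < 2:
            continue
        enz = grp["enzyme"].iloc[0]
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[:-1],
                    "end": starts[1:],
                    "left_enzyme": enz,
                    "right_enzyme": enz,
                    "size": np.diff(starts),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return pd.concat(out, ignore_index=True)


def build_fragments_double(sites_a: pd.DataFrame, sites_b: pd.DataFrame) -> pd.DataFrame:
    """ddRADseq fragments: consecutive site pairs with *different* flanking
    enzymes after merging both site lists; same-enzyme pairs are unusable and
    dropped."""
    ea = set(sites_a["enzyme"].unique())
    eb = set(sites_b["enzyme"].unique())
    if ea & eb:
        raise ValueError(f"double digest requires two distinct enzymes, got {ea & eb}")
    merged = pd.concat([sites_a, sites_b], ignore_index=True)
    out = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="mergesort")
        starts = grp["start"].to_numpy()
        enz = grp["enzyme"].to_numpy()
        if len(starts) < 2:
            continue
        keep = enz[:-1] != enz[1:]
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[:-1][keep],
                    "end": starts[1:][keep],
                    "left_enzyme": enz[:-1][keep],
                    "right_enzyme": enz[1:][keep],
                    "size": (starts[1:] - starts[:-1])[keep],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return pd.concat(out, ignore_index=True)


def size_select(
    fragments: pd.DataFrame, min_bp: int = 200, max_bp: int = 500
) -> pd.DataFrame:
    """Retain fragments with min_bp <= size <= max_bp (inclusive bounds)."""
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    mask = (fragments["size"] >= min_bp) & (fragments["size"] <= max_bp)
    return fragments[mask].reset_index(drop=True)


def make_windows(fragments: pd.DataFrame, read_length: int = 150) -> pd.DataFrame:
    """Two paired-end windows per fragment: read-1 = first ``read_length``
    bases, read-2 = last ``read_length`` bases (they overlap when the
    fragment is shorter than ``2 * read_length``)."""
    if len(fragments) and (fragments["size"] < read_length).any():
        raise ValueError(
            f"fragments shorter than read_length={read_length} present; "
            "apply size selection first"
        )
    frag_id = np.arange(len(fragments))
    r1 = pd.DataFrame(
        {
            "chrom": fragments["chrom"].to_numpy(),
            "win_start": fragments["start"].to_numpy(),
            "win_end": fragments["start"].to_numpy() + read_length,
            "fragment_id": frag_id,
            "read": 1,
        }
    )
    r2 = pd.DataFrame(
        {
            "chrom": fragments["chrom"].to_numpy(),
            "win_start": fragments["end"].to_numpy() - read_length,
            "win_end": fragments["end"].to_numpy(),
            "fragment_id": frag_id,
            "read": 2,
        }
    )
    win = pd.concat([r1, r2], ignore_index=True)
    return win.sort_values(
        ["chrom", "win_start", "win_end"], kind="mergesort"
    ).reset_index(drop=True)


def window_percentage(n_total: int, n_selected: int) -> float:
    """Percentage of fragments in the size window, half-up to 2 decimals."""
    if n_total == 0:
        return 0.0
    pct = Decimal(100 * n_selected) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fragment_stats(
    fragments: pd.DataFrame,
    genome: GenomeAssembly,
    size_min: int = 200,
    size_max: int = 500,
) -> dict:
    """Fragment-count summaries: overall totals and size-window percentage,
    per-chromosome in-window count and count/Mb, and per-chromosome-type
    mean +/- sd of count/Mb.

    The per-type sd is the sample sd (n-1) across chromosomes of the type;
    a singleton class (e.g. the single Z) is reported with sd 0.
    """
    unknown = set(fragments["chrom"]) - set(genome.chroms)
    if unknown:
        raise KeyError(f"fragments reference unknown chromosomes: {sorted(unknown)}")
    selected = size_select(fragments, size_min, size_max)
    per_chrom = []
    for chrom in genome.chroms:
        n = int((selected["chrom"] == chrom).sum())
        mb = genome.length(chrom) / 1e6
        per_chrom.append(
            {
                "chrom": chrom,
                "type": genome.chrom_type(chrom) if genome.chrom_types else "",
                "n_fragments": n,
                "per_mb": n / mb,
            }
        )
    per_chrom = pd.DataFrame(per_chrom)
    if genome.chrom_types:
        per_type = (
            per_chrom.groupby("type")["per_mb"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
            .reset_index()
        )
    else:
        per_type = pd.DataFrame(columns=["type", "mean", "sd"])
    return {
        "total_fragments": int(len(fragments)),
        "selected_fragments": int(len(selected)),
        "percent_selected": window_percentage(len(fragments), len(selected)),
        "per_chrom": per_chrom,
        "per_type": per_type,
    }
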