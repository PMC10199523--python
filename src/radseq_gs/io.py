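"""File interchange: VCF, BED, FASTA and the delimited tables.

VCF is read through pysam; writing uses a small text emitter (plain,
uncompressed VCF 4.2 with GT-only FORMAT, phased ``|`` separators when
haplotypes are known).  Windows go to 6-column BED; fragments, pedigree,
phenotypes and panel lists are plain delimited text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------- VCF
def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    haplotypes: dict[str, np.ndarray] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write genotypes (and phased haplotypes when given) as VCF.

    With ``haplotypes`` (per chrom, (n, 2, m) aligned to ``gm``), GT fields
    are phased ``a|b``; otherwise unphased codes 0/0, 0/1, 1/1 or ./. .
    """
    markers = gm.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in markers["chrom"].unique():
            length = (contig_lengths or {}).get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(str(i) for i in gm.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        if haplotypes is not None:
            offsets = {}
            col = 0
            for chrom, grp in markers.groupby("chrom", sort=False):
                offsets[chrom] = col
                col += len(grp)
        for j, rec in enumerate(markers.itertuples(index=False)):
            if haplotypes is not None:
                local = j - offsets[rec.chrom]
                h = haplotypes[rec.chrom][:, :, local]
                gts = [f"{a}|{b}" for a, b in h]
            else:
                code_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code_map[int(c)] for c in gm.codes[:, j]]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.marker_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, dict[str, np.ndarray] | None]:
    """Read a VCF into a GenotypeMatrix (+ haplotypes if fully phased)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, codes, phased_alleles = [], [], []
    all_phased = True
    for rec in vf:
        rows.append(
            {
                "marker_id": rec.id or f"{rec.chrom}_{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
        )
        row_codes, row_haps = [], []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                row_codes.append(MISSING)
                row_haps.append((0, 0))
                all_phased = False
            else:
                row_codes.append(sum(gt))
                row_haps.append(tuple(gt))
                if not rec.samples[s].phased:
                    all_phased = False
        codes.append(row_codes)
        phased_alleles.append(row_haps)
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(samples, markers, np.array(codes, dtype=np.int8).T)
    haplotypes = None
    if all_phased and len(markers):
        haplotypes = {}
        hap_arr = np.array(phased_alleles, dtype=np.uint8)  # (m, n, 2)
        col = 0
        for chrom, grp in markers.groupby("chrom", sort=False):
            m = len(grp)
            haplotypes[chrom] = hap_arr[col : col + m].transpose(1, 2, 0)
            col += m
    return gm, haplotypes


# ---------------------------------------------------------------------- BED
def write_windows_bed(path: str | Path, windows: pd.DataFrame) -> None:
    """6-column BED: name = fragment_id/read, score = window length."""
    df = pd.DataFrame(
        {
            "chrom": windows["chrom"],
            "start": windows["win_start"],
            "end": windows["win_end"],
            "name": windows["fragment_id"].astype(str) + "/" + windows["read"].astype(str),
            "score": windows["win_end"] - windows["win_start"],
            "strand": ".",
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_windows_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "win_start", "win_end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    parts = df["name"].astype(str).str.split("/", expand=True)
    df["fragment_id"] = pd.to_numeric(parts[0], errors="coerce").fillna(-1).astype(int)
    df["read"] = pd.to_numeric(parts[1], errors="coerce").fillna(0).astype(int)
    return df[["chrom", "win_start", "win_end", "fragment_id", "read"]]


# ------------------------------------------------------------------- tables
def write_fragments(path: str | Path, fragments: pd.DataFrame) -> None:
    fragments.to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_pedigree(path: str | Path, pedigree: pd.DataFrame) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phenotypes(path: str | Path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panel(path: str | Path, panel) -> None:
    Path(path).write_text("\n".join(str(m) for m in panel) + "\n")


def read_panel(path: str | Path) -> pd.Index:
    return pd.Index(Path(path).read_text().split())


def read_markers_table(path: str | Path) -> pd.DataFrame:
    """Markers from a 4/5-column TSV (marker_id, chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "marker_id" not in df.columns:
        df.insert(0, "marker_id", df["chrom"].astype(str) + "_" + df["pos"].astype(str))
    return df
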