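"""Genome container: named chromosome sequences with size-class labels.

Chicken-style genomes partition chromosomes into macro, intermediate and
micro size classes plus the Z sex chromosome; the classes differ in length,
GC content and (downstream) restriction-site density, so most summaries in
this package are reported per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CHROM_TYPES = ("macro", "intermediate", "micro", "Z")


@dataclass
class GenomeAssembly:
    """Chromosome sequences plus a chromosome-type map.

    ``sequences`` maps chromosome name -> uppercase DNA string over
    {A,C,G,T,N}; ``chrom_types`` maps name -> one of ``CHROM_TYPES``.
    """

    sequences: dict[str, str]
    chrom_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        for c, t in self.chrom_types.items():
            if t not in CHROM_TYPES:
                raise ValueError(f"unknown chromosome type {t!r} for {c}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def gc_content(self, chrom: str) -> float:
        s = self.sequences[chrom]
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt

    def chrom_type(self, chrom: str) -> str:
        try:
            return self.chrom_types[chrom]
        except KeyError:
            raise KeyError(f"no type label for chromosome {chrom!r}") from None

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path: str | Path, line_width: int = 60) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(
        cls, path: str | Path, chrom_type_map: dict[str, str] | None = None
    ) -> "GenomeAssembly":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, chrom_type_map or {})

    def write_type_map(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": list(self.chrom_types), "type": list(self.chrom_types.values())}
        ).to_csv(path, sep="\t", index=False)


def read_type_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["chrom"], df["type"]))
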