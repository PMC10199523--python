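"""Restriction enzyme definitions and IUPAC pattern utilities.

Recognition sequences may use IUPAC degeneracy codes (e.g. ``GGWCC`` where
W = A or T).  Only enzymes whose recognition set is closed under reverse
complementation are accepted, because the digestion scanner reads the
forward strand only: for a closed set, every site on the reverse strand is
also a site on the forward strand, so one scan finds them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def allowed_bases(code: str) -> set[str]:
    """Concrete bases matched by one IUPAC code."""
    try:
        return set(IUPAC[code.upper()])
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def is_rc_closed(pattern: str) -> bool:
    """True if the set of concrete sequences matching ``pattern`` equals the
    set of their reverse complements.

    A product-of-sets pattern is closed iff, position by position, the
    allowed set at position i equals the complement of the allowed set at
    the mirrored position.
    """
    pattern = pattern.upper()
    n = len(pattern)
    for i in range(n):
        left = allowed_bases(pattern[i])
        right = {b.translate(_COMPLEMENT) for b in allowed_bases(pattern[n - 1 - i])}
        if left != right:
            return False
    return True


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: name, IUPAC recognition sequence, and a free-text
    methylation-sensitivity note (metadata only; methylation is not simulated).
    """

    name: str
    recognition: str
    methylation_note: str = ""

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        for c in self.recognition:
            allowed_bases(c)  # raises on invalid code
        if not is_rc_closed(self.recognition):
            raise ValueError(
                f"recognition sequence {self.recognition!r} for {self.name} is not "
                "reverse-complement closed; forward-strand scanning would miss "
                "reverse-strand sites. Supply both strand patterns as two enzymes."
            )
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def site_length(self) -> int:
        return len(self.recognition)


#: The four enzymes used in the layer-chicken genome-reduction study.
ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("AvaII", "GGWCC", "CpG and dcm methylation"),
        EnzymeSpec("EcoRI", "GAATTC", "CpG methylation"),
        EnzymeSpec("PstI", "CTGCAG", "Not sensitive"),
        EnzymeSpec("TaqI", "TCGA", "dam methylation"),
    )
}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins are {sorted(ENZYMES)}"
        ) from None
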