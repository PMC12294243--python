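"""Amino-acid codes and protein-change notation.

Variants are handled purely at the protein level in 1-based UniProt
numbering; nonsense changes (alt = stop) are representable but are flagged
so missense-only analyses can exclude them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AA1 = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}


class ProteinChangeError(ValueError):
    """Raised for malformed or inconsistent protein-change notation."""


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A single amino-acid substitution, e.g. V133A or Y98* (nonsense)."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1:
            raise ProteinChangeError(f"unknown reference residue {self.ref_aa!r}")
        if self.alt_aa not in AA1 and self.alt_aa != STOP:
            raise ProteinChangeError(f"unknown alternate residue {self.alt_aa!r}")
        if self.position < 1:
            raise ProteinChangeError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ProteinChangeError(f"reference and alternate residues both {self.ref_aa!r}")

    @property
    def is_nonsense(self) -> bool:
        return self.alt_aa == STOP

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


_COMPACT = re.compile(r"^([A-Za-z])(\d+)([A-Za-z*])$")
_THREE = re.compile(r"^p\.\(?([A-Za-z]{3})(\d+)([A-Za-z]{3}|\*)\)?$")


def parse_protein_change(text: str) -> ProteinChange:
    """Parse compact one-letter ("V133A", stop as "X" or "*") or
    three-letter "p.Val133Ala" notation into a :class:`ProteinChange`."""
    token = text.strip()
    if not token:
        raise ProteinChangeError("empty protein-change string")
    m = _COMPACT.match(token)
    if m:
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if alt == "X":  # clinical shorthand for a stop gain
            alt = STOP
        if pos == 0:
            raise ProteinChangeError(f"position 0 in {token!r}")
        return ProteinChange(ref, pos, alt)
    m = _THREE.match(token)
    if m:
        ref3, pos, alt3 = m.group(1).capitalize(), int(m.group(2)), m.group(3)
        alt3 = STOP if alt3 == "*" else alt3.capitalize()
        if ref3 not in AA3TO1:
            raise ProteinChangeError(f"unknown residue code {ref3!r} in {token!r}")
        if alt3 != STOP and alt3 not in AA3TO1:
            raise ProteinChangeError(f"unknown residue code {alt3!r} in {token!r}")
        return ProteinChange(AA3TO1[ref3], pos, alt3 if alt3 == STOP else AA3TO1[alt3])
    raise ProteinChangeError(f"malformed protein change {token!r}")
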