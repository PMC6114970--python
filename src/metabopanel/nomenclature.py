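"""Parser/formatter for panel metabolite nomenclature.

Lipid names follow the kit convention: ``PC aa Cx:y`` / ``PC ae Cx:y``
for diacyl and acyl-alkyl phosphatidylcholines (two letters mean both
glycerol positions carry a residue, aa = diacyl, ae = acyl-alkyl),
``lysoPC a Cx:y`` for single-residue species, ``SM Cx:y`` /
``SM (OH) Cx:y`` for sphingomyelins, and ``Cx:y`` with optional ``-OH``
(hydroxyl), ``-DC`` (dicarboxyl) and ``-M`` (methyl) suffixes for
acylcarnitines.  x counts acyl carbons and y double bonds.

Amino acids, biogenic amines, the hexoses channel and the energy
metabolites are plain tokens looked up in the roster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import _roster

__all__ = [
    "LipidName",
    "AnalyteToken",
    "MetaboliteNameError",
    "parse_metabolite_name",
]


class MetaboliteNameError(ValueError):
    """Raised for names that do not follow the panel nomenclature."""


_TOKEN_CLASS = {
    name: _roster.CLASS_OF[name]
    for name in (
        _roster.AMINO_ACIDS
        + _roster.BIOGENIC_AMINES
        + _roster.HEXOSES
        + _roster.ENERGY
    )
}

_AC_RE = re.compile(r"^C(\d+)(?::(\d+))?(-M)?(-OH)?(-DC)?$")
_PC_RE = re.compile(r"^PC (aa|ae) C(\d+):(\d+)$")
_LPC_RE = re.compile(r"^lysoPC (a|e) C(\d+):(\d+)$")
_SM_RE = re.compile(r"^SM (\(OH\) )?C(\d+):(\d+)$")


@dataclass(frozen=True)
class AnalyteToken:
    """A non-lipid panel analyte (amino acid, amine, hexoses, energy)."""

    name: str
    analyte_class: str

    def format(self) -> str:
        return self.name


@dataclass(frozen=True)
class LipidName:
    """Structured form of a lipid-class analyte name.

    ``bond`` is one of aa/ae (both glycerol positions esterified), a/e
    (lyso species), or "none" for acylcarnitines and sphingomyelins.
    """

    family: str  # PC | lysoPC | SM | acylcarnitine
    carbons: int
    double_bonds: int = 0
    bond: str = "none"
    hydroxyl: bool = False
    dicarboxyl: bool = False
    methyl: bool = field(default=False)

    def format(self) -> str:
        if self.family == "acylcarnitine":
            s = f"C{self.carbons}"
            if self.double_bonds:
                s += f":{self.double_bonds}"
            if self.methyl:
                s += "-M"
            if self.hydroxyl:
                s += "-OH"
            if self.dicarboxyl:
                s += "-DC"
            return s
        if self.family == "PC":
            return f"PC {self.bond} C{self.carbons}:{self.double_bonds}"
        if self.family == "lysoPC":
            return f"lysoPC {self.bond} C{self.carbons}:{self.double_bonds}"
        if self.family == "SM":
            oh = "(OH) " if self.hydroxyl else ""
            return f"SM {oh}C{self.carbons}:{self.double_bonds}"
        raise ValueError(f"unknown lipid family {self.family!r}")


def parse_metabolite_name(name: str) -> LipidName | AnalyteToken:
    """Parse a panel analyte name into its structured form.

    Raises :class:`MetaboliteNameError` for names outside the
    nomenclature, naming the offending token.
    """
    if not name or not name.strip():
        raise MetaboliteNameError("empty metabolite name")
    name = name.strip()

    if name in _TOKEN_CLASS:
        return AnalyteToken(name, _TOKEN_CLASS[name])

    m = _PC_RE.match(name)
    if m:
        return LipidName(
            family="PC", bond=m.group(1),
            carbons=int(m.group(2)), double_bonds=int(m.group(3)),
        )
    m = _LPC_RE.match(name)
    if m:
        return LipidName(
            family="lysoPC", bond=m.group(1),
            carbons=int(m.group(2)), double_bonds=int(m.group(3)),
        )
    m = _SM_RE.match(name)
    if m:
        return LipidName(
            family="SM", hydroxyl=m.group(1) is not None,
            carbons=int(m.group(2)), double_bonds=int(m.group(3)),
        )
    m = _AC_RE.match(name)
    if m:
        return LipidName(
            family="acylcarnitine",
            carbons=int(m.group(1)),
            double_bonds=int(m.group(2) or 0),
            methyl=m.group(3) is not None,
            hydroxyl=m.group(4) is not None,
            dicarboxyl=m.group(5) is not None,
        )
    raise MetaboliteNameError(f"unrecognized metabolite name: {name!r}")
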