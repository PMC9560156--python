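"""Monoisotopic mass arithmetic for isotopologue m/z prediction.

Atomic masses come from the NIST isotope table shipped with pyteomics;
the handful the package relies on are re-exported here so that every
m/z printed by this package traces to one documented source.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

from pyteomics import mass as _pt_mass

#: Monoisotopic masses of the light isotopes used in packaged formulas (Da).
MONOISOTOPIC: dict[str, float] = {
    "C": _pt_mass.nist_mass["C"][12][0],
    "H": _pt_mass.nist_mass["H"][1][0],
    "N": _pt_mass.nist_mass["N"][14][0],
    "O": _pt_mass.nist_mass["O"][16][0],
    "S": _pt_mass.nist_mass["S"][32][0],
    "P": _pt_mass.nist_mass["P"][31][0],
}

#: Mass of a bare proton (Da); used for protonation/deprotonation adducts.
PROTON_MASS: float = _pt_mass.nist_mass["H+"][0][0]

#: Electron mass (Da), for ions whose written formula already carries the charge.
ELECTRON_MASS: float = _pt_mass.nist_mass["H"][1][0] - PROTON_MASS

#: Mass shift per substituted heavy atom (Da).
C13_SHIFT: float = _pt_mass.nist_mass["C"][13][0] - _pt_mass.nist_mass["C"][12][0]
N15_SHIFT: float = _pt_mass.nist_mass["N"][15][0] - _pt_mass.nist_mass["N"][14][0]

#: Terrestrial natural abundance of 13C, used by the optional
#: natural-abundance convolution.
C13_NATURAL_ABUNDANCE: float = 0.0107


@dataclass(frozen=True)
class MolecularFormula(Mapping):
    """An elemental composition, e.g. valine ``C5H11NO2``.

    Behaves as a read-only mapping from element symbol to atom count.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one atom")
        for element, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {element!r}")
            if element not in MONOISOTOPIC:
                raise ValueError(f"element {element!r} not in packaged mass table")
        if all(n == 0 for n in self.counts.values()):
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_string(cls, formula: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C5H11NO2"``."""
        comp = _pt_mass.Composition(formula=formula)
        return cls({el: int(n) for el, n in comp.items() if n})

    @property
    def n_carbon(self) -> int:
        return self.counts.get("C", 0)

    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass with all atoms at their light isotope (Da)."""
        return sum(MONOISOTOPIC[el] * n for el, n in self.counts.items())

    def contains(self, other: "MolecularFormula") -> bool:
        """True when *other* is an element-wise sub-formula of this one."""
        return all(self.counts.get(el, 0) >= n for el, n in other.counts.items())

    def __getitem__(self, element: str) -> int:
        return self.counts[element]

    def __iter__(self):
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in sorted(self.counts.items())
        )


#: Packaged compositions used throughout the valine-tracing workflow.
VALINE = MolecularFormula.from_string("C5H11NO2")
ALANINE = MolecularFormula.from_string("C3H7NO2")
DIHYDROXY_ISOVALERATE = MolecularFormula.from_string("C5H10O4")
#: Valine immonium fragment (carboxyl carbon lost on CID); already a cation.
VALINE_IMMONIUM = MolecularFormula.from_string("C4H10N")
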