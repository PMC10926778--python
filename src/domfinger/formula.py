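"""Core CHNOS molecular-formula type and exact-mass arithmetic.

All downstream analysis (assignment, van Krevelen indices, rank
classification) operates on neutral CHNOS formulas observed as singly
deprotonated [M-H]- ions, the standard ionization for solid-phase-extracted
dissolved organic matter in negative-mode FT-ICR MS.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

#: Monoisotopic masses (Da) of the elements handled by this package.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

#: Mass of a proton (Da); [M-H]- ion mass = neutral mass - PROTON_MASS
#: (the ion loses H+ but keeps the electron).
PROTON_MASS = 1.00727646

_ELEMENT_ORDER = ("C", "H", "N", "O", "S")
_FORMULA_RE = re.compile(r"([CHNOS])(\d*)")


@dataclass(frozen=True, order=True)
class Formula:
    """A neutral CHNOS molecular formula.

    Invariants enforced at construction: all counts are non-negative
    integers, at least one carbon and one hydrogen, H + N even (nitrogen
    rule for neutral CHNOS molecules, equivalent to integer DBE), and
    DBE >= 0.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"element count {name!r} must be an int, got {v!r}")
            if v < 0:
                raise ValueError(f"element count {name!r} must be >= 0, got {v}")
        if self.c < 1:
            raise ValueError("a formula must contain at least one carbon")
        if self.h < 1:
            raise ValueError("a formula must contain at least one hydrogen")
        if (self.h + self.n) % 2 != 0:
            raise ValueError(
                f"nitrogen rule violated for {self._fmt()}: H + N must be even"
            )
        if self.dbe < 0:
            raise ValueError(f"negative DBE for {self._fmt()}: chemically invalid")

    @property
    def dbe(self) -> int:
        """Double bond equivalents, 1 + C - H/2 + N/2 (rings + double bonds)."""
        return (2 + 2 * self.c + self.n - self.h) // 2

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (
            self.c * MONOISOTOPIC_MASS["C"]
            + self.h * MONOISOTOPIC_MASS["H"]
            + self.n * MONOISOTOPIC_MASS["N"]
            + self.o * MONOISOTOPIC_MASS["O"]
            + self.s * MONOISOTOPIC_MASS["S"]
        )

    @property
    def ion_mz(self) -> float:
        """m/z of the singly deprotonated [M-H]- ion in Th."""
        return self.neutral_mass - PROTON_MASS

    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    def _fmt(self) -> str:
        parts = []
        for sym, cnt in zip(_ELEMENT_ORDER, (self.c, self.h, self.n, self.o, self.s)):
            if cnt > 0:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:
        # Canonical string: C,H,N,O,S order, counts always printed,
        # zero-count elements omitted (e.g. "C10H14N2O5").
        return self._fmt()

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a formula string like ``C10H14N2O5`` (counts optional: ``CH4O``)."""
        stripped = text.strip()
        if not stripped:
            raise ValueError("empty formula string")
        pos = 0
        counts = {sym: 0 for sym in _ELEMENT_ORDER}
        for m in _FORMULA_RE.finditer(stripped):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula string {text!r}")
            sym, digits = m.group(1), m.group(2)
            counts[sym] += int(digits) if digits else 1
            pos = m.end()
        if pos != len(stripped):
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"], s=counts["S"])


def neutral_mass(formula: Formula) -> float:
    """Neutral monoisotopic mass (Da) of a formula."""
    return formula.neutral_mass


def ion_mz(formula: Formula) -> float:
    """[M-H]- ion m/z (Th) of a neutral formula."""
    return formula.ion_mz
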