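"""Atomic-mass constants and elemental-formula mass arithmetic.

Monoisotopic masses come from the CODATA/AME tables bundled with pyteomics
(:data:`pyteomics.mass.nist_mass`).  Anion masses (ECNI produces negative
ions) are the neutral isotope mass *plus* one electron mass; rounding is a
display concern only and never applied to stored values.
"""

from __future__ import annotations

from pyteomics.mass import nist_mass

#: Electron rest mass in Da.
ELECTRON_MASS: float = nist_mass["e*"][0][0]

#: Elements supported in formula generation, in Hill-ish display order.
ELEMENTS = ("C", "H", "N", "O", "S", "P", "Cl", "Br")

#: Monoisotopic mass of the most abundant isotope of each supported element.
MONOISOTOPIC = {el: nist_mass[el][0][0] for el in ELEMENTS}


def isotope_mass(element: str, mass_number: int) -> float:
    """Neutral atomic mass of a specific isotope, e.g. ``isotope_mass("Cl", 37)``."""
    try:
        return nist_mass[element][mass_number][0]
    except KeyError as exc:
        raise ValueError(f"unknown isotope {mass_number}{element}") from exc


def formula_mass(counts: dict[str, int]) -> float:
    """Monoisotopic mass of a neutral formula given as element→count."""
    unknown = set(counts) - set(ELEMENTS)
    if unknown:
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    return sum(MONOISOTOPIC[el] * n for el, n in counts.items())


def dbe(counts: dict[str, int], even_electron_ion: bool = False) -> float:
    """Double-bond equivalents (rings + double bonds) of a formula.

    Uses the neutral-molecule convention, with monovalent halogens counted
    together with hydrogen:

        DBE = C + 1 + N/2 − (H + Cl + Br)/2

    With ``even_electron_ion=True`` the even-electron-ion convention is used
    instead, which sits 0.5 below the neutral value.
    """
    c = counts.get("C", 0)
    h = counts.get("H", 0) + counts.get("Cl", 0) + counts.get("Br", 0)
    n = counts.get("N", 0) + counts.get("P", 0)
    value = c + 1 + n / 2 - h / 2
    if even_electron_ion:
        value -= 0.5
    return value


def format_formula(counts: dict[str, int]) -> str:
    """Human-readable formula string, e.g. ``C15H24`` or ``C9HCl7N2``."""
    parts = []
    for el in ELEMENTS:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)
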