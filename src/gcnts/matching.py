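"""Spectral similarity, hit/non-hit classification, and formula annotation.

The similarity score is the NIST-style mass-weighted dot product
(Stein–Scott family): peaks are binned to unit mass, each bin is weighted
``w = intensity^0.5 · mz^1.3``, and the score is

    100 · (Σ w_a·w_b)² / (Σ w_a² · Σ w_b²)

over shared bins in the numerator.  Identical spectra score 100; spectra
sharing no bin score 0; the score is symmetric and invariant to rescaling
either spectrum.

Components whose best library score exceeds the hit threshold (60 by
default, strict) take the library name; everything else becomes a "non-hit"
tracked by a retention-time identifier ``RT_<rt to 0.01 min>``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

from .masses import ELECTRON_MASS, ELEMENTS, MONOISOTOPIC, dbe, format_formula


def _binned_weights(
    peaks, int_exp: float, mz_exp: float, bin_width: float
) -> dict[int, float]:
    """Unit-mass binning (intensities summed per bin) then weighting."""
    binned: dict[int, float] = {}
    for m, i in peaks:
        binned[int(round(m / bin_width))] = binned.get(int(round(m / bin_width)), 0.0) + i
    return {
        b: (inten ** int_exp) * ((b * bin_width) ** mz_exp)
        for b, inten in binned.items()
        if inten > 0
    }


def similarity(
    a,
    b,
    int_exp: float = 0.5,
    mz_exp: float = 1.3,
    bin_width: float = 1.0,
) -> float:
    """Weighted-cosine spectral similarity on a 0–100 scale.

    ``a`` and ``b`` are iterables of ``(mz, intensity)`` pairs.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("similarity of an empty spectrum is undefined")
    wa = _binned_weights(a, int_exp, mz_exp, bin_width)
    wb = _binned_weights(b, int_exp, mz_exp, bin_width)
    shared = set(wa) & set(wb)
    if not shared:
        return 0.0
    num = sum(wa[k] * wb[k] for k in shared) ** 2
    den = sum(w * w for w in wa.values()) * sum(w * w for w in wb.values())
    return 100.0 * num / den


@dataclass
class MatchResult:
    """Best library matches for one component, rank 1 first."""

    library_name: str
    score: float
    rank: int


def best_matches(component_peaks, library, n: int = 3) -> list[MatchResult]:
    """Score a component spectrum against every library entry; top ``n``."""
    scored = [
        (similarity(component_peaks, e.peaks), e.name) for e in library
    ]
    scored.sort(key=lambda x: (-x[0], x[1]))
    return [
        MatchResult(library_name=name, score=score, rank=i + 1)
        for i, (score, name) in enumerate(scored[:n])
    ]


def rt_identifier(rt: float) -> str:
    """Non-hit naming rule: retention time to 0.01 min."""
    return f"RT_{rt:.2f}"


def classify(components, ref_library, threshold: float = 60.0):
    """Split components into hits (named) and non-hits (RT identifiers).

    A component is a hit iff its best score is *strictly above* the
    threshold.  Returns ``(hits, non_hits)`` as lists of
    ``(component, assigned_name, best_score)``; every component appears in
    exactly one list.
    """
    if not ref_library:
        raise ValueError("reference library is empty")
    hits, non_hits = [], []
    for comp in components:
        matches = best_matches(comp.spectrum, ref_library, n=1)
        score = matches[0].score if matches else 0.0
        if score > threshold:
            hits.append((comp, matches[0].library_name, score))
        else:
            non_hits.append((comp, rt_identifier(comp.rt_apex), score))
    return hits, non_hits


def rename_duplicates(names: list[str]) -> list[str]:
    """Make names unique by suffixing later occurrences with _2, _3, …

    The caller is expected to present entries in priority order (highest
    score first, ties by earlier RT); the first occurrence keeps the name.
    """
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name not in seen:
            seen[name] = 1
            out.append(name)
        else:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
    return out


# ---------------------------------------------------------------------------
# Formula generation
# ---------------------------------------------------------------------------


@dataclass
class FormulaCandidate:
    counts: dict[str, int]
    monoisotopic_mass: float  # of the measured species (ion for charge −1)
    dbe: float
    ppm_error: float

    @property
    def formula(self) -> str:
        return format_formula(self.counts)


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``C15H24``-style formulas over the supported element set."""
    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if not el:
            continue
        if el not in ELEMENTS:
            raise ValueError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def generate_formulas(
    mz: float,
    tol_ppm: float,
    element_ranges: dict[str, tuple[int, int]],
    charge: int = 0,
    electron_adjust: bool = True,
    even_electron_ion: bool = False,
    min_dbe: float | None = 0.0,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate formulas matching ``mz`` within ``tol_ppm``.

    For ``charge == −1`` (ECNI anions) one electron mass is added to the
    formula mass before comparison when ``electron_adjust`` is set.
    Candidates with DBE below ``min_dbe`` are dropped (pass ``None`` to keep
    all); results are sorted by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if charge not in (0, -1):
        raise ValueError("only charge 0 and −1 are supported")
    for el, (lo, hi) in element_ranges.items():
        if el not in ELEMENTS:
            raise ValueError(f"unsupported element {el!r}")
        if lo < 0 or hi < lo or hi > 1000:
            raise ValueError(f"element range for {el} must be bounded and sane")

    elements = sorted(element_ranges)
    ranges = [range(element_ranges[el][0], element_ranges[el][1] + 1) for el in elements]
    tol_da = mz * tol_ppm * 1e-6
    adjust = ELECTRON_MASS if (charge == -1 and electron_adjust) else 0.0

    out: list[FormulaCandidate] = []
    for combo in itertools.product(*ranges):
        counts = {el: n for el, n in zip(elements, combo) if n > 0}
        if not counts:
            continue
        mass = sum(MONOISOTOPIC[el] * n for el, n in counts.items()) + adjust
        if abs(mass - mz) > tol_da:
            continue
        d = dbe(counts, even_electron_ion=even_electron_ion)
        if min_dbe is not None and d < min_dbe:
            continue
        out.append(
            FormulaCandidate(
                counts=counts,
                monoisotopic_mass=mass,
                dbe=d,
                ppm_error=(mass - mz) / mz * 1e6,
            )
        )
    out.sort(key=lambda c: (abs(c.ppm_error), c.formula))
    return out
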