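"""Spectral similarity, classification, duplicate renaming, formulas."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcnts.matching as matching
from gcnts.deconvolution import Component
from gcnts.masses import dbe, formula_mass
from gcnts.matching import (
    classify,
    generate_formulas,
    parse_formula,
    rename_duplicates,
    rt_identifier,
    similarity,
)


def brute_force_similarity(a, b, int_exp=0.5, mz_exp=1.3, bin_width=1.0):
    """Independent evaluation of the weighted-cosine formula.

    Written directly from the definition: bin to unit mass, weight
    w = intensity^0.5 · mz^1.3, score = 100·(Σ w_a w_b)²/(Σ w_a²·Σ w_b²).
    """
    def weights(peaks):
        bins = {}
        for m, i in peaks:
            key = int(round(m / bin_width))
            bins[key] = bins.get(key, 0.0) + i
        return {k: (v ** int_exp) * ((k * bin_width) ** mz_exp) for k, v in bins.items() if v > 0}

    wa, wb = weights(a), weights(b)
    num = sum(wa[k] * wb[k] for k in wa if k in wb) ** 2
    den = sum(v * v for v in wa.values()) * sum(v * v for v in wb.values())
    return 100.0 * num / den if den else 0.0


def random_spectrum(rng, n_max=12):
    n = int(rng.integers(1, n_max))
    mz = rng.uniform(50, 450, n)
    inten = rng.uniform(1, 999, n)
    return list(zip(mz.tolist(), inten.tolist()))


class TestSimilarity:
    def test_identical_spectra_score_100(self):
        peaks = [(50.0, 999.0), (77.0, 500.0), (105.0, 120.0)]
        assert similarity(peaks, peaks) == pytest.approx(100.0)

    def test_disjoint_spectra_score_0(self):
        assert similarity([(50.0, 999.0)], [(77.0, 999.0)]) == 0.0

    def test_two_peak_example_matches_brute_force(self):
        a = [(50.0, 999.0), (77.0, 500.0)]
        b = [(50.0, 500.0), (77.0, 999.0)]
        assert similarity(a, b) == pytest.approx(brute_force_similarity(a, b), abs=1e-9)

    def test_oracle_equivalence_on_random_spectra(self):
        """100 random small spectra pairs agree with the independently coded
        formula to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            a, b = random_spectrum(rng), random_spectrum(rng)
            assert similarity(a, b) == pytest.approx(
                brute_force_similarity(a, b), abs=1e-9
            )

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            similarity([], [(50.0, 1.0)])

    @given(st.integers(0, 10_000), st.floats(0.1, 1000.0))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_scale_invariant_bounded(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = random_spectrum(rng), random_spectrum(rng)
        s_ab = similarity(a, b)
        assert 0.0 <= s_ab <= 100.0 + 1e-9
        assert s_ab == pytest.approx(similarity(b, a), abs=1e-9)
        scaled = [(m, i * scale) for m, i in a]
        assert s_ab == pytest.approx(similarity(scaled, b), rel=1e-9)


def _component(rt: float, peaks) -> Component:
    return Component(
        rt_apex=rt,
        spectrum=list(peaks),
        base_peak_mz=max(peaks, key=lambda p: p[1])[0],
        quantifier_mz=max(peaks, key=lambda p: p[1])[0],
    )


class TestClassify:
    def test_strict_threshold_boundary(self, monkeypatch):
        """Best score of exactly 60.0 is a non-hit; anything strictly above
        (even 60.01) is a hit — the rule reads 'above 60%'."""
        comps = [_component(7.21, [(50.0, 999.0)]), _component(9.0, [(60.0, 999.0)])]
        lib = [
            type("E", (), {"name": "Entry", "peaks": [(50.0, 999.0)]})(),
        ]
        scores = {7.21: 60.0, 9.0: 60.01}

        def fake_best(peaks, library, n=1):
            rt = 7.21 if int(peaks[0][0]) == 50 else 9.0
            return [matching.MatchResult("Entry", scores[rt], 1)]

        monkeypatch.setattr(matching, "best_matches", fake_best)
        hits, non_hits = classify(comps, lib, threshold=60.0)
        assert [c.rt_apex for c, _n, _s in hits] == [9.0]
        assert [c.rt_apex for c, _n, _s in non_hits] == [7.21]

    def test_non_hit_gets_rt_identifier(self, toy_library):
        comp = _component(7.214, [(499.9, 999.0)])  # matches nothing
        hits, non_hits = classify([comp], toy_library)
        assert not hits
        (c, name, score) = non_hits[0]
        assert name == "RT_7.21"

    def test_partition_property(self, toy_library):
        rng = np.random.default_rng(1)
        comps = [
            _component(float(rt), random_spectrum(rng))
            for rt in rng.uniform(5, 40, 12)
        ]
        hits, non_hits = classify(comps, toy_library)
        assert len(hits) + len(non_hits) == len(comps)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            classify([], [])

    def test_rt_identifier_format(self):
        assert rt_identifier(7.205) in ("RT_7.20", "RT_7.21")  # banker's rounding
        assert rt_identifier(12.0) == "RT_12.00"


class TestRenameDuplicates:
    @pytest.mark.parametrize(
        "names,expected",
        [
            (["A", "A", "B"], ["A", "A_2", "B"]),
            (["A", "B", "C"], ["A", "B", "C"]),
            (["A", "A", "A"], ["A", "A_2", "A_3"]),
            ([], []),
        ],
    )
    def test_cases(self, names, expected):
        assert rename_duplicates(names) == expected

    def test_output_always_unique(self):
        rng = np.random.default_rng(0)
        names = [f"N{int(i)}" for i in rng.integers(0, 5, 50)]
        out = rename_duplicates(names)
        assert len(set(out)) == len(out)


# independent atomic-mass oracle: literature monoisotopic masses, typed in
# by hand, deliberately not imported from the package under test
ORACLE_MASSES = {"C": 12.0, "H": 1.007825032, "Cl": 34.96885268, "Br": 78.9183376}


class TestFormulas:
    def test_chloride_anion_unique_candidate(self):
        """At the printed chloride anion mass, enumeration over {Cl: 0–2}
        with charge −1 returns exactly ³⁵Cl⁻."""
        out = generate_formulas(
            34.9694, tol_ppm=20.0, element_ranges={"Cl": (0, 2)}, charge=-1,
            min_dbe=None,
        )
        assert len(out) == 1
        assert out[0].formula == "Cl"
        assert abs(out[0].ppm_error) < 5

    def test_sesquiterpene_formula_recovered(self):
        """C15H24 recomputed by independent mass summation, then found by
        enumeration at 5 ppm over C0–20 H0–40 as the only candidate."""
        target = 15 * ORACLE_MASSES["C"] + 24 * ORACLE_MASSES["H"]
        out = generate_formulas(
            target, tol_ppm=5.0, element_ranges={"C": (0, 20), "H": (0, 40)}
        )
        assert [c.formula for c in out] == ["C15H24"]
        assert out[0].dbe == pytest.approx(4.0)

    def test_dbe_conventions(self):
        assert dbe(parse_formula("C15H24")) == pytest.approx(4.0)
        # squalene: neutral convention 6, even-electron-ion convention 5.5
        assert dbe(parse_formula("C30H50")) == pytest.approx(6.0)
        assert dbe(parse_formula("C30H50"), even_electron_ion=True) == pytest.approx(5.5)
        # halogens count with hydrogen: hexachlorobenzene keeps DBE 4
        assert dbe(parse_formula("C6Cl6")) == pytest.approx(4.0)

    def test_ppm_error_reconstructs_from_masses(self):
        target = 20 * ORACLE_MASSES["C"] + 20 * ORACLE_MASSES["H"] + 0.002
        out = generate_formulas(
            target, tol_ppm=50.0, element_ranges={"C": (0, 20), "H": (0, 40)}
        )
        assert out
        for cand in out:
            recomputed = formula_mass(cand.counts)
            assert cand.ppm_error == pytest.approx(
                (recomputed - target) / target * 1e6, abs=1e-9
            )
            assert cand.monoisotopic_mass == pytest.approx(recomputed, abs=1e-12)

    def test_unbounded_or_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_formulas(100.0, 5.0, {"C": (0, 5000)})
        with pytest.raises(ValueError):
            generate_formulas(100.0, 5.0, {"Xx": (0, 2)})
        with pytest.raises(ValueError):
            generate_formulas(100.0, -1.0, {"C": (0, 5)})
        with pytest.raises(ValueError):
            generate_formulas(100.0, 5.0, {"C": (0, 5)}, charge=2)

    def test_sorted_by_abs_ppm_error(self):
        out = generate_formulas(
            200.2, tol_ppm=500.0, element_ranges={"C": (0, 16), "H": (0, 34)},
            min_dbe=None,
        )
        errs = [abs(c.ppm_error) for c in out]
        assert errs == sorted(errs)
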