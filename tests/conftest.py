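"""Shared fixtures: tiny synthetic specs and canned runs.

Session-scoped fixtures keep the expensive pieces (toy library load, which
triggers the matchms import, and small synthetic datasets) to one build per
test session.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from gcnts.msdata import EI, Run, SampleMeta, Spectrum, load_library
from gcnts.simulate import (
    CompoundSpec,
    FoodWebSpec,
    SampleTemplate,
    generate_foodweb,
    small_foodweb_spec,
    toy_library_path,
)


@pytest.fixture(scope="session")
def toy_library():
    return load_library(toy_library_path())


@pytest.fixture(scope="session")
def small_spec():
    return small_foodweb_spec(42)


def make_mini_spec(seed: int = 42, **overrides) -> FoodWebSpec:
    """A deliberately tiny food web: 2 biota samples + blanks, 3 compounds,
    6-minute runs — fast enough to regenerate freely inside unit tests."""
    lib = {e.name: e for e in load_library(toy_library_path())}
    samples = [
        SampleTemplate("BM", "blue mussel", "flesh", "filter_feeder", 20.0, 2.1),
        SampleTemplate("EM", "eelpout", "muscle", "benthic_fish", 50.0, 0.5),
        SampleTemplate("MB", "method blank", "none", "blank_method", 1.0, 0.0, is_blank=True),
        SampleTemplate("SB", "solvent blank", "none", "blank_solvent", 1.0, 0.0, is_blank=True),
    ]
    compounds = [
        CompoundSpec(
            name="Sesquiterpene-A",
            rt=2.0,
            ei_spectrum=lib["Sesquiterpene-A"].peaks,
            fraction_id=1,
            conc_per_g_lipid={"BM": 4.0e5, "EM": 8.0e5},
        ),
        CompoundSpec(
            name="Bornyl-chloride-like",
            rt=3.0,
            ei_spectrum=lib["Bornyl-chloride-like"].peaks,
            ecni_halides=[("35Cl", 0.7576), ("37Cl", 0.2424)],
            fraction_id=1,
            conc_per_g_lipid={"BM": 2.0e5, "EM": 2.0e6},
        ),
        CompoundSpec(
            name="BDE-like-047",
            rt=4.2,
            ei_spectrum=lib["BDE-like-047"].peaks,
            ecni_halides=[("79Br", 0.5069), ("81Br", 0.4931)],
            fraction_id=2,
            conc_per_g_lipid={"BM": 3.0e5, "EM": 6.0e5},
        ),
    ]
    standards = [
        CompoundSpec(
            name="VS-13C-CB-097",
            rt=1.2,
            ei_spectrum=lib["VS-13C-CB-097"].peaks,
            ecni_halides=[("35Cl", 0.7576), ("37Cl", 0.2424)],
            fraction_split={1: 1.0, 2: 1.0, 3: 1.0},
            standard_amount=2.0e5,
        ),
        CompoundSpec(
            name="VS-13C-CB-188",
            rt=5.0,
            ei_spectrum=lib["VS-13C-CB-188"].peaks,
            ecni_halides=[("35Cl", 0.7576), ("37Cl", 0.2424)],
            fraction_split={1: 1.0, 2: 1.0, 3: 1.0},
            standard_amount=2.0e5,
        ),
    ]
    spec = FoodWebSpec(
        samples=samples,
        compounds=compounds,
        standards=standards,
        pairs=[("EM", "BM")],
        seed=seed,
        duration_min=6.0,
        ecni_duration_min=6.0,
        n_noise_channels=5,
    )
    return replace(spec, **overrides) if overrides else spec


@pytest.fixture(scope="session")
def mini_spec():
    return make_mini_spec(42)


@pytest.fixture(scope="session")
def mini_dataset(mini_spec):
    return generate_foodweb(mini_spec)


@pytest.fixture(scope="session")
def mini_noiseless_dataset(mini_spec):
    return generate_foodweb(mini_spec.noiseless(), modes=(EI,))


def make_run(
    spectra_data: list[tuple[float, list[float], list[float]]],
    mode: str = EI,
    fraction: int = 1,
    lipid: float = 1.0,
) -> Run:
    """Hand-built run from (rt, mz list, intensity list) triples."""
    meta = SampleMeta(
        sample_code="T",
        species="test",
        tissue="test",
        trophic_role="benthic_fish",
        replicate_id=1,
        fraction_id=fraction,
        lipid_mass_g=lipid,
    )
    spectra = [
        Spectrum(rt=rt, mz=np.array(mz), intensity=np.array(inten), mode=mode)
        for rt, mz, inten in spectra_data
    ]
    return Run(spectra, meta, mode=mode)


def gaussian_trace(
    n: int = 600,
    center_s: float = 300.0,
    sigma_s: float = 2.0,
    area: float = 1.0e4,
    noise_sd: float = 0.0,
    noise_floor: float = 0.0,
    hz: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(rt_minutes, intensity) for one sampled Gaussian peak."""
    rng = np.random.default_rng(seed)
    t_s = np.arange(n) / hz
    height = area / (sigma_s * np.sqrt(2 * np.pi))
    y = height * np.exp(-0.5 * ((t_s - center_s) / sigma_s) ** 2)
    if noise_sd > 0 or noise_floor > 0:
        y = np.clip(y + rng.normal(noise_floor, noise_sd, n), 0, None)
    return t_s / 60.0, y
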