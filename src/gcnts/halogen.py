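"""ECNI halogen-selective screening.

Electron-capture negative ionization of halogenated compounds releases
halide anions, so screening the four EICs of ³⁵Cl⁻, ³⁷Cl⁻, ⁷⁹Br⁻ and ⁸¹Br⁻
finds chlorinated/brominated compounds regardless of their EI response.
Anion m/z values are computed from bundled isotope masses plus the electron
mass — never hard-coded.  Isotope channels of one element are merged per
feature (areas summed) with the observed isotope ratio kept as a QC value;
Cl and Br channels are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatography import align_features, detect_peaks, extract_eic
from .deconvolution import ModeError
from .masses import ELECTRON_MASS, isotope_mass
from .msdata import ECNI, Run

#: isotope label → (element, mass number)
HALIDE_ISOTOPES = {
    "35Cl": ("Cl", 35),
    "37Cl": ("Cl", 37),
    "79Br": ("Br", 79),
    "81Br": ("Br", 81),
}

#: light/heavy isotope channel per element
ELEMENT_CHANNELS = {"Cl": ("35Cl", "37Cl"), "Br": ("79Br", "81Br")}


@dataclass(frozen=True)
class HalideTarget:
    isotope: str
    mz: float


def halide_mz(isotope: str) -> float:
    """Exact m/z of a halide anion: neutral isotope mass + one electron mass."""
    if isotope not in HALIDE_ISOTOPES:
        raise ValueError(
            f"unsupported isotope {isotope!r}; choose from {sorted(HALIDE_ISOTOPES)}"
        )
    element, a = HALIDE_ISOTOPES[isotope]
    return isotope_mass(element, a) + ELECTRON_MASS


def halide_targets() -> list[HalideTarget]:
    return [HalideTarget(iso, halide_mz(iso)) for iso in HALIDE_ISOTOPES]


def screen_halides_run(
    run: Run,
    snr_min: float = 3.0,
    eic_tol: float = 0.005,
    rt_tol: float = 0.05,
) -> list[dict]:
    """Detect halide features in one ECNI run.

    Peaks are detected per isotope EIC, then the light/heavy channels of each
    element are merged by RT: one feature per (element, rt) with the channel
    areas summed and the light:heavy area ratio reported as QC.  Returns a
    list of dicts with keys element, rt, area, isotope_ratio.
    """
    if run.mode != ECNI:
        raise ModeError("halide screening expects ECNI runs")
    features: list[dict] = []
    for element, (light, heavy) in ELEMENT_CHANNELS.items():
        per_channel = {}
        for iso in (light, heavy):
            eic = extract_eic(run, halide_mz(iso), tol=eic_tol)
            per_channel[iso] = detect_peaks(eic, snr_min=snr_min)
        groups = align_features(per_channel, rt_tol=rt_tol)
        for g in groups:
            area_light = g["areas"][light]
            area_heavy = g["areas"][heavy]
            ratio = area_light / area_heavy if area_heavy > 0 else np.inf
            features.append(
                {
                    "element": element,
                    "rt": g["rt"],
                    "area": area_light + area_heavy,
                    "isotope_ratio": ratio,
                }
            )
    features.sort(key=lambda f: (f["rt"], f["element"]))
    return features


def halogen_screen_runs(
    runs: list[Run],
    rt_tol: float = 0.05,
    snr_min: float = 3.0,
    eic_tol: float = 0.005,
    standard_rts: list[float] | None = None,
    standard_rt_window: float = 0.1,
) -> pd.DataFrame:
    """Screen many ECNI runs and align halide features across them.

    Features whose RT falls within ``standard_rt_window`` of a volumetric
    standard RT are tagged ``is_standard`` (the spiked ¹³C-PCB standards are
    chlorinated and show up in the Cl channel); they are kept in the table so
    the BMF stage can normalize against them, but should be excluded from
    contaminant candidate lists.

    Returns a feature table with one row per (feature, run): columns
    ``name, rt_min, element, sample_code, replicate_id, fraction_id, area,
    area_per_g_lipid, isotope_ratio, is_standard``.
    """
    per_run_features = {}
    run_meta = {}
    for idx, run in enumerate(runs):
        m = run.sample_meta
        key = (m.sample_code, m.replicate_id, m.fraction_id, idx)
        run_meta[key] = m
        per_run_features[key] = screen_halides_run(
            run, snr_min=snr_min, eic_tol=eic_tol, rt_tol=rt_tol
        )

    rows = []
    for element in ELEMENT_CHANNELS:
        # align this element's features across runs using ChromPeak-like stubs
        from .chromatography import ChromPeak

        peak_lists = {
            key: [
                ChromPeak(
                    rt_apex=f["rt"],
                    rt_start=f["rt"],
                    rt_end=f["rt"],
                    area=f["area"],
                    height=f["area"],
                    snr=np.inf,
                )
                for f in feats
                if f["element"] == element
            ]
            for key, feats in per_run_features.items()
        }
        ratio_lookup = {
            (key, round(f["rt"], 6)): f["isotope_ratio"]
            for key, feats in per_run_features.items()
            for f in feats
            if f["element"] == element
        }
        for feat in align_features(peak_lists, rt_tol=rt_tol):
            rt = feat["rt"]
            is_standard = bool(
                standard_rts
                and any(abs(rt - s) <= standard_rt_window for s in standard_rts)
            )
            name = f"{element}_{rt:.2f}"
            for key, meta in run_meta.items():
                peak = feat["peaks"].get(key)
                if peak is None:
                    continue
                rows.append(
                    {
                        "name": name,
                        "rt_min": rt,
                        "element": element,
                        "sample_code": meta.sample_code,
                        "replicate_id": meta.replicate_id,
                        "fraction_id": meta.fraction_id,
                        "area": peak.area,
                        "area_per_g_lipid": peak.area / meta.lipid_mass_g,
                        "isotope_ratio": ratio_lookup.get((key, round(peak.rt_apex, 6)), np.nan),
                        "is_standard": is_standard,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["rt_min", "name", "sample_code", "replicate_id", "fraction_id"],
            kind="stable",
        ).reset_index(drop=True)
    return df
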