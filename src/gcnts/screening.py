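"""Targeted re-screening of samples against a custom library.

Every sample run is interrogated for every library entry: the quantifier-ion
EIC is extracted, the peak nearest the entry's RT (within ``rt_window``) at
S/N ≥ 3 is integrated, and qualifier-ion areas are measured over the same
peak span.  A row whose observed qualifier:quantifier ratio deviates from
the library's expected ratio by more than ``qual_ratio_tol`` (relative) is
kept but flagged ``qualifier_out`` — mirroring manual scrutiny rather than
silently dropping data.  Areas are lipid-normalized against the grams of
lipid originally extracted from the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chromatography import detect_peaks, extract_eic
from .library_pipeline import CustomLibrary
from .msdata import Run

SCREEN_COLUMNS = [
    "name",
    "rt_min",
    "lri",
    "sample_code",
    "replicate_id",
    "fraction_id",
    "area",
    "area_per_g_lipid",
    "qc_flags",
]


def normalize_to_lipid(area: float, lipid_mass_g: float) -> float:
    """Area per gram of extracted lipid."""
    if lipid_mass_g <= 0:
        raise ValueError("lipid_mass_g must be positive")
    return area / lipid_mass_g


def _integrate_window(run: Run, mz: float, rt_start: float, rt_end: float, eic_tol: float) -> float:
    """Baseline-corrected trapezoidal area of an ion over a fixed RT span."""
    eic = extract_eic(run, mz, tol=eic_tol)
    sel = (eic.rt >= rt_start) & (eic.rt <= rt_end)
    if sel.sum() < 2:
        return 0.0
    t = eic.rt[sel]
    y = eic.intensity[sel]
    baseline = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    return float(np.trapezoid(np.clip(y - baseline, 0, None), t) * 60.0)


def screen_sample(
    run: Run,
    library: CustomLibrary,
    rt_window: float = 0.1,
    qual_ratio_tol: float = 0.30,
    snr_min: float = 3.0,
    eic_tol: float = 0.005,
) -> pd.DataFrame:
    """Screen one run for all library entries of its Florisil fraction.

    Returns feature rows (possibly empty); entries absent from the run
    produce no row.
    """
    meta = run.sample_meta
    rows = []
    for entry in library.entries:
        if entry.fraction_id != meta.fraction_id:
            continue
        eic = extract_eic(run, entry.quantifier_mz, tol=eic_tol)
        peaks = [
            p
            for p in detect_peaks(eic, snr_min=snr_min)
            if abs(p.rt_apex - entry.rt) <= rt_window
        ]
        if not peaks:
            continue
        peak = min(peaks, key=lambda p: abs(p.rt_apex - entry.rt))
        flags = []
        for qmz, expected in zip(entry.qualifier_mzs, entry.qualifier_ratios):
            if expected <= 0:
                continue
            qarea = _integrate_window(run, qmz, peak.rt_start, peak.rt_end, eic_tol)
            observed = qarea / peak.area if peak.area > 0 else 0.0
            if abs(observed - expected) / expected > qual_ratio_tol:
                flags.append("qualifier_out")
                break
        rows.append(
            {
                "name": entry.name,
                "rt_min": peak.rt_apex,
                "lri": entry.lri if entry.lri is not None else np.nan,
                "sample_code": meta.sample_code,
                "replicate_id": meta.replicate_id,
                "fraction_id": meta.fraction_id,
                "area": peak.area,
                "area_per_g_lipid": normalize_to_lipid(peak.area, meta.lipid_mass_g),
                "qc_flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def screen_samples(
    runs: list[Run],
    library: CustomLibrary,
    rt_window: float = 0.1,
    qual_ratio_tol: float = 0.30,
    snr_min: float = 3.0,
    eic_tol: float = 0.005,
) -> pd.DataFrame:
    """Screen many runs and concatenate the feature rows."""
    frames = [
        screen_sample(
            run,
            library,
            rt_window=rt_window,
            qual_ratio_tol=qual_ratio_tol,
            snr_min=snr_min,
            eic_tol=eic_tol,
        )
        for run in runs
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(
        ["rt_min", "name", "sample_code", "replicate_id", "fraction_id"], kind="stable"
    ).reset_index(drop=True)


def measure_standards(
    run: Run,
    standards: list[tuple[str, float, float]],
    rt_window: float = 0.2,
    snr_min: float = 3.0,
    eic_tol: float = 0.005,
) -> pd.DataFrame:
    """Measure volumetric-standard peak areas in one run.

    ``standards`` is a list of ``(name, quantifier_mz, rt)``.  Returns one
    row per standard with its area (NaN when not found).
    """
    meta = run.sample_meta
    rows = []
    for name, mz, rt in standards:
        eic = extract_eic(run, mz, tol=eic_tol)
        peaks = [
            p
            for p in detect_peaks(eic, snr_min=snr_min)
            if abs(p.rt_apex - rt) <= rt_window
        ]
        area = min(peaks, key=lambda p: abs(p.rt_apex - rt)).area if peaks else np.nan
        rows.append(
            {
                "standard": name,
                "rt_min": rt,
                "sample_code": meta.sample_code,
                "replicate_id": meta.replicate_id,
                "fraction_id": meta.fraction_id,
                "area": area,
            }
        )
    return pd.DataFrame(rows)
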