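"""Deconvolution of EI runs into components (pseudo-spectra).

Centroids observed anywhere in the run are clustered on the m/z axis
(gap-based, 0.005 Da) into per-ion traces; each trace yields an EIC whose
peaks are detected with the usual S/N ≥ 3 gate.  Ion peaks are then grouped
into components: the largest unassigned peak seeds a cluster and collects
every peak whose apex lies within ``apex_tol`` seconds and whose EIC shape
correlates (Pearson ≥ ``shape_corr_min``) with the seed's over the seed's
span.  Each cluster is one component whose pseudo-spectrum is the per-ion
peak areas; the quantifier is the largest-area ion, qualifiers the next two
with their expected area ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatography import EIC, ChromPeak, detect_peaks
from .msdata import ECNI, EI, Run, Spectrum


class ModeError(ValueError):
    """Wrong ionization mode for this operation."""


@dataclass
class Component:
    """A deconvolved pseudo-spectrum at one apex RT."""

    rt_apex: float
    spectrum: list[tuple[float, float]]  # (mz, area) sorted by mz
    base_peak_mz: float
    quantifier_mz: float
    qualifier_mzs: list[float] = field(default_factory=list)
    qualifier_ratios: list[float] = field(default_factory=list)  # area / quantifier area
    total_area: float = 0.0

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError("component spectrum must be non-empty")
        self.spectrum = sorted(self.spectrum)
        self.total_area = float(sum(a for _, a in self.spectrum))


def ion_traces(run: Run, mz_tol: float = 0.005, min_points: int = 5):
    """Cluster observed centroid m/z into per-ion traces.

    Returns a list of ``(trace_mz, EIC)`` with ``trace_mz`` the
    intensity-weighted mean m/z of the cluster.  Gap-based 1-D clustering:
    a new trace starts wherever consecutive sorted centroids are more than
    ``mz_tol`` apart.
    """
    if getattr(run, "channels", None) is not None:
        centers, mz_matrix, inten_matrix = run.channels
        rt = run.scan_times
        traces = []
        for j, center in enumerate(centers):
            col = inten_matrix[:, j]
            total = col.sum()
            if total <= 0 or np.count_nonzero(col) < min_points:
                continue
            if mz_matrix is None:
                mean_mz = float(center)
            else:
                mean_mz = float(np.average(mz_matrix[:, j], weights=col))
            traces.append((mean_mz, EIC(mean_mz, mz_tol, rt, col)))
        traces.sort(key=lambda t: t[0])
        return traces
    flat_mz, flat_int, flat_scan = run.flattened()
    if flat_mz.size == 0:
        return []
    gaps = np.diff(flat_mz) > mz_tol
    boundaries = np.flatnonzero(gaps) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [flat_mz.size]))
    rt = run.scan_times
    traces = []
    n_scans = len(run)
    for s, e in zip(starts, ends):
        if e - s < min_points:
            continue
        seg_int = flat_int[s:e]
        total = seg_int.sum()
        if total <= 0:
            continue
        center = float(np.average(flat_mz[s:e], weights=seg_int))
        intensity = np.bincount(flat_scan[s:e], weights=seg_int, minlength=n_scans)
        traces.append((center, EIC(center, mz_tol, rt, intensity)))
    traces.sort(key=lambda t: t[0])
    return traces


def _shape_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def find_components(
    run: Run,
    snr_min: float = 3.0,
    apex_tol_s: float = 2.0,
    shape_corr_min: float = 0.9,
    mz_tol: float = 0.005,
) -> list[Component]:
    """Deconvolve an EI run into components, sorted by apex RT."""
    if run.mode == ECNI:
        raise ModeError(
            "find_components expects an EI run; ECNI data goes through the "
            "halogen-selective screen"
        )
    traces = ion_traces(run, mz_tol=mz_tol)
    rt = run.scan_times
    apex_tol_min = apex_tol_s / 60.0

    # all ion peaks: (area, apex_rt, trace_mz, peak, trace_intensity)
    ion_peaks = []
    for trace_mz, eic in traces:
        for p in detect_peaks(eic, snr_min=snr_min):
            ion_peaks.append((p.area, p.rt_apex, trace_mz, p, eic.intensity))
    ion_peaks.sort(key=lambda x: (-x[0], x[1], x[2]))

    assigned = np.zeros(len(ion_peaks), dtype=bool)
    components: list[Component] = []
    for i, (area_i, apex_i, mz_i, peak_i, trace_i) in enumerate(ion_peaks):
        if assigned[i]:
            continue
        assigned[i] = True
        lo = int(np.searchsorted(rt, peak_i.rt_start))
        hi = int(np.searchsorted(rt, peak_i.rt_end, side="right"))
        seed_shape = trace_i[lo:hi]
        members = [(mz_i, peak_i)]
        for j in range(i + 1, len(ion_peaks)):
            if assigned[j]:
                continue
            area_j, apex_j, mz_j, peak_j, trace_j = ion_peaks[j]
            if abs(apex_j - apex_i) > apex_tol_min:
                continue
            if _shape_correlation(seed_shape, trace_j[lo:hi]) < shape_corr_min:
                continue
            assigned[j] = True
            members.append((mz_j, peak_j))
        spectrum = sorted((mz, p.area) for mz, p in members)
        quant_mz, quant_area = max(spectrum, key=lambda x: x[1])
        others = sorted(
            (s for s in spectrum if s[0] != quant_mz), key=lambda x: -x[1]
        )[:2]
        components.append(
            Component(
                rt_apex=apex_i,
                spectrum=spectrum,
                base_peak_mz=quant_mz,
                quantifier_mz=quant_mz,
                qualifier_mzs=[m for m, _ in others],
                qualifier_ratios=[a / quant_area for _, a in others],
            )
        )
    components.sort(key=lambda c: c.rt_apex)
    return components


def extract_spectrum(
    run: Run,
    rt: float,
    bg_offsets: tuple[float, float] = (-0.2, 0.2),
    mz_tol: float = 0.005,
) -> Spectrum:
    """Background-subtracted spectrum at ``rt``.

    The scan nearest ``rt`` has the average of the two scans at
    ``rt + offset`` subtracted, centroids matched within ``mz_tol`` Da and
    the result clipped at zero.  The signal scan's m/z grid is kept.
    """
    times = run.scan_times
    if rt < times[0] or rt > times[-1]:
        raise ValueError(f"rt {rt:.3f} min outside run ({times[0]:.3f}–{times[-1]:.3f})")

    def nearest_scan(target: float) -> Spectrum:
        idx = int(np.clip(np.searchsorted(times, target), 0, len(times) - 1))
        if idx > 0 and abs(times[idx - 1] - target) < abs(times[idx] - target):
            idx -= 1
        return run.spectra[idx]

    signal = nearest_scan(rt)
    out = signal.intensity.astype(np.float64).copy()
    backgrounds = [nearest_scan(rt + off) for off in bg_offsets]
    for bg in backgrounds:
        if bg.mz.size == 0:
            continue
        # nearest background centroid for each signal centroid, matched within tol
        idx = np.clip(np.searchsorted(bg.mz, signal.mz), 0, bg.mz.size - 1)
        left = np.clip(idx - 1, 0, bg.mz.size - 1)
        use_left = np.abs(bg.mz[left] - signal.mz) < np.abs(bg.mz[idx] - signal.mz)
        nearest = np.where(use_left, left, idx)
        match = np.abs(bg.mz[nearest] - signal.mz) <= mz_tol
        contrib = np.where(match, bg.intensity[nearest].astype(np.float64), 0.0)
        out -= contrib / len(backgrounds)
    return Spectrum(
        rt=signal.rt,
        mz=signal.mz.copy(),
        intensity=np.clip(out, 0, None),
        mode=run.mode,
    )
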