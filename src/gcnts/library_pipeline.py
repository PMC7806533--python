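"""Custom-library construction from reference-sample triplicates and blanks.

The pipeline mirrors how species-specific contaminant libraries are built
from a template sample: deconvolve each reference replicate, classify
components against a reference spectral library (hits keep the best-match
name, the rest get RT identifiers), rename duplicates, align components
across the three replicates, then apply two set filters —

* frequency filter: drop features found in fewer than 2 of 3 replicates;
* blank filter: drop features whose mean blank area *strictly exceeds*
  20% of the mean reference-sample area ("sample area" is read as the mean
  over the reference triplicates, the stable interpretation of the rule).

The surviving components become two disjoint libraries (hits / non-hits)
with quantifier/qualifier ions, expected qualifier ratios, and a filter log
whose counts always satisfy entries_in = entries_out + removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatography import AlkaneLadder, align_features, compute_lri
from .deconvolution import Component, find_components
from .matching import best_matches, rename_duplicates, rt_identifier
from .msdata import LibrarySpectrum, Run, save_library


@dataclass
class LibraryEntry:
    """One screened component retained in a custom library."""

    name: str
    status: str  # "hit" | "non_hit"
    rt: float
    lri: float | None
    spectrum: list[tuple[float, float]]
    quantifier_mz: float
    qualifier_mzs: list[float]
    qualifier_ratios: list[float]
    fraction_id: int
    mean_area: float
    n_replicates: int
    best_score: float


@dataclass
class CustomLibrary:
    """Named entries surviving all filters, plus provenance."""

    entries: list[LibraryEntry]
    reference_code: str
    filter_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # a compound recovered in several Florisil fractions appears once per
        # fraction under the same name; names are unique within a fraction
        keys = [(e.name, e.fraction_id) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("library entry names must be unique per fraction")

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_msp(self, path) -> None:
        save_library(
            [
                LibrarySpectrum(
                    name=e.name,
                    peaks=e.spectrum,
                    rt=e.rt,
                    lri=e.lri,
                    metadata={
                        "Status": e.status,
                        "Fraction": e.fraction_id,
                        "Quantifier": f"{e.quantifier_mz:.4f}",
                    },
                ).normalized()
                for e in self.entries
            ],
            path,
        )


def frequency_filter(
    detections: dict[str, int], min_count: int = 2, n_replicates: int = 3
) -> set[str]:
    """Names detected in at least ``min_count`` of ``n_replicates`` replicates."""
    if min_count > n_replicates:
        raise ValueError("min_count cannot exceed the replicate count")
    bad = [n for n, c in detections.items() if c > n_replicates]
    if bad:
        raise ValueError(f"detection count exceeds replicate count for {bad}")
    return {name for name, count in detections.items() if count >= min_count}


def blank_filter(
    entry_areas: dict[str, float],
    blank_areas: dict[str, float],
    frac: float = 0.20,
) -> set[str]:
    """Names retained by the blank rule.

    An entry is removed iff its mean blank area strictly exceeds
    ``frac`` × its mean sample area; absent from blanks always retains.
    A blank-only feature (sample area 0, blank area > 0) is removed.
    """
    retained = set()
    for name, sample_area in entry_areas.items():
        if sample_area < 0:
            raise ValueError("areas must be non-negative")
        blank = blank_areas.get(name, 0.0)
        if blank > frac * sample_area:
            continue
        retained.add(name)
    return retained


def build_custom_library(
    reference_runs: list[Run],
    blank_runs: list[Run],
    ref_library: list[LibrarySpectrum],
    threshold: float = 60.0,
    snr_min: float = 3.0,
    rt_tol: float = 0.05,
    min_count: int = 2,
    blank_frac: float = 0.20,
    ladder: AlkaneLadder | None = None,
) -> tuple[CustomLibrary, CustomLibrary]:
    """Build (hits, non_hits) libraries from one fraction's reference triplicate.

    ``reference_runs`` are the ≥3 replicate EI runs of the template sample for
    a single Florisil fraction; ``blank_runs`` are the blank injections of the
    same fraction.  Deterministic given identical inputs.
    """
    if len(reference_runs) < 3:
        raise ValueError("need at least 3 reference replicate runs")
    if not blank_runs:
        raise ValueError("need at least 1 blank run")
    fractions = {r.sample_meta.fraction_id for r in reference_runs}
    if len(fractions) != 1:
        raise ValueError("reference runs must come from a single fraction")
    fraction_id = fractions.pop()
    ref_code = reference_runs[0].sample_meta.sample_code

    per_replicate: dict[str, list[Component]] = {}
    for run in reference_runs:
        rep = f"r{run.sample_meta.replicate_id}"
        per_replicate[rep] = find_components(run, snr_min=snr_min)

    # align replicate components by apex RT; each group is one candidate feature
    peak_lists = {
        rep: [_component_stub(c) for c in comps] for rep, comps in per_replicate.items()
    }
    comp_lookup = {
        (rep, round(c.rt_apex, 6)): c
        for rep, comps in per_replicate.items()
        for c in comps
    }
    groups = align_features(peak_lists, rt_tol=rt_tol)

    candidates = []  # (representative component, detection count, mean area, rt)
    for g in groups:
        members = [
            comp_lookup[(rep, round(p.rt_apex, 6))] for rep, p in g["peaks"].items()
        ]
        representative = max(members, key=lambda c: c.total_area)
        mean_area = float(np.mean([c.total_area for c in members]))
        candidates.append((representative, len(members), mean_area, g["rt"]))

    n_in = len(candidates)

    # classification + naming (priority order: best score desc, earlier rt)
    scored = []
    for comp, count, mean_area, rt in candidates:
        matches = best_matches(comp.spectrum, ref_library, n=1) if ref_library else []
        score = matches[0].score if matches else 0.0
        if score > threshold:
            status, name = "hit", matches[0].library_name
        else:
            status, name = "non_hit", rt_identifier(rt)
        scored.append((comp, count, mean_area, rt, status, name, score))
    scored.sort(key=lambda x: (-x[6], x[3]))
    unique_names = rename_duplicates([s[5] for s in scored])

    named = [
        (comp, count, mean_area, rt, status, uname, score)
        for (comp, count, mean_area, rt, status, _n, score), uname in zip(
            scored, unique_names
        )
    ]

    # frequency filter
    detections = {uname: count for _c, count, _a, _rt, _s, uname, _sc in named}
    freq_kept = frequency_filter(detections, min_count=min_count, n_replicates=len(reference_runs))
    n_removed_freq = n_in - len(freq_kept)

    # blank filter: mean blank quantifier area aligned to entry RT
    blank_components: dict[str, list] = {}
    for i, run in enumerate(blank_runs):
        blank_components[f"b{i}"] = [
            _component_stub(c) for c in find_components(run, snr_min=snr_min)
        ]
    sample_areas = {}
    blank_areas = {}
    for comp, count, mean_area, rt, status, uname, score in named:
        if uname not in freq_kept:
            continue
        sample_areas[uname] = mean_area
        areas = []
        for blist in blank_components.values():
            matching = [p.area for p in blist if abs(p.rt_apex - rt) <= rt_tol]
            areas.append(max(matching) if matching else 0.0)
        blank_areas[uname] = float(np.mean(areas)) if areas else 0.0
    blank_kept = blank_filter(sample_areas, blank_areas, frac=blank_frac)
    n_removed_blank = len(freq_kept) - len(blank_kept)

    hits, non_hits = [], []
    for comp, count, mean_area, rt, status, uname, score in named:
        if uname not in blank_kept:
            continue
        entry = LibraryEntry(
            name=uname,
            status=status,
            rt=rt,
            lri=_safe_lri(rt, ladder),
            spectrum=comp.spectrum,
            quantifier_mz=comp.quantifier_mz,
            qualifier_mzs=comp.qualifier_mzs,
            qualifier_ratios=comp.qualifier_ratios,
            fraction_id=fraction_id,
            mean_area=mean_area,
            n_replicates=count,
            best_score=score,
        )
        (hits if status == "hit" else non_hits).append(entry)

    log = {
        "entries_in": n_in,
        "removed_frequency": n_removed_freq,
        "removed_blank": n_removed_blank,
        "entries_out": len(hits) + len(non_hits),
    }
    hits.sort(key=lambda e: (e.rt, e.name))
    non_hits.sort(key=lambda e: (e.rt, e.name))
    return (
        CustomLibrary(hits, reference_code=ref_code, filter_log=dict(log)),
        CustomLibrary(non_hits, reference_code=ref_code, filter_log=dict(log)),
    )


def _component_stub(c: Component):
    """Adapter so components can ride through :func:`align_features`."""
    from .chromatography import ChromPeak

    return ChromPeak(
        rt_apex=c.rt_apex,
        rt_start=c.rt_apex,
        rt_end=c.rt_apex,
        area=c.total_area,
        height=c.total_area,
        snr=np.inf,
    )


def _safe_lri(rt: float, ladder: AlkaneLadder | None) -> float | None:
    if ladder is None:
        return None
    try:
        return round(compute_lri(rt, ladder), 1)
    except ValueError:
        return None
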