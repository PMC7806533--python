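"""Synthetic Baltic-food-web GC-HRMS dataset with known ground truth.

The generator emulates the study design the pipeline is built for: pooled
biota samples from a benthic/pelagic food web (blue mussel → eelpout;
herring → seals/porpoise), extracted in triplicate, split over three
Florisil fractions, and injected in EI and ECNI mode on a 1 spectrum/s
GC-QTOF.  Every run is a set of centroided spectra in which each compound
is a Gaussian chromatographic peak (default σ = 2 s) whose area is
proportional to its configured lipid-normalized concentration times the
sample's extracted lipid mass.  Two volumetric standards are spiked at a
constant amount per run, independent of lipid mass.  Method and solvent
blanks carry only configured laboratory contaminants plus noise.

Ground truth (true areas, concentrations, and every pairwise BMF) is
recorded alongside, so each downstream stage has a known answer.

What this emulates and what it does not: peaks are ideal Gaussians (no
tailing), isotopologue envelopes are collapsed to single fragments except
for the ECNI halide channels, and noise is additive truncated Gaussian on a
fixed set of m/z channels — enough to exercise S/N gating, replicate
statistics and blank filtering, but not matrix effects or chimeric spectra.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .chromatography import AlkaneLadder, compute_lri
from .halogen import halide_mz
from .msdata import (
    ECNI,
    EI,
    LibrarySpectrum,
    Run,
    SampleMeta,
    Spectrum,
    load_library,
    write_manifest,
    write_run,
)

# natural isotope abundances used as default halide ion yields
_CL_YIELDS = (("35Cl", 0.7576), ("37Cl", 0.2424))
_BR_YIELDS = (("79Br", 0.5069), ("81Br", 0.4931))
_MIXED_YIELDS = (("35Cl", 0.38), ("37Cl", 0.12), ("79Br", 0.25), ("81Br", 0.25))


@dataclass
class CompoundSpec:
    """One synthetic analyte (or volumetric standard, or blank contaminant)."""

    name: str
    rt: float  # apex, minutes
    ei_spectrum: list[tuple[float, float]]  # (mz, relative intensity, base 999)
    ecni_halides: list[tuple[str, float]] = field(default_factory=list)
    fraction_id: int = 1
    conc_per_g_lipid: dict[str, float] = field(default_factory=dict)
    fraction_split: dict[int, float] | None = None  # overrides fraction_id
    present_in_replicates: tuple[int, ...] | None = None  # None = all
    standard_amount: float | None = None  # constant area per run; overrides conc

    def fraction_shares(self) -> dict[int, float]:
        if self.fraction_split:
            return self.fraction_split
        return {self.fraction_id: 1.0}

    @property
    def quantifier_mz(self) -> float:
        return max(self.ei_spectrum, key=lambda p: p[1])[0]


@dataclass
class SampleTemplate:
    """One pooled sample (Table-1 style metadata)."""

    code: str
    species: str
    tissue: str
    trophic_role: str
    sample_weight_g: float
    lipid_content_pct: float
    n_replicates: int = 3
    is_blank: bool = False

    @property
    def lipid_mass_g(self) -> float:
        if self.is_blank:
            return 1.0  # nominal, keeps normalization defined
        return self.sample_weight_g * self.lipid_content_pct / 100.0


@dataclass
class FoodWebSpec:
    """Complete description of one synthetic experiment."""

    samples: list[SampleTemplate]
    compounds: list[CompoundSpec]
    standards: list[CompoundSpec]
    seed: int | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)
    noise_sd: float = 20.0
    noise_floor: float = 60.0  # flat channel baseline; keeps MAD well defined
    replicate_cv: float = 0.05  # lognormal CV per compound per run
    injection_cv: float = 0.05  # lognormal CV per run, shared by all compounds
    mz_jitter_sd: float = 0.0005  # Da, per-centroid
    peak_sigma_s: float = 2.0
    scan_hz: float = 1.0
    duration_min: float = 48.0  # EI oven program: 80 °C 2 min + 5 °C/min to 300 + 2 min
    ecni_duration_min: float = 53.0  # ECNI runs to 325 °C
    n_noise_channels: int = 20
    baseline: dict | None = None  # unresolved-hydrocarbon hump, see _hump_channels

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("FoodWebSpec.seed is mandatory (reproducibility)")
        roles = {s.trophic_role for s in self.samples}
        if not {"blank_method", "blank_solvent"} <= roles:
            raise ValueError("spec must include method and solvent blanks")
        if any(s.n_replicates != 3 for s in self.samples):
            raise ValueError("every sample must have 3 replicates")

    def noiseless(self) -> "FoodWebSpec":
        """Copy with every stochastic ingredient switched off."""
        return replace(
            self,
            noise_sd=0.0,
            noise_floor=0.0,
            replicate_cv=0.0,
            injection_cv=0.0,
            mz_jitter_sd=0.0,
            baseline=None,
            n_noise_channels=0,
        )

    def duration_for(self, mode: str) -> float:
        return self.ecni_duration_min if mode == ECNI else self.duration_min

    def true_bmf(self) -> dict[str, dict[str, float | None]]:
        """Ground-truth BMF per pair: ratio of configured concentrations."""
        out: dict[str, dict[str, float | None]] = {}
        for pred, prey in self.pairs:
            label = f"{pred}:{prey}"
            out[label] = {}
            for comp in self.compounds:
                cp = comp.conc_per_g_lipid.get(pred, 0.0)
                cq = comp.conc_per_g_lipid.get(prey, 0.0)
                out[label][comp.name] = (cp / cq) if cp > 0 and cq > 0 else None
        return out


# ---------------------------------------------------------------------------
# Default study design
# ---------------------------------------------------------------------------

#: (code, species, tissue, trophic_role, sample weight g, lipid %)
_SAMPLE_TABLE = [
    ("BM", "blue mussel", "flesh", "filter_feeder", 20.0, 2.1),
    ("EM", "eelpout", "muscle", "benthic_fish", 50.0, 0.5),
    ("HL", "herring", "liver", "pelagic_fish", 4.4, 7.1),
    ("HM", "herring", "muscle", "pelagic_fish", 40.0, 6.3),
    ("GSM", "grey seal", "muscle", "top_consumer", 50.0, 0.5),
    ("HSB", "harbor seal", "blubber", "top_consumer", 4.5, 82.0),
    ("HSL", "harbor seal", "liver", "top_consumer", 9.4, 5.0),
    ("HSM", "harbor seal", "muscle", "top_consumer", 49.0, 0.9),
    ("HPB", "harbor porpoise", "blubber", "top_consumer", 4.4, 80.0),
    ("HPL", "harbor porpoise", "liver", "top_consumer", 9.7, 8.8),
    ("HPM", "harbor porpoise", "muscle", "top_consumer", 49.0, 2.7),
]

DEFAULT_PAIRS = [
    ("EM", "BM"),
    ("GSM", "HM"),
    ("HSM", "HM"),
    ("HSL", "HM"),
    ("HSB", "HM"),
    ("HPM", "HM"),
    ("HPL", "HM"),
    ("HPB", "HM"),
]

#: core analytes: (name, rt min, fraction, halide class, fraction_split)
_CORE_CATALOG = [
    ("Sesquiterpene-A", 7.10, 1, None, None),
    ("Sesquiterpene-B", 8.30, 1, None, None),
    ("Bornyl-chloride-like", 8.90, 1, "Cl", None),
    ("Terpenoid-C", 9.60, 1, None, None),
    ("Terpenoid-D", 10.90, 1, None, None),
    ("Terpenoid-E", 12.20, 1, None, None),
    ("Hexahydroindene-F", 13.50, 1, None, None),
    ("Phenanthrene-like", 23.10, 2, None, None),
    ("PCB-like-052", 26.20, 1, "Cl", None),
    ("MHC-1-like", 28.00, 2, "ClBr", None),
    ("Fluoranthene-like", 28.50, 2, None, None),
    ("Q1-like", 29.10, 1, "Cl", None),
    ("PCB-like-101", 29.50, 1, "Cl", None),
    ("Pyrene-like", 29.70, 2, None, None),
    ("DDE-like", 30.60, 1, "Cl", {1: 0.7, 2: 0.3}),
    ("PCB-like-118", 31.80, 1, "Cl", None),
    ("DDD-like", 32.20, 2, "Cl", None),
    ("PCB-like-153", 32.70, 1, "Cl", None),
    ("DDT-like", 33.50, 1, "Cl", None),
    ("PCB-like-138", 33.90, 1, "Cl", None),
    ("PCB-like-187", 34.40, 1, "Cl", None),
    ("BDE-like-047", 35.80, 2, "Br", {2: 0.6, 1: 0.25, 3: 0.15}),
    ("PCB-like-180", 36.00, 1, "Cl", None),
    ("Sterol-like-A", 36.40, 3, None, None),
    ("PCB-like-170", 37.00, 1, "Cl", None),
    ("MeO-BDE-like-068", 37.40, 3, "Br", None),
    ("Sterol-like-B", 37.90, 3, None, None),
    ("BDE-like-099", 39.80, 1, "Br", None),
    ("Cholestadiene-like", 39.90, 3, None, None),
    ("BDE-like-153", 43.30, 1, "Br", None),
]

_SPORADIC_CATALOG = [("Sporadic-X", 14.80, 1), ("Sporadic-Y", 24.30, 2)]
#: (name, rt, fraction, blank area as fraction of the EM-sample area)
_CONTAMINANT_CATALOG = [
    ("BHT-like-antioxidant", 9.95, 1, 0.5),
    ("Alkylphenol-antioxidant", 16.40, 2, 0.1),
]
_STANDARD_CATALOG = [("VS-13C-CB-097", 26.80), ("VS-13C-CB-188", 35.20)]

#: true BMF values cycled over (compound, pair)
_BMF_LEVELS = [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0]

_HALIDE_CLASS = {"Cl": _CL_YIELDS, "Br": _BR_YIELDS, "ClBr": _MIXED_YIELDS}


def toy_library_path() -> Path:
    """Bundled ~36-entry EI reference library (NIST stand-in)."""
    return Path(importlib.resources.files("gcnts") / "data" / "toy_library.msp")


def default_ladder() -> AlkaneLadder:
    """n-alkane ladder consistent with the default oven program."""
    return AlkaneLadder([(n, 4.0 + 1.75 * (n - 6)) for n in range(6, 31)])


def _toy_spectra() -> dict[str, LibrarySpectrum]:
    return {e.name: e for e in load_library(toy_library_path())}


def default_foodweb_spec(seed: int) -> FoodWebSpec:
    """The full default study design: 11 biota samples + 2 blanks, ~30 analytes."""
    spectra = _toy_spectra()
    samples = [
        SampleTemplate(code, sp, ti, role, w, lp)
        for code, sp, ti, role, w, lp in _SAMPLE_TABLE
    ] + [
        SampleTemplate("MB", "method blank", "none", "blank_method", 1.0, 0.0, is_blank=True),
        SampleTemplate("SB", "solvent blank", "none", "blank_solvent", 1.0, 0.0, is_blank=True),
    ]
    biota = [s.code for s in samples if not s.is_blank]

    compounds: list[CompoundSpec] = []
    for i, (name, rt, fr, hal, split) in enumerate(_CORE_CATALOG):
        base = 1.0e5 * (1.6 ** (i % 5))
        conc = {"HM": base, "HL": 0.8 * base, "BM": 0.9 * base}
        for j, (pred, prey) in enumerate(DEFAULT_PAIRS):
            conc[pred] = _BMF_LEVELS[(i + j) % len(_BMF_LEVELS)] * conc[prey]
        compounds.append(
            CompoundSpec(
                name=name,
                rt=rt,
                ei_spectrum=spectra[name].peaks,
                ecni_halides=list(_HALIDE_CLASS.get(hal, ())),
                fraction_id=fr,
                conc_per_g_lipid=conc,
                fraction_split=split,
            )
        )
    for name, rt, fr in _SPORADIC_CATALOG:
        compounds.append(
            CompoundSpec(
                name=name,
                rt=rt,
                ei_spectrum=spectra[name].peaks,
                fraction_id=fr,
                conc_per_g_lipid={c: 2.0e5 for c in biota},
                present_in_replicates=(1,),
            )
        )
    em_lipid = next(s.lipid_mass_g for s in samples if s.code == "EM")
    for name, rt, fr, blank_ratio in _CONTAMINANT_CATALOG:
        conc = {c: 2.0e5 for c in biota}
        conc["MB"] = conc["SB"] = blank_ratio * 2.0e5 * em_lipid  # blank lipid = 1 g
        compounds.append(
            CompoundSpec(
                name=name,
                rt=rt,
                ei_spectrum=spectra[name].peaks,
                fraction_id=fr,
                conc_per_g_lipid=conc,
            )
        )
    standards = [
        CompoundSpec(
            name=name,
            rt=rt,
            ei_spectrum=spectra[name].peaks,
            ecni_halides=list(_CL_YIELDS),
            fraction_id=1,
            fraction_split={1: 1.0, 2: 1.0, 3: 1.0},  # added to every fraction vial
            standard_amount=2.0e5,
        )
        for name, rt in _STANDARD_CATALOG
    ]
    return FoodWebSpec(
        samples=samples,
        compounds=compounds,
        standards=standards,
        pairs=list(DEFAULT_PAIRS),
        seed=seed,
    )


def small_foodweb_spec(seed: int) -> FoodWebSpec:
    """Reduced food web for fast end-to-end demonstrations.

    Four biota samples + both blanks, 8 analytes, 20-minute runs (compound
    RTs compressed into the shorter window).  Same noise model and rules.
    """
    full = default_foodweb_spec(seed)
    keep_samples = {"BM", "EM", "HM", "HPB", "MB", "SB"}
    keep_compounds = [
        "Sesquiterpene-A",
        "Bornyl-chloride-like",
        "Terpenoid-C",
        "PCB-like-052",
        "DDE-like",
        "BDE-like-047",
        "Sporadic-X",
        "BHT-like-antioxidant",
    ]

    def squeeze(rt: float) -> float:
        return round(3.0 + (rt - 6.0) * (14.5 / 38.0), 3)

    samples = [s for s in full.samples if s.code in keep_samples]
    compounds = [
        replace(c, rt=squeeze(c.rt)) for c in full.compounds if c.name in keep_compounds
    ]
    # standards placed well clear of every analyte: in the compressed RT
    # window the default positions would put the ¹³C standards' Cl⁻ signal on
    # the shoulder of large PCB peaks, biasing the area ratios
    standard_rts = {"VS-13C-CB-097": 9.0, "VS-13C-CB-188": 16.5}
    standards = [replace(s, rt=standard_rts[s.name]) for s in full.standards]
    return FoodWebSpec(
        samples=samples,
        compounds=compounds,
        standards=standards,
        pairs=[("EM", "BM"), ("HPB", "HM")],
        seed=seed,
        duration_min=20.0,
        ecni_duration_min=20.0,
        n_noise_channels=8,
    )


# ---------------------------------------------------------------------------
# Run synthesis
# ---------------------------------------------------------------------------


def run_id(sample_code: str, replicate: int, fraction: int, mode: str) -> str:
    return f"{sample_code}_r{replicate}_f{fraction}_{mode}"


def _hump_channels(baseline: dict, mass_range: tuple[float, float]) -> list[float]:
    """m/z channels carrying the unresolved-hydrocarbon hump (CnH2n+1 series)."""
    if "channels" in baseline:
        return list(baseline["channels"])
    lo, hi = mass_range
    series = [57.0699 + 14.01565 * k for k in range(0, 24)]
    return [m for m in series if lo <= m <= hi]


def _mode_mass_range(mode: str) -> tuple[float, float]:
    return (33.0, 650.0) if mode == ECNI else (48.0, 450.0)


def generate_run(
    spec: FoodWebSpec,
    template: SampleTemplate,
    replicate: int,
    fraction: int,
    mode: str = EI,
) -> tuple[Run, dict[str, float]]:
    """Synthesize one injection; returns the run and its true base-peak areas.

    True areas are the actually injected analytic Gaussian areas (after the
    per-run injection factor and per-compound replicate variability), in
    intensity·seconds, keyed by compound name; volumetric standards are
    included under their own names.
    """
    seed_seq = np.random.SeedSequence(
        [
            int(spec.seed),
            int.from_bytes(template.code.encode(), "little"),
            int(replicate),
            int(fraction),
            0 if mode == EI else 1,
        ]
    )
    rng = np.random.default_rng(seed_seq)
    duration = spec.duration_for(mode)
    n_scans = int(round(duration * 60.0 * spec.scan_hz))
    t_s = np.arange(n_scans, dtype=np.float64) / spec.scan_hz
    sigma = spec.peak_sigma_s

    inj = (
        float(rng.lognormal(mean=0.0, sigma=spec.injection_cv))
        if spec.injection_cv > 0
        else 1.0
    )

    # channel m/z → list of (t0_s, height)
    channels: dict[float, list[tuple[float, float]]] = {}
    true_areas: dict[str, float] = {}

    def add_peak(mz: float, t0_s: float, height: float) -> None:
        channels.setdefault(round(mz, 5), []).append((t0_s, height))

    height_norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for comp in list(spec.compounds) + list(spec.standards):
        share = comp.fraction_shares().get(fraction, 0.0)
        if share <= 0:
            continue
        if comp.present_in_replicates is not None and replicate not in comp.present_in_replicates:
            continue
        if comp.standard_amount is not None:
            amount = comp.standard_amount
        else:
            conc = comp.conc_per_g_lipid.get(template.code, 0.0)
            if conc <= 0:
                continue
            amount = conc * template.lipid_mass_g
        eps = (
            float(rng.lognormal(mean=0.0, sigma=spec.replicate_cv))
            if spec.replicate_cv > 0
            else 1.0
        )
        area = amount * inj * eps * share
        if comp.rt > duration - 0.5:
            continue
        true_areas[comp.name] = true_areas.get(comp.name, 0.0) + area
        t0 = comp.rt * 60.0
        if mode == EI:
            for fmz, rel in comp.ei_spectrum:
                add_peak(fmz, t0, area * (rel / 999.0) * height_norm)
        else:
            for iso, yld in comp.ecni_halides:
                add_peak(halide_mz(iso), t0, area * yld * height_norm)

    mass_lo, mass_hi = _mode_mass_range(mode)
    if mode == ECNI:
        # poor ECNI response of non-halogenated matrix: halide channels only,
        # plus a couple of weak background channels
        n_noise = min(spec.n_noise_channels, 4)
    else:
        n_noise = spec.n_noise_channels
    existing = np.array(sorted(channels), dtype=float)
    added = 0
    while added < n_noise:
        mz = float(rng.uniform(mass_lo + 2, mass_hi - 2))
        if existing.size and np.min(np.abs(existing - mz)) < 0.05:
            continue
        channels.setdefault(round(mz, 5), [])
        existing = np.append(existing, mz)
        added += 1

    hump = None
    if spec.baseline and mode == EI:
        hump = dict(spec.baseline)
        for mz in _hump_channels(hump, (mass_lo, mass_hi)):
            channels.setdefault(round(mz, 5), [])

    mz_sorted = np.array(sorted(channels), dtype=np.float64)
    n_ch = mz_sorted.size
    intensity = np.zeros((n_scans, n_ch), dtype=np.float64)
    if spec.noise_sd > 0:
        intensity += rng.normal(spec.noise_floor, spec.noise_sd, size=(n_scans, n_ch))
    else:
        intensity += spec.noise_floor

    for j, mz in enumerate(mz_sorted):
        for t0, h in channels[mz]:
            lo = int(max(0, np.floor((t0 - 8 * sigma) * spec.scan_hz)))
            hi = int(min(n_scans, np.ceil((t0 + 8 * sigma) * spec.scan_hz) + 1))
            intensity[lo:hi, j] += h * np.exp(
                -0.5 * ((t_s[lo:hi] - t0) / sigma) ** 2
            )

    if hump is not None:
        hump_mask = np.isin(
            mz_sorted, np.round(_hump_channels(hump, (mass_lo, mass_hi)), 5)
        )
        profile = hump["amplitude"] * np.exp(
            -0.5 * ((t_s / 60.0 - hump["center_min"]) / hump["sigma_min"]) ** 2
        )
        intensity[:, hump_mask] += profile[:, None]

    np.clip(intensity, 0.0, None, out=intensity)

    meta = SampleMeta(
        sample_code=template.code,
        species=template.species,
        tissue=template.tissue,
        trophic_role=template.trophic_role,
        replicate_id=replicate,
        fraction_id=fraction,
        lipid_mass_g=template.lipid_mass_g,
        is_blank=template.is_blank,
    )

    rt_min = t_s / 60.0
    inten32 = intensity.astype(np.float32)
    if spec.mz_jitter_sd > 0:
        jittered = mz_sorted[None, :] + rng.normal(
            0.0, spec.mz_jitter_sd, size=(n_scans, n_ch)
        )
        channels = (mz_sorted, jittered, inten32.astype(np.float64))

        def build_spectra() -> list[Spectrum]:
            order = np.argsort(jittered, axis=1)
            mz_rows = np.take_along_axis(jittered, order, axis=1)
            int_rows = np.take_along_axis(inten32, order, axis=1)
            return [
                Spectrum(rt=rt_min[i], mz=mz_rows[i], intensity=int_rows[i],
                         mode=mode, validate=False)
                for i in range(n_scans)
            ]

    else:
        channels = (mz_sorted, None, inten32.astype(np.float64))

        def build_spectra() -> list[Spectrum]:
            return [
                Spectrum(rt=rt_min[i], mz=mz_sorted, intensity=inten32[i],
                         mode=mode, validate=False)
                for i in range(n_scans)
            ]

    run = Run(
        None,
        meta,
        mode=mode,
        channels=channels,
        spectra_factory=build_spectra,
        scan_times=rt_min,
    )
    return run, true_areas


def generate_blank(
    spec: FoodWebSpec,
    kind: str = "method",
    replicate: int = 1,
    fraction: int = 1,
    mode: str = EI,
) -> Run:
    """One blank injection: configured laboratory contaminants + noise only."""
    role = f"blank_{kind}"
    template = next(s for s in spec.samples if s.trophic_role == role)
    run, _ = generate_run(spec, template, replicate, fraction, mode)
    return run


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------


class SimulatedDataset:
    """In-memory collection of synthetic runs plus ground truth."""

    def __init__(self, spec: FoodWebSpec, runs: dict[str, Run], truth: dict):
        self.spec = spec
        self.runs = runs
        self.truth = truth

    def select(
        self,
        sample_code: str | None = None,
        mode: str | None = None,
        fraction: int | None = None,
        replicate: int | None = None,
        include_blanks: bool = True,
    ) -> list[Run]:
        out = []
        for run in self.runs.values():
            m = run.sample_meta
            if sample_code is not None and m.sample_code != sample_code:
                continue
            if mode is not None and run.mode != mode:
                continue
            if fraction is not None and m.fraction_id != fraction:
                continue
            if replicate is not None and m.replicate_id != replicate:
                continue
            if not include_blanks and m.is_blank:
                continue
            out.append(run)
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write mzML runs, manifest.csv, truth.yaml, ladder and library copy."""
        out_dir = Path(out_dir)
        (out_dir / "runs").mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for rid, run in self.runs.items():
            fname = f"runs/{rid}.mzML"
            write_run(run, out_dir / fname)
            m = run.sample_meta
            manifest_rows.append(
                {
                    "run_file": fname,
                    "sample_code": m.sample_code,
                    "species": m.species,
                    "tissue": m.tissue,
                    "trophic_role": m.trophic_role,
                    "replicate_id": m.replicate_id,
                    "fraction_id": m.fraction_id,
                    "mode": run.mode,
                    "lipid_mass_g": m.lipid_mass_g,
                    "is_blank": m.is_blank,
                }
            )
        write_manifest(manifest_rows, out_dir / "manifest.csv")
        with open(out_dir / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)
        default_ladder().to_csv(out_dir / "alkane_ladder.csv")


def generate_foodweb(
    spec: FoodWebSpec,
    modes: tuple[str, ...] = (EI, ECNI),
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate every sample × replicate × fraction × mode run plus truth."""
    ladder = default_ladder()
    runs: dict[str, Run] = {}
    areas: dict[str, dict[str, float]] = {}
    for template in spec.samples:
        for rep in range(1, template.n_replicates + 1):
            for fraction in (1, 2, 3):
                for mode in modes:
                    run, true_areas = generate_run(spec, template, rep, fraction, mode)
                    rid = run_id(template.code, rep, fraction, mode)
                    runs[rid] = run
                    areas[rid] = true_areas

    def lri_of(rt: float) -> float:
        try:
            return round(compute_lri(rt, ladder), 1)
        except ValueError:
            return float("nan")

    truth = {
        "pairs": [f"{p}:{q}" for p, q in spec.pairs],
        "true_bmf": spec.true_bmf(),
        "conc_per_g_lipid": {
            s.code: {
                c.name: c.conc_per_g_lipid.get(s.code, 0.0) for c in spec.compounds
            }
            for s in spec.samples
        },
        "compounds": {
            c.name: {
                "rt": c.rt,
                "lri": lri_of(c.rt),
                "fractions": c.fraction_shares(),
                "quantifier_mz": c.quantifier_mz,
                "halides": dict(c.ecni_halides),
                "sporadic": c.present_in_replicates is not None,
            }
            for c in spec.compounds
        },
        "standards": {
            s.name: {"rt": s.rt, "amount": s.standard_amount} for s in spec.standards
        },
        "true_areas": areas,
    }
    dataset = SimulatedDataset(spec, runs, truth)
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
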