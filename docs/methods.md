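# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `gcnts`. It is written for users who need to judge what
a passing test suite does — and does not — demonstrate about real data.

## The screening model

The pipeline implements the two-step design used in non-target screening of
food-web biota by GC-HRMS. In step one, *reference (template) samples* —
fish muscle, because fish are the intermediate trophic link for which both
upward and downward pairs exist — are deconvolved into components and
classified against a reference EI library. Components whose best
mass-weighted cosine score is **strictly above 60** are *hits* and inherit
the library name; everything else is a *non-hit* named `RT_<rt to 0.01 min>`.
Since similar spectra can attract the same name, duplicates are renamed
(`name`, `name_2`, …; priority: higher score, then earlier RT). Two set
filters follow:

* **frequency filter** — a feature found in fewer than 2 of the 3 reference
  replicates is discarded (irreproducible detections);
* **blank filter** — a feature whose mean area in the method/solvent blank
  triplicates *strictly exceeds* 20% of its mean area in the reference
  triplicates is discarded (laboratory background). "Sample area" is read
  as the mean over the reference triplicates; the replicate-wise reading
  would make the rule depend on replicate ordering.

In step two every sample is *re-screened, targeted*, against the surviving
library: the quantifier-ion EIC is extracted, the S/N ≥ 3 peak nearest the
entry's RT (± 0.1 min) is integrated, and the qualifier-ion ratios are
compared with the library's expectation (± 30% relative). Deviating rows
are flagged `qualifier_out` but kept — the flag models the manual scrutiny
step of a human reviewer, and silently dropping rows would bias BMFs.

A complementary ECNI (electron-capture negative ionization) channel screens
for halogenated compounds that respond poorly or invisibly in EI: EICs of
the four halide anions are extracted at masses computed as *neutral isotope
mass + electron mass* (³⁵Cl⁻ 34.9694, ³⁷Cl⁻ 36.9665, ⁷⁹Br⁻ 78.9189,
⁸¹Br⁻ 80.9168 Da at 4 decimals). The light/heavy channels of one element
are merged per feature (areas summed; the observed isotope ratio is kept as
a QC value), and Cl and Br channels are never merged.

## Biomagnification factors

Without quantification standards, concentrations are proxied by **area
ratios**: AR = (lipid-normalized component area) / (area of the
closest-eluting volumetric standard). The standard is spiked at a constant
amount per injection, so the ratio cancels injection-volume and detector
drift; lipid normalization (area ÷ grams of lipid originally extracted)
puts samples of very different fat content (0.5–82%) on a common basis.
Then

    BMF = C(predator)/C(prey) ≈ AR(predator)/AR(prey)

Aggregation rules: per Florisil fraction, the **geometric mean** over the
triplicate ARs (robust to the multiplicative, roughly lognormal
run-to-run variability; a missing replicate reduces n); across fractions,
the **sum** of the fraction-level means (the compound's signal is split by
the fractionation, so the fractions are additive contributions). The order
— mean within fraction first, then sum — damps replicate noise before
summation; the opposite order would geometric-average already-summed
quantities and is not what the aggregation is meant to express. A feature
undetected in either member of a pair yields an undefined BMF serialized as
`#N/A`; zero-imputation would fabricate infinite or zero BMFs.

Two invariants worth stating because the tests rely on them: BMF is
invariant under any global scale factor applied to a whole run (analyte and
standard scale together), and on noiseless data BMF(a,b)·BMF(b,c) =
BMF(a,c).

## Peak detection

EICs are one point per scan (zeros kept). Detection is two-stage:

1. **Candidates** come from the trace smoothed with a Gaussian kernel whose
   width equals the nominal chromatographic peak sigma (2 s) — a matched
   filter. Peak bounds sit at the nearest smoothed local minima; flat-topped
   apexes (a peak centered between two samples) are handled explicitly.
2. **Gates.** A candidate must pass the documented S/N rule — raw height
   above a straight baseline drawn between the bounds, divided by
   1.4826 × MAD of a ± 0.5 min surrounding window with the peak span
   excluded, at least `snr_min` = 3 — *and* a matched-filter significance
   test: the least-squares Gaussian height over its standard error must
   reach `z_detect` = 6. The second gate exists because a run scans ~10⁵
   noise points; a bare 3σ height gate would fire dozens of times per blank
   run, while a genuine peak spread over the expected width carries
   √(Σg²) ≈ 1.9× more matched evidence than its apex height. With these
   defaults, an S/N-5 peak is detected and an S/N-2 peak rejected ≥ 90% of
   the time, and pure-noise blanks yield no components.

Areas are trapezoidal integrals of the raw trace above the linear
between-bounds baseline, in intensity·seconds; at 1 spectrum/s and σ = 2 s
the sampled area is within 0.5% of the analytic Gaussian area. Peaks whose
bounds hit the trace edge are discarded on noisy traces (the baseline under
them is unconstrained). Noise exactly zero (noiseless synthetic data) gives
S/N = ∞ so closed-form tests are never gated away.

## Deconvolution

Centroids are clustered on the m/z axis by gap clustering (break at > 0.005
Da — mirroring the EIC tolerance) into per-ion traces. Ion peaks are
grouped into components greedily: the largest unassigned peak seeds a
cluster and collects peaks whose apex lies within 2 s and whose trace
correlates (Pearson ≥ 0.9) with the seed's over the seed's span. The
quantifier is the largest-area ion; the 2nd/3rd largest become qualifiers,
with expected ratios taken from the component itself — the same way
quantification methods derive qualifier ratios from reference samples.
On noisy data a weak fragment can fail the correlation gate and appear as a
single-ion splinter at the same RT; the replicate-alignment step absorbs
these (each replicate contributes its largest component per RT group), so
they do not reach the library.

## Spectral similarity and formulas

The score is the Stein–Scott weighted cosine: peaks binned to unit mass,
weights `intensity^0.5 · mz^1.3`, score `100·(Σ w_a w_b)²/(Σ w_a²·Σ w_b²)`
over shared bins. Identity scores 100, disjoint spectra 0, and the score is
symmetric and scale-invariant. The exponents are configurable; the defaults
are the classic library-search settings.

Formula generation is exhaustive enumeration over bounded element ranges
({C,H,N,O,S,P,Cl,Br}) with a ppm window; for anions one electron mass is
added before comparison. DBE uses the neutral-molecule convention with
halogens counted like hydrogen, DBE = C + 1 + N/2 − (H+Cl+Br)/2, which
gives dbe(C15H24) = 4 and dbe(C6Cl6) = 4; the even-electron-ion convention
(−0.5, e.g. squalene C30H50 → 5.5) is available as a flag because both
conventions appear in practice.

Retention indices use the van den Dool & Kratz linear form against an
n-alkane ladder. Absolute LRI values depend entirely on the ladder supplied;
only the formula's properties (exactness on ladder points, linearity,
monotonicity) are portable.

## The synthetic food web

The generator emulates the study design the pipeline targets: 11 pooled
biota samples (mussel, eelpout muscle, herring muscle/liver, grey-seal
muscle, harbor-seal and harbor-porpoise muscle/liver/blubber; lipid
contents 0.5–82% of 4.4–50 g samples), method and solvent blanks,
triplicate injections, three Florisil fractions, and both ionization modes
(EI 48 min / ECNI 53 min at 1 spectrum/s, matching a 80 °C → 300/325 °C
oven program at 5 °C/min).

Signal model per run: each compound is a Gaussian peak (σ = 2 s) on each of
its EI fragment channels (spectra from the bundled 36-entry toy MSP
library, which doubles as the reference library and removes any dependency
on a commercial library), with base-peak area = concentration ×
lipid mass. ECNI-active compounds emit only halide-anion channels with
configured isotope yields (natural ³⁵Cl/³⁷Cl = 0.7576/0.2424,
⁷⁹Br/⁸¹Br = 0.5069/0.4931). Stochastic ingredients, all seeded and all
switchable to zero by `FoodWebSpec.noiseless()`:

| ingredient | default | rationale |
|---|---|---|
| channel noise | additive Gaussian, sd 20, floor 60, clipped at 0 | exercises the S/N gate; the floor keeps the MAD noise estimate well defined |
| replicate variability | lognormal, CV 5% per compound per run | exercises the geometric-mean logic; no published replicate CVs exist for this design, 5% is a typical GC-QTOF figure |
| injection factor | lognormal, CV 5% per run, shared by all compounds | what the volumetric standard is meant to cancel |
| m/z jitter | Gaussian, sd 0.0005 Da per centroid | makes m/z clustering non-degenerate, consistent with sub-3-ppm-class accuracy |
| baseline hump | off by default | optional unresolved-hydrocarbon hump (CnH2n+1 channel series spaced 14 Da) for background-subtraction tests |

True BMFs are configured per (compound, pair) from the ladder
{0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50}; the ground truth records every true
area (after the stochastic factors), every concentration, and every pairwise
BMF. Two compounds are spiked into only one replicate (frequency-filter
fodder), two antioxidant-type lab contaminants appear in blanks and samples
(blank-filter fodder at 50% and 10% of the eelpout-sample area), and two
compounds are split across fractions to exercise the AR summation rule.

A reduced web (4 biota samples, 8 compounds, 20-min runs) supports fast
end-to-end demonstrations; its volumetric standards are placed ≥ 1 min away
from every analyte because in the compressed RT window the standard's Cl⁻
signal would otherwise sit on the shoulder of much larger PCB peaks and the
between-bounds baseline would clip its area (deconvolution of overlapping
peaks within one EIC is out of scope, see Limitations).

**What passing tests show — and don't.** Parameter recovery (noiseless
exactness to < 10⁻⁶; median relative BMF error ≈ 4% over 20 realizations at
5% CV) demonstrates that the chain screening → AR → geometric mean →
fraction sum → ratio is implemented correctly and propagates no systematic
bias. It does not demonstrate robustness to features absent from the
generator: chromatographic tailing, isotopologue envelopes, chimeric
spectra from severe co-elution, matrix-dependent response, or RT drift
between runs (alignment here only handles jitter within ± 0.05 min).

## Numerical and determinism choices

* All randomness flows from one integer seed through per-run
  `SeedSequence`s keyed by (seed, sample, replicate, fraction, mode), so a
  dataset is byte-identical across executions and independent of which
  subset of runs is generated.
* Intensities are stored as 32-bit floats (as written to mzML), m/z as
  64-bit; noiseless "exactness" is therefore limited by float32
  quantization (~10⁻⁷ relative), well below the 10⁻⁶ test tolerance.
* CSV/MSP writers use fixed float formats and fully specified sort orders
  (rt, then name, then sample/replicate/fraction; ties in alignment resolve
  to earlier RT), making every output file reproducible byte-for-byte.
* EIC extraction tolerance defaults to ± 0.005 Da, a conservative window
  for sub-3-ppm instruments at m/z ≤ 650.
* The mzML and MSP codecs are implemented in-package (centroid MS1 mzML
  with zlib-compressed 64/32-bit arrays; the Name/RT/RI/Num Peaks MSP
  dialect) and are round-trip-tested; the MSP reader rejects entries whose
  declared peak count disagrees with the parsed peaks, naming the entry.

## Limitations

* No deconvolution of overlapping chromatographic peaks *within one EIC*:
  a small peak on the shoulder of a much larger one loses part of its area
  to the between-bounds baseline.
* Non-hit features are identified by RT only; two different compounds
  co-eluting in different fractions can share an RT identifier and would be
  summed as one feature.
* Screening is fraction-exact: a compound leaking into an unconfigured
  fraction would be missed there.
* BMFs are point estimates; no uncertainty is propagated, and diet-weighted
  multi-prey BMFs and trophic magnification factors (regression over
  trophic level) are out of scope.
* The ECNI model treats halide yield as compound-constant; real
  electron-capture response varies with source conditions.
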