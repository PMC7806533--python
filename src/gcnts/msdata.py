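"""Domain containers and file I/O: mzML runs, MSP libraries, manifests, tables.

A :class:`Run` is one GC-MS injection (one Florisil fraction of one sample)
holding RT-ordered centroided spectra.  Sample metadata travels in a separate
manifest file keyed by run filename, because mzML has no standard slots for
lipid mass or trophic role.

mzML support is a minimal standards-conformant reader/writer pair (64-bit
m/z, 32-bit intensity, zlib-compressed, centroid MS1 cvParams) so that
load∘write is bit-identical on both arrays; the reader handles centroided
MS1 mzML as produced by common converters and rejects profile-mode data.

MSP follows the common NIST text dialect::

    Name: <text>
    RT: <minutes>            (optional)
    RI: <retention index>    (optional)
    Num Peaks: <n>
    <mz> <intensity> [<mz> <intensity> ...]

Peak intensities are rescaled on load so the base peak is 999.
"""

from __future__ import annotations

import base64
import io
import zlib
from dataclasses import InitVar, dataclass, field, replace
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

EI = "EI"
ECNI = "ECNI"

TROPHIC_ROLES = (
    "filter_feeder",
    "benthic_fish",
    "pelagic_fish",
    "top_consumer",
    "blank_method",
    "blank_solvent",
)


class MzMLError(ValueError):
    """Malformed or unsupported mzML content."""


class MSPError(ValueError):
    """Malformed MSP library content."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and normalization metadata for one injected extract."""

    sample_code: str
    species: str
    tissue: str
    trophic_role: str
    replicate_id: int
    fraction_id: int
    lipid_mass_g: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.trophic_role not in TROPHIC_ROLES:
            raise ValueError(f"unknown trophic role {self.trophic_role!r}")
        if self.fraction_id not in (1, 2, 3):
            # the 4th Florisil fraction carries too much matrix and is never analyzed
            raise ValueError("fraction_id must be 1, 2 or 3")
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be >= 1")
        if self.lipid_mass_g <= 0:
            raise ValueError("lipid_mass_g must be positive (blanks use nominal 1)")


@dataclass
class Spectrum:
    """One centroided scan: RT in minutes, ascending m/z in Da, intensities."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = EI
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if not validate:
            return
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.rt < 0:
            raise ValueError("rt must be >= 0")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ValueError("intensities must be >= 0")


class Run:
    """One GC-MS acquisition: RT-ordered spectra plus sample metadata.

    ``channels`` is an optional fast-access cache used by in-memory synthetic
    runs whose centroids live on a fixed set of m/z channels: a tuple
    ``(centers, mz_matrix, intensity_matrix)`` with ``centers`` the channel
    m/z values, ``mz_matrix`` the per-scan jittered m/z (or ``None`` when all
    scans share ``centers``), and ``intensity_matrix`` of shape
    (n_scans, n_channels).  It is equivalent to — and cross-checked against —
    the generic per-spectrum representation.
    """

    def __init__(
        self,
        spectra: list[Spectrum] | None,
        sample_meta: SampleMeta,
        mode: str = EI,
        channels: tuple[np.ndarray, np.ndarray | None, np.ndarray] | None = None,
        validate: bool = True,
        spectra_factory=None,
        scan_times: np.ndarray | None = None,
    ):
        if spectra is None:
            # lazy construction: scan_times + factory must be supplied
            if spectra_factory is None or scan_times is None:
                raise ValueError("lazy Run needs spectra_factory and scan_times")
            if scan_times.size == 0:
                raise ValueError("no spectra")
        else:
            if not spectra:
                raise ValueError("no spectra")
            if validate:
                rts = np.array([s.rt for s in spectra])
                if np.any(np.diff(rts) < 0):
                    raise ValueError("spectra must be ordered by non-decreasing RT")
            for s in spectra:
                s.mode = mode
        self._spectra = spectra
        self._factory = spectra_factory
        self.sample_meta = sample_meta
        self.mode = mode
        self.channels = channels
        self._flat: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._scan_times: np.ndarray | None = scan_times
        self._n = len(spectra) if spectra is not None else scan_times.size

    def __len__(self) -> int:
        return self._n

    @property
    def spectra(self) -> list[Spectrum]:
        if self._spectra is None:
            self._spectra = self._factory()
            for s in self._spectra:
                s.mode = self.mode
        return self._spectra

    @property
    def scan_times(self) -> np.ndarray:
        """Scan RTs in minutes (one per spectrum)."""
        if self._scan_times is None:
            self._scan_times = np.array([s.rt for s in self.spectra])
        return self._scan_times

    def flattened(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids as (mz, intensity, scan_index), sorted by m/z.

        Cached; makes EIC extraction a binary search plus a bincount.
        """
        if self._flat is None:
            mz = np.concatenate([s.mz for s in self.spectra])
            inten = np.concatenate([s.intensity for s in self.spectra]).astype(np.float64)
            scan = np.concatenate(
                [np.full(s.mz.size, i, dtype=np.int64) for i, s in enumerate(self.spectra)]
            )
            order = np.argsort(mz, kind="stable")
            self._flat = (mz[order], inten[order], scan[order])
        return self._flat


@dataclass
class LibrarySpectrum:
    """A named reference EI spectrum (NIST-style entry)."""

    name: str
    peaks: list[tuple[float, float]]
    rt: float | None = None
    lri: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"library entry {self.name!r} has no peaks")
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)

    def normalized(self, base: float = 999.0) -> "LibrarySpectrum":
        """Copy with intensities rescaled so the base peak equals ``base``."""
        top = max(i for _, i in self.peaks)
        if top <= 0:
            raise ValueError(f"library entry {self.name!r} has no positive intensity")
        scale = base / top
        return replace(self, peaks=[(m, i * scale) for m, i in self.peaks])

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(arr: np.ndarray, dtype: str) -> str:
    raw = np.asarray(arr, dtype=dtype).tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_run(run: Run, path: str | Path) -> None:
    """Serialize a run to centroid-MS1 mzML (64-bit m/z, 32-bit intensity, zlib)."""
    path = Path(path)
    polarity = (
        '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
        if run.mode == ECNI
        else '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
    )
    with io.StringIO() as buf:
        buf.write(_MZML_HEADER.format(run_id=escape(path.stem), count=len(run)))
        for i, s in enumerate(run.spectra):
            mz64 = _encode_array(s.mz, "<f8")
            int32 = _encode_array(s.intensity, "<f4")
            buf.write(
                f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        {polarity}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(s.rt)!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int32)}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int32}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""",
            )
        buf.write(_MZML_FOOTER)
        text = buf.getvalue()
    path.write_text(text)


_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS accessions used by the reader
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary(elem, n_expected: int) -> np.ndarray:
    accessions = {
        cv.get("accession") for cv in elem.iter(_NS + "cvParam")
    }
    dtype = "<f8" if _ACC_64BIT in accessions else "<f4"
    binary = elem.find(_NS + "binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"), validate=True)
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype)
    if n_expected >= 0 and arr.size != n_expected:
        raise MzMLError(
            f"binary array length {arr.size} != defaultArrayLength {n_expected}"
        )
    return arr


def _parse_spectrum_elem(elem, mode: str) -> Spectrum:
    accessions = {}
    for cv in elem.iter(_NS + "cvParam"):
        accessions.setdefault(cv.get("accession"), cv)
    if _ACC_PROFILE in accessions:
        raise MzMLError("profile-mode data is unsupported (centroid before loading)")
    rt_cv = accessions.get(_ACC_SCAN_START)
    if rt_cv is None:
        raise MzMLError("spectrum without scan start time")
    rt = float(rt_cv.get("value"))
    if rt_cv.get("unitName", "minute").lower().startswith("sec"):
        rt /= 60.0
    n = int(elem.get("defaultArrayLength", -1))
    mz = intensity = None
    for arr_elem in elem.iter(_NS + "binaryDataArray"):
        arr_acc = {cv.get("accession") for cv in arr_elem.iter(_NS + "cvParam")}
        if _ACC_MZ_ARRAY in arr_acc:
            mz = _decode_binary(arr_elem, n)
        elif _ACC_INT_ARRAY in arr_acc:
            intensity = _decode_binary(arr_elem, n)
    if mz is None or intensity is None:
        raise MzMLError("spectrum lacks m/z or intensity array")
    return Spectrum(rt=rt, mz=mz, intensity=intensity, mode=mode)


def load_run(path: str | Path, sample_meta: SampleMeta, mode: str = EI) -> Run:
    """Read a centroid-MS1 mzML file into a :class:`Run`.

    ``sample_meta`` comes from the manifest, and so does ``mode`` (mzML has no
    EI/ECNI slot; polarity alone does not determine the ionization mode).
    Profile-mode spectra and malformed content are rejected with the failing
    spectrum index in the message.
    """
    spectra: list[Spectrum] = []
    index = -1
    try:
        context = etree.iterparse(str(path), events=("end",), tag=_NS + "spectrum")
        for _, elem in context:
            index += 1
            try:
                spectra.append(_parse_spectrum_elem(elem, mode))
            except MzMLError as exc:
                raise MzMLError(f"spectrum {index}: {exc}") from exc
            except Exception as exc:  # noqa: BLE001 - surface parser context
                raise MzMLError(f"malformed mzML at spectrum {index}: {exc}") from exc
            elem.clear()
    except MzMLError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise MzMLError(f"malformed mzML near spectrum {index + 1}: {exc}") from exc
    if not spectra:
        raise MzMLError("no spectra")
    return Run(spectra, sample_meta, mode=mode)


# ---------------------------------------------------------------------------
# MSP libraries
# ---------------------------------------------------------------------------


_MSP_NAME_KEYS = ("name", "compound_name")
_MSP_RT_KEYS = ("rt", "retention_time", "retentiontime")
_MSP_RI_KEYS = ("ri", "retention_index", "retentionindex")


def _pop_first(meta: dict, keys) -> str | None:
    for key in keys:
        if key in meta:
            return meta.pop(key)
    return None


def load_library(path: str | Path) -> list[LibrarySpectrum]:
    """Load an MSP library; intensities rescaled to base peak 999.

    Accepts the common NIST text dialect: ``Key: value`` metadata lines, a
    ``Num Peaks:`` line, then whitespace- or semicolon-separated peak pairs
    (several pairs per line allowed).  Duplicate names are preserved as-is
    (renaming is a downstream step); an entry whose declared peak count
    mismatches the parsed peaks is an error naming the entry.
    """
    entries: list[LibrarySpectrum] = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    declared: int | None = None
    in_peaks = False

    def finish() -> None:
        nonlocal meta, peaks, declared, in_peaks
        if not meta and not peaks:
            return
        name = _pop_first(meta, _MSP_NAME_KEYS)
        if name is None:
            raise MSPError("MSP entry without a Name field")
        if declared is not None and declared != len(peaks):
            raise MSPError(
                f"entry {name!r}: declared Num Peaks {declared} but parsed {len(peaks)}"
            )
        if not peaks:
            raise MSPError(f"entry {name!r} has no peaks")
        rt = _pop_first(meta, _MSP_RT_KEYS)
        lri = _pop_first(meta, _MSP_RI_KEYS)
        entries.append(
            LibrarySpectrum(
                name=str(name),
                peaks=peaks,
                rt=None if rt is None else float(rt),
                lri=None if lri is None else float(lri),
                metadata=meta,
            ).normalized()
        )
        meta, peaks, declared, in_peaks = {}, [], None, False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                finish()
                continue
            if not in_peaks and ":" in line:
                key, _, value = line.partition(":")
                key_norm = key.strip().lower().replace(" ", "_")
                if key_norm == "num_peaks":
                    declared = int(value.strip())
                    in_peaks = True
                else:
                    meta[key_norm] = value.strip()
                continue
            if not in_peaks:
                raise MSPError(f"unexpected line outside an entry: {line!r}")
            values = line.replace(";", " ").replace(",", " ").split()
            if len(values) % 2:
                name = meta.get("name", meta.get("compound_name", "?"))
                raise MSPError(f"entry {name!r}: odd peak-value count on line {line!r}")
            for mz_txt, int_txt in zip(values[::2], values[1::2]):
                peaks.append((float(mz_txt), float(int_txt)))
    finish()
    return entries


def save_library(entries: list[LibrarySpectrum], path: str | Path) -> None:
    """Write entries as MSP in the Name/RT/RI/Num Peaks dialect."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            if e.rt is not None:
                fh.write(f"RT: {e.rt:.6g}\n")
            if e.lri is not None:
                fh.write(f"RI: {e.lri:.6g}\n")
            for key, value in sorted(e.metadata.items()):
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(e.peaks)}\n")
            for m, i in e.peaks:
                fh.write(f"{m:.5f} {i:.6g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "run_file",
    "sample_code",
    "species",
    "tissue",
    "trophic_role",
    "replicate_id",
    "fraction_id",
    "mode",
    "lipid_mass_g",
    "is_blank",
]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Write the run manifest (one row per mzML file) as CSV."""
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def meta_from_row(row) -> SampleMeta:
    """Build a :class:`SampleMeta` from a manifest row."""
    return SampleMeta(
        sample_code=str(row["sample_code"]),
        species=str(row["species"]),
        tissue=str(row["tissue"]),
        trophic_role=str(row["trophic_role"]),
        replicate_id=int(row["replicate_id"]),
        fraction_id=int(row["fraction_id"]),
        lipid_mass_g=float(row["lipid_mass_g"]),
        is_blank=bool(row["is_blank"]),
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "name",
    "rt_min",
    "lri",
    "sample_code",
    "replicate_id",
    "fraction_id",
    "area",
    "area_per_g_lipid",
    "ar",
    "qc_flags",
]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write feature rows as CSV, ordered by (rt, name, sample_code).

    An empty table produces a header-only file.  Numeric formatting is fixed
    so identical tables serialize byte-identically.
    """
    df = table.copy()
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[FEATURE_COLUMNS]
    if len(df):
        df = df.sort_values(
            ["rt_min", "name", "sample_code", "replicate_id", "fraction_id"],
            kind="stable",
        )
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)
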