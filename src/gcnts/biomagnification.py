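"""Biomagnification-factor estimation from area ratios.

Without quantification standards, a component's concentration is proxied by
its area ratio (AR): the component area divided by the area of the
*closest-eluting* volumetric standard, which is constant per injection and
therefore cancels injection-volume differences.  The BMF of a predator/prey
pair is then

    BMF = C(predator) / C(prey) ≈ AR(predator) / AR(prey)

computed on lipid-normalized areas.  Robustness rules: per Florisil
fraction the AR is the geometric mean over the triplicate injections
(missing replicates simply reduce n); a compound recovered in several
fractions contributes the *sum* of its fraction-level ARs.  A feature
undetected in either member of a pair yields an undefined BMF, reported
with the ``#N/A`` sentinel — never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NA_SENTINEL = "#N/A"


@dataclass
class AreaRatio:
    """Feature area relative to the closest-eluting volumetric standard."""

    feature: str
    sample_code: str
    ar: float | None  # None = undefined (feature or standard missing)
    n_replicates: int = 0
    fractions: tuple[int, ...] = ()
    diagnostic: str = ""


@dataclass
class BMFResult:
    feature: str
    rt: float
    lri: float
    predator: str
    prey: str
    bmf: float | None
    flag_biomagnifying: bool = field(init=False)

    def __post_init__(self) -> None:
        self.flag_biomagnifying = self.bmf is not None and self.bmf > 1.0


def area_ratio(
    feature_area: float,
    standards: list[tuple[float, float]],
    feature_rt: float,
) -> float | None:
    """AR against the standard with minimal |ΔRT| (ties → earlier-eluting).

    ``standards`` is a list of ``(rt, area)``.  Standards with zero or
    missing area are unusable; if none is usable the AR is undefined (None).
    """
    usable = [
        (rt, area)
        for rt, area in standards
        if area is not None and np.isfinite(area) and area > 0
    ]
    if not usable:
        return None
    usable.sort(key=lambda s: (abs(s[0] - feature_rt), s[0]))
    return feature_area / usable[0][1]


def geometric_mean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of no values")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def aggregate_ar(ar_by_fraction: dict[int, list[float]]) -> AreaRatio | None:
    """Geometric mean over replicates within each fraction, then sum fractions.

    ``ar_by_fraction`` maps fraction_id → defined replicate AR values.
    Returns None when no fraction has any defined value.
    """
    fraction_means = {}
    n_used = 0
    for fraction, values in sorted(ar_by_fraction.items()):
        defined = [v for v in values if v is not None and np.isfinite(v) and v > 0]
        if not defined:
            continue
        fraction_means[fraction] = geometric_mean(defined)
        n_used = max(n_used, len(defined))
    if not fraction_means:
        return None
    return AreaRatio(
        feature="",
        sample_code="",
        ar=float(sum(fraction_means.values())),
        n_replicates=n_used,
        fractions=tuple(sorted(fraction_means)),
    )


def bmf(ar_predator: AreaRatio | None, ar_prey: AreaRatio | None, feature: str = "",
        rt: float = np.nan, lri: float = np.nan, predator: str = "", prey: str = "") -> BMFResult:
    """Eq.-style BMF: AR(predator)/AR(prey); undefined if either is missing."""
    value = None
    if (
        ar_predator is not None
        and ar_prey is not None
        and ar_predator.ar is not None
        and ar_prey.ar is not None
        and ar_prey.ar > 0
    ):
        value = ar_predator.ar / ar_prey.ar
    return BMFResult(feature=feature, rt=rt, lri=lri, predator=predator, prey=prey, bmf=value)


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------


def attach_area_ratios(
    features: pd.DataFrame,
    standards: pd.DataFrame,
    use_lipid_normalized: bool = True,
) -> pd.DataFrame:
    """Add an ``ar`` column to screening rows.

    ``features`` has one row per (name, sample, replicate, fraction) with
    ``area`` / ``area_per_g_lipid`` / ``rt_min``; ``standards`` one row per
    (standard, sample, replicate, fraction) with ``rt_min`` and ``area``.
    The AR denominator is the closest-eluting standard *in the same run*.
    """
    value_col = "area_per_g_lipid" if use_lipid_normalized else "area"
    std_lookup: dict[tuple, list[tuple[float, float]]] = {}
    for _, row in standards.iterrows():
        key = (row["sample_code"], row["replicate_id"], row["fraction_id"])
        std_lookup.setdefault(key, []).append((row["rt_min"], row["area"]))

    out = features.copy()
    ars = []
    for _, row in out.iterrows():
        key = (row["sample_code"], row["replicate_id"], row["fraction_id"])
        stds = std_lookup.get(key, [])
        ar = area_ratio(row[value_col], stds, row["rt_min"]) if stds else None
        ars.append(np.nan if ar is None else ar)
    out["ar"] = ars
    return out


def aggregate_sample_ars(features_with_ar: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate/fraction rows to one AR per (feature, sample)."""
    rows = []
    for (name, sample), group in features_with_ar.groupby(["name", "sample_code"], sort=True):
        by_fraction: dict[int, list[float]] = {}
        for _, row in group.iterrows():
            if np.isfinite(row["ar"]) and row["ar"] > 0:
                by_fraction.setdefault(int(row["fraction_id"]), []).append(float(row["ar"]))
        agg = aggregate_ar(by_fraction)
        if agg is None:
            continue
        lri_vals = group["lri"].dropna()
        rows.append(
            {
                "name": name,
                "sample_code": sample,
                "ar": agg.ar,
                "n_replicates": agg.n_replicates,
                "fractions": ",".join(str(f) for f in agg.fractions),
                "rt_min": float(group["rt_min"].median()),
                "lri": float(lri_vals.median()) if len(lri_vals) else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "sample_code", "ar", "n_replicates", "fractions", "rt_min", "lri"],
    )


def bmf_table(
    aggregated: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """One BMF row per feature × predator/prey pair.

    Undefined BMFs (feature missing in either sample) are retained as NaN
    and serialized as ``#N/A``.  Deterministic ordering: (rt, name, pair).
    """
    known = set(aggregated["sample_code"])
    for pred, prey in pairs:
        missing = {pred, prey} - known
        if missing:
            raise ValueError(f"unknown sample_code(s) in pairs: {sorted(missing)}")
    lookup = {
        (row["name"], row["sample_code"]): row for _, row in aggregated.iterrows()
    }

    def _median(series: pd.Series) -> float:
        finite = series.dropna()
        return float(finite.median()) if len(finite) else float("nan")

    feature_info = (
        aggregated.groupby("name")
        .agg(rt_min=("rt_min", _median), lri=("lri", _median), fractions=("fractions", "first"))
        .reset_index()
    )
    rows = []
    for _, feat in feature_info.iterrows():
        name = feat["name"]
        for pred, prey in pairs:
            ar_p = lookup.get((name, pred))
            ar_q = lookup.get((name, prey))
            value = np.nan
            if ar_p is not None and ar_q is not None and ar_q["ar"] > 0:
                value = ar_p["ar"] / ar_q["ar"]
            rows.append(
                {
                    "name": name,
                    "rt_min": feat["rt_min"],
                    "lri": feat["lri"],
                    "fractions": feat["fractions"],
                    "predator": pred,
                    "prey": prey,
                    "bmf": value,
                    "biomagnifying": bool(np.isfinite(value) and value > 1.0),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["name", "rt_min", "lri", "fractions", "predator", "prey", "bmf", "biomagnifying"],
    )
    if len(df):
        df = df.sort_values(["rt_min", "name", "predator", "prey"], kind="stable").reset_index(
            drop=True
        )
    return df


def write_bmf_table(table: pd.DataFrame, path) -> None:
    """CSV with one BMF column per pair, ``#N/A`` for undefined values."""
    if not len(table):
        pd.DataFrame(columns=["rt_min", "lri", "name", "fractions"]).to_csv(path, index=False)
        return
    wide = table.pivot_table(
        index=["rt_min", "lri", "name", "fractions"],
        columns="predator",
        values="bmf",
        aggfunc="first",
        dropna=False,
        sort=False,
    ).reset_index()
    wide.columns.name = None
    wide = wide.sort_values(["rt_min", "name"], kind="stable")
    wide.to_csv(path, index=False, float_format="%.6g", na_rep=NA_SENTINEL)
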