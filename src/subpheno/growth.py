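"""Age- and sex-referenced growth classification of macrocephaly subtypes.

Head circumference and height are converted to z-scores against reference
tables of per-age, per-sex means and standard deviations (linearly
interpolated in age). A proband is macrocephalic when the head-circumference
z-score exceeds a permissive cutoff (default 1.5 SD above the reference
mean). Macrocephalic probands are subtyped into:

* **SO** (somatic overgrowth): head circumference *and* height percentiles
  both above 90;
* **DMac** (disproportionate macrocephaly): height-to-head-circumference
  percentile ratio below 0.7;
* **RM** (relative macrocephaly): everything else (ratio >= 0.7).

Disproportionate megalencephaly is called analogously from the
cerebral-volume-to-height ratio using its own reference table.

All cutoff inequalities are strict; a ratio of exactly 0.7 is assigned RM
(the complement class). SO is checked before the ratio rule so that the
three subtypes partition the macrocephalic probands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GrowthReferenceTable",
    "SubphenotypeCall",
    "zscore",
    "percentile_from_z",
    "call_head_size",
    "call_megalencephaly",
    "zscore_outlier",
    "classify_cohort",
]

#: subtypes a macrocephalic proband can receive
SUBTYPES = ("SO", "DMac", "RM")

#: ages this far (months) outside the reference range are clamped to the edge
AGE_CLAMP_MONTHS = 3.0


class GrowthReferenceTable:
    """Sex- and age-indexed reference means and SDs for one growth measure.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sex`` ('M'/'F'), ``age_months``, ``mean``, ``sd``.
        Ages must be unique and sorted rows are stored per sex; at least two
        ages per sex are required so that interpolation is defined.
    measure : str
        Name of the measure the table refers to, e.g.
        ``'head_circumference_cm'``.
    """

    def __init__(self, table: pd.DataFrame, measure: str = ""):
        required = {"sex", "age_months", "mean", "sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if (table["sd"] <= 0).any() or (table["mean"] <= 0).any():
            raise ValueError("reference mean and sd must be positive")
        if table.duplicated(subset=["sex", "age_months"]).any():
            raise ValueError("reference rows must be unique on (sex, age_months)")
        self.measure = measure
        self._by_sex: dict[str, pd.DataFrame] = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("age_months").reset_index(drop=True)
            if len(grp) < 2:
                raise ValueError(f"need >= 2 reference ages for sex {sex!r}")
            self._by_sex[str(sex)] = grp

    @classmethod
    def from_tsv(cls, path, measure: str | None = None) -> "GrowthReferenceTable":
        df = pd.read_csv(path, sep="\t")
        if measure is not None and "measure" in df.columns:
            df = df[df["measure"] == measure]
            if df.empty:
                raise ValueError(f"measure {measure!r} not present in {path}")
        return cls(df, measure=measure or "")

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self._by_sex)

    def age_range(self, sex: str) -> tuple[float, float]:
        grp = self._grp(sex)
        return float(grp["age_months"].iloc[0]), float(grp["age_months"].iloc[-1])

    def _grp(self, sex: str) -> pd.DataFrame:
        try:
            return self._by_sex[sex]
        except KeyError:
            raise ValueError(f"sex {sex!r} absent from reference table") from None

    def lookup(self, sex: str, age_months: float) -> tuple[float, float]:
        """Return (mean, sd) linearly interpolated in age within ``sex``.

        Ages up to ``AGE_CLAMP_MONTHS`` outside the tabulated range are
        clamped to the nearest tabulated age; beyond that an error is raised.
        """
        grp = self._grp(sex)
        ages = grp["age_months"].to_numpy(dtype=float)
        lo, hi = ages[0], ages[-1]
        if age_months < lo - AGE_CLAMP_MONTHS or age_months > hi + AGE_CLAMP_MONTHS:
            raise ValueError(
                f"age {age_months} months outside reference range "
                f"[{lo}, {hi}] beyond {AGE_CLAMP_MONTHS}-month clamp"
            )
        age = float(np.clip(age_months, lo, hi))
        mean = float(np.interp(age, ages, grp["mean"].to_numpy(dtype=float)))
        sd = float(np.interp(age, ages, grp["sd"].to_numpy(dtype=float)))
        return mean, sd


def zscore(value: float, sex: str, age_months: float, table: GrowthReferenceTable) -> float:
    """Standardize ``value`` against the age/sex reference distribution."""
    if not value > 0:
        raise ValueError("measurement must be positive")
    mean, sd = table.lookup(sex, age_months)
    return (value - mean) / sd


def percentile_from_z(z: float) -> float:
    """Percentile (0-100) of a z-score under the standard normal."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    return 100.0 * norm.cdf(z)


@dataclass
class SubphenotypeCall:
    """Head-size classification of a single proband."""

    proband_id: str
    hc_z: float | None = None
    hc_percentile: float | None = None
    height_percentile: float | None = None
    macrocephaly: bool | None = None
    megalencephaly: bool | None = None
    subtype: str = "none"
    ratio: float | None = None
    warnings: list[str] = field(default_factory=list)


def call_head_size(
    anthro,
    hc_table: GrowthReferenceTable,
    ht_table: GrowthReferenceTable,
    threshold_sd: float = 1.5,
    so_percentile: float = 90.0,
    ratio_cutoff: float = 0.7,
) -> SubphenotypeCall:
    """Call macrocephaly and its subtype for one proband.

    ``anthro`` is any mapping/namespace with ``proband_id``, ``sex``,
    ``age_months``, ``head_circumference_cm`` and ``height_cm`` fields
    (missing measurements yield a call with subtype fields absent and a
    warning record).
    """
    get = (lambda k: anthro.get(k)) if hasattr(anthro, "get") else (
        lambda k: getattr(anthro, k, None)
    )
    call = SubphenotypeCall(proband_id=str(get("proband_id")))
    hc = get("head_circumference_cm")
    ht = get("height_cm")
    if hc is None or ht is None or pd.isna(hc) or pd.isna(ht):
        call.warnings.append("missing head circumference or height; subtype not called")
        return call
    sex, age = get("sex"), float(get("age_months"))
    call.hc_z = zscore(float(hc), sex, age, hc_table)
    call.hc_percentile = float(percentile_from_z(call.hc_z))
    ht_z = zscore(float(ht), sex, age, ht_table)
    call.height_percentile = float(percentile_from_z(ht_z))
    call.macrocephaly = call.hc_z > threshold_sd
    call.ratio = call.height_percentile / call.hc_percentile
    if not call.macrocephaly:
        call.subtype = "none"
    elif call.hc_percentile > so_percentile and call.height_percentile > so_percentile:
        call.subtype = "SO"
    elif call.ratio < ratio_cutoff:
        call.subtype = "DMac"
    else:
        call.subtype = "RM"
    return call


def call_megalencephaly(
    anthro,
    ratio_table: GrowthReferenceTable,
    threshold_sd: float = 1.5,
) -> bool:
    """True when cerebral-volume/height ratio is > ``threshold_sd`` SD above
    the age/sex reference mean."""
    get = (lambda k: anthro.get(k)) if hasattr(anthro, "get") else (
        lambda k: getattr(anthro, k, None)
    )
    cv = get("cerebral_volume_cm3")
    ht = get("height_cm")
    if cv is None or ht is None or pd.isna(cv) or pd.isna(ht):
        raise ValueError("cerebral volume and height required for megalencephaly call")
    ratio = float(cv) / float(ht)
    z = zscore(ratio, get("sex"), float(get("age_months")), ratio_table)
    return bool(z > threshold_sd)


def zscore_outlier(value: float, population: Iterable[float], threshold: float = 3.0) -> bool:
    """True when ``value`` lies more than ``threshold`` SDs above the mean of
    ``population`` (used e.g. for expression-outlier calls)."""
    pop = np.asarray(list(population), dtype=float)
    if pop.size < 3:
        raise ValueError("population must contain at least 3 values")
    sd = pop.std(ddof=1)
    if sd == 0:
        raise ValueError("population has zero variance")
    return bool((value - pop.mean()) / sd > threshold)


def classify_cohort(
    cohort: pd.DataFrame,
    hc_table: GrowthReferenceTable,
    ht_table: GrowthReferenceTable,
    ratio_table: GrowthReferenceTable | None = None,
    threshold_sd: float = 1.5,
    so_percentile: float = 90.0,
    ratio_cutoff: float = 0.7,
) -> pd.DataFrame:
    """Classify every proband row of a cohort table.

    Returns a DataFrame mirroring :class:`SubphenotypeCall`, one row per
    proband; megalencephaly is called only when a ratio reference table and
    cerebral-volume measurements are supplied.
    """
    rows = []
    for rec in cohort.to_dict("records"):
        call = call_head_size(
            rec, hc_table, ht_table,
            threshold_sd=threshold_sd, so_percentile=so_percentile,
            ratio_cutoff=ratio_cutoff,
        )
        mega: bool | None = None
        if ratio_table is not None and rec.get("cerebral_volume_cm3") is not None \
                and not pd.isna(rec.get("cerebral_volume_cm3")):
            try:
                mega = call_megalencephaly(rec, ratio_table, threshold_sd=threshold_sd)
            except ValueError as exc:
                call.warnings.append(str(exc))
        if call.warnings:
            warnings.warn(f"{call.proband_id}: {'; '.join(call.warnings)}")
        rows.append({
            "proband_id": call.proband_id,
            "hc_z": call.hc_z,
            "hc_percentile": call.hc_percentile,
            "height_percentile": call.height_percentile,
            "macrocephaly": call.macrocephaly,
            "megalencephaly": mega,
            "subtype": call.subtype,
            "ratio": call.ratio,
        })
    return pd.DataFrame(rows)
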