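"""Domain types and deterministic risk equations.

The exposure chain implemented here is the standard USEPA dietary route:
fresh-weight conversion of tissue concentrations, soil-to-plant
bioaccumulation factors (BCF), estimated daily intake (EDI), target hazard
quotients (THQ = EDI/RfD) and the hazard index (HI = sum of THQs), plus the
descriptive statistics and regulatory threshold screening used to
characterise contamination in paired soil--vegetable surveys.

Units are fixed throughout the package:

* concentrations: mg/kg (dry weight for soil, fresh or dry weight for
  vegetables, always labelled);
* ingestion rate IR: g/d; body weight BW: kg; exposure frequency EF: d/yr;
  exposure duration ED: yr;
* EDI and RfD: ug/(kg body weight * d).  The g->kg and mg->ug conversion
  factors live inside :func:`edi`, never in callers, so that
  :func:`thq` is a bare ratio.

The averaging time for non-carcinogenic effects is AT = ED * 365 d, so ED
cancels algebraically in the EDI and is never a free parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical metal codes, in the conventional reporting order.
METALS: tuple[str, ...] = ("As", "Cd", "Cu", "Pb", "Zn")

#: Vegetable categories used for MAC screening and category contrasts.
CATEGORIES: tuple[str, ...] = ("leafy", "rootstalk", "legume", "fruit")

#: Population groups with their age bounds (years, inclusive).
GROUPS: Mapping[str, tuple[int, int]] = {
    "children": (4, 11),
    "adolescents": (12, 17),
    "adults": (18, 60),
}


class InvalidInputError(ValueError):
    """A physical or structural precondition on an input was violated."""


class ConfigurationError(ValueError):
    """A toxicological or run configuration value is missing or invalid."""


def _check_metal(code: str) -> str:
    if not code or not code[0].isupper():
        raise InvalidInputError(f"metal code {code!r} is not a valid element symbol")
    return code


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """One paired soil--vegetable observation.

    ``soil_conc`` is in mg/kg dry weight; ``veg_conc_fw`` in mg/kg fresh
    weight.  ``veg_conc_dw`` together with the water content ``w`` must be
    consistent with ``veg_conc_fw`` via the fresh-weight conversion.
    """

    site_id: str
    village: str
    veg_species: str
    veg_category: str
    soil_conc: dict[str, float]
    veg_conc_fw: dict[str, float]
    soil_ph: float | None = None
    soil_som: float | None = None  # g/kg
    veg_conc_dw: dict[str, float] | None = None
    fresh_mass: float | None = None  # g
    dry_mass: float | None = None  # g
    water_content_w: float | None = None

    def __post_init__(self) -> None:
        if self.veg_category not in CATEGORIES:
            raise InvalidInputError(
                f"sample {self.site_id}: unknown vegetable category {self.veg_category!r}"
            )
        for table in (self.soil_conc, self.veg_conc_fw, self.veg_conc_dw or {}):
            for metal, value in table.items():
                _check_metal(metal)
                if value < 0:
                    raise InvalidInputError(
                        f"sample {self.site_id}: negative concentration for {metal}"
                    )
        if self.fresh_mass is not None and self.dry_mass is not None:
            if self.dry_mass > self.fresh_mass:
                raise InvalidInputError(
                    f"sample {self.site_id}: dry mass exceeds fresh mass"
                )
        if self.water_content_w is not None and not 0 <= self.water_content_w < 1:
            raise InvalidInputError(
                f"sample {self.site_id}: water content must lie in [0, 1)"
            )
        if self.veg_conc_dw is not None and self.water_content_w is not None:
            w = self.water_content_w
            for metal, c_dw in self.veg_conc_dw.items():
                c_fw = self.veg_conc_fw.get(metal)
                if c_fw is None:
                    continue
                expected = c_dw * (1.0 - w)
                if not math.isclose(c_fw, expected, rel_tol=1e-9, abs_tol=1e-12):
                    raise InvalidInputError(
                        f"sample {self.site_id}: fresh-weight {metal} concentration "
                        f"{c_fw} inconsistent with dry weight {c_dw} at w={w}"
                    )


@dataclass
class ExposureRecord:
    """One surveyed person's exposure factors."""

    person_id: str
    group: str
    bw: float  # kg
    ir: float  # g/d
    ed: float  # yr
    ef: float  # d/yr
    age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(
                f"person {self.person_id}: unknown group {self.group!r}"
            )
        if self.bw <= 0:
            raise InvalidInputError(f"person {self.person_id}: body weight must be > 0")
        if self.ir < 0:
            raise InvalidInputError(f"person {self.person_id}: ingestion rate < 0")
        if self.ed <= 0:
            raise InvalidInputError(f"person {self.person_id}: exposure duration must be > 0")
        if not 0 < self.ef <= 365:
            raise InvalidInputError(
                f"person {self.person_id}: exposure frequency must lie in (0, 365]"
            )
        if self.age is not None:
            lo, hi = GROUPS[self.group]
            if not lo <= self.age <= hi:
                raise InvalidInputError(
                    f"person {self.person_id}: age {self.age} outside "
                    f"{self.group} bounds [{lo}, {hi}]"
                )


@dataclass
class ToxTable:
    """Toxicological reference values and regulatory thresholds.

    * ``rfd``: chronic oral reference dose per metal, ug/(kg*d);
    * ``ptdi``: provisional tolerable daily intake, ug/(kg*d), keyed by
      (metal, group) -- group-independent metals repeat the value;
    * ``mac``: maximum allowable concentration in food, mg/kg fresh weight,
      keyed by (metal, category); absent entries mean "no limit set";
    * ``rsv``: soil risk screening values, mg/kg dry weight.
    """

    rfd: dict[str, float]
    ptdi: dict[tuple[str, str], float] = field(default_factory=dict)
    mac: dict[tuple[str, str], float] = field(default_factory=dict)
    rsv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("rfd", self.rfd), ("rsv", self.rsv)):
            for key, value in table.items():
                if value <= 0:
                    raise ConfigurationError(f"{name}[{key}] must be strictly positive")
        for name, table in (("ptdi", self.ptdi), ("mac", self.mac)):
            for key, value in table.items():
                if value <= 0:
                    raise ConfigurationError(f"{name}[{key}] must be strictly positive")

    def rfd_for(self, metal: str) -> float:
        try:
            return self.rfd[metal]
        except KeyError:
            raise ConfigurationError(f"no RfD configured for {metal}") from None


@dataclass
class DescriptiveSummary:
    """Summary row matching the survey-table convention (min/max/median/
    mean/SD/CV%/Shapiro--Wilk p)."""

    name: str
    n: int
    min: float
    max: float
    median: float
    mean: float
    sd: float
    cv_percent: float | None
    normality_p: float | None


# ---------------------------------------------------------------------------
# Equations
# ---------------------------------------------------------------------------


def water_content(fresh_mass: float, dry_mass: float, *, sample: str = "?") -> float:
    """Tissue water content w = (fresh - dry) / fresh, a fraction in [0, 1)."""
    if fresh_mass <= 0:
        raise InvalidInputError(f"sample {sample}: fresh mass must be > 0")
    if dry_mass < 0 or dry_mass > fresh_mass:
        raise InvalidInputError(
            f"sample {sample}: dry mass must lie in [0, fresh mass]"
        )
    return (fresh_mass - dry_mass) / fresh_mass


def fw_from_dw(c_dw: float, w: float) -> float:
    """Convert a dry-weight concentration to fresh weight: C_fw = C_dw * (1 - w)."""
    if c_dw < 0:
        raise InvalidInputError("dry-weight concentration must be >= 0")
    if not 0 <= w < 1:
        raise InvalidInputError("water content must lie in [0, 1)")
    return c_dw * (1.0 - w)


def bcf(c_veg_fw: float, c_soil: float, *, site: str = "?") -> float:
    """Bioaccumulation factor: vegetable fresh-weight concentration over
    soil dry-weight concentration."""
    if c_soil <= 0:
        raise InvalidInputError(f"site {site}: soil concentration must be > 0 for BCF")
    if c_veg_fw < 0:
        raise InvalidInputError(f"site {site}: vegetable concentration must be >= 0")
    return c_veg_fw / c_soil


def edi(c_fw: float, ir: float, bw: float, ef: float = 365.0, ed: float = 1.0) -> float:
    """Estimated daily intake in ug/(kg*d).

    EDI = EF * ED * C_fw * IR / (BW * AT) with AT = ED * 365 d, so the
    result reduces to C[mg/kg] * IR[g/d] * (EF/365) / BW[kg]; the mg*g ->
    ug*kg factors cancel exactly.  ED is accepted (and validated) but has
    no numerical effect.
    """
    if bw <= 0:
        raise InvalidInputError("body weight must be > 0")
    if ed <= 0:
        raise InvalidInputError("exposure duration must be > 0")
    if not 0 < ef <= 365:
        raise InvalidInputError("exposure frequency must lie in (0, 365]")
    if c_fw < 0 or ir < 0:
        raise InvalidInputError("concentration and ingestion rate must be >= 0")
    return c_fw * ir * (ef / 365.0) / bw


def thq(edi_value: float, rfd: float) -> float:
    """Target hazard quotient: intake over reference dose, both in ug/(kg*d)."""
    if rfd <= 0:
        raise ConfigurationError("RfD must be strictly positive")
    if edi_value < 0:
        raise InvalidInputError("EDI must be >= 0")
    return edi_value / rfd


def hazard_index(thqs: Mapping[str, float]) -> float:
    """Hazard index: sum of the per-metal THQs (additivity assumption)."""
    if not thqs:
        raise InvalidInputError("hazard index of an empty THQ map is undefined")
    if any(v < 0 for v in thqs.values()):
        raise InvalidInputError("THQs must be >= 0")
    return float(sum(thqs.values()))


# ---------------------------------------------------------------------------
# Descriptive statistics and screening
# ---------------------------------------------------------------------------


def cv_percent(mean: float, sd: float) -> float | None:
    """Coefficient of variation, 100*sd/mean; None when the mean is not positive."""
    if mean <= 0:
        return None
    return 100.0 * sd / mean


def describe(values: Sequence[float], name: str = "") -> DescriptiveSummary:
    """Min/max/median/mean/sample-SD/CV%/Shapiro--Wilk p for one field.

    The SD uses the n-1 denominator; the median of an even-sized sample is
    the mean of the two central order statistics.  With fewer than 3
    observations the normality p-value is omitted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError(f"describe({name!r}): empty input")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"describe({name!r}): non-finite values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    normality_p: float | None = None
    if arr.size >= 3 and sd > 0:
        normality_p = float(stats.shapiro(arr).pvalue)
    return DescriptiveSummary(
        name=name,
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        median=float(np.median(arr)),
        mean=mean,
        sd=sd,
        cv_percent=cv_percent(mean, sd),
        normality_p=normality_p,
    )


def exceedance_rate(values: Sequence[float], threshold: float) -> float:
    """Percentage of values strictly above a regulatory threshold.

    Ties count as non-exceeding: "exceeds" reads as strictly above.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be strictly positive")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("exceedance rate of an empty list is undefined")
    return 100.0 * float(np.count_nonzero(arr > threshold)) / arr.size


def substitute_censored(
    values: Iterable[float | None], lod: float, *, field_name: str = ""
) -> list[float]:
    """Replace below-detection-limit observations (None) by LOD/2.

    The number of substitutions is logged so the censoring treatment of any
    run is visible.
    """
    if lod <= 0:
        raise ConfigurationError("detection limit must be strictly positive")
    out: list[float] = []
    n_sub = 0
    for v in values:
        if v is None:
            out.append(lod / 2.0)
            n_sub += 1
        else:
            out.append(float(v))
    if n_sub:
        logger.info(
            "substituted %d censored value(s) in %s at LOD/2 = %g",
            n_sub, field_name or "field", lod / 2.0,
        )
    return out


def category_mean_ratio(
    samples: Sequence[SampleRecord], metal: str, cat_a: str, cat_b: str
) -> float:
    """Ratio of mean fresh-weight concentrations between two vegetable
    categories (e.g. leafy Pb relative to legume Pb)."""
    for cat in (cat_a, cat_b):
        if cat not in CATEGORIES:
            raise InvalidInputError(f"unknown vegetable category {cat!r}")

    def _mean(cat: str) -> float:
        vals = [
            s.veg_conc_fw[metal]
            for s in samples
            if s.veg_category == cat and metal in s.veg_conc_fw
        ]
        if not vals:
            raise InvalidInputError(
                f"no {cat} samples with a {metal} concentration"
            )
        return float(np.mean(vals))

    mean_b = _mean(cat_b)
    if mean_b == 0:
        raise InvalidInputError(
            f"mean {metal} in {cat_b} is zero; ratio undefined"
        )
    return _mean(cat_a) / mean_b
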