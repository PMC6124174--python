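"""Clinical-biochemistry primitives for calcium–phosphate diagnostics.

Everything downstream — the case-control evaluation, the laboratory-database
cascade, the synthetic generators — consumes the types and formulas defined
here: the laboratory record, the reference intervals, unit conversion between
SI (mmol/L) and conventional (mg/dL) systems, albumin-corrected calcium, the
MDRD estimate of glomerular filtration rate, and the Ca/P ratio itself.

All internal computation is in SI units (Ca and P in mmol/L, PTH in ng/L,
creatinine in µmol/L, albumin in g/L, 25-OH vitamin D in nmol/L); conventional
units appear only at explicit conversion boundaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Sex",
    "UnitSystem",
    "LabRecord",
    "ReferenceRanges",
    "DEFAULT_RANGES",
    "DomainError",
    "CorrectionUnavailableError",
    "CA_MGDL_PER_MMOL",
    "P_MGDL_PER_MMOL",
    "CREATININE_UMOL_PER_MGDL",
    "RATIO_CU_PER_SI",
    "ca_p_ratio",
    "convert_ratio_cutoff",
    "corrected_calcium",
    "mdrd_gfr",
    "convert_units",
    "round_half_away",
    "truncate_decimal",
]

# Molar-mass derived factors: mg/dL per mmol/L (atomic masses 40.08 and 30.97,
# divided by 10 for the dL scale). Creatinine converts µmol/L <-> mg/dL.
CA_MGDL_PER_MMOL = 4.008
P_MGDL_PER_MMOL = 3.097
CREATININE_UMOL_PER_MGDL = 88.4

#: Multiplier taking a Ca/P ratio of mmol/L values to the ratio of mg/dL values.
RATIO_CU_PER_SI = CA_MGDL_PER_MMOL / P_MGDL_PER_MMOL

# SI -> CU multipliers per convertible analyte.
_SI_TO_CU = {
    "ca": CA_MGDL_PER_MMOL,
    "p": P_MGDL_PER_MMOL,
    "creatinine": 1.0 / CREATININE_UMOL_PER_MGDL,
}


class DomainError(ValueError):
    """A physically impossible input (nonpositive concentration, unknown analyte)."""


class CorrectionUnavailableError(ValueError):
    """Albumin is absent, so the albumin-corrected calcium cannot be computed."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class UnitSystem(str, enum.Enum):
    SI = "SI"  # mmol/L (µmol/L for creatinine)
    CU = "CU"  # mg/dL


@dataclass(frozen=True)
class LabRecord:
    """One measurement occasion: demographics plus a serum biochemistry panel.

    Required analytes are total calcium ``ca`` (mmol/L), phosphorous ``p``
    (mmol/L), intact PTH ``pth`` (ng/L) and ``creatinine`` (µmol/L). Albumin
    (g/L) and 25-OH vitamin D (nmol/L) are optional and represented by ``None``
    when not measured — never by a sentinel number. ``exclusion_flags`` carries
    coded chart-review reasons (cancer, malabsorption, lithium, thiazide,
    bisphosphonate, vitamin-D-active-form, severe_obesity, bone_disease, ...).
    ``truth_phpt`` is the chart-level ground-truth diagnosis where known; the
    pipelines never infer it from biochemistry.
    """

    record_id: str
    age: float
    sex: Sex
    ca: float
    p: float
    pth: float
    creatinine: float
    black: bool = False
    albumin: float | None = None
    vitd25: float | None = None
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)
    truth_phpt: bool | None = None

    def __post_init__(self) -> None:
        for name in ("ca", "p", "pth", "creatinine"):
            value = getattr(self, name)
            if not value > 0:
                raise DomainError(f"{name} must be > 0, got {value!r}")
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age!r}")
        if self.albumin is not None and not self.albumin > 0:
            raise DomainError(f"albumin must be > 0, got {self.albumin!r}")

    @property
    def ca_p(self) -> float:
        """Serum Ca/P ratio in the SI system."""
        return ca_p_ratio(self.ca, self.p)


#: Analytes a ReferenceRanges instance must cover.
_ANALYTES = ("ca", "p", "pth", "vitd25", "albumin", "creatinine")


@dataclass(frozen=True)
class ReferenceRanges:
    """Lower/upper normal limits per analyte, SI units."""

    ca: tuple[float, float] = (2.12, 2.65)
    p: tuple[float, float] = (0.81, 1.65)
    pth: tuple[float, float] = (15.0, 88.0)
    vitd25: tuple[float, float] = (74.9, 249.6)
    albumin: tuple[float, float] = (35.0, 50.0)
    creatinine: tuple[float, float] = (44.2, 123.8)

    def __post_init__(self) -> None:
        for name in _ANALYTES:
            low, high = getattr(self, name)
            if not low < high:
                raise DomainError(f"{name} range must satisfy low < high, got {low}–{high}")

    def contains(self, analyte: str, value: float) -> bool:
        low, high = getattr(self, analyte)
        return low <= value <= high


DEFAULT_RANGES = ReferenceRanges()


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be > 0, got {value!r}")


def ca_p_ratio(ca: float, p: float) -> float:
    """Calcium-to-phosphorous ratio; both inputs in the same unit system."""
    _require_positive(ca, "ca")
    _require_positive(p, "p")
    return ca / p


def convert_ratio_cutoff(cutoff_si: float) -> float:
    """Re-express a Ca/P cutoff computed on mmol/L values as a mg/dL-ratio cutoff.

    The two unit systems scale Ca and P by different molar-mass factors, so the
    ratio itself rescales by 4.008/3.097. Reporting conventionally rounds the
    result to one decimal (e.g. 2.71 -> 3.5).
    """
    _require_positive(cutoff_si, "cutoff")
    return cutoff_si * RATIO_CU_PER_SI


def corrected_calcium(ca: float, albumin: float | None) -> float:
    """Albumin-corrected total calcium, mmol/L.

    corrected Ca = Ca + 0.02 × (40 − albumin[g/L]); the identity at the
    reference albumin of 40 g/L. Raises :class:`CorrectionUnavailableError`
    when albumin was not measured — callers fall back to uncorrected Ca.
    """
    if albumin is None:
        raise CorrectionUnavailableError("albumin unavailable; corrected Ca undefined")
    _require_positive(ca, "ca")
    _require_positive(albumin, "albumin")
    return ca + 0.02 * (40.0 - albumin)


def mdrd_gfr(creatinine: float, age: float, sex: Sex, black: bool = False) -> float:
    """MDRD estimate of GFR, mL/min/1.73 m².

    Creatinine is taken in µmol/L and converted to mg/dL internally (÷88.4),
    because the 186 coefficient is defined for mg/dL:

        GFR = 186 · creat^−1.154 · age^−0.203 · (1.210 if black) · (0.742 if female)
    """
    _require_positive(creatinine, "creatinine")
    _require_positive(age, "age")
    creat_mgdl = creatinine / CREATININE_UMOL_PER_MGDL
    gfr = 186.0 * creat_mgdl**-1.154 * age**-0.203
    if black:
        gfr *= 1.210
    if Sex(sex) is Sex.FEMALE:
        gfr *= 0.742
    return gfr


def convert_units(value: float, analyte: str, from_system: UnitSystem, to_system: UnitSystem) -> float:
    """Convert a single analyte value between SI and conventional units.

    Supported analytes: ca, p (mmol/L <-> mg/dL) and creatinine
    (µmol/L <-> mg/dL). Round-trip conversion is the identity to floating
    precision.
    """
    if analyte not in _SI_TO_CU:
        raise DomainError(f"no unit conversion defined for analyte {analyte!r}")
    from_system = UnitSystem(from_system)
    to_system = UnitSystem(to_system)
    if from_system is to_system:
        return value
    factor = _SI_TO_CU[analyte]
    return value * factor if to_system is UnitSystem.CU else value / factor


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in reported tables)."""
    shifted = value * 10**ndigits
    rounded = math.floor(abs(shifted) + 0.5) * (1 if shifted >= 0 else -1)
    return rounded / 10**ndigits


def truncate_decimal(value: float, ndigits: int = 0) -> float:
    """Truncate toward zero at ``ndigits`` decimals (alternative table convention)."""
    shifted = value * 10**ndigits
    return math.trunc(shifted) / 10**ndigits
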