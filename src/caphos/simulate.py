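"""Synthetic patient cohorts and laboratory-database extracts.

The published study deposits no data, so every pipeline stage is exercised on
simulated records with the statistical structure the analysis assumes:

* a case-control cohort of 97 primary-hyperparathyroidism (PHPT) patients —
  62 hypercalcemic, 35 normocalcemic — against 96 controls, whose group-wise
  medians and min–max ranges are calibrated to the published biochemistry
  (PHPT: Ca median 2.75 mmol/L, P 0.77, PTH 135.2 ng/L; controls: 2.35, 1.14,
  32.1);
* a raw laboratory-database extract mixing healthy panels with PHPT-like and
  hypoparathyroid-like tails, renal-failure records, incomplete panels and
  out-of-age-range rows, so the mining cascade has something to exclude at
  every stage.

Distribution families are a modelling choice (the study reports only medians
and ranges): truncated skew-normals for Ca and P, truncated log-normals for
PTH, 25-OH vitamin D and creatinine, truncated normal for albumin. Each
marginal's location is solved numerically so a stated quantile (usually the
median) matches the calibration target exactly; scale and shape are frozen in
the versioned ``CALIBRATION`` table below. Ca and P are negatively coupled
through a Gaussian copula on ranks (default ρ = −0.4), reflecting their
approximately inverse physiological relationship.

A single global seed governs all draws; per-group substreams are spawned
deterministically so adding one group never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .biochem import CREATININE_UMOL_PER_MGDL, LabRecord, Sex
from .stats import ConfusionCounts

__all__ = [
    "Marginal",
    "GroupSpec",
    "CohortSpec",
    "LabDbSpec",
    "CALIBRATION_VERSION",
    "default_cohort_spec",
    "default_labdb_spec",
    "generate_cohort",
    "generate_labdb",
    "worked_fixtures",
]

CALIBRATION_VERSION = "1"

_FAMILIES = ("norm", "skewnorm", "lognorm")


@dataclass(frozen=True)
class Marginal:
    """A truncated univariate marginal calibrated to one quantile.

    ``family`` is ``norm``, ``skewnorm`` (shape = slant parameter) or
    ``lognorm`` (a normal on the log scale; ``scale`` is the log-sd). Support
    is truncated to [lo, hi]; the location is solved so the truncated
    distribution's ``target_q`` quantile equals ``target``.
    """

    family: str
    lo: float
    hi: float
    target: float
    scale: float
    shape: float = 0.0
    target_q: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.lo < self.target < self.hi:
            raise ValueError(
                f"target {self.target} must lie strictly inside [{self.lo}, {self.hi}]"
            )
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if not 0.0 < self.target_q < 1.0:
            raise ValueError("target_q must lie in (0, 1)")
        if self.family == "lognorm" and self.lo <= 0:
            raise ValueError("lognorm support must be positive")

    def _support(self) -> tuple[float, float, float]:
        if self.family == "lognorm":
            return math.log(self.lo), math.log(self.hi), math.log(self.target)
        return self.lo, self.hi, self.target

    def _trunc_ppf(self, q, loc: float):
        lo, hi, _ = self._support()
        if self.family == "skewnorm":
            dist = sps.skewnorm(self.shape, loc=loc, scale=self.scale)
            flo, fhi = dist.cdf(lo), dist.cdf(hi)
            x = dist.ppf(flo + np.asarray(q) * (fhi - flo))
        else:
            # truncnorm handles far-tail truncation in a numerically stable way
            a, b = (lo - loc) / self.scale, (hi - loc) / self.scale
            x = sps.truncnorm(a, b, loc=loc, scale=self.scale).ppf(q)
        return np.clip(x, lo, hi)

    @cached_property
    def loc(self) -> float:
        """Location solved so the truncated ``target_q`` quantile hits ``target``."""
        lo, hi, target = self._support()

        def gap(loc: float) -> float:
            return float(self._trunc_ppf(self.target_q, loc)) - target

        if self.family != "skewnorm":
            span = (hi - lo) + 10.0 * self.scale
            return optimize.brentq(gap, lo - span, hi + span, xtol=1e-10)
        # The skew-normal cdf loses precision when the support sits deep in a
        # tail, so bracket locally: start from the location whose untruncated
        # target_q quantile hits the target, then expand until the sign flips.
        guess = target - self.scale * float(sps.skewnorm(self.shape).ppf(self.target_q))
        step = self.scale
        a, b = guess - step, guess + step
        ga, gb = gap(a), gap(b)
        for _ in range(60):
            if ga <= 0.0 <= gb:
                return optimize.brentq(gap, a, b, xtol=1e-10)
            if ga > 0.0:
                a -= step
                ga = gap(a)
            if gb < 0.0:
                b += step
                gb = gap(b)
            step *= 1.5
        raise RuntimeError(f"calibration failed for marginal {self}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniforms into the calibrated truncated marginal."""
        x = self._trunc_ppf(u, self.loc)
        if self.family == "lognorm":
            return np.exp(x)
        return np.asarray(x, dtype=float)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, calibrated marginals, demographics, coupling."""

    n: int
    marginals: dict[str, Marginal]
    age_range: tuple[int, int]
    p_female: float
    rho_ca_p: float = -0.4
    albumin_availability: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if not -1.0 < self.rho_ca_p < 1.0:
            raise ValueError("rho_ca_p must lie in (-1, 1)")
        if not 0.0 <= self.albumin_availability <= 1.0:
            raise ValueError("albumin_availability must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Case-control cohort layout: hypercalcemic PHPT, normocalcemic PHPT, controls."""

    phpt_hyper: GroupSpec
    phpt_normo: GroupSpec
    control: GroupSpec
    seed: int = 0

    def groups(self) -> dict[str, GroupSpec]:
        return {
            "phpt_hyper": self.phpt_hyper,
            "phpt_normo": self.phpt_normo,
            "control": self.control,
        }


# The PHPT group's overall Ca median must sit at 2.75 mmol/L although 35 of 97
# members are normocalcemic (Ca <= 2.65): the 0.5 mixture quantile falls at the
# hypercalcemic marginal's (48.5 - 35)/62 = 0.2177 quantile, which is therefore
# the calibrated target for that marginal.
_HYPER_CA_Q = (0.5 * 97 - 35) / 62

CALIBRATION: dict[str, GroupSpec] = {
    "phpt_hyper": GroupSpec(
        n=62,
        marginals={
            "ca": Marginal("skewnorm", 2.65, 3.87, 2.75, scale=0.30, shape=3.0, target_q=_HYPER_CA_Q),
            "p": Marginal("skewnorm", 0.45, 1.26, 0.77, scale=0.20, shape=2.0),
            "pth": Marginal("lognorm", 57.6, 1748.0, 135.2, scale=0.80),
            "vitd25": Marginal("lognorm", 10.0, 110.0, 40.7, scale=0.55),
            "creatinine": Marginal("lognorm", 44.2, 132.6, 70.7, scale=0.22),
            "albumin": Marginal("norm", 27.0, 48.0, 43.0, scale=3.5),
        },
        age_range=(23, 90),
        p_female=0.7113,
        albumin_availability=0.75,
    ),
    "phpt_normo": GroupSpec(
        n=35,
        marginals={
            # High-normal calcium: the clinical signature of normocalcemic PHPT.
            "ca": Marginal("skewnorm", 2.35, 2.65, 2.55, scale=0.12, shape=-2.0),
            "p": Marginal("skewnorm", 0.45, 1.26, 0.77, scale=0.20, shape=2.0),
            "pth": Marginal("lognorm", 88.0, 1748.0, 135.2, scale=0.80),
            "vitd25": Marginal("lognorm", 10.0, 110.0, 40.7, scale=0.55),
            "creatinine": Marginal("lognorm", 44.2, 132.6, 70.7, scale=0.22),
            "albumin": Marginal("norm", 27.0, 48.0, 43.0, scale=3.5),
        },
        age_range=(23, 90),
        p_female=0.7113,
        albumin_availability=0.75,
    ),
    "control": GroupSpec(
        n=96,
        marginals={
            # Truncated to the intersection of the observed control range and the
            # reference interval, so every generated control satisfies the
            # control definition (Ca and PTH both within normal limits).
            "ca": Marginal("norm", 2.12, 2.55, 2.35, scale=0.10),
            "p": Marginal("norm", 0.68, 1.45, 1.14, scale=0.16),
            "pth": Marginal("lognorm", 15.0, 80.7, 32.1, scale=0.45),
            "vitd25": Marginal("lognorm", 10.0, 103.0, 50.8, scale=0.50),
            "creatinine": Marginal("lognorm", 44.2, 150.2, 70.7, scale=0.25),
            "albumin": Marginal("norm", 26.0, 50.0, 41.0, scale=4.0),
        },
        age_range=(20, 89),
        p_female=0.4536,
        albumin_availability=0.70,
    ),
}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The calibrated case-control cohort (97 PHPT = 62 + 35, 96 controls)."""
    return CohortSpec(seed=seed, **CALIBRATION)


def _gaussian_copula_uniforms(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return sps.norm.cdf(z1), sps.norm.cdf(z2)


def _sample_group(
    rng: np.random.Generator, gspec: GroupSpec, prefix: str, truth_phpt: bool
) -> list[LabRecord]:
    n = gspec.n
    if n == 0:
        return []
    u_ca, u_p = _gaussian_copula_uniforms(rng, n, gspec.rho_ca_p)
    ca = gspec.marginals["ca"].ppf(u_ca)
    p = gspec.marginals["p"].ppf(u_p)
    pth = gspec.marginals["pth"].sample(rng, n)
    vitd = gspec.marginals["vitd25"].sample(rng, n)
    creat = gspec.marginals["creatinine"].sample(rng, n)
    albumin = gspec.marginals["albumin"].sample(rng, n)
    has_albumin = rng.uniform(size=n) < gspec.albumin_availability
    age = rng.integers(gspec.age_range[0], gspec.age_range[1] + 1, size=n)
    female = rng.uniform(size=n) < gspec.p_female

    records = []
    for i in range(n):
        records.append(
            LabRecord(
                record_id=f"{prefix}{i + 1:03d}",
                age=float(age[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                ca=float(ca[i]),
                p=float(p[i]),
                pth=float(pth[i]),
                creatinine=float(creat[i]),
                albumin=float(albumin[i]) if has_albumin[i] else None,
                vitd25=float(vitd[i]),
                truth_phpt=truth_phpt,
            )
        )
    return records


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> list[LabRecord]:
    """Simulate a case-control cohort with ground-truth diagnoses attached.

    Deterministic given (spec, seed): per-group substreams are spawned from a
    single ``SeedSequence``. ``seed`` overrides ``spec.seed`` when given.
    """
    spec = spec if spec is not None else default_cohort_spec()
    seed = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(3)
    prefixes = {"phpt_hyper": "H", "phpt_normo": "N", "control": "C"}
    records: list[LabRecord] = []
    for stream, (name, gspec) in zip(streams, spec.groups().items()):
        rng = np.random.default_rng(stream)
        records.extend(_sample_group(rng, gspec, prefixes[name], name.startswith("phpt")))
    return records


# ---------------------------------------------------------------------------
# Laboratory-database extract
# ---------------------------------------------------------------------------

_LABDB_COMPONENTS = ("healthy", "phpt", "hypopara", "renal", "incomplete", "out_of_age")

_LABDB_MARGINALS: dict[str, dict[str, Marginal]] = {
    "healthy": {
        "ca": Marginal("norm", 1.90, 2.70, 2.30, scale=0.122),
        "p": Marginal("norm", 0.50, 1.70, 1.10, scale=0.183),
        "pth": Marginal("lognorm", 5.0, 250.0, 37.0, scale=0.45),
        "creatinine": Marginal("lognorm", 40.0, 120.0, 75.0, scale=0.22),
    },
    "phpt": {
        "ca": Marginal("norm", 2.55, 3.90, 2.80, scale=0.25),
        "p": Marginal("norm", 0.45, 1.30, 0.80, scale=0.15),
        "pth": Marginal("lognorm", 85.0, 1800.0, 140.0, scale=0.70),
        "creatinine": Marginal("lognorm", 40.0, 120.0, 75.0, scale=0.22),
    },
    "hypopara": {
        "ca": Marginal("norm", 1.80, 2.30, 2.05, scale=0.08),
        "p": Marginal("norm", 0.80, 1.90, 1.30, scale=0.18),
        "pth": Marginal("lognorm", 2.0, 14.9, 8.0, scale=0.40),
        "creatinine": Marginal("lognorm", 40.0, 120.0, 75.0, scale=0.22),
    },
}


@dataclass(frozen=True)
class LabDbSpec:
    """Mixture layout of a raw laboratory-database extract.

    ``weights`` maps component name to mixture fraction; components are
    healthy, phpt (upper-tail PTH and Ca with low P), hypopara (lower-tail PTH
    and Ca), renal (creatinine forced high enough that MDRD GFR < 30),
    incomplete (one required analyte blanked) and out_of_age (<18 or >90).
    """

    n_rows: int = 20_000
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 0.731,
            "phpt": 0.029,
            "hypopara": 0.08,
            "renal": 0.10,
            "incomplete": 0.05,
            "out_of_age": 0.01,
        }
    )
    rho_ca_p: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        unknown = set(self.weights) - set(_LABDB_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights.values())}")


def default_labdb_spec(seed: int = 0, n_rows: int = 20_000) -> LabDbSpec:
    return LabDbSpec(n_rows=n_rows, seed=seed)


def _sample_component(
    rng: np.random.Generator, component: str, n: int, rho: float
) -> pd.DataFrame:
    # incomplete and out_of_age rows are biochemically healthy; renal rows are
    # healthy apart from creatinine.
    base = "healthy" if component in ("incomplete", "out_of_age", "renal") else component
    marg = _LABDB_MARGINALS[base]
    u_ca, u_p = _gaussian_copula_uniforms(rng, n, rho)
    df = pd.DataFrame(
        {
            "ca": marg["ca"].ppf(u_ca),
            "p": marg["p"].ppf(u_p),
            "pth": marg["pth"].sample(rng, n),
            "creatinine": marg["creatinine"].sample(rng, n),
        }
    )
    df["age"] = rng.integers(18, 91, size=n).astype(float)
    df["sex"] = np.where(rng.uniform(size=n) < 0.5, "female", "male")
    df["black"] = False
    df["component"] = component

    if component == "out_of_age":
        young = rng.uniform(size=n) < 0.5
        df.loc[young, "age"] = rng.integers(8, 18, size=int(young.sum())).astype(float)
        df.loc[~young, "age"] = rng.integers(91, 100, size=int((~young).sum())).astype(float)
    elif component == "renal":
        # Invert the MDRD formula at GFR = 30 for each row's age and sex, then
        # draw creatinine strictly above that bound so every renal row fails
        # the GFR > 30 retention rule.
        sex_factor = np.where(df["sex"] == "female", 0.742, 1.0)
        creat_mgdl_min = (186.0 * df["age"] ** -0.203 * sex_factor / 30.0) ** (1.0 / 1.154)
        factor = 1.0 + rng.lognormal(mean=-0.7, sigma=0.6, size=n)
        df["creatinine"] = creat_mgdl_min * factor * CREATININE_UMOL_PER_MGDL
    elif component == "incomplete":
        which = rng.integers(0, 4, size=n)
        for j, col in enumerate(("ca", "p", "pth", "creatinine")):
            df.loc[which == j, col] = np.nan
    return df


def generate_labdb(spec: LabDbSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a raw laboratory-database extract (one row = one occasion).

    Component sizes are multinomial in the spec weights; rows are shuffled so
    component identity is not positional. The hidden ``component`` column is
    the generator's own truth and is ignored by the mining cascade.
    """
    spec = spec if spec is not None else default_labdb_spec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(_LABDB_COMPONENTS) + 2)
    count_rng = np.random.default_rng(streams[0])
    weights = np.array([spec.weights.get(c, 0.0) for c in _LABDB_COMPONENTS])
    counts = count_rng.multinomial(spec.n_rows, weights)

    frames = []
    for stream, component, n in zip(streams[1:-1], _LABDB_COMPONENTS, counts):
        if n == 0:
            continue
        frames.append(_sample_component(np.random.default_rng(stream), component, int(n), spec.rho_ca_p))
    df = pd.concat(frames, ignore_index=True)
    shuffle_rng = np.random.default_rng(streams[-1])
    df = df.sample(frac=1.0, random_state=np.random.RandomState(shuffle_rng.integers(2**31)))
    df = df.reset_index(drop=True)
    df.insert(0, "record_id", [f"R{i + 1:06d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Hand-checkable fixtures
# ---------------------------------------------------------------------------

def _refine_fixture() -> pd.DataFrame:
    """Ten raw rows: 2 incomplete, 1 renal failure, 1 over-age, 6 clean."""
    rows = [
        # record_id, age, sex, ca, p, pth, creatinine
        ("F01", 50, "male", 2.40, 1.10, 40.0, 70.0),
        ("F02", 50, "male", 2.40, np.nan, 40.0, 70.0),      # incomplete: P missing
        ("F03", 64, "female", 2.30, 1.20, 35.0, 80.0),
        ("F04", 42, "female", np.nan, 1.05, 50.0, 75.0),    # incomplete: Ca missing
        ("F05", 50, "male", 2.45, 0.95, 60.0, 600.0),       # renal: GFR ~ 9
        ("F06", 95, "male", 2.35, 1.15, 45.0, 72.0),        # over age 90
        ("F07", 33, "female", 2.50, 1.00, 55.0, 65.0),
        ("F08", 71, "male", 2.25, 1.30, 30.0, 90.0),
        ("F09", 58, "female", 2.60, 0.90, 70.0, 68.0),
        ("F10", 27, "male", 2.42, 1.22, 38.0, 74.0),
    ]
    df = pd.DataFrame(rows, columns=["record_id", "age", "sex", "ca", "p", "pth", "creatinine"])
    df["age"] = df["age"].astype(float)
    df["black"] = False
    return df


def _evaluation_fixture() -> list[LabRecord]:
    """Twelve curated records: 6 PHPT cases (one with Ca/P below 2.71) and six
    controls (one with Ca/P above), giving sensitivity = specificity = 5/6."""

    def rec(rid, ca, p, pth, truth):
        return LabRecord(
            record_id=rid, age=55.0, sex=Sex.FEMALE, ca=ca, p=p, pth=pth,
            creatinine=70.0, truth_phpt=truth,
        )

    cases = [
        rec("E01", 2.90, 0.80, 150.0, True),   # ratio 3.63
        rec("E02", 2.80, 0.70, 190.0, True),   # ratio 4.00
        rec("E03", 3.10, 0.90, 240.0, True),   # ratio 3.44
        rec("E04", 2.85, 0.75, 130.0, True),   # ratio 3.80
        rec("E05", 2.70, 0.85, 110.0, True),   # ratio 3.18
        rec("E06", 2.75, 1.10, 120.0, True),   # ratio 2.50 — the missed case
    ]
    controls = [
        rec("E07", 2.30, 1.10, 35.0, False),   # ratio 2.09
        rec("E08", 2.40, 1.20, 42.0, False),   # ratio 2.00
        rec("E09", 2.25, 1.05, 28.0, False),   # ratio 2.14
        rec("E10", 2.35, 1.30, 50.0, False),   # ratio 1.81
        rec("E11", 2.20, 1.15, 30.0, False),   # ratio 1.91
        rec("E12", 2.45, 0.80, 60.0, False),   # ratio 3.06 — the false alarm
    ]
    return cases + controls


def worked_fixtures() -> dict:
    """Small hand-tallied fixtures with their expected outputs.

    * ``trial1_counts`` / ``trial2_counts`` — the published confusion counts of
      the two evaluations, for metric-layer checks.
    * ``refine_rows`` — ten raw rows of which the mining cascade keeps six,
      with the expected stage-by-stage counts.
    * ``evaluation_cohort`` — twelve curated records whose Ca/P evaluation at
      cutoff 2.71 gives sensitivity = specificity = 83.33%.
    """
    return {
        "trial1_counts": ConfusionCounts(tp=84, fp=12, tn=84, fn=13),
        "trial2_counts": ConfusionCounts(tp=441, fp=1762, tn=18095, fn=149),
        "refine_rows": _refine_fixture(),
        "refine_expected_counts": [10, 8, 7, 6],
        "evaluation_cohort": _evaluation_fixture(),
        "evaluation_expected": {"sensitivity": 500.0 / 6, "specificity": 500.0 / 6},
    }
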