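"""Run configuration: cutoffs, reference ranges, conventions, seeds.

Defaults reproduce the published operating points: Ca/P cutoff 2.71 in SI
(3.5 when Ca and P are expressed in mg/dL), total Ca upper limit 2.65 mmol/L,
PTH upper limit 88 ng/L, serum-P lower cutoff 2.5 mg/dL (converted to SI
internally). The configuration round-trips through YAML without loss.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .biochem import P_MGDL_PER_MMOL, ReferenceRanges


@dataclass(frozen=True)
class Config:
    ranges: ReferenceRanges = field(default_factory=ReferenceRanges)
    ratio_cutoff_si: float = 2.71
    ca_cutoff: float = 2.65        # mmol/L, upper reference limit
    pth_cutoff: float = 88.0       # ng/L, upper reference limit
    p_cutoff_cu: float = 2.5       # mg/dL, lower cutoff for phosphorous
    boundary: str = "gte"          # positivity at a ROC-derived ratio cutoff
    rounding: str = "half_away"    # integer-percent convention: half_away | truncate
    transform_trigger: str = "skewness"  # skewness | shapiro
    skew_threshold: float = 1.0    # |skewness| beyond which an analyte is log-transformed
    bounds_on: str = "pre_exclusion"  # centile bounds computed before hypopara exclusion
    ncphpt_on_corrected: bool = False  # subtype split on total (not corrected) Ca
    ci_method: str = "hanley"      # hanley | bootstrap
    bootstrap_n: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ratio_cutoff_si", "ca_cutoff", "pth_cutoff", "p_cutoff_cu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.boundary not in ("gte", "gt"):
            raise ValueError(f"unknown boundary convention {self.boundary!r}")
        if self.rounding not in ("half_away", "truncate"):
            raise ValueError(f"unknown rounding convention {self.rounding!r}")
        if self.transform_trigger not in ("skewness", "shapiro"):
            raise ValueError(f"unknown transform trigger {self.transform_trigger!r}")
        if self.bounds_on != "pre_exclusion":
            raise ValueError("only pre_exclusion centile bounds are implemented")
        if self.ci_method not in ("hanley", "bootstrap"):
            raise ValueError(f"unknown CI method {self.ci_method!r}")

    @property
    def p_cutoff_si(self) -> float:
        """Phosphorous cutoff in mmol/L (2.5 mg/dL ≈ 0.807 mmol/L)."""
        return self.p_cutoff_cu / P_MGDL_PER_MMOL

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        data = dict(data)
        ranges = data.pop("ranges", None)
        if ranges is not None:
            ranges = ReferenceRanges(**{k: tuple(v) for k, v in ranges.items()})
            data["ranges"] = ranges
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "Config":
        return replace(self, seed=seed)
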