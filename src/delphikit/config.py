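"""Run configuration for a Delphi analysis."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ValidationError


@dataclass
class PanelConfig:
    """All tunable knobs of the pipeline, with conventional defaults.

    The importance scale defaults to 0-10 with full score 10.  Display
    rounding follows the convention of published consensus tables:
    means / SDs / coefficients of variation at 2 decimal places,
    full-score frequency as a percent at 2 dp, authority coefficients at
    3 dp, ties rounded half-up.
    """

    scale_min: int = 0
    scale_max: int = 10
    full_score: int | None = None  # defaults to scale_max
    sd_denominator: str = "n_minus_1"  # or "n"
    boundary_grouping: str = "global"  # or "per_tier"
    #: values exactly at a screening boundary count as failing
    strict_boundaries: bool = True
    rounding: dict = field(
        default_factory=lambda: {"Mj": 2, "sd": 2, "Vj": 2, "Kj_pct": 2, "authority": 3}
    )
    response_rate_good: float = 70.0  # percent
    cr_acceptable: float = 0.7
    cr_bands: tuple = (0.5, 0.75)
    w_coordinated: float = 0.4  # W above this: coordination is good
    w_complete: float = 0.5    # W above this: consultation can stop
    require_complete_matrix: bool = True
    w_permutation_test: bool = False

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValidationError("scale_min must be < scale_max")
        if self.full_score is None:
            self.full_score = self.scale_max
        if not (self.scale_min <= self.full_score <= self.scale_max):
            raise ValidationError("full_score must lie within the scale")
        if self.sd_denominator not in ("n_minus_1", "n"):
            raise ValidationError(f"unknown sd_denominator {self.sd_denominator!r}")
        if self.boundary_grouping not in ("global", "per_tier"):
            raise ValidationError(f"unknown boundary_grouping {self.boundary_grouping!r}")
        self.cr_bands = tuple(self.cr_bands)
        if len(self.cr_bands) != 2 or self.cr_bands[0] >= self.cr_bands[1]:
            raise ValidationError("cr_bands must be (low, high) with low < high")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_denominator == "n_minus_1" else 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["cr_bands"] = list(self.cr_bands)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
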