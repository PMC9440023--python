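"""Domain types for multi-round Delphi consensus panels.

A Delphi study scores a hierarchy of candidate indicators (tier 1 =
primary, tier 2 = secondary, tier 3 = tertiary) over one or more
anonymous survey rounds.  Each responding expert gives every active
indicator an integer importance score on a bounded scale, a familiarity
self-rating (6 ordinal levels mapping to the coefficients
1, 0.8, 0.6, 0.4, 0.2, 0) and a self-rated judgment basis on four
dimensions (practical experience, theoretical analysis, understanding
of peers, insight), each banded low / mid / high.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import pandas as pd


class DelphiError(ValueError):
    """Base class for domain and validation errors."""


class ValidationError(DelphiError):
    """Raised when an input table or object violates its invariants."""


# ---------------------------------------------------------------------------
# shared schema constants (fixtures, synthetic data and I/O all use these)
# ---------------------------------------------------------------------------

#: Familiarity self-rating: ordinal level name -> familiarity coefficient Cs.
FAMILIARITY_COEFFICIENTS: dict[str, float] = {
    "very_familiar": 1.0,
    "familiar": 0.8,
    "relatively_familiar": 0.6,
    "generally_familiar": 0.4,
    "not_very_familiar": 0.2,
    "unfamiliar": 0.0,
}

#: The four judgment bases, in canonical column order.
JUDGMENT_BASES: tuple[str, ...] = ("practical", "theoretical", "peers", "insight")

#: Self-rated judgment score bands (0-1 / 2-3 / 4-5 on the 0-5 scale).
JUDGMENT_BANDS: tuple[str, ...] = ("low", "mid", "high")

#: Long-format response table columns.
RESPONSE_COLUMNS: tuple[str, ...] = (
    "round",
    "expert_id",
    "indicator_id",
    "score",
    "familiarity_level",
    "jb_practical",
    "jb_theoretical",
    "jb_peers",
    "jb_insight",
)

HIERARCHY_COLUMNS: tuple[str, ...] = (
    "id", "label", "tier", "parent_id", "status", "origin_round",
)

EDIT_COLUMNS: tuple[str, ...] = (
    "round", "action", "indicator_id", "label", "tier", "parent_id", "note",
)

EDIT_ACTIONS: tuple[str, ...] = ("delete", "add", "rename", "move", "keep")

NODE_STATUSES: tuple[str, ...] = ("active", "deleted", "added", "renamed")


def round_half_up(value: float, digits: int) -> float:
    """Round with ties away from zero, as the printed tables do.

    Python's builtin ``round`` is banker's rounding; display values in
    consensus tables conventionally round 0.5 up (0.9235 -> 0.924).
    NaN passes through (e.g. an undefined coefficient of variation).
    """
    value, digits = float(value), int(digits)
    if math.isnan(value) or math.isinf(value):
        return value
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def band_of_judgment_score(score: int) -> str:
    """Map a 0-5 self-rated judgment score to its band."""
    if score in (0, 1):
        return "low"
    if score in (2, 3):
        return "mid"
    if score in (4, 5):
        return "high"
    raise DelphiError(f"judgment score {score!r} outside 0-5")


# ---------------------------------------------------------------------------
# judgment-basis impact matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JudgmentBasisMatrix:
    """Impact coefficients per (band, basis) used to build Ca.

    An expert's judgment coefficient Ca for an indicator is the sum over
    the four bases of the coefficient for the band they rated themselves
    in.  The default values are the conventional instrument: with all
    four bases rated high the sum is 1.0; all mid gives 0.8; all low 0.6.
    """

    coefficients: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "low": (0.3, 0.1, 0.1, 0.1),
            "mid": (0.4, 0.2, 0.1, 0.1),
            "high": (0.5, 0.3, 0.1, 0.1),
        }
    )

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(JUDGMENT_BANDS):
            raise ValidationError(
                f"matrix bands {sorted(self.coefficients)} != {sorted(JUDGMENT_BANDS)}"
            )
        for band, row in self.coefficients.items():
            if len(row) != len(JUDGMENT_BASES):
                raise ValidationError(f"band {band!r} needs {len(JUDGMENT_BASES)} entries")
            if any(not (0.0 <= c <= 1.0) for c in row):
                raise ValidationError(f"band {band!r} has coefficients outside [0, 1]")
            if not (0.0 < sum(row) <= 1.0):
                raise ValidationError(f"band {band!r} row sum {sum(row)} outside (0, 1]")

    def coefficient(self, band: str, basis: str) -> float:
        try:
            return self.coefficients[band][JUDGMENT_BASES.index(basis)]
        except (KeyError, ValueError) as exc:
            raise DelphiError(f"unknown band/basis {band!r}/{basis!r}") from exc


DEFAULT_JUDGMENT_MATRIX = JudgmentBasisMatrix()


# ---------------------------------------------------------------------------
# indicator hierarchy
# ---------------------------------------------------------------------------

@dataclass
class IndicatorNode:
    """One indicator in the three-tier index system."""

    id: str
    label: str
    tier: int
    parent_id: Optional[str] = None
    status: str = "active"
    origin_round: int = 0

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValidationError(f"{self.id}: tier must be 1, 2 or 3, got {self.tier}")
        if self.tier == 1 and self.parent_id:
            raise ValidationError(f"{self.id}: tier-1 node cannot have a parent")
        if self.tier > 1 and not self.parent_id:
            raise ValidationError(f"{self.id}: tier-{self.tier} node needs a parent")
        if self.status not in NODE_STATUSES:
            raise ValidationError(f"{self.id}: unknown status {self.status!r}")

    @property
    def active(self) -> bool:
        return self.status != "deleted"


class IndicatorHierarchy:
    """A validated three-tier indicator system for one round.

    Secondary tiers may be skipped: a tertiary node may attach directly
    to a primary node (e.g. burn sites that have no intermediate
    grouping).  Only nodes whose status is not ``deleted`` count as
    active; only active leaf indicators are scored in a round.
    """

    def __init__(self, nodes: Iterable[IndicatorNode], round: int = 1):
        self.round = round
        self._nodes: dict[str, IndicatorNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise ValidationError(f"duplicate indicator id {node.id!r}")
            self._nodes[node.id] = node
        self._validate()

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise ValidationError(
                    f"{node.id}: parent {node.parent_id!r} does not exist"
                )
            if parent.tier >= node.tier:
                raise ValidationError(
                    f"{node.id}: parent tier {parent.tier} not below node tier {node.tier}"
                )
        # tier monotonicity makes cycles impossible; walk anyway to catch
        # future mutation bugs early
        for node in self._nodes.values():
            seen = set()
            cur: Optional[IndicatorNode] = node
            while cur is not None:
                if cur.id in seen:
                    raise ValidationError(f"cycle through {cur.id!r}")
                seen.add(cur.id)
                cur = self._nodes.get(cur.parent_id) if cur.parent_id else None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, indicator_id: str) -> IndicatorNode:
        try:
            return self._nodes[indicator_id]
        except KeyError as exc:
            raise DelphiError(f"unknown indicator {indicator_id!r}") from exc

    @property
    def nodes(self) -> list[IndicatorNode]:
        return list(self._nodes.values())

    def active_nodes(self, tier: Optional[int] = None) -> list[IndicatorNode]:
        return [
            n for n in self._nodes.values()
            if n.active and (tier is None or n.tier == tier)
        ]

    def active_leaves(self) -> list[IndicatorNode]:
        """Active nodes with no active children — the scored indicators."""
        parents = {
            n.parent_id for n in self._nodes.values() if n.active and n.parent_id
        }
        return [n for n in self._nodes.values() if n.active and n.id not in parents]

    def tier_counts(self, active_only: bool = True) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for node in self._nodes.values():
            if active_only and not node.active:
                continue
            counts[node.tier - 1] += 1
        return tuple(counts)  # type: ignore[return-value]

    def copy(self, round: Optional[int] = None) -> "IndicatorHierarchy":
        return IndicatorHierarchy(
            (replace(n) for n in self._nodes.values()),
            round=self.round if round is None else round,
        )

    def sort_key(self, indicator_id: str):
        """Stable output ordering: position in hierarchy, then id."""
        node = self[indicator_id]
        chain = []
        cur: Optional[IndicatorNode] = node
        while cur is not None:
            chain.append(list(self._nodes).index(cur.id))
            cur = self._nodes.get(cur.parent_id) if cur.parent_id else None
        return (tuple(reversed(chain)), indicator_id)


# ---------------------------------------------------------------------------
# expert panel
# ---------------------------------------------------------------------------

EXPERT_FIELDS: tuple[str, ...] = ("clinical_medicine", "animal_research")
EXPERIENCE_BANDS: tuple[str, ...] = ("lt15", "15to30", "gt30")
EXPERT_TITLES: tuple[str, ...] = ("associate_professor", "professor")


@dataclass
class ExpertProfile:
    """Panel-member characteristics (professional field, experience, title)."""

    id: str
    field: str
    experience_band: str
    title: str
    participated: dict[int, bool] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.field not in EXPERT_FIELDS:
            raise ValidationError(f"{self.id}: unknown field {self.field!r}")
        if self.experience_band not in EXPERIENCE_BANDS:
            raise ValidationError(f"{self.id}: unknown experience {self.experience_band!r}")
        if self.title not in EXPERT_TITLES:
            raise ValidationError(f"{self.id}: unknown title {self.title!r}")
        if self.participated is None:
            self.participated = {}


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

@dataclass
class ResponseSet:
    """All expert responses for one round, in long format.

    ``data`` holds one row per (expert, indicator) with columns
    :data:`RESPONSE_COLUMNS`.  ``score`` may be missing (NaN) when an
    expert skipped an indicator; familiarity levels are ordinal names
    from :data:`FAMILIARITY_COEFFICIENTS`; the four ``jb_*`` columns are
    bands from :data:`JUDGMENT_BANDS`.
    """

    round: int
    distributed: int
    returned: int
    data: pd.DataFrame
    scale_min: int = 0
    scale_max: int = 10

    def __post_init__(self) -> None:
        if self.distributed < 1:
            raise ValidationError("distributed must be >= 1")
        if not (0 <= self.returned <= self.distributed):
            raise ValidationError(
                f"returned {self.returned} outside [0, distributed={self.distributed}]"
            )
        missing = set(RESPONSE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"response table missing columns {sorted(missing)}")
        dup = self.data.duplicated(["expert_id", "indicator_id"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValidationError(
                f"duplicate response for expert {row['expert_id']!r}, "
                f"indicator {row['indicator_id']!r}"
            )
        scored = self.data.dropna(subset=["score"])
        bad = scored[
            (scored["score"] < self.scale_min) | (scored["score"] > self.scale_max)
        ]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValidationError(
                f"score {row['score']!r} for expert {row['expert_id']!r} on "
                f"indicator {row['indicator_id']!r} outside scale "
                f"[{self.scale_min}, {self.scale_max}]"
            )
        n_experts = self.data["expert_id"].nunique()
        if n_experts > self.returned:
            raise ValidationError(
                f"{n_experts} scoring experts exceed returned={self.returned}"
            )
        bad_fam = set(scored["familiarity_level"].dropna()) - set(
            FAMILIARITY_COEFFICIENTS
        )
        if bad_fam:
            raise ValidationError(f"unknown familiarity levels {sorted(bad_fam)}")
        for basis in JUDGMENT_BASES:
            col = f"jb_{basis}"
            bad_band = set(self.data[col].dropna()) - set(JUDGMENT_BANDS)
            if bad_band:
                raise ValidationError(f"unknown {col} bands {sorted(bad_band)}")

    @property
    def experts(self) -> list[str]:
        return sorted(self.data["expert_id"].unique())

    @property
    def indicators(self) -> list[str]:
        return sorted(self.data["indicator_id"].unique())

    def scores_for(self, indicator_id: str) -> pd.Series:
        """Non-missing importance scores for one indicator, indexed by expert."""
        sub = self.data[self.data["indicator_id"] == indicator_id]
        return sub.dropna(subset=["score"]).set_index("expert_id")["score"]

    def score_matrix(self, indicator_ids: Optional[list[str]] = None) -> pd.DataFrame:
        """Experts x indicators pivot of importance scores (NaN = skipped)."""
        mat = self.data.pivot(index="expert_id", columns="indicator_id", values="score")
        if indicator_ids is not None:
            mat = mat.reindex(columns=indicator_ids)
        return mat
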