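"""Boundary-value screening of indicators.

Retention thresholds are computed from the cross-indicator distribution
of each concentration statistic:

* mean importance  Mj — boundary = mean(Mj) - sd(Mj), keep strictly above;
* full-score rate  Kj — boundary = mean(Kj) - sd(Kj), keep strictly above;
* variation coeff. Vj — boundary = mean(Vj) + sd(Vj), keep strictly below.

An indicator failing all three criteria is deleted outright; failing one
or two sends it to expert discussion ("review"); failing none retains
it.  Expert review may override any disposition — overrides of retained
indicators are allowed but flagged in the audit trail.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import PanelConfig
from .model import DelphiError, IndicatorHierarchy, ValidationError

CRITERIA = ("Mj", "Kj", "Vj")
#: retain-above for Mj/Kj, retain-below for Vj
DIRECTIONS = {"Mj": "above", "Kj": "above", "Vj": "below"}
DISPOSITIONS = ("retain", "review", "delete")


@dataclass(frozen=True)
class CriterionBoundary:
    criterion: str
    mean: float
    sd: float
    boundary: float
    direction: str
    group: str = "global"


@dataclass
class BoundaryValues:
    """Per-criterion (and per-group) retention thresholds."""

    boundaries: dict[str, dict[str, CriterionBoundary]] = field(default_factory=dict)
    # boundaries[group][criterion]

    def for_group(self, group: str) -> Mapping[str, CriterionBoundary]:
        return self.boundaries[group]


def boundary_values(
    stats: pd.DataFrame,
    config: Optional[PanelConfig] = None,
    hierarchy: Optional[IndicatorHierarchy] = None,
) -> BoundaryValues:
    """Compute the three retention boundaries from a stats table.

    Grouping is global by default; ``per_tier`` grouping (requires the
    hierarchy to assign tiers) computes separate boundaries within each
    tier.  A group needs at least 2 indicators for its sd to exist.
    """
    config = config or PanelConfig()
    df = stats.copy()
    if config.boundary_grouping == "per_tier":
        if hierarchy is None:
            raise DelphiError("per_tier boundary grouping requires a hierarchy")
        df["_group"] = [f"tier{hierarchy[i].tier}" for i in df["indicator_id"]]
    else:
        df["_group"] = "global"
    result = BoundaryValues()
    for group, sub in df.groupby("_group"):
        if len(sub) < 2:
            raise DelphiError(
                f"boundary group {group!r} has {len(sub)} indicator(s); "
                "need at least 2 for a standard deviation"
            )
        entry: dict[str, CriterionBoundary] = {}
        for crit in CRITERIA:
            values = sub[crit].to_numpy(float)
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=config.ddof))
            boundary = mean - sd if DIRECTIONS[crit] == "above" else mean + sd
            entry[crit] = CriterionBoundary(
                criterion=crit, mean=mean, sd=sd, boundary=boundary,
                direction=DIRECTIONS[crit], group=str(group),
            )
        result.boundaries[str(group)] = entry
    return result


def screen(
    stats: pd.DataFrame,
    boundaries: BoundaryValues,
    hierarchy: Optional[IndicatorHierarchy] = None,
) -> pd.DataFrame:
    """Assign a disposition to every indicator in the stats table.

    Comparisons are strict: a value exactly at its boundary counts as
    failing that criterion.  Returns one row per indicator with the
    failed-criterion flags, the disposition, and ``final_action``
    initialised to the automatic outcome (``deleted`` only when all
    three criteria fail, pending expert review otherwise).
    """
    multi_group = len(boundaries.boundaries) > 1
    rows = []
    for _, row in stats.iterrows():
        if multi_group:
            if hierarchy is None:
                raise DelphiError("per-group screening requires a hierarchy")
            group = f"tier{hierarchy[row['indicator_id']].tier}"
        else:
            group = next(iter(boundaries.boundaries))
        bounds = boundaries.for_group(group)
        failed = []
        for crit in CRITERIA:
            b = bounds[crit]
            value = float(row[crit])
            if b.direction == "above":
                ok = value > b.boundary
            else:
                ok = value < b.boundary
            if not ok:
                failed.append(crit)
        n_failed = len(failed)
        disposition = (
            "retain" if n_failed == 0 else "delete" if n_failed == 3 else "review"
        )
        rows.append(
            {
                "indicator_id": row["indicator_id"],
                "Mj_fail": "Mj" in failed,
                "Kj_fail": "Kj" in failed,
                "Vj_fail": "Vj" in failed,
                "n_failed": n_failed,
                "disposition": disposition,
                "final_action": "deleted" if disposition == "delete" else "",
                "rationale": "",
            }
        )
    return pd.DataFrame(rows)


def apply_review(decisions: pd.DataFrame, edits: pd.DataFrame) -> pd.DataFrame:
    """Resolve review dispositions with the expert edit log.

    Every ``review`` indicator must have an explicit edit-log entry
    (keep / delete / rename / move count as resolutions); unresolved
    review items raise.  Edits that delete a *retained* indicator are
    honoured but flagged ``expert-override`` in the rationale, since
    they depart from the statistical screen.
    """
    out = decisions.copy()
    known = set(out["indicator_id"])
    edit_rows = edits[edits["action"] != "add"]
    unknown = set(edit_rows["indicator_id"]) - known
    if unknown:
        raise ValidationError(
            f"edit log references unknown indicators: {sorted(unknown)}"
        )
    by_id = {row["indicator_id"]: row for _, row in edit_rows.iterrows()}
    final_actions, rationales = [], []
    unresolved = []
    for _, row in out.iterrows():
        iid = row["indicator_id"]
        edit = by_id.get(iid)
        note = str(edit["note"]) if edit is not None and pd.notna(edit["note"]) else ""
        if row["disposition"] == "delete":
            final_actions.append("deleted")
            rationales.append(note or "failed all three boundary criteria")
        elif edit is None:
            if row["disposition"] == "review":
                unresolved.append(iid)
                final_actions.append("")
                rationales.append("")
            else:
                final_actions.append("kept")
                rationales.append("")
        else:
            action = edit["action"]
            if action == "delete":
                final_actions.append("deleted")
                if row["disposition"] == "retain":
                    note = (note + "; " if note else "") + "expert-override"
                rationales.append(note)
            elif action in ("rename", "move"):
                final_actions.append("modified")
                rationales.append(note)
            else:  # keep
                final_actions.append("kept")
                rationales.append(note)
    if unresolved:
        raise DelphiError(
            "review-disposition indicators without an edit-log resolution: "
            + ", ".join(sorted(unresolved))
        )
    out["final_action"] = final_actions
    out["rationale"] = rationales
    return out
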