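"""Readers and writers for the pipeline's CSV/JSON artifacts.

All tables are plain CSV with headers; column sets are the schema
constants in :mod:`delphikit.model` so that fixtures, synthetic data
and user files stay interchangeable.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PanelConfig
from .model import (
    EDIT_ACTIONS,
    EDIT_COLUMNS,
    HIERARCHY_COLUMNS,
    RESPONSE_COLUMNS,
    DelphiError,
    IndicatorHierarchy,
    IndicatorNode,
    ResponseSet,
    ValidationError,
    round_half_up,
)

STATS_COLUMNS = ("indicator_id", "m_j", "Mj", "sd", "Vj", "Kj_pct", "Cs", "Ca", "Cr")


def read_responses(
    path: str | Path,
    config: Optional[PanelConfig] = None,
    *,
    distributed: Optional[int] = None,
    hierarchy: Optional[IndicatorHierarchy] = None,
) -> ResponseSet:
    """Load a long-format response table.

    ``distributed`` is the number of questionnaires sent out; it
    defaults to the number of distinct experts in the file (i.e. a 100%
    recovery rate).  When ``hierarchy`` is given, rows must reference
    known indicators.
    """
    config = config or PanelConfig()
    df = pd.read_csv(path, dtype={"expert_id": str, "indicator_id": str})
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    rounds = df["round"].unique()
    if len(rounds) != 1:
        raise ValidationError(f"{path}: expected a single round, found {sorted(rounds)}")
    if hierarchy is not None:
        unknown = set(df["indicator_id"]) - {n.id for n in hierarchy.nodes}
        if unknown:
            bad = df[df["indicator_id"].isin(unknown)].index[0]
            raise ValidationError(
                f"{path} row {bad + 2}: unknown indicator "
                f"{df.loc[bad, 'indicator_id']!r}"
            )
    returned = df["expert_id"].nunique()
    return ResponseSet(
        round=int(rounds[0]),
        distributed=int(distributed) if distributed is not None else returned,
        returned=returned,
        data=df[list(RESPONSE_COLUMNS)].copy(),
        scale_min=config.scale_min,
        scale_max=config.scale_max,
    )


def write_responses(responses: ResponseSet, path: str | Path) -> None:
    responses.data.to_csv(path, index=False)


def read_hierarchy(path: str | Path) -> IndicatorHierarchy:
    """Load an indicator hierarchy table (id, label, tier, parent_id, ...)."""
    df = pd.read_csv(path, dtype={"id": str, "parent_id": str, "label": str})
    missing = {"id", "label", "tier", "parent_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    nodes = []
    for _, row in df.iterrows():
        parent = row["parent_id"]
        nodes.append(
            IndicatorNode(
                id=row["id"],
                label=row["label"],
                tier=int(row["tier"]),
                parent_id=None if pd.isna(parent) or parent == "" else parent,
                status=row.get("status", "active") if "status" in df.columns else "active",
                origin_round=int(row["origin_round"]) if "origin_round" in df.columns else 0,
            )
        )
    return IndicatorHierarchy(nodes)


def write_hierarchy(hierarchy: IndicatorHierarchy, path: str | Path) -> None:
    rows = [
        {
            "id": n.id,
            "label": n.label,
            "tier": n.tier,
            "parent_id": n.parent_id or "",
            "status": n.status,
            "origin_round": n.origin_round,
        }
        for n in hierarchy.nodes
    ]
    pd.DataFrame(rows, columns=list(HIERARCHY_COLUMNS)).to_csv(path, index=False)


def read_edits(path: str | Path) -> pd.DataFrame:
    """Load an edit log (round, action, indicator_id, label, tier, parent_id, note)."""
    df = pd.read_csv(path, dtype={"indicator_id": str, "parent_id": str, "label": str})
    missing = set(EDIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["action"]) - set(EDIT_ACTIONS)
    if bad:
        raise ValidationError(f"{path}: unknown actions {sorted(bad)}")
    return df[list(EDIT_COLUMNS)].copy()


def round_stats_for_display(stats: pd.DataFrame, config: PanelConfig) -> pd.DataFrame:
    """Apply the configured half-up display rounding to a stats table."""
    digits = config.rounding
    out = stats.copy()
    for col, key in (("Mj", "Mj"), ("sd", "sd"), ("Vj", "Vj"), ("Kj_pct", "Kj_pct")):
        if col in out:
            out[col] = [round_half_up(v, digits[key]) for v in out[col].to_numpy(float)]
    for col in ("Cs", "Ca", "Cr"):
        if col in out:
            out[col] = [round_half_up(v, digits["authority"]) for v in out[col].to_numpy(float)]
    return out


def write_stats_table(stats: pd.DataFrame, path: str | Path, config: Optional[PanelConfig] = None) -> None:
    """Write a per-indicator statistics table, rounded for display."""
    config = config or PanelConfig()
    cols = [c for c in STATS_COLUMNS if c in stats.columns]
    cols += [c for c in stats.columns if c not in cols]
    out = round_stats_for_display(stats[cols], config)
    out.to_csv(path, index=False)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"indicator_id": str})
    if "indicator_id" not in df.columns:
        raise ValidationError(f"{path}: not a stats table (no indicator_id column)")
    return df


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def load_error(path: str | Path, message: str) -> DelphiError:
    return ValidationError(f"{path}: {message}")
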