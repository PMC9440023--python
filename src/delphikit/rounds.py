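"""Multi-round orchestration: per-round pipeline, hierarchy evolution, reports.

A round runs engagement -> authority -> concentration -> coordination ->
screening in that order on one response set; the expert edit log then
advances the indicator hierarchy into the next round.  The pipeline
supports any number of rounds; the conventional stopping signal
(W > 0.5) is reported but never auto-enforced.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from .concentration import stats_table
from .config import PanelConfig
from .coordination import ConcordanceResult, coordination_report
from .io import round_stats_for_display, write_stats_table, write_summary
from .model import (
    DEFAULT_JUDGMENT_MATRIX,
    DelphiError,
    IndicatorHierarchy,
    IndicatorNode,
    JudgmentBasisMatrix,
    ResponseSet,
)
from .reliability import authority_band_counts, panel_authority, response_rate
from .screening import apply_review, boundary_values, screen


@dataclass
class RoundSummary:
    round: int
    distributed: int
    returned: int
    response_rate: float
    response_rate_good: bool
    panel_cr: float
    concordance: ConcordanceResult
    authority_bands: tuple[int, int, int]
    tier_counts_before: tuple[int, int, int]
    tier_counts_after: Optional[tuple[int, int, int]] = None
    decision_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "round": self.round,
            "distributed": self.distributed,
            "returned": self.returned,
            "response_rate": self.response_rate,
            "response_rate_good": self.response_rate_good,
            "panel_cr": self.panel_cr,
            "concordance": self.concordance.as_dict(),
            "authority_bands": {
                "above_high": self.authority_bands[0],
                "between": self.authority_bands[1],
                "below_low": self.authority_bands[2],
            },
            "tier_counts_before": list(self.tier_counts_before),
            "decision_counts": self.decision_counts,
        }
        if self.tier_counts_after is not None:
            out["tier_counts_after"] = list(self.tier_counts_after)
        return out


@dataclass
class RoundResult:
    stats: pd.DataFrame
    decisions: pd.DataFrame
    summary: RoundSummary


def run_round(
    responses: ResponseSet,
    hierarchy: IndicatorHierarchy,
    config: Optional[PanelConfig] = None,
    matrix: JudgmentBasisMatrix = DEFAULT_JUDGMENT_MATRIX,
    out_dir: Optional[str | Path] = None,
) -> RoundResult:
    """Execute the full statistical pipeline for one round.

    Returns the per-indicator stats table, the screening decisions
    (dispositions only; expert review is applied separately) and a
    round summary.  When ``out_dir`` is given, writes ``stats.csv``,
    ``screening.csv`` and ``summary.json`` there.
    """
    config = config or PanelConfig()
    if responses.data.dropna(subset=["score"]).empty:
        raise DelphiError(f"round {responses.round}: response set contains no scores")
    unknown = set(responses.data["indicator_id"]) - {n.id for n in hierarchy.nodes}
    if unknown:
        raise DelphiError(f"responses reference unknown indicators: {sorted(unknown)}")

    rate = response_rate(
        responses.distributed, responses.returned, config.response_rate_good
    )
    stats = stats_table(responses, config, matrix)
    # stable ordering: hierarchy position, then id
    stats = stats.sort_values(
        "indicator_id", key=lambda col: col.map(hierarchy.sort_key)
    ).reset_index(drop=True)
    concordance = coordination_report(responses, config)
    bounds = boundary_values(stats, config, hierarchy)
    decisions = screen(stats, bounds, hierarchy)
    bands = authority_band_counts(stats["Cr"], config.cr_bands)
    summary = RoundSummary(
        round=responses.round,
        distributed=responses.distributed,
        returned=responses.returned,
        response_rate=rate.percent,
        response_rate_good=rate.good,
        panel_cr=panel_authority(stats),
        concordance=concordance,
        authority_bands=bands,
        tier_counts_before=hierarchy.tier_counts(),
        decision_counts=decisions["disposition"].value_counts().to_dict(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stats_table(stats, out / "stats.csv", config)
        decisions.to_csv(out / "screening.csv", index=False)
        write_summary(summary.as_dict(), out / "summary.json")
    return RoundResult(stats=stats, decisions=decisions, summary=summary)


def advance_hierarchy(
    hierarchy: IndicatorHierarchy,
    edits: pd.DataFrame,
    decisions: Optional[pd.DataFrame] = None,
) -> IndicatorHierarchy:
    """Apply an edit log to produce the next round's hierarchy.

    When screening ``decisions`` are given, review items must have been
    resolved (``apply_review``) first; indicators whose final action is
    ``deleted`` are removed in addition to explicit edit-log deletions.
    Deleting a node also deletes its descendants.  Replaying the same
    edit log on the same hierarchy is deterministic and reproducible.
    """
    if decisions is not None:
        pending = decisions[
            (decisions["disposition"] == "review") & (decisions["final_action"] == "")
        ]
        if not pending.empty:
            raise DelphiError(
                "unresolved review items: "
                + ", ".join(sorted(pending["indicator_id"]))
            )
    nxt = hierarchy.copy(round=hierarchy.round + 1)
    nodes = {n.id: n for n in nxt.nodes}

    def delete(node_id: str) -> None:
        if node_id not in nodes:
            raise DelphiError(f"edit log deletes unknown indicator {node_id!r}")
        nodes[node_id].status = "deleted"
        for child in [n for n in nodes.values() if n.parent_id == node_id]:
            delete(child.id)

    for _, edit in edits.iterrows():
        action, iid = edit["action"], edit["indicator_id"]
        if action == "delete":
            delete(iid)
        elif action == "add":
            if iid in nodes:
                raise DelphiError(f"edit log adds existing indicator {iid!r}")
            parent = edit["parent_id"] if pd.notna(edit["parent_id"]) else None
            if parent and parent not in nodes:
                raise DelphiError(f"added indicator {iid!r} has unknown parent {parent!r}")
            nodes[iid] = IndicatorNode(
                id=iid,
                label=edit["label"],
                tier=int(edit["tier"]),
                parent_id=parent or None,
                status="added",
                origin_round=nxt.round,
            )
        elif action == "rename":
            if iid not in nodes:
                raise DelphiError(f"edit log renames unknown indicator {iid!r}")
            nodes[iid].label = edit["label"]
            if nodes[iid].status == "active":
                nodes[iid].status = "renamed"
        elif action == "move":
            if iid not in nodes:
                raise DelphiError(f"edit log moves unknown indicator {iid!r}")
            nodes[iid].parent_id = edit["parent_id"]
        elif action == "keep":
            if iid not in nodes:
                raise DelphiError(f"edit log keeps unknown indicator {iid!r}")
    if decisions is not None:
        for _, row in decisions.iterrows():
            if row["final_action"] == "deleted" and nodes[row["indicator_id"]].active:
                delete(row["indicator_id"])
    return IndicatorHierarchy(nodes.values(), round=nxt.round)


def final_report(
    summaries: list[RoundSummary],
    final_hierarchy: IndicatorHierarchy,
    out_dir: Optional[str | Path] = None,
    round_stats: Optional[dict[int, pd.DataFrame]] = None,
    config: Optional[PanelConfig] = None,
) -> dict:
    """Consolidated multi-round report (JSON dict + human-readable tables)."""
    if not summaries:
        raise DelphiError("final_report needs at least one completed round")
    config = config or PanelConfig()
    report = {
        "rounds": [s.as_dict() for s in summaries],
        "final_tier_counts": list(final_hierarchy.tier_counts()),
        "n_rounds": len(summaries),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary(report, out / "report.json")
        if round_stats:
            lines = []
            for rnd in sorted(round_stats):
                stats = round_stats[rnd]
                labelled = stats.copy()
                labelled.insert(
                    1, "label",
                    [final_hierarchy[i].label if i in final_hierarchy else i
                     for i in stats["indicator_id"]],
                )
                lines.append(f"Round {rnd}")
                lines.append(
                    round_stats_for_display(labelled, config).to_string(index=False)
                )
                lines.append("")
            (out / "report.txt").write_text("\n".join(lines))
    return report
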