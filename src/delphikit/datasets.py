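"""Packaged reference tables from the published two-round burn-model study.

The round-1 and round-2 per-indicator tables (mean importance, SD,
coefficient of variation, full-score percentage and the three authority
coefficients, all as printed), the round-1 indicator hierarchy
(8 primary / 16 secondary / 54 tertiary) and the structured edit log
that turns it into the round-2 hierarchy (8 / 14 / 46).

Known quirks of the printed tables, preserved verbatim:

* the round-1 ``Kj_pct`` column duplicates ``Mj`` (a typesetting fault
  in the source; never trust it — recompute Kj from raw scores),
* round-2 "Subcutaneous injury" prints ``Kj_pct`` 28.46, which is not
  k/13 for any integer k (evidently a typo of 38.46),
* a handful of printed ``Vj``/``Cr`` cells differ from sd/Mj resp.
  (Cs+Ca)/2 recomputed from the printed inputs by slightly more than
  half an ulp, because the source computed them from unrounded raw
  statistics (see ``PRINTED_VJ_OUTLIERS`` / ``PRINTED_CR_OUTLIERS``).
"""
from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .model import EDIT_COLUMNS, IndicatorHierarchy, IndicatorNode

#: rows whose printed Vj differs from sd/Mj by more than 0.005
PRINTED_VJ_OUTLIERS = {
    (1, "lactate_ringers_solution"),
    (1, "analgin"),
    (1, "wound_color"),
    (2, "uratan"),
}
#: rows whose printed Cr differs from (Cs+Ca)/2 by more than 0.0005
PRINTED_CR_OUTLIERS = {(1, "between_80_and_100c")}
#: round-2 Kj_pct cell that is not k/13 for any integer k
PRINTED_KJ_TYPOS = {(2, "subcutaneous_injury")}


def _read(name: str, **kwargs) -> pd.DataFrame:
    with files("delphikit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_round_table(round: int) -> pd.DataFrame:
    """Printed per-indicator statistics for round 1 (54 rows) or 2 (46)."""
    if round not in (1, 2):
        raise ValueError("published tables exist for rounds 1 and 2 only")
    return _read(f"round{round}_stats.csv", dtype={"indicator_id": str})


def load_round1_hierarchy() -> IndicatorHierarchy:
    """The round-1 three-tier indicator system (8 / 16 / 54)."""
    df = _read("round1_hierarchy.csv", dtype={"id": str, "parent_id": str, "label": str})
    nodes = []
    for _, row in df.iterrows():
        parent = row["parent_id"]
        nodes.append(
            IndicatorNode(
                id=row["id"],
                label=row["label"],
                tier=int(row["tier"]),
                parent_id=None if pd.isna(parent) or parent == "" else parent,
                status=row["status"],
                origin_round=int(row["origin_round"]),
            )
        )
    return IndicatorHierarchy(nodes, round=1)


def load_round1_edits() -> pd.DataFrame:
    """The structured edit log applied between rounds 1 and 2."""
    df = _read("round1_edits.csv", dtype={"indicator_id": str, "parent_id": str, "label": str})
    return df[list(EDIT_COLUMNS)]
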