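from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from delphikit.model import JUDGMENT_BASES, ResponseSet


def make_responses(
    score_matrix: dict[str, dict[str, float]],
    *,
    round: int = 1,
    distributed: int | None = None,
    familiarity: str = "familiar",
    bands: dict[str, str] | None = None,
    scale=(0, 10),
) -> ResponseSet:
    """Build a ResponseSet from {expert: {indicator: score}} (None = skipped)."""
    bands = bands or {b: "high" for b in JUDGMENT_BASES}
    rows = []
    for expert, scores in score_matrix.items():
        for indicator, score in scores.items():
            rows.append(
                {
                    "round": round,
                    "expert_id": expert,
                    "indicator_id": indicator,
                    "score": np.nan if score is None else score,
                    "familiarity_level": familiarity,
                    **{f"jb_{b}": bands[b] for b in JUDGMENT_BASES},
                }
            )
    n = len(score_matrix)
    return ResponseSet(
        round=round,
        distributed=distributed if distributed is not None else n,
        returned=n,
        data=pd.DataFrame(rows),
        scale_min=scale[0],
        scale_max=scale[1],
    )


@pytest.fixture
def tiny_responses() -> ResponseSet:
    """Three experts scoring two indicators, one skip."""
    return make_responses(
        {
            "E1": {"A": 9, "B": 4},
            "E2": {"A": 8, "B": 5},
            "E3": {"A": 10, "B": None},
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
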