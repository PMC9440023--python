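"""Opinion-concentration statistics per indicator.

For indicator j scored by m_j experts with integer importance scores
C_ij, the concentration summary is

* ``Mj``  — arithmetic mean of the scores,
* ``sd``  — their standard deviation (sample, n-1, by default),
* ``Vj``  — coefficient of variation sd / Mj (smaller = tighter consensus),
* ``Kj``  — full-score frequency m'_j / m_j, the fraction of respondents
  awarding the maximum possible score (supplementary to Mj).
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .config import PanelConfig
from .model import DelphiError, JudgmentBasisMatrix, DEFAULT_JUDGMENT_MATRIX, ResponseSet
from .reliability import authority_per_indicator


def mean_importance(scores) -> float:
    """Mean importance Mj of one indicator's scores."""
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise DelphiError("no scores: indicator has no respondents")
    return float(values.mean())


def full_score_frequency(scores, full_score: float) -> float:
    """Full-score frequency Kj = (# scores == full) / m_j, in [0, 1]."""
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise DelphiError("no scores: indicator has no respondents")
    return float((values == full_score).sum() / values.size)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Vj = sd / Mj; undefined (raises) when the mean is zero."""
    if mean == 0:
        raise DelphiError("coefficient of variation undefined for zero mean")
    return sd / mean


def stats_table(
    responses: ResponseSet,
    config: Optional[PanelConfig] = None,
    matrix: JudgmentBasisMatrix = DEFAULT_JUDGMENT_MATRIX,
) -> pd.DataFrame:
    """One row per scored indicator: m_j, Mj, sd, Vj, Kj(%), Cs, Ca, Cr.

    Indicators nobody scored are excluded with a warning; an indicator
    whose mean is zero gets ``Vj = NaN`` and a warning (possible when
    the scale starts at 0).
    """
    config = config or PanelConfig()
    scored = responses.data.dropna(subset=["score"])
    if scored.empty:
        raise DelphiError("response set contains no scores")
    grouped = scored.groupby("indicator_id", sort=True)["score"]
    out = grouped.agg(
        m_j="size",
        Mj="mean",
        sd=lambda s: s.std(ddof=config.ddof) if len(s) > 1 else 0.0,
        full_count=lambda s: int((s == config.full_score).sum()),
    ).reset_index()
    zero_mean = out["Mj"] == 0
    if zero_mean.any():
        warnings.warn(
            "Vj undefined (mean 0) for: "
            + ", ".join(out.loc[zero_mean, "indicator_id"]),
            stacklevel=2,
        )
    out["Vj"] = np.where(zero_mean, np.nan, out["sd"] / out["Mj"].replace(0, np.nan))
    out["Kj"] = out["full_count"] / out["m_j"]
    out["Kj_pct"] = 100.0 * out["Kj"]
    authority = authority_per_indicator(responses, matrix)
    out = out.merge(authority[["indicator_id", "Cs", "Ca", "Cr"]], on="indicator_id")
    return out[
        ["indicator_id", "m_j", "Mj", "sd", "Vj", "full_count", "Kj", "Kj_pct",
         "Cs", "Ca", "Cr"]
    ]
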