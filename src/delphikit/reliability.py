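"""Engagement and authority statistics for a Delphi panel.

Engagement ("positive coefficient") is the questionnaire recovery rate;
a rate above 70% is conventionally considered good.  Authority is
summarised per indicator by the familiarity coefficient Cs (mean of the
experts' familiarity self-ratings), the judgment coefficient Ca (mean of
the per-expert sums of judgment-basis impact coefficients) and the
authority coefficient Cr = (Ca + Cs) / 2; Cr >= 0.7 is read as
acceptable reliability.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .model import (
    FAMILIARITY_COEFFICIENTS,
    JUDGMENT_BASES,
    DEFAULT_JUDGMENT_MATRIX,
    DelphiError,
    JudgmentBasisMatrix,
    ResponseSet,
)


class ResponseRate(NamedTuple):
    percent: float
    good: bool


def response_rate(distributed: int, returned: int, threshold: float = 70.0) -> ResponseRate:
    """Recovery rate in percent, with the >= threshold quality flag."""
    if distributed < 1:
        raise DelphiError(f"distributed must be >= 1, got {distributed}")
    if not (0 <= returned <= distributed):
        raise DelphiError(f"returned {returned} outside [0, {distributed}]")
    pct = 100.0 * returned / distributed
    return ResponseRate(percent=pct, good=pct >= threshold)


def familiarity_coefficient(level: str | float) -> float:
    """Map a familiarity self-rating to its coefficient Cs.

    Accepts either the ordinal level name or a numeric coefficient
    already in {1, 0.8, 0.6, 0.4, 0.2, 0}.
    """
    if isinstance(level, str):
        try:
            return FAMILIARITY_COEFFICIENTS[level]
        except KeyError:
            raise DelphiError(f"unknown familiarity level {level!r}") from None
    value = float(level)
    if not any(np.isclose(value, c) for c in FAMILIARITY_COEFFICIENTS.values()):
        raise DelphiError(f"familiarity coefficient {value} not in the 6-level set")
    return value


def judgment_coefficient(
    bands: Mapping[str, str],
    matrix: JudgmentBasisMatrix = DEFAULT_JUDGMENT_MATRIX,
) -> float:
    """One expert's Ca for one indicator: sum of the per-basis impacts."""
    missing = set(JUDGMENT_BASES) - set(bands)
    if missing:
        raise DelphiError(f"judgment bands missing bases {sorted(missing)}")
    return sum(matrix.coefficient(bands[basis], basis) for basis in JUDGMENT_BASES)


def authority_per_indicator(
    responses: ResponseSet,
    matrix: JudgmentBasisMatrix = DEFAULT_JUDGMENT_MATRIX,
) -> pd.DataFrame:
    """Per-indicator Cs, Ca and Cr, averaged over responding experts.

    Experts who skipped an indicator (missing score) do not contribute
    to its authority statistics.  Indicators with zero respondents are
    excluded with a warning.
    """
    scored = responses.data.dropna(subset=["score"]).copy()
    dropped = set(responses.data["indicator_id"]) - set(scored["indicator_id"])
    if dropped:
        warnings.warn(
            f"indicators with no respondents excluded from authority: {sorted(dropped)}",
            stacklevel=2,
        )
    scored["Cs_i"] = scored["familiarity_level"].map(familiarity_coefficient)
    band_sums = np.zeros(len(scored))
    for basis in JUDGMENT_BASES:
        col = scored[f"jb_{basis}"]
        lookup = {b: matrix.coefficient(b, basis) for b in matrix.coefficients}
        band_sums = band_sums + col.map(lookup).to_numpy(float)
    scored["Ca_i"] = band_sums
    grouped = scored.groupby("indicator_id", sort=True).agg(
        Cs=("Cs_i", "mean"), Ca=("Ca_i", "mean"), m_j=("score", "size")
    )
    grouped["Cr"] = (grouped["Ca"] + grouped["Cs"]) / 2.0
    return grouped.reset_index()[["indicator_id", "m_j", "Cs", "Ca", "Cr"]]


def authority_band_counts(
    cr_values: Iterable[float],
    cutoffs: tuple[float, float] = (0.5, 0.75),
) -> tuple[int, int, int]:
    """Partition Cr values into (> high, [low, high], < low) counts.

    Comparisons are strict on both sides, so a value exactly at a cutoff
    lands in the middle band; the three counts always sum to the number
    of indicators.
    """
    lo, hi = cutoffs
    values = np.asarray(list(cr_values), dtype=float)
    n_hi = int((values > hi).sum())
    n_lo = int((values < lo).sum())
    return n_hi, len(values) - n_hi - n_lo, n_lo


def panel_authority(authority: pd.DataFrame) -> float:
    """Panel-level Cr: unweighted mean of per-indicator Cr (informational)."""
    return float(authority["Cr"].mean())
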