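"""Cross-expert coordination via Kendall's coefficient of concordance W.

W measures how consistently m experts rank n indicators.  With tied
scores receiving average ranks, the tie-corrected statistic is

    W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i)

where S is the sum of squared deviations of the per-indicator rank sums
from their mean and T_i = sum over tie groups of (t^3 - t) for expert i.
Significance uses the chi-square approximation chi2 = m (n - 1) W with
n - 1 degrees of freedom.  Conventionally W > 0.4 indicates good
coordination and W > 0.5 that the consultation can be concluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PanelConfig
from .model import DelphiError, ResponseSet


@dataclass(frozen=True)
class ConcordanceResult:
    W: float
    chi2: float
    df: int
    p_value: float
    n_experts: int
    n_items: int
    tie_correction_total: float
    coordinated: bool  # W above the "research coordination is better" gate
    complete: bool     # W above the "consulting work can be completed" gate

    def as_dict(self) -> dict:
        return {
            "W": self.W,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "n_experts": self.n_experts,
            "n_items": self.n_items,
            "tie_correction_total": self.tie_correction_total,
            "flags": {"coordinated": self.coordinated, "complete": self.complete},
        }


def rank_scores(scores) -> np.ndarray:
    """Rank one expert's scores across items, descending with average ties.

    The most important item gets rank 1; tied scores share the average
    of the ranks they span, so the rank sum is always n(n+1)/2.
    """
    values = np.asarray(scores, dtype=float)
    if values.size < 2:
        raise DelphiError("need at least 2 items to rank")
    return sps.rankdata(-values, method="average")


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    return float((counts**3 - counts).sum())


def kendall_w(
    matrix,
    *,
    w_coordinated: float = 0.4,
    w_complete: float = 0.5,
    permutation: bool = False,
    n_permutations: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> ConcordanceResult:
    """Tie-corrected Kendall's W for an m-experts x n-items score matrix.

    With ``permutation=True`` the p-value is estimated by independently
    permuting each expert's scores instead of the chi-square
    approximation (useful for very small panels).
    """
    scores = np.asarray(matrix, dtype=float)
    if scores.ndim != 2:
        raise DelphiError("score matrix must be 2-dimensional (experts x items)")
    m, n = scores.shape
    if m < 2:
        raise DelphiError(f"need at least 2 experts, got {m}")
    if n < 2:
        raise DelphiError(f"need at least 2 items, got {n}")
    if np.isnan(scores).any():
        raise DelphiError("score matrix must be complete (no missing values)")
    if n < 3:
        warnings.warn(
            "chi-square approximation for Kendall's W is unreliable for n < 3",
            stacklevel=2,
        )

    ranks = np.apply_along_axis(rank_scores, 1, scores)
    w = _w_from_ranks(ranks)
    tie_total = float(sum(_tie_term(row) for row in ranks))
    chi2 = m * (n - 1) * w
    df = n - 1
    if permutation:
        rng = rng or np.random.default_rng(0)
        count = 0
        for _ in range(n_permutations):
            perm = np.array([rng.permutation(row) for row in ranks])
            if _w_from_ranks(perm) >= w - 1e-15:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        p = float(sps.chi2.sf(chi2, df))
    return ConcordanceResult(
        W=float(w),
        chi2=float(chi2),
        df=df,
        p_value=p,
        n_experts=m,
        n_items=n,
        tie_correction_total=tie_total,
        coordinated=w > w_coordinated,
        complete=w > w_complete,
    )


def _w_from_ranks(ranks: np.ndarray) -> float:
    m, n = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_total = sum(_tie_term(row) for row in ranks)
    denom = m**2 * (n**3 - n) - m * tie_total
    if denom <= 0:
        # every expert tied every item: no information, define W = 0
        return 0.0
    return 12.0 * s / denom


def coordination_report(
    responses: ResponseSet,
    config: Optional[PanelConfig] = None,
    indicator_ids: Optional[list[str]] = None,
) -> ConcordanceResult:
    """Kendall's W over a round's active indicators.

    Experts with missing scores on any included indicator are dropped
    (with a warning) when the configuration requires a complete matrix.
    """
    config = config or PanelConfig()
    mat = responses.score_matrix(indicator_ids)
    if mat.shape[1] < 2:
        raise DelphiError(
            f"coordination needs at least 2 indicators, got {mat.shape[1]}"
        )
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        if config.require_complete_matrix:
            warnings.warn(
                f"dropping {int(incomplete.sum())} expert(s) with incomplete "
                "scores from the coordination matrix",
                stacklevel=2,
            )
            mat = mat[~incomplete]
        else:
            mat = mat.fillna(mat.mean())
    return kendall_w(
        mat.to_numpy(float),
        w_coordinated=config.w_coordinated,
        w_complete=config.w_complete,
        permutation=config.w_permutation_test,
    )
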