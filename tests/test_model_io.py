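"""Domain types, validation, and CSV round trips."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from delphikit import (
    IndicatorHierarchy,
    IndicatorNode,
    JudgmentBasisMatrix,
    PanelConfig,
    ValidationError,
    read_hierarchy,
    read_responses,
    read_stats_table,
    round_half_up,
    write_hierarchy,
    write_responses,
    write_stats_table,
)
from delphikit.datasets import load_round1_hierarchy
from delphikit.model import band_of_judgment_score

from conftest import make_responses


class TestHierarchy:
    def test_single_primary_node_counts(self):
        h = IndicatorHierarchy([IndicatorNode("p", "Primary", 1)])
        assert h.tier_counts() == (1, 0, 0)

    def test_tertiary_may_attach_directly_to_primary(self):
        # burn-sites pattern: no secondary tier in between
        h = IndicatorHierarchy(
            [
                IndicatorNode("sites", "Burn sites", 1),
                IndicatorNode("back", "Back", 3, parent_id="sites"),
            ]
        )
        assert h.tier_counts() == (1, 0, 1)
        assert [n.id for n in h.active_leaves()] == ["back"]

    @pytest.mark.parametrize(
        "nodes, message",
        [
            (
                [IndicatorNode("a", "A", 1), IndicatorNode("a", "A2", 1)],
                "duplicate",
            ),
            (
                [IndicatorNode("b", "B", 2, parent_id="ghost")],
                "does not exist",
            ),
            (
                [
                    IndicatorNode("p", "P", 1),
                    IndicatorNode("s", "S", 2, parent_id="p"),
                    IndicatorNode("s2", "S2", 2, parent_id="s"),
                ],
                "tier",
            ),
        ],
        ids=["duplicate-id", "orphan-parent", "tier-inversion"],
    )
    def test_invalid_hierarchies_rejected(self, nodes, message):
        with pytest.raises(ValidationError, match=message):
            IndicatorHierarchy(nodes)

    def test_node_level_invariants(self):
        with pytest.raises(ValidationError):
            IndicatorNode("x", "X", 4)
        with pytest.raises(ValidationError):
            IndicatorNode("x", "X", 2)  # non-primary without parent
        with pytest.raises(ValidationError):
            IndicatorNode("x", "X", 1, parent_id="y")

    def test_deleted_nodes_not_counted_active(self):
        h = IndicatorHierarchy(
            [
                IndicatorNode("p", "P", 1),
                IndicatorNode("t", "T", 3, parent_id="p", status="deleted"),
            ]
        )
        assert h.tier_counts() == (1, 0, 0)
        assert h.tier_counts(active_only=False) == (1, 0, 1)

    def test_packaged_hierarchy_counts(self):
        assert load_round1_hierarchy().tier_counts() == (8, 16, 54)


class TestJudgmentMatrix:
    def test_default_rows_sum_within_unit_interval(self):
        m = JudgmentBasisMatrix()
        sums = {band: sum(row) for band, row in m.coefficients.items()}
        assert sums == {"low": pytest.approx(0.6), "mid": pytest.approx(0.8),
                        "high": pytest.approx(1.0)}

    def test_rejects_out_of_range_coefficients(self):
        with pytest.raises(ValidationError):
            JudgmentBasisMatrix({"low": (1.2, 0, 0, 0),
                                 "mid": (0.4, 0.2, 0.1, 0.1),
                                 "high": (0.5, 0.3, 0.1, 0.1)})

    @pytest.mark.parametrize("score, band", [(0, "low"), (1, "low"), (2, "mid"),
                                             (3, "mid"), (4, "high"), (5, "high")])
    def test_score_banding(self, score, band):
        assert band_of_judgment_score(score) == band


class TestResponseValidation:
    def test_score_outside_scale_names_offender(self):
        with pytest.raises(ValidationError, match=r"12.*E1.*A|E1.*A.*12"):
            make_responses({"E1": {"A": 12}})

    def test_duplicate_response_rejected(self):
        r = make_responses({"E1": {"A": 5}})
        dup = pd.concat([r.data, r.data])
        with pytest.raises(ValidationError, match="duplicate"):
            type(r)(round=1, distributed=1, returned=1, data=dup)

    def test_returned_cannot_exceed_distributed(self):
        with pytest.raises(ValidationError):
            make_responses({"E1": {"A": 5}, "E2": {"A": 6}}, distributed=1)

    def test_missing_scores_allowed(self, tiny_responses):
        assert len(tiny_responses.scores_for("B")) == 2
        assert len(tiny_responses.scores_for("A")) == 3


class TestRoundTrips:
    def test_responses_round_trip(self, tiny_responses, tmp_path):
        path = tmp_path / "responses.csv"
        write_responses(tiny_responses, path)
        back = read_responses(path, distributed=tiny_responses.distributed)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True),
            tiny_responses.data.reset_index(drop=True),
            check_dtype=False,
        )
        assert (back.distributed, back.returned) == (3, 3)

    def test_hierarchy_round_trip(self, tmp_path):
        h = load_round1_hierarchy()
        path = tmp_path / "hierarchy.csv"
        write_hierarchy(h, path)
        back = read_hierarchy(path)
        assert back.tier_counts() == h.tier_counts()
        assert {n.id for n in back.nodes} == {n.id for n in h.nodes}

    def test_stats_table_round_trip_at_configured_rounding(self, tmp_path):
        config = PanelConfig()
        stats = pd.DataFrame(
            {
                "indicator_id": ["a", "b"],
                "m_j": [15, 15],
                "Mj": [7.8012, 5.00449],
                "sd": [1.7971, 2.399],
                "Vj": [0.23037, 0.47945],
                "Kj_pct": [38.4615, 0.0],
                "Cs": [0.79003, 0.45],
                "Ca": [0.8732, 0.78666],
                "Cr": [0.83162, 0.61833],
            }
        )
        path = tmp_path / "stats.csv"
        write_stats_table(stats, path, config)
        back = read_stats_table(path)
        assert back["Vj"].tolist() == [0.23, 0.48]
        assert back["Cr"].tolist() == [0.832, 0.618]
        # writing the read-back table again is the identity
        write_stats_table(back, tmp_path / "stats2.csv", config)
        assert (tmp_path / "stats.csv").read_text() == (tmp_path / "stats2.csv").read_text()

    def test_empty_stats_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_stats_table(
            pd.DataFrame(columns=["indicator_id", "Mj", "sd", "Vj"]), path
        )
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("indicator_id")

    def test_unknown_indicator_in_responses_rejected(self, tmp_path, tiny_responses):
        h = IndicatorHierarchy([IndicatorNode("A", "A", 1)])  # no "B"
        path = tmp_path / "responses.csv"
        write_responses(tiny_responses, path)
        with pytest.raises(ValidationError, match="'B'"):
            read_responses(path, hierarchy=h)


@pytest.mark.parametrize(
    "value, digits, expected",
    [(0.9235, 3, 0.924), (0.4715, 3, 0.472), (0.175, 2, 0.18), (2.5, 0, 3.0),
     (-0.125, 2, -0.13)],
)
def test_round_half_up_breaks_ties_away_from_zero(value, digits, expected):
    assert round_half_up(value, digits) == expected
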