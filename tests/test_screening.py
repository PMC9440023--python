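"""Boundary-value screening: thresholds, dispositions, review resolution."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from delphikit import (
    DelphiError,
    PanelConfig,
    ValidationError,
    apply_review,
    boundary_values,
    screen,
)


def stats_frame(rows: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"indicator_id": k, "Mj": v[0], "Kj": v[1], "Vj": v[2]} for k, v in rows.items()]
    )


def random_stats(rng, n):
    return pd.DataFrame(
        {
            "indicator_id": [f"I{i}" for i in range(n)],
            "Mj": rng.uniform(0.5, 10, n),
            "Kj": rng.uniform(0, 1, n),
            "Vj": rng.uniform(0, 1.2, n),
        }
    )


class TestBoundaryValues:
    def test_hand_computed_mean_minus_sd(self):
        stats = stats_frame({"a": (9, 0.9, 0.1), "b": (6, 0.6, 0.2), "c": (3, 0.3, 0.6)})
        b = boundary_values(stats).for_group("global")
        assert b["Mj"].boundary == pytest.approx(6 - 3)  # mean 6, sd 3 (n-1)
        decisions = screen(stats, boundary_values(stats)).set_index("indicator_id")
        # only the indicator sitting exactly at the boundary fails Mj
        assert decisions["Mj_fail"].tolist() == [False, False, True]

    def test_vj_boundary_is_mean_plus_sd(self):
        # right-skewed Mj/Kj so those boundaries pass everywhere; only the
        # high-variation indicator d trips the Vj = mean + sd rule
        stats = stats_frame(
            {"a": (10, 1.0, 0.10), "b": (8, 0.8, 0.20),
             "c": (8, 0.8, 0.15), "d": (8, 0.8, 0.60)}
        )
        b = boundary_values(stats).for_group("global")
        vals = np.array([0.10, 0.20, 0.15, 0.60])
        assert b["Vj"].boundary == pytest.approx(vals.mean() + vals.std(ddof=1))
        decisions = screen(stats, boundary_values(stats)).set_index("indicator_id")
        assert decisions["Vj_fail"].tolist() == [False, False, False, True]
        assert not decisions[["Mj_fail", "Kj_fail"]].any().any()
        assert decisions.loc["d", "disposition"] == "review"  # 1 failure, never auto-delete

    def test_degenerate_identical_stats_fail_strict_comparison(self):
        # sd = 0 puts every value exactly at its boundary; strict rules
        # count at-boundary as failing, so all three criteria fail everywhere
        stats = stats_frame({k: (7, 0.5, 0.3) for k in "abc"})
        decisions = screen(stats, boundary_values(stats))
        assert (decisions["n_failed"] == 3).all()
        assert (decisions["disposition"] == "delete").all()

    def test_group_of_one_is_error(self):
        with pytest.raises(DelphiError, match="at least 2"):
            boundary_values(stats_frame({"a": (5, 0.5, 0.2)}))

    def test_population_sd_follows_config(self):
        stats = stats_frame({"a": (9, 0.9, 0.1), "b": (3, 0.3, 0.6)})
        b_sample = boundary_values(stats, PanelConfig()).for_group("global")
        b_pop = boundary_values(stats, PanelConfig(sd_denominator="n")).for_group("global")
        assert b_sample["Mj"].sd > b_pop["Mj"].sd


class TestScreen:
    def test_strictly_best_indicator_retained(self, rng):
        stats = random_stats(rng, 12)
        best = stats.copy()
        best.loc[0, ["Mj", "Kj", "Vj"]] = [10.0, 1.0, 0.0]
        decisions = screen(best, boundary_values(best)).set_index("indicator_id")
        assert decisions.loc["I0", "disposition"] == "retain"

    def test_constructed_all_fail_indicator_deleted_alone(self):
        stats = stats_frame(
            {
                "good1": (8.0, 0.8, 0.15),
                "good2": (8.5, 0.7, 0.12),
                "good3": (7.8, 0.75, 0.18),
                "good4": (8.2, 0.85, 0.14),
                "bad": (1.0, 0.0, 1.5),  # >2 sd worse on every criterion
            }
        )
        decisions = screen(stats, boundary_values(stats)).set_index("indicator_id")
        assert decisions.loc["bad", "disposition"] == "delete"
        assert (decisions.drop("bad")["disposition"] != "delete").all()

    def test_partition_and_dominance_on_random_tables(self, rng):
        for _ in range(200):
            stats = random_stats(rng, int(rng.integers(3, 30)))
            decisions = screen(stats, boundary_values(stats))
            assert set(decisions["disposition"]) <= {"retain", "review", "delete"}
            assert decisions["disposition"].notna().all()
            assert len(decisions) == len(stats)
            assert (
                decisions["n_failed"]
                == decisions[["Mj_fail", "Kj_fail", "Vj_fail"]].sum(axis=1)
            ).all()
            # dominance: indicator at least as good on all criteria fails
            # a subset of the weaker one's criteria
            merged = stats.merge(decisions, on="indicator_id")
            a = merged.sample(n=1, random_state=int(rng.integers(2**31))).iloc[0]
            for _, b in merged.iterrows():
                if a["Mj"] >= b["Mj"] and a["Kj"] >= b["Kj"] and a["Vj"] <= b["Vj"]:
                    for crit in ("Mj_fail", "Kj_fail", "Vj_fail"):
                        assert not (a[crit] and not b[crit])

    def test_scale_equivariance(self, rng):
        stats = random_stats(rng, 15)
        doubled = stats.copy()
        doubled["Mj"] *= 2.0  # Vj is scale-free, Kj untouched
        d1 = screen(stats, boundary_values(stats))
        d2 = screen(doubled, boundary_values(doubled))
        pd.testing.assert_frame_equal(d1, d2)
        b1 = boundary_values(stats).for_group("global")["Mj"].boundary
        b2 = boundary_values(doubled).for_group("global")["Mj"].boundary
        assert b2 == pytest.approx(2.0 * b1)


class TestApplyReview:
    def edits(self, rows):
        return pd.DataFrame(
            rows, columns=["round", "action", "indicator_id", "label", "tier",
                           "parent_id", "note"]
        )

    def decisions(self):
        stats = stats_frame(
            {
                "keepme": (9.0, 0.9, 0.1),
                "fine": (8.5, 0.8, 0.12),
                "alsofine": (8.8, 0.82, 0.11),
                "borderline": (5.0, 0.05, 0.5),
                "hopeless": (0.5, 0.0, 2.0),
            }
        )
        return screen(stats, boundary_values(stats))

    def test_review_items_need_explicit_resolution(self):
        decisions = self.decisions()
        assert (decisions.set_index("indicator_id").loc["borderline", "disposition"]
                == "review")
        with pytest.raises(DelphiError, match="borderline"):
            apply_review(decisions, self.edits([]))

    def test_resolved_review_and_auto_delete(self):
        decisions = self.decisions()
        edits = self.edits([[1, "delete", "borderline", "Borderline", 3, "", "weak support"]])
        final = apply_review(decisions, edits).set_index("indicator_id")
        assert final.loc["borderline", "final_action"] == "deleted"
        assert final.loc["hopeless", "final_action"] == "deleted"
        assert final.loc["keepme", "final_action"] == "kept"

    def test_empty_log_with_no_review_items_is_identity(self):
        stats = stats_frame({"a": (10, 1.0, 0.05), "b": (8, 0.8, 0.2),
                             "c": (8, 0.8, 0.2), "d": (8, 0.8, 0.2)})
        decisions = screen(stats, boundary_values(stats))
        assert (decisions["disposition"] == "retain").all()
        final = apply_review(decisions, self.edits([]))
        assert (final["final_action"] == "kept").all()
        pd.testing.assert_frame_equal(
            final.drop(columns=["final_action", "rationale"]),
            decisions.drop(columns=["final_action", "rationale"]),
        )

    def test_deleting_retained_indicator_flags_override(self):
        decisions = self.decisions()
        edits = self.edits(
            [[1, "delete", "keepme", "Keep me", 3, "", "redundant with fine"],
             [1, "keep", "borderline", "Borderline", 3, "", "discussed, kept"]]
        )
        final = apply_review(decisions, edits).set_index("indicator_id")
        assert final.loc["keepme", "final_action"] == "deleted"
        assert "expert-override" in final.loc["keepme", "rationale"]
        assert final.loc["borderline", "final_action"] == "kept"

    def test_unknown_indicator_in_edits_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            apply_review(self.decisions(),
                         self.edits([[1, "delete", "ghost", "?", 3, "", ""]]))
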