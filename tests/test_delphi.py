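"""Round engine: carryover, exclusion, feedback reports, roster summaries."""

import numpy as np
import pandas as pd
import pytest

from delphiscore import (
    ConsensusRule,
    DelphiConfig,
    PanelModel,
    PanelRoster,
    RatingMatrix,
    RatingScale,
    feedback_report,
    roster_summary,
    run_delphi,
    run_round,
    simulate_panel,
)
from delphiscore.consensus import summaries_frame
from delphiscore.delphi import read_roster_csv, report_frame

SCALE = RatingScale(1, 10)


def matrix_from(round_id: int, ratings_by_item: dict[str, list[int]]) -> RatingMatrix:
    records = [
        {"item_id": item, "rater_id": f"r{i}", "rating": r}
        for item, ratings in ratings_by_item.items()
        for i, r in enumerate(ratings)
    ]
    return RatingMatrix(
        round_id=round_id, scale=SCALE, frame=pd.DataFrame(records)
    )


# panel-consistent reconstructions of the published two-round summaries:
# round 1 tubes scatters (median 7, P25 5, P75 10), round 2 converges
# (median 7, P25 7, P75 8.5) with 16 of 19 at or above the cutoff
TUBES_R1 = [1, 2, 3, 3, 3, 7, 7, 7, 7, 7, 8, 9, 10, 10, 10, 10, 10, 10, 10]
TUBES_R2 = [5, 6, 6] + [7] * 7 + [8] * 4 + [9, 10, 10, 10, 10]
HYGIENE_R2 = [8] * 19  # unanimous: 100% agreement
PARENTERAL_R1 = [10] * 13 + [9, 9, 8, 6, 5, 3]  # 16/19 >= 7 -> consensus


class TestRunRound:
    def test_consensus_items_settle_in_round_one(self):
        m1 = matrix_from(1, {"parenteral_access": PARENTERAL_R1, "tubes": TUBES_R1})
        res = run_round(m1)
        assert res.consensus_items == {"parenteral_access"}
        assert res.carryover_items == {"tubes"}
        assert not res.excluded_items
        s = res.summaries["parenteral_access"]
        assert (s.n_agree, str(s.pct_agree)) == (16, "84.2")

    def test_sets_are_disjoint_and_cover_the_round(self):
        m1 = matrix_from(1, {"a": [10] * 19, "b": [1] * 19, "c": TUBES_R1})
        res = run_round(m1)
        sets = [res.consensus_items, res.carryover_items, res.excluded_items]
        assert set().union(*sets) == {"a", "b", "c"}
        assert sum(len(s) for s in sets) == 3

    def test_settled_item_rerated_is_skipped_with_warning(self):
        m1 = matrix_from(1, {"a": [10] * 19})
        r1 = run_round(m1)
        m2 = matrix_from(2, {"a": [10] * 19, "b": TUBES_R2})
        with pytest.warns(UserWarning, match="'a'"):
            r2 = run_round(m2, history=[r1])
        assert "a" not in r2.summaries
        assert r2.consensus_items == {"b"}

    def test_zero_agreement_single_item_carries_over(self):
        res = run_round(matrix_from(1, {"solo": [1] * 5}))
        assert res.carryover_items == {"solo"}
        assert res.summaries["solo"].n_agree == 0

    def test_unknown_rater_warns(self):
        roster = [PanelRoster("r0", "physician")]
        with pytest.warns(UserWarning, match="not in roster"):
            run_round(matrix_from(1, {"a": [8, 9]}), roster=roster)

    def test_low_agreement_policy_rerates_wide_iqr_items(self):
        # 16/19 >= 7 passes the rule, but P25=7, P75=10 spans 3 points
        wide = [7] * 6 + [8] * 4 + [10] * 6 + [5, 5, 5]
        cfg = DelphiConfig(
            carryover_policy="low_agreement", low_agreement_iqr_width=3.0
        )
        res = run_round(matrix_from(1, {"a": wide}), cfg)
        assert res.carryover_items == {"a"}
        cfg_default = DelphiConfig()
        assert run_round(matrix_from(1, {"a": wide}), cfg_default).consensus_items == {"a"}


class TestExclusion:
    def test_stagnant_item_excluded_at_max_rounds(self):
        cfg = DelphiConfig(max_rounds=2)
        stuck = [5] * 10 + [8] * 9  # 9/19 agree, median 5
        r1 = run_round(matrix_from(1, {"a": stuck}), cfg)
        r2 = run_round(matrix_from(2, {"a": stuck}), cfg, history=[r1])
        assert r2.excluded_items == {"a"}

    def test_moving_item_stays_open_at_max_rounds(self):
        cfg = DelphiConfig(max_rounds=2)
        r1 = run_round(matrix_from(1, {"a": [5] * 10 + [8] * 9}), cfg)
        improved = [5] * 6 + [8] * 13  # agreement jumped 9/19 -> 13/19
        r2 = run_round(matrix_from(2, {"a": improved}), cfg, history=[r1])
        assert r2.carryover_items == {"a"}
        assert not r2.excluded_items

    def test_before_max_rounds_nothing_is_excluded(self):
        cfg = DelphiConfig(max_rounds=4)
        stuck = [5] * 10 + [8] * 9
        r1 = run_round(matrix_from(1, {"a": stuck}), cfg)
        r2 = run_round(matrix_from(2, {"a": stuck}), cfg, history=[r1])
        assert r2.excluded_items == set()


class TestMultiRound:
    def test_settled_items_never_reappear_in_carryover(self):
        rounds = {
            1: matrix_from(1, {"a": [10] * 19, "b": TUBES_R1, "c": [4] * 19}),
            2: matrix_from(2, {"b": TUBES_R2, "c": [4] * 19}),
        }
        results = run_delphi(rounds)
        settled: set[str] = set()
        for res in results:
            assert not (settled & res.carryover_items)
            settled |= res.consensus_items
        assert settled == {"a", "b"}

    def test_fully_agreeing_synthetic_panel_settles_in_round_one(self):
        matrix = simulate_panel(PanelModel(agreement=1.0, seed=7))
        res = run_round(matrix)
        assert res.consensus_items == set(matrix.items)
        assert all(
            str(s.pct_agree) == "100.0" for s in res.summaries.values()
        )


class TestReports:
    def test_report_rows_mirror_published_round_summaries(self):
        r1 = run_round(matrix_from(1, {"tubes": TUBES_R1}))
        assert "| tubes | 7 (5–10) | 14 (73.7%) | carryover |" in feedback_report(r1)
        r2 = run_round(
            matrix_from(2, {"tubes": TUBES_R2, "hygiene": HYGIENE_R2}),
            history=[r1],
        )
        report = feedback_report(r2)
        assert "| tubes | 7 (7–8.5) | 16 (84.2%) | consensus |" in report
        assert "| hygiene | 8 (8–8) | 19 (100%) | consensus |" in report

    def test_empty_round_gives_header_only_report(self):
        from delphiscore.delphi import RoundResult

        empty = RoundResult(1, {}, frozenset(), frozenset(), frozenset())
        report = feedback_report(empty)
        assert "| Item |" in report
        assert report.count("\n") == 4

    def test_report_frame_matches_summaries_frame_values(self):
        res = run_round(matrix_from(1, {"a": TUBES_R1, "b": [9] * 19}))
        rframe = report_frame(res)
        sframe = summaries_frame(dict(res.summaries))
        pd.testing.assert_frame_equal(rframe.drop(columns="status"), sframe)

    def test_reports_never_expose_individual_raters(self):
        res = run_round(matrix_from(1, {"a": TUBES_R1}))
        assert "r0" not in feedback_report(res)


class TestRoster:
    def make_roster(self):
        members = []
        for i in range(13):
            members.append(PanelRoster(f"r{i:02d}", "physician", "specialist", ">10 years"))
        for i in range(13, 19):
            members.append(PanelRoster(f"r{i:02d}", "nurse", "postgraduate", ">10 years"))
        # one panellist with the shorter experience band
        members[0] = PanelRoster("r00", "physician", "specialist", "5-10 years")
        return members

    def test_profession_split(self):
        table = roster_summary(self.make_roster()).set_index(["field", "level"])
        assert table.loc[("profession", "physician"), "count"] == 13
        assert table.loc[("profession", "physician"), "pct"] == 68.4
        assert table.loc[("profession", "nurse"), "pct"] == 31.6

    def test_experience_band_percentages_are_computed_not_copied(self):
        # 18 of 19 -> 94.7 (the arithmetic value, whatever a source table prints)
        table = roster_summary(self.make_roster()).set_index(["field", "level"])
        assert table.loc[("experience_band", ">10 years"), "pct"] == 94.7
        assert table.loc[("experience_band", "5-10 years"), "pct"] == 5.3

    def test_empty_roster(self):
        assert roster_summary([]).empty

    def test_roster_csv(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text(
            "rater_id,profession,training,experience_band\n"
            "r1,physician,specialist,>10 years\n"
            "r2,nurse,,\n"
        )
        roster = read_roster_csv(path)
        assert [m.profession for m in roster] == ["physician", "nurse"]
        table = roster_summary(roster).set_index(["field", "level"])
        assert table.loc[("profession", "nurse"), "pct"] == 50.0
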