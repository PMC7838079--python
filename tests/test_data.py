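import numpy as np
import pandas as pd
import pytest

from moralcan.data import (
    Battery,
    BatteryValidationError,
    CellCounts,
    SchemaError,
    UnknownParticipantError,
    read_long_table,
    write_long_table,
    write_wide_counts,
)

from conftest import battery_from_counts


class TestReadLongTable:
    def test_reads_two_participant_fixture(self, tmp_path, two_participant_battery):
        path = tmp_path / "battery.csv"
        write_long_table(two_participant_battery, path)
        battery = read_long_table(path)
        assert battery.n_participants == 2
        assert battery.participants == ["s01", "s02"]
        counts = battery.df.groupby(["participant", "cell"]).size()
        assert set(counts) == {6}

    def test_round_trip_preserves_battery(self, tmp_path, two_participant_battery):
        path = tmp_path / "battery.csv"
        write_long_table(two_participant_battery, path,
                         header_comments=["provenance line"])
        assert read_long_table(path) == two_participant_battery

    def test_string_coding_equivalent_to_numeric(self, tmp_path,
                                                 two_participant_battery):
        df = two_participant_battery.df.copy()
        df["response"] = df["response"].map({1: "yes", 0: "no"})
        path = tmp_path / "coded.csv"
        df.to_csv(path, index=False)
        battery = read_long_table(path, response_values={"yes": 1, "no": 0})
        assert battery == two_participant_battery

    def test_column_map_resolves_renamed_columns(self, tmp_path,
                                                 two_participant_battery):
        df = two_participant_battery.df.rename(
            columns={"participant": "subj", "response": "resp"}
        )
        path = tmp_path / "renamed.csv"
        df.to_csv(path, index=False)
        battery = read_long_table(
            path, column_map={"participant": "subj", "response": "resp"}
        )
        assert battery == two_participant_battery

    def test_missing_column_error_names_it(self, tmp_path):
        path = tmp_path / "broken.csv"
        pd.DataFrame(
            {"participant": ["a"], "dilemma": ["d1"], "response": [1],
             "consequence": ["greater"]}
        ).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="norm"):
            read_long_table(path)

    def test_unknown_response_code_rejected(self, tmp_path,
                                            two_participant_battery):
        df = two_participant_battery.df.copy()
        df.loc[0, "response"] = 7
        path = tmp_path / "badcode.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="response"):
            read_long_table(path)

    def test_participant_missing_cell_named_in_error(self, tmp_path):
        battery = battery_from_counts({"s01": (1, 2, 3, 4), "s07": (1, 2, 3, 4)})
        df = battery.df
        df = df[~((df.participant == "s07") & (df.cell == 4))]
        path = tmp_path / "incomplete.csv"
        df.drop(columns="cell").to_csv(path, index=False)
        with pytest.raises(BatteryValidationError, match="s07"):
            read_long_table(path)
        kept = read_long_table(path, allow_incomplete=True)
        assert kept.participants == ["s01"]


class TestCellProbabilities:
    @pytest.mark.parametrize(
        "actions, expected",
        [
            ((6, 0, 6, 0), (1.0, 0.0, 1.0, 0.0)),
            ((3, 3, 3, 3), (0.5, 0.5, 0.5, 0.5)),
            ((4, 1, 5, 3), (4 / 6, 1 / 6, 5 / 6, 3 / 6)),
        ],
    )
    def test_empirical_proportions(self, actions, expected):
        battery = battery_from_counts({"p": actions})
        np.testing.assert_allclose(
            battery.cell_probabilities("p").as_array(), expected, atol=1e-12
        )

    def test_unknown_participant(self, two_participant_battery):
        with pytest.raises(UnknownParticipantError):
            two_participant_battery.cell_probabilities("nobody")

    def test_probability_times_trials_is_integral(self, rng):
        counts = {f"s{k}": tuple(rng.integers(0, 7, 4)) for k in range(5)}
        battery = battery_from_counts(counts)
        for pid in battery.participants:
            p = battery.cell_probabilities(pid).as_array()
            np.testing.assert_allclose(p * 6, np.round(p * 6), atol=1e-9)


class TestAggregateCounts:
    def test_two_participant_sum(self, two_participant_battery):
        counts = two_participant_battery.aggregate_counts()
        assert counts.actions == (6, 0, 12, 6)
        assert counts.totals == (12, 12, 12, 12)

    def test_single_participant_identity(self):
        battery = battery_from_counts({"p": (4, 1, 5, 3)})
        counts = battery.aggregate_counts()
        assert counts.actions == (4, 1, 5, 3)
        assert counts.totals == (6, 6, 6, 6)

    def test_absent_group_errors(self, two_participant_battery):
        battery = battery_from_counts(
            {"a": (1, 1, 1, 1)}, group={"a": "g1"}
        )
        with pytest.raises(BatteryValidationError):
            battery.aggregate_counts(group="missing")

    def test_group_aggregation_conserves_total(self, rng):
        counts = {f"s{k}": tuple(rng.integers(0, 7, 4)) for k in range(8)}
        groups = {pid: ("g1" if int(pid[1:]) % 2 else "g2") for pid in counts}
        battery = battery_from_counts(counts, group=groups)
        total = battery.aggregate_counts()
        by_group = battery.counts_by_group()
        summed = by_group["g1"] + by_group["g2"]
        assert summed == total


class TestCellCounts:
    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            CellCounts((7, 0, 0, 0), (6, 6, 6, 6))
        with pytest.raises(ValueError):
            CellCounts((0, 0, 0, 0), (6, 0, 6, 6))

    def test_proportions(self):
        c = CellCounts((3, 0, 6, 2), (6, 6, 6, 6))
        np.testing.assert_allclose(
            c.proportions.as_array(), [0.5, 0.0, 1.0, 1 / 3]
        )


def test_wide_counts_export(tmp_path, two_participant_battery):
    path = tmp_path / "wide.csv"
    write_wide_counts(two_participant_battery, path)
    wide = pd.read_csv(path)
    assert list(wide.participant) == ["s01", "s02"]
    assert wide.loc[0, "actions_1"] == 6 and wide.loc[0, "totals_1"] == 6
    assert wide.loc[1, "actions_4"] == 6
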