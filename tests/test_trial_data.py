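import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtcnma import (
    ArmRecord,
    Outcome,
    ParseError,
    Treatment,
    TrialRecord,
    TrialSet,
    ValidationError,
    apply_treatment_overrides,
    build_network,
    center_covariates,
    check_connectivity,
    classify_mph,
    default_adhd_config,
    filter_trials,
    read_arm_table,
    simulate_trials,
    write_arm_table,
)
from conftest import make_trialset


class TestClassifyMph:
    @pytest.mark.parametrize(
        "doses,expected",
        [(3, Treatment.MPH_IR), (4, Treatment.MPH_IR), (2, Treatment.MPH_ER), (1, Treatment.MPH_ER)],
    )
    def test_dosing_frequency_rule(self, doses, expected):
        assert classify_mph(doses) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            classify_mph(0)


class TestValidation:
    def test_count_exceeding_n_rejected(self):
        with pytest.raises(ValidationError, match="responders"):
            ArmRecord(trial_id="T", treatment=Treatment.GXR, n=10, responders=12)

    def test_se_must_accompany_mean(self):
        with pytest.raises(ValidationError):
            ArmRecord(trial_id="T", treatment=Treatment.GXR, n=10, mean_change=-5.0)

    def test_arm_without_outcome_rejected(self):
        with pytest.raises(ValidationError, match="no outcome"):
            ArmRecord(trial_id="T", treatment=Treatment.GXR, n=10)

    def test_duration_bounds(self):
        with pytest.raises(ValidationError):
            TrialRecord(trial_id="T", duration_weeks=17.0)

    def test_single_arm_trial_rejected(self):
        with pytest.raises(ValidationError, match=">=2 arms"):
            TrialSet(
                trials={"T": TrialRecord(trial_id="T", duration_weeks=8.0)},
                arms=[ArmRecord(trial_id="T", treatment=Treatment.GXR, n=10, responders=3)],
            )


class TestIO:
    def test_two_arm_file_roundtrip(self, tmp_path, binary_pair_ts):
        write_arm_table(binary_pair_ts, tmp_path / "arms.csv", tmp_path / "trials.csv")
        ts = read_arm_table(tmp_path / "arms.csv", tmp_path / "trials.csv")
        assert len(ts.trials) == 1 and len(ts.arms) == 2
        assert ts.arms == binary_pair_ts.arms

    @pytest.mark.parametrize("outcome", list(Outcome))
    def test_synthetic_roundtrip_identity(self, tmp_path, outcome):
        ts, _ = simulate_trials(default_adhd_config(outcome), outcome, seed=5)
        write_arm_table(ts, tmp_path / "a.csv", tmp_path / "t.csv")
        back = read_arm_table(tmp_path / "a.csv", tmp_path / "t.csv")
        assert back.arms == sorted(ts.arms, key=lambda a: (a.trial_id, a.treatment.order))
        assert back.trials == ts.trials

    def test_joined_wide_file(self, tmp_path, binary_pair_ts):
        write_arm_table(binary_pair_ts, tmp_path / "wide.csv")
        ts = read_arm_table(tmp_path / "wide.csv")
        assert ts.trials == binary_pair_ts.trials
        assert ts.arms == binary_pair_ts.arms

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "trial_id,treatment,n,responders,duration_weeks\nT1,PLACEBO,abc,3,8\nT1,GXR,50,9,8\n"
        )
        with pytest.raises(ParseError, match="row 2.*'n'"):
            read_arm_table(tmp_path / "bad.csv")

    def test_count_over_n_in_file(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "trial_id,treatment,n,responders,duration_weeks\nT1,PLACEBO,10,12,8\nT1,GXR,50,9,8\n"
        )
        with pytest.raises(ValidationError):
            read_arm_table(tmp_path / "bad.csv")

    def test_raw_mph_requires_dosing(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "trial_id,treatment,n,responders,duration_weeks\nT1,PLACEBO,50,12,8\nT1,MPH,50,20,8\n"
        )
        with pytest.raises(ValidationError, match="doses_per_day"):
            read_arm_table(tmp_path / "bad.csv")

    def test_raw_mph_resolved_by_dosing(self, tmp_path):
        (tmp_path / "ok.csv").write_text(
            "trial_id,treatment,n,responders,doses_per_day,duration_weeks\n"
            "T1,PLACEBO,50,12,,8\nT1,MPH,50,20,3,8\n"
        )
        ts = read_arm_table(tmp_path / "ok.csv")
        assert ts.arms[1].treatment is Treatment.MPH_IR


class TestFilter:
    def _ts(self, durations, covs=None):
        rows = []
        for tid in durations:
            rows += [
                (tid, Treatment.PLACEBO, 50, {"responders": 12}),
                (tid, Treatment.GXR, 50, {"responders": 25}),
            ]
        return make_trialset(rows, durations=durations, covs=covs)

    def test_short_term_exclusion_at_three_weeks(self):
        ts = self._ts({"A": 3.0, "B": 4.0})
        kept = filter_trials(ts, Outcome.CGI_I, exclude_short_term=True)
        assert list(kept.trials) == ["B"]
        kept = filter_trials(ts, Outcome.CGI_I, exclude_short_term=False)
        assert list(kept.trials) == ["A", "B"]

    def test_missing_covariate_exclusion(self):
        ts = self._ts(
            {"A": 8.0, "B": 8.0},
            covs={"A": {"mean_age": None, "pct_female": 20.0, "baseline_adhdrs": None}},
        )
        kept = filter_trials(ts, Outcome.CGI_I, required_covariates=("mean_age", "pct_female"))
        assert list(kept.trials) == ["B"]

    def test_trials_enter_only_reported_outcomes(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"responders": 12}),
                ("A", Treatment.GXR, 50, {"responders": 25}),
                ("B", Treatment.PLACEBO, 50, {"dropouts_all": 12}),
                ("B", Treatment.LDX, 50, {"dropouts_all": 5}),
            ]
        )
        assert list(filter_trials(ts, Outcome.CGI_I).trials) == ["A"]
        assert list(filter_trials(ts, Outcome.DISC_ALL).trials) == ["B"]

    def test_dose_arms_pooled_inverse_variance(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"mean_change": -8.0, "se_change": 1.0}),
                ("A", Treatment.GXR, 50, {"mean_change": -16.0, "se_change": 1.0}),
                ("A", Treatment.GXR, 50, {"mean_change": -18.0, "se_change": 1.0}),
            ]
        )
        kept = filter_trials(ts, Outcome.ADHDRS_CHANGE)
        gxr = [a for a in kept.arms if a.treatment is Treatment.GXR]
        assert len(gxr) == 1
        assert gxr[0].n == 100
        assert gxr[0].mean_change == pytest.approx(-17.0)
        assert gxr[0].se_change == pytest.approx(1.0 / math.sqrt(2.0))


class TestNetwork:
    def test_three_arm_trial_edge_count(self, three_arm_ts):
        net = build_network(three_arm_ts, Outcome.ADHDRS_CHANGE)
        assert len(net.nodes) == 3
        assert sum(1 for *_, tid in net.edges if tid == "H1") == 3

    def test_edge_count_is_choose_two_per_trial(self):
        for outcome in Outcome:
            ts, _ = simulate_trials(default_adhd_config(outcome), outcome, seed=3)
            ts = filter_trials(ts, outcome, exclude_short_term=False)
            net = build_network(ts, outcome)
            expected = sum(
                math.comb(len(ts.arms_of(tid)), 2) for tid in ts.trial_ids
            )
            assert len(net.edges) == expected

    def test_default_adhd_nodes_per_outcome(self):
        for outcome, has_mph_ir in [
            (Outcome.ADHDRS_CHANGE, False),
            (Outcome.CGI_I, True),
            (Outcome.DISC_ALL, True),
            (Outcome.DISC_AE, True),
        ]:
            ts, _ = simulate_trials(default_adhd_config(outcome), outcome, seed=1)
            ts = filter_trials(ts, outcome, exclude_short_term=False)
            net = build_network(ts, outcome)
            assert (Treatment.MPH_IR in net.nodes) == has_mph_ir
            assert net.nodes[0] is Treatment.PLACEBO

    def test_connectivity_star(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"responders": 10}),
                ("A", Treatment.GXR, 50, {"responders": 20}),
                ("B", Treatment.PLACEBO, 50, {"responders": 10}),
                ("B", Treatment.ATX, 50, {"responders": 20}),
            ]
        )
        rep = check_connectivity(
            build_network(ts, Outcome.CGI_I), anchors=[Treatment.GXR, Treatment.ATX]
        )
        assert rep.connected

    def test_disconnected_components_reported(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"responders": 10}),
                ("A", Treatment.GXR, 50, {"responders": 20}),
                ("B", Treatment.LDX, 50, {"responders": 10}),
                ("B", Treatment.MPH_ER, 50, {"responders": 20}),
            ]
        )
        rep = check_connectivity(
            build_network(ts, Outcome.CGI_I), anchors=[Treatment.GXR, Treatment.ATX]
        )
        assert not rep.connected
        assert len(rep.components) == 2
        assert rep.missing_anchors == (Treatment.ATX,)

    def test_connectivity_invariant_to_trial_relabeling(self, three_arm_ts):
        net = build_network(three_arm_ts, Outcome.ADHDRS_CHANGE)
        relabeled = make_trialset(
            [
                ("Z9", a.treatment, a.n, {"mean_change": a.mean_change, "se_change": a.se_change})
                for a in three_arm_ts.arms_of("H1")
            ]
            + [
                ("A0", a.treatment, a.n, {"mean_change": a.mean_change, "se_change": a.se_change})
                for a in three_arm_ts.arms_of("T2")
            ]
        )
        net2 = build_network(relabeled, Outcome.ADHDRS_CHANGE)
        r1 = check_connectivity(net, anchors=[Treatment.GXR, Treatment.ATX])
        r2 = check_connectivity(net2, anchors=[Treatment.GXR, Treatment.ATX])
        assert r1.connected == r2.connected and r1.components == r2.components

    def test_edge_list_and_adjacency_export(self, three_arm_ts):
        import json

        net = build_network(three_arm_ts, Outcome.ADHDRS_CHANGE)
        df = net.edge_dataframe()
        assert list(df.columns) == ["treatment_a", "treatment_b", "trial_id"]
        assert len(df) == len(net.edges)
        summary = json.loads(net.to_json_summary())
        assert summary["nodes"][0] == "PLACEBO"
        assert summary["adjacency"]["PLACEBO"]["ATX"] == 2  # H1 and T2

    def test_overrides_shift_network(self):
        ts = make_trialset(
            [
                ("W", Treatment.PLACEBO, 100, {"responders": 30}),
                ("W", Treatment.MPH_ER, 100, {"responders": 60}),
                ("X", Treatment.PLACEBO, 50, {"responders": 15}),
                ("X", Treatment.MPH_ER, 50, {"responders": 30}),
            ]
        )
        flipped = apply_treatment_overrides(ts, {"W": Treatment.MPH_IR})
        net = build_network(flipped, Outcome.CGI_I)
        assert Treatment.MPH_IR in net.nodes and Treatment.MPH_ER in net.nodes
        assert sum(1 for a, b, _ in net.edges if Treatment.MPH_IR in (a, b)) == 1


class TestCenterCovariates:
    def test_weighted_mean_arithmetic(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"responders": 10}),
                ("A", Treatment.GXR, 50, {"responders": 20}),
                ("B", Treatment.PLACEBO, 150, {"responders": 10}),
                ("B", Treatment.ATX, 150, {"responders": 20}),
            ],
            covs={
                "A": {"mean_age": 10.0, "pct_female": 20.0, "baseline_adhdrs": 38.0},
                "B": {"mean_age": 12.0, "pct_female": 20.0, "baseline_adhdrs": 38.0},
            },
        )
        table, means = center_covariates(ts, ["mean_age"])
        assert means["mean_age"] == pytest.approx(11.5)
        assert table.loc["A", "mean_age"] == pytest.approx(-1.5)
        assert table.loc["B", "mean_age"] == pytest.approx(0.5)

    def test_single_trial_centers_to_zero(self, binary_pair_ts):
        table, _ = center_covariates(binary_pair_ts, ["mean_age", "pct_female"])
        assert np.allclose(table.to_numpy(), 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(
        ages=st.lists(st.floats(8.0, 15.0), min_size=2, max_size=8),
        ns=st.lists(st.integers(16, 222), min_size=2, max_size=8),
    )
    def test_weighted_mean_of_centered_is_zero(self, ages, ns):
        k = min(len(ages), len(ns))
        rows, covs = [], {}
        for i in range(k):
            tid = f"T{i}"
            rows += [
                (tid, Treatment.PLACEBO, ns[i], {"responders": 1}),
                (tid, Treatment.GXR, ns[i], {"responders": 2}),
            ]
            covs[tid] = {"mean_age": ages[i], "pct_female": 20.0, "baseline_adhdrs": 38.0}
        ts = make_trialset(rows, covs=covs)
        table, _ = center_covariates(ts, ["mean_age"])
        w = np.array([ts.total_n(t) for t in ts.trial_ids], dtype=float)
        assert abs(np.sum(w * table["mean_age"].to_numpy()) / w.sum()) < 1e-12
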