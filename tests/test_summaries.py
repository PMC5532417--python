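import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtcnma import (
    EffectModel,
    Outcome,
    Treatment,
    absolute_rate,
    credible_interval,
    or_to_rr,
    pairwise_prob,
    pooled_placebo_risk,
    prob_best,
    summarize_outcome,
)
from mtcnma.model import PosteriorDraws
from mtcnma.summaries import Direction, PooledRisk
from conftest import make_trialset


class TestOrToRr:
    @pytest.mark.parametrize(
        "or_value,p0,expected",
        [(3.34, 0.31, 1.94), (2.69, 0.31, 1.77), (0.58, 0.28, 0.66)],
    )
    def test_published_conversions(self, or_value, p0, expected):
        assert round(or_to_rr(or_value, p0), 2) == expected

    def test_transform_of_rounded_or_near_published_rr(self):
        # published tables summarize unrounded posterior draws, so the
        # transform of the printed OR can differ by one unit in the 2nd dp
        assert or_to_rr(8.43, 0.31) == pytest.approx(2.56, abs=0.01)

    def test_null_invariance(self):
        for p0 in (0.01, 0.31, 0.9):
            assert or_to_rr(1.0, p0) == pytest.approx(1.0)

    def test_rare_outcome_limit(self):
        assert or_to_rr(3.0, 1e-9) == pytest.approx(3.0, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            or_to_rr(3.0, 0.0)
        with pytest.raises(ValueError):
            or_to_rr(-1.0, 0.3)

    @settings(derandomize=True, max_examples=50)
    @given(
        p0=st.floats(0.01, 0.99),
        or_a=st.floats(0.01, 50.0),
        or_b=st.floats(0.01, 50.0),
    )
    def test_monotone_in_or_and_bounded(self, p0, or_a, or_b):
        lo, hi = sorted([or_a, or_b])
        rr_lo, rr_hi = or_to_rr(lo, p0), or_to_rr(hi, p0)
        if hi > lo:
            assert rr_hi > rr_lo
        assert rr_hi < 1.0 / p0


class TestAbsoluteRate:
    @pytest.mark.parametrize(
        "rr,p0,expected", [(2.56, 0.31, 0.79), (0.52, 0.28, 0.15), (1.0, 0.31, 0.31)]
    )
    def test_published_rates(self, rr, p0, expected):
        assert round(absolute_rate(rr, p0), 2) == expected

    def test_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert absolute_rate(5.0, 0.5) == 1.0


class TestCredibleInterval:
    def test_percentiles_on_known_sequence(self):
        lo, hi = credible_interval(np.arange(1, 101, dtype=float), 0.95)
        # linear interpolation between order statistics of 1..100
        assert lo == pytest.approx(1 + 0.025 * 99)
        assert hi == pytest.approx(1 + 0.975 * 99)

    def test_constant_draws_zero_width(self):
        lo, hi = credible_interval([2.0, 2.0, 2.0], 0.95)
        assert lo == hi == 2.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=200))
    def test_brackets_median(self, draws):
        lo, hi = credible_interval(draws, 0.95)
        med = float(np.median(draws))
        assert lo <= med <= hi


class TestRanking:
    def test_dominant_treatment(self):
        mat = np.column_stack([np.full(100, 5.0), np.zeros(100)])
        assert prob_best(mat, Direction.MAXIMIZE).tolist() == [1.0, 0.0]
        assert prob_best(mat, Direction.MINIMIZE).tolist() == [0.0, 1.0]

    def test_exchangeable_treatments_split(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(20_000, 2))
        p = prob_best(mat, Direction.MAXIMIZE)
        assert p[0] == pytest.approx(0.5, abs=0.02)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exact_ties_split_equally(self):
        mat = np.ones((50, 3))
        assert np.allclose(prob_best(mat, Direction.MAXIMIZE), 1 / 3)

    def test_pairwise_dominance_and_self(self):
        a = np.array([3.0, 4.0, 5.0])
        b = np.array([0.0, 1.0, 2.0])
        assert pairwise_prob(a, b, Direction.MAXIMIZE) == 1.0
        assert pairwise_prob(b, a, Direction.MAXIMIZE) == 0.0
        assert pairwise_prob(a, a, Direction.MAXIMIZE) == 0.5

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_complement_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=50), rng.normal(size=50)
        s = pairwise_prob(a, b, Direction.MINIMIZE) + pairwise_prob(b, a, Direction.MINIMIZE)
        assert s == pytest.approx(1.0)


class TestPooledRisk:
    def test_pooled_counts(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 100, {"responders": 10}),
                ("A", Treatment.GXR, 100, {"responders": 30}),
                ("B", Treatment.PLACEBO, 100, {"responders": 20}),
                ("B", Treatment.ATX, 100, {"responders": 30}),
            ]
        )
        pr = pooled_placebo_risk(ts, Outcome.CGI_I)
        assert pr.p_hat == pytest.approx(0.15)
        assert pr.ci_low <= pr.p_hat <= pr.ci_high

    def test_zero_event_boundary(self):
        ts = make_trialset(
            [
                ("A", Treatment.PLACEBO, 50, {"dropouts_ae": 0}),
                ("A", Treatment.GXR, 50, {"dropouts_ae": 2}),
            ]
        )
        pr = pooled_placebo_risk(ts, Outcome.DISC_AE)
        assert pr.p_hat == 0.0
        assert pr.ci_low == 0.0

    def test_no_placebo_arms_is_error(self):
        ts = make_trialset(
            [
                ("A", Treatment.ATX, 50, {"dropouts_all": 5}),
                ("A", Treatment.MPH_ER, 50, {"dropouts_all": 3}),
            ]
        )
        with pytest.raises(ValueError, match="placebo"):
            pooled_placebo_risk(ts, Outcome.DISC_ALL)


def _draws_from_matrix(dmat, outcome, treatments):
    cols = {"chain": np.zeros(len(dmat), dtype=int), "iteration": np.arange(len(dmat))}
    for i, t in enumerate(treatments[1:]):
        cols[f"d[{t.value}]"] = dmat[:, i]
    cols["deviance"] = np.zeros(len(dmat))
    return PosteriorDraws(
        df=pd.DataFrame(cols),
        n_chains=1,
        outcome=outcome,
        effect_model=EffectModel.RANDOM,
        treatments=treatments,
    )


class TestSummaryTable:
    def test_null_effect_gives_rr_one_and_rate_p0(self):
        treats = (Treatment.PLACEBO, Treatment.GXR, Treatment.ATX)
        dmat = np.zeros((500, 2))
        dmat[:, 1] = 0.5  # fixed nonzero log-OR for the second drug
        pooled = PooledRisk(p_hat=0.31, ci_low=0.28, ci_high=0.34, total_events=310, total_n=1000)
        draws = _draws_from_matrix(dmat, Outcome.CGI_I, treats)
        table = summarize_outcome(draws, pooled).table
        gxr = table.loc[table.treatment == "GXR"].iloc[0]
        assert gxr.odds_ratio == pytest.approx(1.0)
        assert gxr.relative_risk == pytest.approx(1.0)
        assert gxr.rate == pytest.approx(0.31)
        assert table.prob_best.sum() == pytest.approx(1.0, abs=1e-9)
        assert list(table.treatment) == ["GXR", "ATX"]

    def test_rr_cri_matches_transform_when_p0_degenerate(self):
        treats = (Treatment.PLACEBO, Treatment.GXR, Treatment.LDX)
        rng = np.random.default_rng(1)
        dmat = np.column_stack([rng.normal(1.2, 0.2, 2000), rng.normal(2.1, 0.2, 2000)])
        n_huge = 10**9
        pooled = PooledRisk(
            p_hat=0.31,
            ci_low=0.31,
            ci_high=0.31,
            total_events=int(0.31 * n_huge),
            total_n=n_huge,
        )
        draws = _draws_from_matrix(dmat, Outcome.CGI_I, treats)
        table = summarize_outcome(draws, pooled, seed=0).table
        for i, row in table.iterrows():
            lo, hi = credible_interval(or_to_rr(np.exp(dmat[:, i]), 0.31))
            assert row.rr_cri_low == pytest.approx(lo, abs=2e-4)
            assert row.rr_cri_high == pytest.approx(hi, abs=2e-4)

    def test_continuous_table_and_reference_probabilities(self):
        treats = (Treatment.PLACEBO, Treatment.GXR, Treatment.ATX)
        rng = np.random.default_rng(2)
        dmat = np.column_stack([rng.normal(-8.7, 1.0, 4000), rng.normal(-6.9, 0.7, 4000)])
        draws = _draws_from_matrix(dmat, Outcome.ADHDRS_CHANGE, treats)
        table = summarize_outcome(draws, None, reference_drug=Treatment.GXR).table
        gxr = table.loc[table.treatment == "GXR"].iloc[0]
        atx = table.loc[table.treatment == "ATX"].iloc[0]
        assert gxr.cri_low < gxr.mean_change < gxr.cri_high
        assert gxr.prob_ref_better is None or np.isnan(gxr.prob_ref_better)
        # GXR more negative than ATX most of the time
        assert atx.prob_ref_better == pytest.approx(
            pairwise_prob(dmat[:, 0], dmat[:, 1], Direction.MINIMIZE), abs=1e-12
        )

    def test_binary_requires_pooled_risk(self):
        treats = (Treatment.PLACEBO, Treatment.GXR, Treatment.ATX)
        draws = _draws_from_matrix(np.zeros((10, 2)), Outcome.CGI_I, treats)
        with pytest.raises(ValueError, match="pooled"):
            summarize_outcome(draws, None)
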