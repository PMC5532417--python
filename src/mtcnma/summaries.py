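"""Posterior reporting: credible intervals, OR/RR conversion, P(best).

Binary outcomes are modeled on the log-odds scale; the reported relative
risks are obtained by converting each posterior odds-ratio draw with the
pooled placebo risk,

    RR = OR / (1 - p0 + p0 * OR),

where p0 is the event proportion pooled over all placebo arms weighted by
sample size.  Per draw, p0 is itself drawn from its Jeffreys sampling
distribution Beta(sum r + 1/2, sum n - sum r + 1/2) so that the RR
credible interval reflects placebo-rate uncertainty; the tabulated RR
point estimate converts the posterior-mean OR at the pooled point
estimate, the convention that reproduces published tables from their
printed odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.stats.proportion import proportion_confint

from .model import PosteriorDraws
from .trial_data import Outcome, Treatment, TrialSet

__all__ = [
    "Direction",
    "PooledRisk",
    "SummaryTable",
    "pooled_placebo_risk",
    "or_to_rr",
    "absolute_rate",
    "credible_interval",
    "prob_best",
    "pairwise_prob",
    "summarize_outcome",
]


class Direction(str, Enum):
    MAXIMIZE = "MAXIMIZE"
    MINIMIZE = "MINIMIZE"


def outcome_direction(outcome: Outcome) -> Direction:
    """Favourable direction on the modeled scale (score change / log-odds)."""
    return Direction.MAXIMIZE if outcome.higher_is_better else Direction.MINIMIZE


@dataclass(frozen=True)
class PooledRisk:
    p_hat: float
    ci_low: float
    ci_high: float
    total_events: int
    total_n: int


def pooled_placebo_risk(
    ts: TrialSet, outcome: Outcome, ci_method: str = "wilson"
) -> PooledRisk:
    """Event proportion pooled over all placebo arms, weighted by sample size."""
    if not outcome.is_binary:
        raise ValueError("pooled placebo risk is defined for binary outcomes")
    events = n = 0
    for arm in ts.arms:
        if arm.treatment is Treatment.PLACEBO and arm.reports(outcome):
            events += arm.events(outcome)
            n += arm.n
    if n == 0:
        raise ValueError(f"no placebo arms report {outcome.value}")
    lo, hi = proportion_confint(events, n, alpha=0.05, method=ci_method)
    return PooledRisk(
        p_hat=events / n, ci_low=float(lo), ci_high=float(hi), total_events=events, total_n=n
    )


def or_to_rr(or_value, p0):
    """Convert an odds ratio to a relative risk at baseline risk p0.

    RR = OR / (1 - p0 + p0 * OR).  Accepts scalars or arrays and is applied
    per posterior draw for credible intervals.
    """
    or_value = np.asarray(or_value, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if np.any(or_value <= 0):
        raise ValueError("odds ratio must be positive")
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("baseline risk must lie strictly inside (0, 1)")
    out = or_value / (1.0 - p0 + p0 * or_value)
    return float(out) if out.ndim == 0 else out


def absolute_rate(rr, p0) -> float:
    """Model-based absolute event rate, rr * p0, clipped to [0, 1]."""
    rate = np.asarray(rr, dtype=float) * np.asarray(p0, dtype=float)
    if np.any(rate > 1):
        import warnings

        warnings.warn("rr * p0 exceeds 1; clipping", stacklevel=2)
    out = np.clip(rate, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def credible_interval(draws: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical credible interval (linear interpolation)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _best_fractions(draw_matrix: np.ndarray, direction: Direction) -> np.ndarray:
    vals = draw_matrix if direction is Direction.MAXIMIZE else -draw_matrix
    best = vals.max(axis=1, keepdims=True)
    ties = vals == best
    return (ties / ties.sum(axis=1, keepdims=True)).mean(axis=0)


def prob_best(
    draw_matrix: np.ndarray, direction: Direction = Direction.MAXIMIZE
) -> np.ndarray:
    """Per-treatment probability of attaining the most favourable draw.

    Exact ties split their draw's weight equally, so the probabilities
    always sum to one.
    """
    draw_matrix = np.asarray(draw_matrix, dtype=float)
    if draw_matrix.ndim != 2 or draw_matrix.shape[0] < 1 or draw_matrix.shape[1] < 2:
        raise ValueError("need a draws x treatments matrix with >=2 treatments")
    return _best_fractions(draw_matrix, direction)


def pairwise_prob(
    draws_a: np.ndarray, draws_b: np.ndarray, direction: Direction = Direction.MAXIMIZE
) -> float:
    """Fraction of draws in which a beats b (ties count half)."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    diff = a - b if direction is Direction.MAXIMIZE else b - a
    return float(np.mean((diff > 0) + 0.5 * (diff == 0)))


@dataclass
class SummaryTable:
    """Machine-readable twin of a published outcome table."""

    outcome: Outcome
    table: pd.DataFrame  # one row per active treatment, fixed treatment order
    pooled: PooledRisk | None
    densities: dict[str, pd.DataFrame]  # treatment -> (grid, density)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            "outcome": self.outcome.value,
            "rows": self.table.to_dict(orient="records"),
        }
        if self.pooled is not None:
            payload["pooled_placebo"] = {
                "p_hat": self.pooled.p_hat,
                "ci_low": self.pooled.ci_low,
                "ci_high": self.pooled.ci_high,
                "total_events": self.pooled.total_events,
                "total_n": self.pooled.total_n,
            }
        import json

        return json.dumps(payload, sort_keys=True, default=float)


def _density(draws: np.ndarray, points: int = 128) -> pd.DataFrame:
    lo, hi = draws.min(), draws.max()
    if hi <= lo:
        grid = np.array([lo, lo + 1e-9])
        dens = np.array([0.0, 0.0])
    else:
        pad = 0.1 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, points)
        dens = gaussian_kde(draws)(grid)
    return pd.DataFrame({"grid": grid, "density": dens})


def summarize_outcome(
    pd_draws: PosteriorDraws,
    pooled: PooledRisk | None = None,
    reference_drug: Treatment = Treatment.GXR,
    level: float = 0.95,
    seed: int = 0,
) -> SummaryTable:
    """Build the published-style summary table for one fitted outcome.

    Continuous: posterior mean difference vs placebo with CrI.  Binary:
    posterior-mean OR with CrI, per-draw RR with CrI (placebo risk drawn
    per iteration from its Jeffreys sampling distribution), absolute rate.
    Both carry P(best) and the probability that the reference drug beats
    each other treatment.
    """
    outcome = pd_draws.outcome
    binary = outcome.is_binary
    if binary and pooled is None:
        raise ValueError("binary outcomes need the pooled placebo risk")
    direction = outcome_direction(outcome)
    treats = pd_draws.active_treatments
    dmat = pd_draws.d_matrix()
    p_best = prob_best(dmat, direction)
    ref_idx = treats.index(reference_drug) if reference_drug in treats else None

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    densities: dict[str, pd.DataFrame] = {}
    if binary:
        p0_draws = rng.beta(
            pooled.total_events + 0.5,
            pooled.total_n - pooled.total_events + 0.5,
            size=dmat.shape[0],
        )
    for i, t in enumerate(treats):
        d_draws = dmat[:, i]
        ref_prob = (
            None
            if ref_idx is None or i == ref_idx
            else pairwise_prob(dmat[:, ref_idx], d_draws, direction)
        )
        row: dict = {"treatment": t.value, "prob_best": float(p_best[i])}
        if binary:
            or_draws = np.exp(d_draws)
            or_mean = float(or_draws.mean())
            rr_draws = or_to_rr(or_draws, p0_draws)
            rr_point = or_to_rr(or_mean, pooled.p_hat)
            row.update(
                odds_ratio=or_mean,
                or_cri_low=credible_interval(or_draws, level)[0],
                or_cri_high=credible_interval(or_draws, level)[1],
                relative_risk=rr_point,
                rr_cri_low=credible_interval(rr_draws, level)[0],
                rr_cri_high=credible_interval(rr_draws, level)[1],
                rr_draw_mean=float(rr_draws.mean()),
                rr_draw_median=float(np.median(rr_draws)),
                rate=absolute_rate(rr_point, pooled.p_hat),
            )
            densities[t.value] = _density(rr_draws)
        else:
            lo, hi = credible_interval(d_draws, level)
            row.update(mean_change=float(d_draws.mean()), cri_low=lo, cri_high=hi)
            densities[t.value] = _density(d_draws)
        row["prob_ref_better"] = ref_prob
        rows.append(row)

    table = pd.DataFrame(rows)
    return SummaryTable(outcome=outcome, table=table, pooled=pooled, densities=densities)
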