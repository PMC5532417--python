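"""Synthetic ADHD trial networks with known ground truth.

The generator emits arm-level trial data whose statistical structure is
exactly the structure the inferential models assume: per-trial nuisance
baselines, trial-specific treatment effects exchangeable around the basic
parameters with between-trial standard deviation tau (contrasts within a
multi-arm trial correlated at one half), trial-level covariates entering
the treatment-versus-reference contrast, normal sampling error for score
change and binomial sampling for event counts.

The default configuration emulates the published ADHD evidence base: a
42-entry trial roster over {placebo, GXR, LDX, ATX, MPH-ER, MPH-IR} whose
per-outcome memberships reproduce the published network sizes (20 trials
for ADHD-RS-IV change with no MPH-IR node, 14 core + 6 short-term trials
for CGI-I response, 31 for all-cause and 32 for AE-related
discontinuation, including one covariate-less trial that only enters the
unadjusted all-cause sensitivity analyses), arm sizes of 16-222, mean age
8.5-14.6 years, 9.4-36.1% female, baseline ADHD-RS-IV 31.5-43.5, and
double-blind durations of 3-16 weeks.  True basic parameters default to
the published point estimates for each outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial_data import (
    ArmRecord,
    Outcome,
    Treatment,
    TrialRecord,
    TrialSet,
    TREATMENT_ORDER,
)

__all__ = ["SimConfig", "GroundTruth", "default_adhd_config", "simulate_trials", "DEFAULT_ROSTER"]

_P, _G, _L, _A, _ME, _MI = (
    Treatment.PLACEBO,
    Treatment.GXR,
    Treatment.LDX,
    Treatment.ATX,
    Treatment.MPH_ER,
    Treatment.MPH_IR,
)

# Trial roster mirroring the published evidence base.  Fields: trial id,
# treatments, outcomes reported (A = score change, C = CGI-I response,
# D = all-cause discontinuation, E = AE discontinuation), short-term flag,
# covariates-missing flag.
_ROSTER_SPEC: tuple[tuple[str, tuple[Treatment, ...], str, bool, bool], ...] = (
    ("S01", (_P, _G, _A), "ACDE", False, False),
    ("S02", (_P, _L, _A), "ACDE", False, False),
    ("S03", (_P, _L, _ME), "ACDE", False, False),
    ("S04", (_P, _A, _ME), "ADE", False, False),
    ("S05", (_P, _A, _ME), "ACDE", False, False),
    ("S06", (_P, _A, _MI), "CDE", False, False),
    ("S07", (_P, _ME, _MI), "CDE", False, False),
    ("S08", (_P, _ME, _MI), "CDE", False, False),
    ("S09", (_P, _ME, _MI), "DE", False, False),
    ("S10", (_A, _ME), "DE", False, False),
    ("S11", (_A, _ME), "DE", False, False),
    ("S12", (_P, _G), "ACDE", False, False),
    ("S13", (_P, _G), "ACDE", False, False),
    ("S14", (_P, _G), "ADE", False, False),
    ("S15", (_P, _G), "ADE", False, False),
    ("S16", (_P, _G), "CDE", False, False),
    ("S17", (_P, _L), "ACDE", False, False),
    ("S18", (_P, _L), "DE", False, False),
    ("S19", (_P, _A), "ADE", False, False),
    ("S20", (_P, _A), "ADE", False, False),
    ("S21", (_P, _A), "A", False, False),
    ("S22", (_P, _A), "A", False, False),
    ("S23", (_P, _A), "AE", False, False),
    ("S24", (_P, _A), "AD", False, False),
    ("S25", (_P, _A), "ADE", False, False),
    ("S26", (_P, _A), "ACDE", False, False),
    ("S27", (_P, _A), "ADE", False, False),
    ("S28", (_P, _A), "DE", False, False),
    ("S29", (_P, _A), "DE", False, False),
    ("S30", (_P, _A), "DE", False, False),
    ("S31", (_P, _A), "DE", False, False),
    ("S32", (_P, _A), "E", False, False),
    ("S33", (_P, _ME), "AE", False, False),
    ("S34", (_P, _ME), "CDE", False, False),
    ("S35", (_P, _MI), "CDE", False, False),
    ("S36", (_P, _MI), "D", False, True),
    ("S37", (_P, _ME), "C", True, False),
    ("S38", (_P, _MI), "C", True, False),
    ("S39", (_P, _ME), "C", True, False),
    ("S40", (_P, _A), "C", True, False),
    ("S41", (_P, _MI), "C", True, False),
    ("S42", (_P, _A, _MI), "C", True, False),
)

_OUTCOME_CODE = {
    Outcome.ADHDRS_CHANGE: "A",
    Outcome.CGI_I: "C",
    Outcome.DISC_ALL: "D",
    Outcome.DISC_AE: "E",
}


@dataclass(frozen=True)
class RosterEntry:
    trial_id: str
    treatments: tuple[Treatment, ...]
    outcomes: frozenset[Outcome]
    short_term: bool
    covariates_missing: bool


DEFAULT_ROSTER: tuple[RosterEntry, ...] = tuple(
    RosterEntry(
        trial_id=tid,
        treatments=treats,
        outcomes=frozenset(o for o, c in _OUTCOME_CODE.items() if c in codes),
        short_term=short,
        covariates_missing=miss,
    )
    for tid, treats, codes, short, miss in _ROSTER_SPEC
)

# Published point estimates used as true basic parameters (vs placebo):
# score-change differences for the continuous outcome, log odds ratios
# for the binary outcomes.
_TRUE_EFFECTS: dict[Outcome, dict[Treatment, float]] = {
    Outcome.ADHDRS_CHANGE: {_G: -8.68, _L: -14.98, _A: -6.88, _ME: -9.33},
    Outcome.CGI_I: {
        _G: math.log(3.34),
        _L: math.log(8.43),
        _A: math.log(2.69),
        _ME: math.log(4.27),
        _MI: math.log(2.22),
    },
    Outcome.DISC_ALL: {
        _G: math.log(0.82),
        _L: math.log(0.58),
        _A: math.log(0.83),
        _ME: math.log(0.43),
        _MI: math.log(0.35),
    },
    Outcome.DISC_AE: {
        _G: math.log(4.50),
        _L: math.log(2.95),
        _A: math.log(2.35),
        _ME: math.log(1.29),
        _MI: math.log(1.02),
    },
}

_PLACEBO_RISK = {Outcome.CGI_I: 0.31, Outcome.DISC_ALL: 0.28, Outcome.DISC_AE: 0.02}


@dataclass
class SimConfig:
    """Ground-truth configuration of the trial-network generator."""

    treatments: tuple[Treatment, ...]
    true_d: dict[Treatment, float]
    tau: float
    beta: dict[str, float]
    topology: tuple[RosterEntry, ...]
    n_trials: int | None = None  # None: one trial per topology entry
    arm_n_range: tuple[int, int] = (16, 222)
    age_range: tuple[float, float] = (8.5, 14.6)
    pct_female_range: tuple[float, float] = (9.4, 36.1)
    baseline_adhdrs_range: tuple[float, float] = (31.5, 43.5)
    duration_range: tuple[float, float] = (3.0, 16.0)
    baseline_mean: float = -9.0  # reference-arm linear predictor mean
    baseline_sd: float = 3.0
    residual_sd: float = 13.0  # within-arm SD of individual score changes
    outcome: Outcome | None = None

    def __post_init__(self) -> None:
        if self.true_d.get(Treatment.PLACEBO, 0.0) != 0.0:
            raise ValueError("true_d[PLACEBO] must be 0")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        for entry in self.topology:
            for t in entry.treatments:
                if t is not Treatment.PLACEBO and t not in self.true_d:
                    raise ValueError(f"topology trial {entry.trial_id} uses {t.value} missing from true_d")


@dataclass
class GroundTruth:
    """Latent values behind a simulated TrialSet."""

    true_d: dict[Treatment, float]
    tau: float
    beta: dict[str, float]
    mu: dict[str, float]  # trial -> reference-arm linear predictor
    delta: dict[str, dict[Treatment, float]]  # trial -> non-reference effects
    covariate_centers: dict[str, float]


def default_adhd_config(outcome: Outcome) -> SimConfig:
    """Generator configuration emulating the published evidence base.

    True effects are the published point estimates; binary placebo risks
    are 0.31 (CGI-I response), 0.28 (all-cause discontinuation) and 0.02
    (AE-related discontinuation).  Between-trial SD defaults to 1.5 score
    points for the continuous outcome and 0.3 log-odds for binary
    outcomes; covariate coefficients default to zero.
    """
    true_d = dict(_TRUE_EFFECTS[outcome])
    topology = tuple(e for e in DEFAULT_ROSTER if outcome in e.outcomes)
    treatments = tuple(
        t for t in TREATMENT_ORDER if any(t in e.treatments for e in topology)
    )
    if outcome is Outcome.ADHDRS_CHANGE:
        baseline_mean, baseline_sd, tau = -9.0, 3.0, 1.5
    else:
        p0 = _PLACEBO_RISK[outcome]
        baseline_mean, baseline_sd, tau = math.log(p0 / (1 - p0)), 0.4, 0.3
    return SimConfig(
        treatments=treatments,
        true_d=true_d,
        tau=tau,
        beta={"mean_age": 0.0, "pct_female": 0.0},
        topology=topology,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        outcome=outcome,
    )


def _ilogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def _effective_topology(cfg: SimConfig) -> list[RosterEntry]:
    """Resolve n_trials by cycling the topology, renaming repeats."""
    entries = list(cfg.topology)
    if cfg.n_trials is None or cfg.n_trials == len(entries):
        return entries
    out: list[RosterEntry] = []
    i = 0
    while len(out) < cfg.n_trials:
        base = entries[i % len(entries)]
        rep = i // len(entries)
        tid = base.trial_id if rep == 0 else f"{base.trial_id}r{rep}"
        out.append(
            RosterEntry(tid, base.treatments, base.outcomes, base.short_term, base.covariates_missing)
        )
        i += 1
    return out


def simulate_trials(
    cfg: SimConfig, outcome: Outcome, seed: int
) -> tuple[TrialSet, GroundTruth]:
    """Draw one synthetic TrialSet plus its latent ground truth.

    For each topology trial: covariates are uniform in their configured
    ranges; the reference-arm linear predictor mu is normal; non-reference
    effects are multivariate normal around the consistency contrasts plus
    the covariate term, with variance tau^2 and correlation 1/2; observed
    continuous outcomes add normal noise with se = residual_sd / sqrt(n),
    binary outcomes are binomial at the inverse-logit of the linear
    predictor.  The same seed always yields the same TrialSet.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    entries = _effective_topology(cfg)
    centers = {
        "mean_age": (cfg.age_range[0] + cfg.age_range[1]) / 2.0,
        "pct_female": (cfg.pct_female_range[0] + cfg.pct_female_range[1]) / 2.0,
        "baseline_adhdrs": (cfg.baseline_adhdrs_range[0] + cfg.baseline_adhdrs_range[1]) / 2.0,
    }
    trials: dict[str, TrialRecord] = {}
    arms: list[ArmRecord] = []
    mu_truth: dict[str, float] = {}
    delta_truth: dict[str, dict[Treatment, float]] = {}

    for entry in entries:
        tid = entry.trial_id
        age = float(rng.uniform(*cfg.age_range))
        female = float(rng.uniform(*cfg.pct_female_range))
        baseline = float(rng.uniform(*cfg.baseline_adhdrs_range))
        if entry.short_term:
            duration = float(rng.uniform(2.0, 3.0))
        else:
            duration = float(rng.uniform(max(cfg.duration_range[0], 3.0) + 1.0, cfg.duration_range[1]))
        trials[tid] = TrialRecord(
            trial_id=tid,
            duration_weeks=round(duration, 1),
            mean_age=None if entry.covariates_missing else round(age, 1),
            pct_female=None if entry.covariates_missing else round(female, 1),
            baseline_adhdrs=None if entry.covariates_missing else round(baseline, 1),
        )
        treats = sorted(entry.treatments, key=lambda t: t.order)
        ref = treats[0]
        others = treats[1:]
        mu_i = float(rng.normal(cfg.baseline_mean, cfg.baseline_sd))
        mu_truth[tid] = mu_i
        x_c = {
            "mean_age": age - centers["mean_age"],
            "pct_female": female - centers["pct_female"],
            "baseline_adhdrs": baseline - centers["baseline_adhdrs"],
        }
        shift = sum(cfg.beta.get(k, 0.0) * v for k, v in x_c.items())
        q = len(others)
        means = np.array(
            [cfg.true_d[t] - cfg.true_d.get(ref, 0.0) + shift for t in others]
        )
        if cfg.tau > 0 and q > 0:
            cov = cfg.tau**2 * (0.5 * np.eye(q) + 0.5 * np.ones((q, q)))
            delta = rng.multivariate_normal(means, cov, method="cholesky")
        else:
            delta = means.copy()
        delta_truth[tid] = {t: float(d) for t, d in zip(others, delta)}

        theta = {ref: mu_i, **{t: mu_i + d for t, d in zip(others, delta)}}
        for t in treats:
            n = int(rng.integers(cfg.arm_n_range[0], cfg.arm_n_range[1] + 1))
            kwargs: dict = {}
            if outcome is Outcome.ADHDRS_CHANGE:
                se = cfg.residual_sd / math.sqrt(n)
                kwargs["mean_change"] = round(float(rng.normal(theta[t], se)), 3)
                kwargs["se_change"] = se
            else:
                p = _ilogit(theta[t])
                kwargs[outcome.count_field] = int(rng.binomial(n, p))
            arms.append(ArmRecord(trial_id=tid, treatment=t, n=n, **kwargs))

    ts = TrialSet(trials=trials, arms=arms)
    truth = GroundTruth(
        true_d=dict(cfg.true_d),
        tau=cfg.tau,
        beta=dict(cfg.beta),
        mu=mu_truth,
        delta=delta_truth,
        covariate_centers=centers,
    )
    return ts, truth
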