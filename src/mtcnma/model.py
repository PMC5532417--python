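"""Bayesian mixed-treatment-comparison models and a self-contained sampler.

Arm-level linear predictor, with trial i, arm treatment k, reference arm
ref(i) (placebo when the trial has one, else the lowest-ordered drug):

    theta_ik = mu_i                                   reference arm
    theta_ik = mu_i + delta_ik + sum_m beta_m * x_im  otherwise

Continuous outcome: y_ik ~ Normal(theta_ik, se_ik^2) (normal/identity).
Binary outcome:     r_ik ~ Binomial(n_ik, inv-logit(theta_ik)).

Fixed effects:  delta_ik = d_k - d_ref(i)  (consistency contrasts).
Random effects: delta vectors are multivariate normal around the
consistency contrasts with between-trial SD tau and correlation 1/2
between a multi-arm trial's contrasts.

Priors are non-informative: Normal(0, 100^2) on all location parameters
and Uniform(0, U) on tau (U = 50 on the score scale, 10 on the logit
scale).  Sampling is blocked Gibbs with exact conjugate updates for every
location block of the normal model, and univariate slice sampling (with
step widths adapted during burn-in and then frozen) for the logit-model
location blocks; tau and, under the logit likelihood, the basic
parameters given the trial effects remain conjugate/closed-form cheap
updates in both models.  Per-draw deviance (-2 log likelihood, constants
included) is recorded for the DIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .trial_data import (
    Outcome,
    Treatment,
    TrialSet,
    build_network,
    center_covariates,
    check_connectivity,
    ValidationError,
)

__all__ = [
    "EffectModel",
    "Likelihood",
    "ModelSpec",
    "PriorSpec",
    "MCMCConfig",
    "Params",
    "ModelState",
    "PosteriorDraws",
    "build_model",
    "log_likelihood",
    "log_prior",
    "deviance",
    "run_mcmc",
]


class EffectModel(str, Enum):
    FIXED = "FIXED"
    RANDOM = "RANDOM"


class Likelihood(str, Enum):
    NORMAL_IDENTITY = "NORMAL_IDENTITY"
    BINOMIAL_LOGIT = "BINOMIAL_LOGIT"


@dataclass(frozen=True)
class ModelSpec:
    outcome: Outcome
    effect_model: EffectModel = EffectModel.RANDOM
    covariates: tuple[str, ...] = ()
    include_short_term: bool = False

    @property
    def likelihood(self) -> Likelihood:
        return (
            Likelihood.BINOMIAL_LOGIT if self.outcome.is_binary else Likelihood.NORMAL_IDENTITY
        )


@dataclass(frozen=True)
class PriorSpec:
    """Non-informative priors; scales are wide relative to observed effects."""

    d_sd: float = 100.0
    mu_sd: float = 100.0
    beta_sd: float = 100.0
    tau_upper: float | None = None  # None: 50 on score scale, 10 on logit scale

    def tau_bound(self, likelihood: Likelihood) -> float:
        if self.tau_upper is not None:
            return self.tau_upper
        return 50.0 if likelihood is Likelihood.NORMAL_IDENTITY else 10.0

    def __post_init__(self) -> None:
        if min(self.d_sd, self.mu_sd, self.beta_sd) <= 0:
            raise ValueError("prior SDs must be positive")
        if self.tau_upper is not None and self.tau_upper <= 0:
            raise ValueError("tau_upper must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 50_000
    samples: int = 50_000
    chains: int = 2
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.samples <= 0 or self.chains <= 0 or self.thin <= 0:
            raise ValueError("burn_in, samples, chains and thin must be positive")


#: Reduced-iteration profile for desk-scale runs and the test suite.
REDUCED = MCMCConfig(burn_in=2_000, samples=4_000, chains=2)


@dataclass
class Params:
    """One point in parameter space (d indexed over all network nodes, d[ref]=0)."""

    mu: np.ndarray
    d: np.ndarray
    beta: np.ndarray
    delta: np.ndarray | None = None  # free only under RANDOM
    tau: float | None = None

    def validate(self) -> None:
        if self.d[0] != 0.0:
            raise ValueError("d at the network reference must be 0")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass
class ModelState:
    """Index structures and data vectors for one outcome network."""

    spec: ModelSpec
    treatments: tuple[Treatment, ...]  # network node order, index 0 = reference
    trial_ids: tuple[str, ...]
    covariates: tuple[str, ...]
    grand_means: dict[str, float]
    # reference arms, one per trial
    y_ref: np.ndarray  # continuous mean change, or event counts (binary)
    se_ref: np.ndarray | None
    n_ref: np.ndarray | None
    # non-reference arms
    arm_trial: np.ndarray  # (J,) trial index
    arm_treat: np.ndarray  # (J,) treatment index into `treatments`
    y_non: np.ndarray
    se_non: np.ndarray | None
    n_non: np.ndarray | None
    C: np.ndarray  # (J, K-1) contrast design onto d[1:]
    X_arm: np.ndarray  # (J, M) centered trial covariates per non-reference arm
    trial_nonref: tuple[np.ndarray, ...]  # per-trial non-reference arm indices

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def n_contrasts(self) -> int:
        return len(self.arm_trial)

    @property
    def binary(self) -> bool:
        return self.spec.likelihood is Likelihood.BINOMIAL_LOGIT

    def delta_labels(self) -> list[str]:
        return [
            f"delta[{self.trial_ids[t]}:{self.treatments[k].value}]"
            for t, k in zip(self.arm_trial, self.arm_treat)
        ]


def build_model(ts: TrialSet, spec: ModelSpec) -> ModelState:
    """Assemble index structures for an already-filtered, connected TrialSet."""
    net = build_network(ts, spec.outcome)
    report = check_connectivity(net)
    if not report.connected:
        comps = "; ".join(
            "{" + ", ".join(t.value for t in comp) + "}" for comp in report.components
        )
        raise ValidationError(f"evidence network is disconnected: components {comps}")

    treatments = net.nodes
    t_index = {t: i for i, t in enumerate(treatments)}
    trial_ids = tuple(ts.trial_ids)
    if spec.covariates:
        centered, grand_means = center_covariates(ts, spec.covariates)
    else:
        centered, grand_means = pd.DataFrame(index=pd.Index(trial_ids)), {}

    binary = spec.likelihood is Likelihood.BINOMIAL_LOGIT
    y_ref, se_ref, n_ref = [], [], []
    arm_trial, arm_treat, y_non, se_non, n_non, x_arm = [], [], [], [], [], []
    trial_nonref: list[list[int]] = []
    for ti, tid in enumerate(trial_ids):
        arms = sorted(ts.arms_of(tid), key=lambda a: a.treatment.order)
        ref, others = arms[0], arms[1:]
        if binary:
            y_ref.append(ref.events(spec.outcome))
            n_ref.append(ref.n)
        else:
            y_ref.append(ref.mean_change)
            se_ref.append(ref.se_change)
        x = (
            centered.loc[tid, list(spec.covariates)].to_numpy(dtype=float)
            if spec.covariates
            else np.zeros(0)
        )
        idxs = []
        for a in others:
            idxs.append(len(arm_trial))
            arm_trial.append(ti)
            arm_treat.append(t_index[a.treatment])
            if binary:
                y_non.append(a.events(spec.outcome))
                n_non.append(a.n)
            else:
                y_non.append(a.mean_change)
                se_non.append(a.se_change)
            x_arm.append(x)
        trial_nonref.append(idxs)

    J, K = len(arm_trial), len(treatments)
    C = np.zeros((J, K - 1))
    for j, (ti, ki) in enumerate(zip(arm_trial, arm_treat)):
        C[j, ki - 1] = 1.0
        ref_k = t_index[
            sorted(ts.arms_of(trial_ids[ti]), key=lambda a: a.treatment.order)[0].treatment
        ]
        if ref_k != 0:
            C[j, ref_k - 1] -= 1.0

    return ModelState(
        spec=spec,
        treatments=treatments,
        trial_ids=trial_ids,
        covariates=tuple(spec.covariates),
        grand_means=grand_means,
        y_ref=np.array(y_ref, dtype=float),
        se_ref=None if binary else np.array(se_ref, dtype=float),
        n_ref=np.array(n_ref, dtype=float) if binary else None,
        arm_trial=np.array(arm_trial, dtype=int),
        arm_treat=np.array(arm_treat, dtype=int),
        y_non=np.array(y_non, dtype=float),
        se_non=None if binary else np.array(se_non, dtype=float),
        n_non=np.array(n_non, dtype=float) if binary else None,
        C=C,
        X_arm=np.array(x_arm, dtype=float).reshape(J, len(spec.covariates)),
        trial_nonref=tuple(np.array(i, dtype=int) for i in trial_nonref),
    )


def _theta(ms: ModelState, p: Params) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictors for (reference arms, non-reference arms)."""
    if ms.spec.effect_model is EffectModel.RANDOM:
        if p.delta is None:
            raise ValueError("random-effects model requires delta")
        eff = p.delta
    else:
        eff = ms.C @ p.d[1:]
    xb = ms.X_arm @ p.beta if ms.covariates else 0.0
    return p.mu, p.mu[ms.arm_trial] + eff + xb


def _log1pexp(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    hi = x > 30
    out[hi] = x[hi]
    out[~hi] = np.log1p(np.exp(x[~hi]))
    return out


def log_likelihood(ms: ModelState, p: Params) -> float:
    """Arm-wise log likelihood, all normalizing constants included."""
    th_ref, th_non = _theta(ms, p)
    if not np.all(np.isfinite(th_ref)) or (len(th_non) and not np.all(np.isfinite(th_non))):
        raise ValueError("non-finite linear predictor")
    if ms.binary:
        ll = 0.0
        for r, n, th in ((ms.y_ref, ms.n_ref, th_ref), (ms.y_non, ms.n_non, th_non)):
            ll += float(
                np.sum(
                    gammaln(n + 1)
                    - gammaln(r + 1)
                    - gammaln(n - r + 1)
                    + r * th
                    - n * _log1pexp(np.asarray(th, dtype=float))
                )
            )
        return ll
    ll = 0.0
    for y, se, th in ((ms.y_ref, ms.se_ref, th_ref), (ms.y_non, ms.se_non, th_non)):
        ll += float(
            np.sum(-0.5 * math.log(2 * math.pi) - np.log(se) - 0.5 * ((y - th) / se) ** 2)
        )
    return ll


def deviance(ms: ModelState, p: Params) -> float:
    """-2 x log likelihood (normalizing constants included consistently)."""
    return -2.0 * log_likelihood(ms, p)


def log_prior(p: Params, priors: PriorSpec, spec: ModelSpec) -> float:
    """Top-level prior density: normals on locations, uniform on tau.

    The hierarchical density of the trial effects given (d, tau) is part of
    the model, not of this function.
    """

    def norm_block(v: np.ndarray, sd: float) -> float:
        return float(np.sum(-0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * (v / sd) ** 2))

    lp = norm_block(p.mu, priors.mu_sd)
    lp += norm_block(p.d[1:], priors.d_sd)
    if len(p.beta):
        lp += norm_block(p.beta, priors.beta_sd)
    if spec.effect_model is EffectModel.RANDOM:
        upper = priors.tau_bound(spec.likelihood)
        if p.tau is None or not 0 <= p.tau <= upper:
            return -math.inf
        lp += -math.log(upper)
    return lp


# --- multi-arm correlation structure -------------------------------------
# R_q = 0.5 I + 0.5 J (unit diagonal would be tau^2, off-diagonal tau^2/2);
# R_q^{-1} = 2 (I - J/(q+1)),  log det R_q = q log 0.5 + log(q + 1).


def _r_inv(q: int) -> np.ndarray:
    return 2.0 * (np.eye(q) - np.ones((q, q)) / (q + 1))


def _draw_mvn(mean: np.ndarray, prec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(mean, prec^{-1}) via the Cholesky factor of the precision."""
    L = np.linalg.cholesky(prec)
    z = rng.standard_normal(len(mean))
    return mean + np.linalg.solve(L.T, z)


def _slice_sample(x0, logf, w, rng, lower=-math.inf, upper=math.inf, max_steps=50):
    """Univariate slice sampler with stepping out and shrinkage."""
    y = logf(x0) - rng.exponential()
    L = x0 - w * rng.uniform()
    R = L + w
    steps = max_steps
    while L > lower and steps > 0 and logf(L) > y:
        L -= w
        steps -= 1
    while R < upper and steps > 0 and logf(R) > y:
        R += w
        steps -= 1
    L, R = max(L, lower), min(R, upper)
    for _ in range(200):
        x1 = L + (R - L) * rng.uniform()
        if logf(x1) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0  # pathological shrinkage; keep current point


def _tau_logpost(tau: float, q_tot: float, n_con: int, upper: float) -> float:
    if not 0 < tau <= upper:
        return -math.inf
    return -n_con * math.log(tau) - q_tot / (2.0 * tau * tau)


def _contrast_structure(ms: ModelState):
    """Precompute the pieces of sum_i C_i' R_i^{-1} (.) used every iteration."""
    singles = np.array(
        [idx[0] for idx in ms.trial_nonref if len(idx) == 1], dtype=int
    )
    multis = [
        (idx, _r_inv(len(idx))) for idx in ms.trial_nonref if len(idx) > 1
    ]
    Km1 = ms.C.shape[1]
    A = ms.C[singles].T @ ms.C[singles] if len(singles) else np.zeros((Km1, Km1))
    for idx, Ri in multis:
        Ci = ms.C[idx]
        A = A + Ci.T @ Ri @ Ci
    return singles, multis, A


def _tau_quadform(ms: ModelState, delta: np.ndarray, m: np.ndarray, singles, multis) -> float:
    """Sum over trials of (delta - m)' R^{-1} (delta - m)."""
    r = delta - m
    q_tot = float(np.dot(r[singles], r[singles])) if len(singles) else 0.0
    for idx, Ri in multis:
        ri = r[idx]
        q_tot += float(ri @ Ri @ ri)
    return q_tot


def _update_d_random(ms, delta, tau, d_sd, rng, singles, multis, A):
    """Conjugate GLS draw of the basic parameters given the trial effects."""
    Km1 = ms.C.shape[1]
    b = ms.C[singles].T @ delta[singles] if len(singles) else np.zeros(Km1)
    for idx, Ri in multis:
        b = b + ms.C[idx].T @ (Ri @ delta[idx])
    prec = A / (tau * tau) + np.eye(Km1) / (d_sd * d_sd)
    mean = np.linalg.solve(prec, b / (tau * tau))
    return _draw_mvn(mean, prec, rng)


def _gibbs_normal_chain(ms, priors, cfg, rng, n_keep):
    """Blocked Gibbs for the normal/identity model (exact conjugate blocks)."""
    random_eff = ms.spec.effect_model is EffectModel.RANDOM
    T, J, M = ms.n_trials, ms.n_contrasts, len(ms.covariates)
    Km1 = ms.C.shape[1]
    upper = priors.tau_bound(Likelihood.NORMAL_IDENTITY)

    w_ref = 1.0 / ms.se_ref**2
    w_non = 1.0 / ms.se_non**2
    mu = ms.y_ref.copy()
    d = np.zeros(Km1)
    beta = np.zeros(M)
    delta = (ms.y_non - mu[ms.arm_trial]).copy() if random_eff else None
    tau = min(1.0, upper / 2.0) if random_eff else None
    singles, multis, A_gls = _contrast_structure(ms)
    tau_w = 0.5

    out = np.empty((n_keep, T + Km1 + M + (J + 1 if random_eff else 0) + 1))
    kept = 0
    total = cfg.burn_in + cfg.samples
    for it in range(total):
        xb = ms.X_arm @ beta if M else np.zeros(J)
        eff = delta if random_eff else ms.C @ d
        # mu | rest
        resid = ms.y_non - eff - xb
        prec = w_ref + 1.0 / priors.mu_sd**2 + np.bincount(ms.arm_trial, w_non, minlength=T)
        num = w_ref * ms.y_ref + np.bincount(ms.arm_trial, w_non * resid, minlength=T)
        mu = num / prec + rng.standard_normal(T) / np.sqrt(prec)

        if random_eff:
            # delta | rest
            m = ms.C @ d
            z = ms.y_non - mu[ms.arm_trial] - xb
            it2 = 1.0 / (tau * tau)
            if len(singles):
                pr = w_non[singles] + it2
                mean = (w_non[singles] * z[singles] + it2 * m[singles]) / pr
                delta[singles] = mean + rng.standard_normal(len(singles)) / np.sqrt(pr)
            for idx, Ri in multis:
                Sinv = Ri * it2
                P = np.diag(w_non[idx]) + Sinv
                rhs = w_non[idx] * z[idx] + Sinv @ m[idx]
                delta[idx] = _draw_mvn(np.linalg.solve(P, rhs), P, rng)
            # d | delta, tau
            d = _update_d_random(ms, delta, tau, priors.d_sd, rng, singles, multis, A_gls)
            # beta | rest
            if M:
                zb = ms.y_non - mu[ms.arm_trial] - delta
                prec_b = (ms.X_arm.T * w_non) @ ms.X_arm + np.eye(M) / priors.beta_sd**2
                beta = _draw_mvn(
                    np.linalg.solve(prec_b, ms.X_arm.T @ (w_non * zb)), prec_b, rng
                )
            # tau | delta, d
            q_tot = _tau_quadform(ms, delta, ms.C @ d, singles, multis)
            tau_new = _slice_sample(
                tau,
                lambda t: _tau_logpost(t, q_tot, J, upper),
                tau_w,
                rng,
                lower=1e-12,
                upper=upper,
            )
            if it < cfg.burn_in:
                tau_w = max(0.05, 0.9 * tau_w + 0.25 * abs(tau_new - tau))
            tau = tau_new
        else:
            # (d, beta) | mu : joint conjugate weighted regression
            G = np.hstack([ms.C, ms.X_arm]) if M else ms.C
            z = ms.y_non - mu[ms.arm_trial]
            prior_prec = np.diag(
                [1.0 / priors.d_sd**2] * Km1 + [1.0 / priors.beta_sd**2] * M
            )
            prec_g = (G.T * w_non) @ G + prior_prec
            draw = _draw_mvn(np.linalg.solve(prec_g, G.T @ (w_non * z)), prec_g, rng)
            d, beta = draw[:Km1], draw[Km1:]

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            p = Params(
                mu=mu,
                d=np.concatenate([[0.0], d]),
                beta=beta,
                delta=delta,
                tau=tau,
            )
            dev = deviance(ms, p)
            row = [*mu, *d, *beta]
            if random_eff:
                row.extend(delta)
                row.append(tau)
            row.append(dev)
            out[kept] = row
            kept += 1
    return out[:kept]


def _bin_ll_scalar(r: float, n: float, th: float) -> float:
    if th > 30:
        return r * th - n * th
    return r * th - n * math.log1p(math.exp(th))


def _slice_binomial_chain(ms, priors, cfg, rng, n_keep):
    """Component-wise sampler for the binomial/logit model.

    Slice updates for mu, the trial effects (random) or basic parameters
    (fixed) and beta; conjugate GLS for d given the trial effects and the
    closed-form quadratic slice for tau under random effects.
    """
    random_eff = ms.spec.effect_model is EffectModel.RANDOM
    T, J, M = ms.n_trials, ms.n_contrasts, len(ms.covariates)
    Km1 = ms.C.shape[1]
    upper = priors.tau_bound(Likelihood.BINOMIAL_LOGIT)

    def logit(r, n):
        p = (r + 0.5) / (n + 1.0)
        return math.log(p / (1 - p))

    mu = np.array([logit(r, n) for r, n in zip(ms.y_ref, ms.n_ref)])
    start_non = np.array([logit(r, n) for r, n in zip(ms.y_non, ms.n_non)])
    d = np.zeros(Km1)
    beta = np.zeros(M)
    delta = (start_non - mu[ms.arm_trial]).copy() if random_eff else None
    tau = min(0.5, upper / 2.0) if random_eff else None
    w_mu = np.full(T, 0.5)
    w_delta = np.full(J, 0.5) if random_eff else None
    w_d = np.full(Km1, 0.5)
    w_beta = np.full(M, 0.1)
    tau_w = 0.25
    mu_prec = 1.0 / priors.mu_sd**2
    d_prec = 1.0 / priors.d_sd**2
    b_prec = 1.0 / priors.beta_sd**2

    singles, multis, A_gls = _contrast_structure(ms)
    affected = [np.nonzero(ms.C[:, k])[0] for k in range(Km1)]

    out = np.empty((n_keep, T + Km1 + M + (J + 1 if random_eff else 0) + 1))
    kept = 0
    total = cfg.burn_in + cfg.samples
    for it in range(total):
        adapting = it < cfg.burn_in
        xb = ms.X_arm @ beta if M else np.zeros(J)
        eff = delta if random_eff else ms.C @ d

        # mu_t | rest
        for t in range(T):
            idx = ms.trial_nonref[t]
            offs = eff[idx] + xb[idx]
            rr, nn = ms.y_ref[t], ms.n_ref[t]
            rs, nss = ms.y_non[idx], ms.n_non[idx]

            def logf(m, offs=offs, rr=rr, nn=nn, rs=rs, nss=nss):
                v = _bin_ll_scalar(rr, nn, m) - 0.5 * mu_prec * m * m
                for r_, n_, o_ in zip(rs, nss, offs):
                    v += _bin_ll_scalar(r_, n_, m + o_)
                return v

            new = _slice_sample(mu[t], logf, w_mu[t], rng)
            if adapting:
                w_mu[t] = max(0.02, 0.9 * w_mu[t] + 0.25 * abs(new - mu[t]))
            mu[t] = new

        if random_eff:
            # delta_j | rest (conditional prior within the trial, rho = 1/2)
            m = ms.C @ d
            for t in range(T):
                idx = ms.trial_nonref[t]
                q = len(idx)
                for pos, j in enumerate(idx):
                    if q == 1:
                        cmean, cvar = m[j], tau * tau
                    else:
                        others = [l for l in idx if l != j]
                        rho = 0.5
                        k = rho / (1 + (q - 2) * rho)
                        cmean = m[j] + k * sum(delta[l] - m[l] for l in others)
                        cvar = tau * tau * (1 - rho) * (1 + (q - 1) * rho) / (1 + (q - 2) * rho)
                    rr, nn, mt = ms.y_non[j], ms.n_non[j], mu[t]
                    o = xb[j]

                    def logf(dl, rr=rr, nn=nn, mt=mt, o=o, cmean=cmean, cvar=cvar):
                        return _bin_ll_scalar(rr, nn, mt + dl + o) - 0.5 * (dl - cmean) ** 2 / cvar

                    new = _slice_sample(delta[j], logf, w_delta[j], rng)
                    if adapting:
                        w_delta[j] = max(0.02, 0.9 * w_delta[j] + 0.25 * abs(new - delta[j]))
                    delta[j] = new
            # d | delta, tau (conjugate, no likelihood dependence)
            d = _update_d_random(ms, delta, tau, priors.d_sd, rng, singles, multis, A_gls)
            eff = delta
        else:
            # d_k | rest (slice over the affected arms)
            for k in range(Km1):
                idx = affected[k]
                coef = ms.C[idx, k]
                base = mu[ms.arm_trial[idx]] + ms.C[idx] @ d + xb[idx] - coef * d[k]
                rs, nss = ms.y_non[idx], ms.n_non[idx]

                def logf(dk, rs=rs, nss=nss, base=base, coef=coef):
                    v = -0.5 * d_prec * dk * dk
                    for r_, n_, b_, c_ in zip(rs, nss, base, coef):
                        v += _bin_ll_scalar(r_, n_, b_ + c_ * dk)
                    return v

                new = _slice_sample(d[k], logf, w_d[k], rng)
                if adapting:
                    w_d[k] = max(0.02, 0.9 * w_d[k] + 0.25 * abs(new - d[k]))
                d[k] = new
            eff = ms.C @ d

        # beta_m | rest (vectorized over all non-reference arms)
        if M:
            base_all = mu[ms.arm_trial] + eff
            for mi in range(M):
                xb_other = ms.X_arm @ beta - ms.X_arm[:, mi] * beta[mi]
                col = ms.X_arm[:, mi]
                base = base_all + xb_other

                def logf(b, col=col, base=base):
                    th = base + col * b
                    return float(
                        np.sum(ms.y_non * th - ms.n_non * _log1pexp(th))
                    ) - 0.5 * b_prec * b * b

                new = _slice_sample(beta[mi], logf, w_beta[mi], rng)
                if adapting:
                    w_beta[mi] = max(0.005, 0.9 * w_beta[mi] + 0.25 * abs(new - beta[mi]))
                beta[mi] = new

        if random_eff:
            q_tot = _tau_quadform(ms, delta, ms.C @ d, singles, multis)
            tau_new = _slice_sample(
                tau,
                lambda t: _tau_logpost(t, q_tot, J, upper),
                tau_w,
                rng,
                lower=1e-12,
                upper=upper,
            )
            if adapting:
                tau_w = max(0.02, 0.9 * tau_w + 0.25 * abs(tau_new - tau))
            tau = tau_new

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            p = Params(mu=mu, d=np.concatenate([[0.0], d]), beta=beta, delta=delta, tau=tau)
            dev = deviance(ms, p)
            row = [*mu, *d, *beta]
            if random_eff:
                row.extend(delta)
                row.append(tau)
            row.append(dev)
            out[kept] = row
            kept += 1
    return out[:kept]


@dataclass
class PosteriorDraws:
    """Labeled retained MCMC draws plus per-draw deviance."""

    df: pd.DataFrame
    n_chains: int
    outcome: Outcome
    effect_model: EffectModel
    treatments: tuple[Treatment, ...]  # network node order; index 0 = reference
    warnings: tuple[str, ...] = ()

    @property
    def active_treatments(self) -> tuple[Treatment, ...]:
        return self.treatments[1:]

    def d_columns(self) -> list[str]:
        return [f"d[{t.value}]" for t in self.active_treatments]

    def d_matrix(self) -> np.ndarray:
        """(draws x active treatments) matrix of basic-parameter draws."""
        return self.df[self.d_columns()].to_numpy()

    def param_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("chain", "iteration")]

    def chain(self, c: int, column: str) -> np.ndarray:
        return self.df.loc[self.df["chain"] == c, column].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def run_mcmc(ms: ModelState, priors: PriorSpec | None = None, cfg: MCMCConfig | None = None) -> PosteriorDraws:
    """Sample the posterior; identical seeds give identical draws.

    Chains are run sequentially with per-chain RNG streams spawned from the
    master seed, so adding chains never perturbs earlier ones.
    """
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    random_eff = ms.spec.effect_model is EffectModel.RANDOM
    n_keep = (cfg.samples + cfg.thin - 1) // cfg.thin
    labels = [f"mu[{tid}]" for tid in ms.trial_ids]
    labels += [f"d[{t.value}]" for t in ms.treatments[1:]]
    labels += [f"beta[{c}]" for c in ms.covariates]
    if random_eff:
        labels += ms.delta_labels()
        labels.append("tau")
    labels.append("deviance")

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    frames = []
    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        if ms.binary:
            draws = _slice_binomial_chain(ms, priors, cfg, rng, n_keep)
        else:
            draws = _gibbs_normal_chain(ms, priors, cfg, rng, n_keep)
        df = pd.DataFrame(draws, columns=labels)
        df.insert(0, "iteration", np.arange(len(draws)))
        df.insert(0, "chain", c)
        frames.append(df)
    all_df = pd.concat(frames, ignore_index=True)
    return PosteriorDraws(
        df=all_df,
        n_chains=cfg.chains,
        outcome=ms.spec.outcome,
        effect_model=ms.spec.effect_model,
        treatments=ms.treatments,
    )


def posterior_mean_params(pd_draws: PosteriorDraws, ms: ModelState) -> Params:
    """Component-wise posterior means assembled into a Params point.

    The linear predictor is linear in every location parameter, so the
    plug-in deviance at these means equals the deviance at the posterior
    mean of the linear predictors (the parameterization-stable DIC plug-in
    for the logit model).
    """
    means = pd_draws.df.mean(numeric_only=True)
    mu = np.array([means[f"mu[{tid}]"] for tid in ms.trial_ids])
    d = np.concatenate(
        [[0.0], [means[f"d[{t.value}]"] for t in ms.treatments[1:]]]
    )
    beta = np.array([means[f"beta[{c}]"] for c in ms.covariates])
    delta = tau = None
    if ms.spec.effect_model is EffectModel.RANDOM:
        delta = np.array([means[lbl] for lbl in ms.delta_labels()])
        tau = float(means["tau"])
    return Params(mu=mu, d=d, beta=beta, delta=delta, tau=tau)
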