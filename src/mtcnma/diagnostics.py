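"""Model-fit, heterogeneity and MCMC convergence diagnostics.

DIC compares fixed- against random-effects fits: DIC = D-bar + p_D with
p_D = D-bar - D-hat, the plug-in deviance evaluated at component-wise
posterior means of the location parameters (equivalently, at the posterior
mean linear predictors, which keeps p_D stable under reparameterization of
the logit model).

Pairwise heterogeneity follows the classical two-treatment meta-analysis:
per-trial contrasts pooled by inverse variance, Cochran's Q against
chi-square with k-1 degrees of freedom, I^2 = max(0, (Q - df)/Q), and a
test-based (Higgins-Thompson) confidence interval for I^2, suppressed for
pairs informed by fewer than three trials.

Convergence uses the Geweke early/late window z-score and the
Heidelberger-Welch stationarity (Cramer-von Mises on the Brownian bridge
of cumulative sums) and half-width tests; spectral density at frequency
zero is estimated from an autoregressive fit with AIC order selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.regression.linear_model import yule_walker

from .model import EffectModel, ModelState, Params, PosteriorDraws
from .model import deviance as model_deviance
from .model import posterior_mean_params
from .trial_data import Outcome, Treatment, TrialSet

__all__ = [
    "DICReport",
    "HeterogeneityResult",
    "ConvergenceReport",
    "dic",
    "pairwise_heterogeneity",
    "geweke",
    "heidelberger_welch",
    "convergence_report",
]


@dataclass(frozen=True)
class DICReport:
    d_bar: float
    d_hat: float
    p_d: float
    dic: float
    negative_p_d: bool

    def to_dict(self) -> dict:
        return {
            "d_bar": self.d_bar,
            "d_hat": self.d_hat,
            "p_d": self.p_d,
            "dic": self.dic,
            "negative_p_d": self.negative_p_d,
        }


def dic(pd_draws: PosteriorDraws, ms: ModelState) -> DICReport:
    """Deviance information criterion from recorded per-draw deviances."""
    if "deviance" not in pd_draws.df.columns:
        raise ValueError("posterior draws carry no deviance column")
    d_bar = float(pd_draws.df["deviance"].mean())
    p_hat = posterior_mean_params(pd_draws, ms)
    d_hat = model_deviance(ms, p_hat)
    p_d = d_bar - d_hat
    return DICReport(
        d_bar=d_bar, d_hat=d_hat, p_d=p_d, dic=d_bar + p_d, negative_p_d=p_d < 0
    )


@dataclass(frozen=True)
class HeterogeneityResult:
    pair: tuple[Treatment, Treatment]
    k: int
    q: float
    df: int
    p_value: float
    i2: float
    i2_ci: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "pair": [self.pair[0].value, self.pair[1].value],
            "k": self.k,
            "q": self.q,
            "df": self.df,
            "p_value": self.p_value,
            "i2": self.i2,
            "i2_ci": list(self.i2_ci) if self.i2_ci is not None else None,
        }


def _trial_contrast(ts: TrialSet, tid: str, pair, outcome: Outcome):
    """(effect, variance) of b vs a in one trial, or None if not estimable.

    Continuous: mean-change difference with variance se_a^2 + se_b^2.
    Binary: log odds ratio with variance sum of reciprocal cells, adding
    1/2 to every cell only when a zero cell occurs.
    """
    a, b = pair
    arm_a = arm_b = None
    for arm in ts.arms_of(tid):
        if arm.treatment is a and arm.reports(outcome):
            arm_a = arm
        elif arm.treatment is b and arm.reports(outcome):
            arm_b = arm
    if arm_a is None or arm_b is None:
        return None
    if outcome.is_binary:
        ra, rb = arm_a.events(outcome), arm_b.events(outcome)
        na, nb = arm_a.n, arm_b.n
        cells = [rb, nb - rb, ra, na - ra]
        if any(c == 0 for c in cells):
            cells = [c + 0.5 for c in cells]
        e1, e0, c1, c0 = cells
        return math.log(e1 * c0 / (e0 * c1)), 1 / e1 + 1 / e0 + 1 / c1 + 1 / c0
    eff = arm_b.mean_change - arm_a.mean_change
    var = arm_a.se_change**2 + arm_b.se_change**2
    return eff, var


def _i2_ci_test_based(q: float, df: int) -> tuple[float, float]:
    """Higgins-Thompson test-based CI for I^2 via ln H."""
    k = df + 1
    if q > k:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (math.sqrt(2 * q) - math.sqrt(2 * df - 1))
    else:
        se_ln_h = math.sqrt((1.0 / (2 * (k - 2))) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    ln_h = 0.5 * max(0.0, math.log(q / df)) if q > 0 else 0.0
    z = stats.norm.ppf(0.975)
    bounds = []
    for lh in (ln_h - z * se_ln_h, ln_h + z * se_ln_h):
        h2 = math.exp(2 * max(lh, 0.0))
        bounds.append(max(0.0, (h2 - 1.0) / h2))
    return bounds[0], bounds[1]


def pairwise_heterogeneity(
    ts: TrialSet, pair: tuple[Treatment, Treatment], outcome: Outcome
) -> HeterogeneityResult:
    """Cochran's Q and I^2 over the trials directly comparing one pair."""
    contrasts = []
    for tid in ts.trial_ids:
        c = _trial_contrast(ts, tid, pair, outcome)
        if c is not None:
            contrasts.append(c)
    k = len(contrasts)
    if k < 2:
        raise ValueError(
            f"heterogeneity for {pair[0].value} vs {pair[1].value} not computable: "
            f"{k} trial(s) compare them"
        )
    y = np.array([c[0] for c in contrasts])
    w = 1.0 / np.array([c[1] for c in contrasts])
    pooled = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - pooled) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    ci = _i2_ci_test_based(q, df) if k >= 3 else None
    return HeterogeneityResult(pair=pair, k=k, q=q, df=df, p_value=p, i2=i2, i2_ci=ci)


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density of x at frequency zero from an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v = float(np.var(x, ddof=1))
    if v == 0:
        raise ValueError("zero-variance window")
    max_order = min(20, n // 10)
    best = (n * math.log(v), 0.0, v)  # (aic, sum of AR coefficients, innovation var)
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate series
            continue
        s2 = float(sigma) ** 2
        if s2 <= 0 or abs(1.0 - np.sum(rho)) < 1e-10:
            continue
        aic = n * math.log(s2) + 2.0 * p
        if aic < best[0]:
            best = (aic, float(np.sum(rho)), s2)
    _, rho_sum, s2 = best
    return s2 / (1.0 - rho_sum) ** 2


def geweke(chain: Sequence[float], frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late window means.

    Window variances are spectral densities at zero from AR fits, so the
    score is robust to autocorrelation within each window.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    if not (0 < frac_first < 1 and 0 < frac_last < 1 and frac_first + frac_last <= 1):
        raise ValueError("window fractions must be in (0,1) and non-overlapping")
    n1 = int(frac_first * n)
    n2 = int(frac_last * n)
    first, last = x[:n1], x[n - n2 :]
    if np.var(first) == 0 or np.var(last) == 0:
        if np.mean(first) == np.mean(last):
            return 0.0
        raise ValueError("zero-variance window")
    s1, s2 = _spectrum0_ar(first), _spectrum0_ar(last)
    return float((first.mean() - last.mean()) / math.sqrt(s1 / n1 + s2 / n2))


# Asymptotic Cramer-von Mises critical values for the Brownian-bridge test.
_CVM_CRIT = {0.10: 0.347, 0.05: 0.461, 0.025: 0.580, 0.01: 0.743}


@dataclass(frozen=True)
class HWResult:
    stationarity_pass: bool
    retained_fraction: float
    halfwidth_pass: bool | None  # None: mean near zero, ratio not applicable
    halfwidth_ratio: float | None
    cvm_statistic: float


def _cvm_statistic(x: np.ndarray) -> float:
    n = len(x)
    mean = x.mean()
    # spectral variance from the second half only, so that early
    # non-stationarity cannot inflate it and mask itself
    s0 = _spectrum0_ar(x[n // 2 :])
    csum = np.cumsum(x - mean)
    bridge = csum / math.sqrt(n * s0)
    return float(np.sum(bridge**2) / n)


def heidelberger_welch(
    chain: Sequence[float], alpha: float = 0.05, halfwidth_eps: float = 0.1
) -> HWResult:
    """Heidelberger-Welch stationarity and half-width tests.

    Drops leading 10% increments until the Cramer-von Mises statistic of
    the cumulative-sum bridge passes at level alpha, or more than half the
    chain is gone (stationarity failure).  The half-width test passes when
    the relative half-width of the mean's asymptotic CI is at most
    halfwidth_eps; a mean indistinguishable from zero makes the ratio
    unstable and is reported as not applicable.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain too short for Heidelberger-Welch (need >= 100)")
    crit = _CVM_CRIT.get(alpha)
    if crit is None:
        crit = _CVM_CRIT[min(_CVM_CRIT, key=lambda a: abs(a - alpha))]
    n = len(x)
    stationary = False
    start = 0
    cvm = math.inf
    for drop in range(0, 6):  # 0%,10%,...,50% discarded
        start = int(drop * 0.1 * n)
        seg = x[start:]
        if np.var(seg) == 0:
            cvm = 0.0
            stationary = True
            break
        cvm = _cvm_statistic(seg)
        if cvm <= crit:
            stationary = True
            break
    retained = (n - start) / n if stationary else 0.5
    if not stationary:
        return HWResult(False, retained, None, None, cvm)

    seg = x[start:]
    if np.var(seg) == 0:
        return HWResult(True, retained, True, 0.0, cvm)
    s0 = _spectrum0_ar(seg)
    se = math.sqrt(s0 / len(seg))
    mean = float(seg.mean())
    z = stats.norm.ppf(1 - alpha / 2)
    if abs(mean) < z * se:  # mean not resolved from zero: ratio unstable
        return HWResult(True, retained, None, None, cvm)
    ratio = z * se / abs(mean)
    return HWResult(True, retained, bool(ratio <= halfwidth_eps), float(ratio), cvm)


@dataclass
class ConvergenceReport:
    """Per-parameter Geweke and Heidelberger-Welch results over all chains."""

    geweke_z: dict[str, float]  # parameter -> max |z| over chains (signed)
    hw_stationarity: dict[str, bool]
    hw_halfwidth: dict[str, bool | None]
    flags: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "geweke_z": self.geweke_z,
            "hw_stationarity": self.hw_stationarity,
            "hw_halfwidth": self.hw_halfwidth,
            "flags": list(self.flags),
        }


def convergence_report(
    pd_draws: PosteriorDraws, parameters: Sequence[str] | None = None, z_threshold: float = 3.0
) -> ConvergenceReport:
    """Run Geweke and Heidelberger-Welch on the monitored parameters.

    Defaults to the basic parameters, meta-regression coefficients and tau.
    Each parameter is checked per chain; the worst chain is reported.
    """
    if parameters is None:
        parameters = [
            c
            for c in pd_draws.param_columns()
            if c.startswith(("d[", "beta[")) or c == "tau"
        ]
    gz: dict[str, float] = {}
    st: dict[str, bool] = {}
    hw: dict[str, bool | None] = {}
    flags: list[str] = []
    for name in parameters:
        worst_z = 0.0
        stat_ok = True
        half: bool | None = True
        for c in range(pd_draws.n_chains):
            x = pd_draws.chain(c, name)
            try:
                z = geweke(x)
            except ValueError:
                z = math.nan
            if math.isnan(z) or abs(z) >= abs(worst_z):
                worst_z = z
            res = heidelberger_welch(x)
            stat_ok = stat_ok and res.stationarity_pass
            if res.halfwidth_pass is None:
                half = None if half is not False else False
            elif not res.halfwidth_pass:
                half = False
        gz[name] = worst_z
        st[name] = stat_ok
        hw[name] = half
        if not math.isnan(worst_z) and abs(worst_z) > z_threshold:
            flags.append(f"{name}: |geweke z| > {z_threshold}")
        if not stat_ok:
            flags.append(f"{name}: stationarity failed")
    return ConvergenceReport(geweke_z=gz, hw_stationarity=st, hw_halfwidth=hw, flags=tuple(flags))
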