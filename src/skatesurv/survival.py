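"""Binomial survival estimation, CI-width planning, and the logistic model.

The headline quantity is the proportion of released animals judged to have
survived, with a 95% Wilson score interval: for k = 6 survivors of n = 23
released (the control excluded) this is 26% (13-46%).  The Wilson interval
inverts the score test,

    (p + z^2/2n  +/-  z sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n),

and behaves well at small n; Clopper-Pearson ("exact") and Wald ("normal")
intervals are available for sensitivity.  A planning curve reports how the
interval width shrinks with n at a fixed observed proportion.  Factors in
survival are modelled with a binomial GLM (logit link) on capture depth,
total length, sex, time out of water and soak time; the depth effect is
reported as an odds ratio per 100 m shallower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist
from scipy.stats import norm

DEFAULT_PREDICTORS = [
    "capture_depth_m",
    "total_length_mm",
    "sex",
    "time_out_water_min",
    "soak_time_h",
]


@dataclass
class SurvivalEstimate:
    n: int
    k_survivors: int
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float
    method: str

    @property
    def pct(self) -> int:
        return int(round(100.0 * self.proportion))

    @property
    def ci_pct(self) -> tuple[int, int]:
        return int(round(100.0 * self.ci_low)), int(round(100.0 * self.ci_high))


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2.0 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    return (centre - half) / denom, (centre + half) / denom


def survival_estimate(
    k: int, n: int, conf: float = 0.95, method: str = "wilson"
) -> SurvivalEstimate:
    """Binomial survival estimate with confidence interval.

    ``method`` is one of wilson (default), exact (Clopper-Pearson) or
    normal (Wald).  Wilson is the default because it is well behaved at the
    study's small n; exact is wider, normal can escape [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    if method == "wilson":
        lo, hi = wilson_interval(k, n, conf)
    elif method == "exact":
        a = (1.0 - conf) / 2.0
        lo = beta_dist.ppf(a, k, n - k + 1) if k > 0 else 0.0
        hi = beta_dist.ppf(1.0 - a, k + 1, n - k) if k < n else 1.0
    elif method == "normal":
        z = norm.ppf(0.5 + conf / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return SurvivalEstimate(
        n=n,
        k_survivors=k,
        proportion=p,
        ci_low=float(lo),
        ci_high=float(hi),
        conf_level=conf,
        method=method,
    )


@dataclass
class PowerCurve:
    p_hat: float
    n_grid: np.ndarray
    widths: np.ndarray
    n_ref: int
    width_ref: float
    target_fraction: float
    n_for_target: int | None
    method: str = "wilson"

    def n_for_width(self, target_width: float) -> int | None:
        ok = np.flatnonzero(self.widths <= target_width)
        return int(self.n_grid[ok[0]]) if len(ok) else None


def _wilson_width(p_hat: float, n: np.ndarray, conf: float) -> np.ndarray:
    z = norm.ppf(0.5 + conf / 2.0)
    denom = 1.0 + z * z / n
    return 2.0 * z * np.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n)) / denom


def ci_width_curve(
    p_hat: float,
    n_ref: int = 23,
    n_max: int = 2000,
    target_fraction: float = 0.5,
    conf: float = 0.95,
) -> PowerCurve:
    """Wilson CI width versus sample size at a fixed observed proportion.

    Reports the smallest n whose width is at most ``target_fraction`` times
    the width at ``n_ref`` (e.g. how many tags halve the interval).  The
    observed proportion is held fixed across n; widths decrease strictly
    in n.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError("p_hat must lie strictly in (0, 1)")
    n_grid = np.arange(n_ref, n_max + 1)
    widths = _wilson_width(p_hat, n_grid.astype(float), conf)
    width_ref = float(widths[0])
    target = target_fraction * width_ref
    ok = np.flatnonzero(widths <= target)
    n_for_target = int(n_grid[ok[0]]) if len(ok) else None
    return PowerCurve(
        p_hat=p_hat,
        n_grid=n_grid,
        widths=widths,
        n_ref=n_ref,
        width_ref=width_ref,
        target_fraction=target_fraction,
        n_for_target=n_for_target,
    )


@dataclass
class GLMResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    or_per_100m_shallower: float
    or_ci: tuple[float, float]
    separation_flag: bool
    n: int
    log_likelihood: float
    llnull: float
    model: object = field(repr=False, default=None)


def fit_survival_glm(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    outcome: str = "survived",
    depth_column: str = "capture_depth_m",
) -> GLMResult:
    """Binomial GLM (logit link) of survival on capture covariates.

    Depth enters in metres; the odds ratio per 100 m *shallower* is the
    derived report quantity exp(-100 * beta_depth) with its Wald 95% CI.
    Quasi-separation (fitted probabilities within 1e-8 of 0 or 1) is
    flagged; capture area is not a default predictor (it confounds with
    depth) but can be added explicitly.
    """
    predictors = list(predictors or DEFAULT_PREDICTORS)
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit the survival GLM")
    y = table[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("no outcome variation: all outcomes identical")
    X = pd.get_dummies(
        table[predictors], columns=[c for c in predictors if c == "sex"],
        drop_first=True, dtype=float,
    )
    X = sm.add_constant(X.astype(float))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    fitted = res.fittedvalues
    separation = bool(np.any(fitted < 1e-8) | np.any(fitted > 1.0 - 1e-8))
    beta = float(res.params[depth_column])
    se = float(res.bse[depth_column])
    z = norm.ppf(0.975)
    or100 = float(np.exp(-100.0 * beta))
    or_ci = (
        float(np.exp(-100.0 * (beta + z * se))),
        float(np.exp(-100.0 * (beta - z * se))),
    )
    llnull = float(
        sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit().llf
    )
    return GLMResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        or_per_100m_shallower=or100,
        or_ci=or_ci,
        separation_flag=separation,
        n=len(table),
        log_likelihood=float(res.llf),
        llnull=llnull,
        model=res,
    )
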