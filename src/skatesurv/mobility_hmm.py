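"""Pooled two-state Gaussian hidden Markov model on windowed tag mobility.

The two latent states, "non-mobile" and "mobile", proxy an inactive versus
active animal.  One model is fitted to the whole cohort by Baum-Welch
(expectation-maximization with scaled forward-backward recursions): emission
parameters and the transition matrix are shared across tags, while each
tag's chain runs independently from the shared initial distribution.  Tags
are then decoded individually (Viterbi path plus forward-backward
posteriors) and labelled by their dominant decoded state.

Fitting a separate two-state model per tag would force a split of pure
noise into two states on an always-inactive tag; the pooled fit avoids
this, and a per-tag mode remains available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

STATE_NAMES = ("non_mobile", "mobile")
SD_FLOOR = 0.5  # sensor resolution scale; prevents emission collapse


class DegenerateEmissionsError(ValueError):
    """All observations identical: a two-state emission fit is meaningless."""


@dataclass
class HMMFit:
    """Fitted pooled model; state 0 is always the lower-mean (non-mobile) state."""

    means: np.ndarray
    sds: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    sd_floored: bool = False
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return len(self.means)


@dataclass
class StatePath:
    """Per-tag decoded state sequence with posteriors."""

    tag_id: str
    states: np.ndarray  # Viterbi path, 0 = non_mobile, 1 = mobile
    posterior_mobile: np.ndarray
    dominant_state: str
    dominant_fraction: float
    tied: bool = False


def _emission_logpdf(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """(T, K) log N(x | mean_k, sd_k)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z * z - np.log(sds[None, :]) - 0.5 * np.log(2.0 * np.pi)


def _forward_backward(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward; returns (gamma, xi_sum, alpha0, loglik)."""
    T, K = logb.shape
    # scale emission likelihoods per step to avoid under/overflow
    logb_max = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - logb_max)
    alpha = np.empty((T, K))
    c = np.empty(T)
    alpha[0] = initial * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transition) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (transition @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb) * transition / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(logb_max))
    return gamma, xi_sum, gamma[0], loglik


def fit_hmm(
    sequences: Sequence[np.ndarray],
    init: HMMFit | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    sd_floor: float = SD_FLOOR,
) -> HMMFit:
    """Fit the pooled two-state Gaussian HMM by Baum-Welch.

    Initialization is deterministic given the data: state means start at the
    pooled 25th/75th mobility percentiles, both sds at the pooled sd, and
    self-transitions at 0.95 (``seed`` is reserved for optional multi-start
    and unused by the default deterministic initialization).  The total
    log-likelihood is asserted non-decreasing at every EM step; emission sds
    are floored at the sensor resolution scale and flagged if the floor
    binds.  States are relabelled so the non-mobile state has the lower mean.
    """
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    if not seqs or any(len(s) < 2 for s in seqs):
        raise ValueError("need at least one sequence, each with >= 2 windows")
    pooled = np.concatenate(seqs)
    if np.ptp(pooled) == 0.0:
        raise DegenerateEmissionsError(
            "all observations identical; a single-state summary is the "
            "appropriate model"
        )
    if init is not None:
        means = init.means.astype(float).copy()
        sds = init.sds.astype(float).copy()
        transition = init.transition.astype(float).copy()
        initial = init.initial.astype(float).copy()
    else:
        means = np.percentile(pooled, [25.0, 75.0]).astype(float)
        if means[0] == means[1]:
            means[1] = means[0] + max(pooled.std(), sd_floor)
        sds = np.full(2, max(pooled.std(), sd_floor))
        transition = np.array([[0.95, 0.05], [0.05, 0.95]])
        initial = np.array([0.5, 0.5])

    prev_ll = -np.inf
    ll_hist = []
    converged = False
    floored = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_sum = np.zeros(2)
        gx_sum = np.zeros(2)
        gxx_sum = np.zeros(2)
        xi_total = np.zeros((2, 2))
        g0_sum = np.zeros(2)
        g_trans_denom = np.zeros(2)
        total_ll = 0.0
        for s in seqs:
            logb = _emission_logpdf(s, means, sds)
            gamma, xi_sum, g0, ll = _forward_backward(logb, transition, initial)
            total_ll += ll
            g_sum += gamma.sum(axis=0)
            gx_sum += gamma.T @ s
            gxx_sum += gamma.T @ (s * s)
            xi_total += xi_sum
            g0_sum += g0
            g_trans_denom += gamma[:-1].sum(axis=0)
        ll_hist.append(total_ll)
        if total_ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: "
                f"{prev_ll} -> {total_ll}"
            )
        if np.isfinite(prev_ll) and total_ll - prev_ll < tol:
            converged = True
            break
        prev_ll = total_ll
        # M-step
        initial = g0_sum / g0_sum.sum()
        transition = xi_total / g_trans_denom[:, None]
        transition /= transition.sum(axis=1, keepdims=True)
        means = gx_sum / g_sum
        var = gxx_sum / g_sum - means**2
        sds = np.sqrt(np.maximum(var, 0.0))
        if np.any(sds < sd_floor):
            floored = True
            sds = np.maximum(sds, sd_floor)

    if floored:
        log.info("emission sd collapsed below %.2f during EM; floored", sd_floor)
    order = np.argsort(means)
    fit = HMMFit(
        means=means[order],
        sds=sds[order],
        transition=transition[np.ix_(order, order)],
        initial=initial[order],
        log_likelihood=float(ll_hist[-1]),
        n_iter=n_iter,
        converged=converged,
        sd_floored=floored,
        ll_history=np.asarray(ll_hist),
    )
    return fit


def forward_loglik(fit: HMMFit, sequence: np.ndarray) -> float:
    """Forward-algorithm log-likelihood of one sequence under the model."""
    s = np.asarray(sequence, dtype=float)
    logb = _emission_logpdf(s, fit.means, fit.sds)
    _, _, _, ll = _forward_backward(logb, fit.transition, fit.initial)
    return ll


def decode_states(fit: HMMFit, sequence: np.ndarray, tag_id: str = "") -> StatePath:
    """Viterbi path plus forward-backward posteriors for one tag."""
    s = np.asarray(sequence, dtype=float)
    logb = _emission_logpdf(s, fit.means, fit.sds)
    T = len(s)
    log_trans = np.log(fit.transition)
    delta = np.log(fit.initial) + logb[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logb[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    gamma, _, _, _ = _forward_backward(logb, fit.transition, fit.initial)
    frac_mobile = float(np.mean(states == 1))
    tied = abs(frac_mobile - 0.5) < 1e-12
    if tied:
        # exact 50/50 path: break toward mobile (conservative for mortality)
        dominant = "mobile"
        log.warning("tag %s: 50/50 state path, tie broken toward mobile", tag_id)
    else:
        dominant = STATE_NAMES[int(frac_mobile > 0.5)]
    return StatePath(
        tag_id=tag_id,
        states=states,
        posterior_mobile=gamma[:, 1],
        dominant_state=dominant,
        dominant_fraction=max(frac_mobile, 1.0 - frac_mobile),
        tied=tied,
    )


def classify_tags(paths: Sequence[StatePath]) -> dict[str, str]:
    """Per-tag mobile/non-mobile label from the dominant decoded state.

    Deployments are expected to sit in one state throughout; a dominant
    fraction below 0.95 (a mid-deployment switch) is logged as unusual.
    """
    labels: dict[str, str] = {}
    for p in paths:
        if p.dominant_fraction < 0.95 and not p.tied:
            log.warning(
                "tag %s: dominant state holds only %.0f%% of the path",
                p.tag_id,
                100 * p.dominant_fraction,
            )
        labels[p.tag_id] = p.dominant_state
    return labels


def sample_hmm(
    means: Sequence[float],
    sds: Sequence[float],
    transition: np.ndarray,
    initial: Sequence[float],
    n_windows: int,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (observations, states) from a Gaussian HMM; for testing."""
    rng = np.random.default_rng(seed)
    transition = np.asarray(transition, dtype=float)
    states = np.empty(n_windows, dtype=int)
    states[0] = rng.choice(len(means), p=np.asarray(initial, dtype=float))
    for t in range(1, n_windows):
        states[t] = rng.choice(len(means), p=transition[states[t - 1]])
    obs = rng.normal(np.asarray(means)[states], np.asarray(sds)[states])
    return obs, states
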