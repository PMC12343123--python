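"""Stillness, bout and tilt summaries, and Lomb-Scargle periodicity screening.

A summary window is "still" when its mean tag mobility falls below the
cutoff of 9, the value consistent with only gravity (-1 g) acting on the
tag.  Stillness percentages are computed over *received* windows only
(transmission dropout leaves gaps); bout durations bridge short gaps, since
a handful of missing windows inside an otherwise continuous still period
does not interrupt the underlying behaviour.

Periodicity in mobility (or depth) is screened with the Lomb-Scargle
periodogram, which accepts the irregular sampling left by dropout, over
periods of 6 h to 10 days.  Significance of the peak is assessed by a
seeded permutation test; an analytic false-alarm bound is reported for
reference but the permutation value is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .tag_model import MobilitySeries

STILL_CUTOFF = 9.0


@dataclass
class ActivitySummary:
    """Per-tag activity summary: the four ordination inputs plus support."""

    tag_id: str
    mean_mobility: float
    pct_still: float
    n_long_still_bouts: int
    hours_tilted: float
    pct_time_tilted: float
    detachment_type: str
    n_windows_received: int = 0
    longest_still_bout_h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pct_still", "pct_time_tilted"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PeriodogramResult:
    """Normalized Lomb-Scargle periodogram with its peak."""

    periods_h: np.ndarray
    power: np.ndarray
    peak_period_h: float
    pn_max: float
    p_value: float | None = None
    fap_analytic: float | None = None
    no_variance: bool = False


def classify_stillness(
    ms: MobilitySeries, cutoff: float = STILL_CUTOFF
) -> tuple[np.ndarray, float]:
    """Flag each received window still (mean mobility < cutoff) and return
    the still fraction.

    A window at exactly the cutoff counts as not-still (conservative toward
    activity).
    """
    if ms.n_windows == 0:
        raise ValueError("mobility series has no windows")
    flags = ms.mean_mobility < cutoff
    return flags, float(flags.mean())


def still_bouts(
    flags: np.ndarray,
    window_hours: float,
    min_hours: float = 24.0,
    window_start_s: np.ndarray | None = None,
    max_gap_h: float = 6.0,
) -> tuple[int, np.ndarray]:
    """Count still bouts strictly longer than ``min_hours``.

    A bout is a maximal run of still windows; when ``window_start_s`` is
    given (series with transmission gaps), gaps up to ``max_gap_h`` between
    consecutive received still windows are bridged and contribute to the
    bout duration, while a not-still window always ends the bout.
    """
    flags = np.asarray(flags, dtype=bool)
    n = len(flags)
    if window_start_s is None:
        window_start_s = np.arange(n) * window_hours * 3600.0
    starts_h = np.asarray(window_start_s, dtype=float) / 3600.0
    durations = []
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and flags[j + 1]
            and starts_h[j + 1] - (starts_h[j] + window_hours) <= max_gap_h
        ):
            j += 1
        durations.append(starts_h[j] + window_hours - starts_h[i])
        i = j + 1
    durations = np.asarray(durations)
    count = int(np.sum(durations > min_hours))
    return count, durations


def tilt_hours(ms: MobilitySeries) -> tuple[float, float]:
    """Total hours the tag was tilted (not upright) and the tilted fraction."""
    pu = ms.pct_upright
    if np.any((pu < 0) | (pu > 1)):
        raise ValueError("pct_upright must lie in [0, 1]")
    hours = float(np.sum(ms.window_hours * (1.0 - pu)))
    total = ms.n_windows * ms.window_hours
    return hours, hours / total if total else 0.0


def summarize_activity(
    ms: MobilitySeries,
    detachment_type: str,
    cutoff: float = STILL_CUTOFF,
    long_bout_hours: float = 24.0,
) -> ActivitySummary:
    """Build the per-tag activity summary used for ordination and fate calls."""
    flags, pct_still = classify_stillness(ms, cutoff)
    n_long, durations = still_bouts(
        flags, ms.window_hours, long_bout_hours, ms.window_start_s
    )
    hours_tilted, pct_tilted = tilt_hours(ms)
    return ActivitySummary(
        tag_id=ms.tag_id,
        mean_mobility=float(ms.mean_mobility.mean()),
        pct_still=pct_still,
        n_long_still_bouts=n_long,
        hours_tilted=hours_tilted,
        pct_time_tilted=pct_tilted,
        detachment_type=detachment_type,
        n_windows_received=ms.n_windows,
        longest_still_bout_h=float(durations.max()) if len(durations) else 0.0,
    )


def lomb_scargle(
    times_s: np.ndarray,
    values: np.ndarray,
    min_period_h: float = 6.0,
    max_period_h: float = 240.0,
    oversample: float = 5.0,
) -> PeriodogramResult:
    """Normalized Lomb-Scargle periodogram over a 6 h - 10 d period grid.

    Power is normalized by the variance of the (mean-subtracted) series so
    it is invariant to adding a constant or rescaling the values and lies in
    [0, 1]; PN_max is the peak normalized power.  Needs at least 8 finite
    samples at strictly increasing times; gaps are allowed, which is the
    point of using Lomb-Scargle.  A constant series carries no periodicity
    information and is flagged (p = 1).
    """
    t = np.asarray(times_s, dtype=float) / 3600.0  # hours
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 8:
        raise ValueError("need at least 8 finite samples for a periodogram")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    span = t[-1] - t[0]
    max_period_h = min(max_period_h, span)
    freqs = _frequency_grid(span, min_period_h, max_period_h, oversample)
    if np.var(y) == 0.0:
        return PeriodogramResult(
            periods_h=1.0 / freqs,
            power=np.zeros_like(freqs),
            peak_period_h=np.nan,
            pn_max=0.0,
            p_value=1.0,
            no_variance=True,
        )
    power = _normalized_power(t, y, freqs)
    k = int(np.argmax(power))
    pr = PeriodogramResult(
        periods_h=1.0 / freqs,
        power=power,
        peak_period_h=float(1.0 / freqs[k]),
        pn_max=float(power[k]),
    )
    pr.fap_analytic = _analytic_fap(pr.pn_max, len(t), len(freqs), oversample)
    return pr


def _frequency_grid(
    span_h: float, min_period_h: float, max_period_h: float, oversample: float
) -> np.ndarray:
    if max_period_h <= min_period_h:
        raise ValueError("series too short for the requested period range")
    df = 1.0 / (oversample * span_h)
    return np.arange(1.0 / max_period_h, 1.0 / min_period_h + df, df)


def _normalized_power(t: np.ndarray, y: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    # scipy normalize=True divides by the sum of squares of the centered data
    return lombscargle(t, yc, 2.0 * np.pi * freqs, normalize=True)


def _analytic_fap(z: float, n: int, n_freq: int, oversample: float) -> float:
    """Rough analytic false-alarm bound for the peak normalized power.

    Single-frequency tail for the variance-normalized periodogram,
    Bonferroni-corrected by the number of effectively independent
    frequencies; reported for reference only.
    """
    m_eff = max(1.0, n_freq / oversample)
    single = (1.0 - z) ** max((n - 3) / 2.0, 0.5)
    return float(min(1.0, m_eff * single))


def periodogram_significance(
    pr: PeriodogramResult,
    times_s: np.ndarray,
    values: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    min_period_h: float = 6.0,
    max_period_h: float = 240.0,
    oversample: float = 5.0,
) -> float:
    """Permutation p-value for the periodogram peak.

    Values are shuffled across the fixed observation times; the p-value is
    (1 + #{permuted PN_max >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve p = 0.05")
    if pr.no_variance:
        pr.p_value = 1.0
        return 1.0
    t = np.asarray(times_s, dtype=float) / 3600.0
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    span = t[-1] - t[0]
    freqs = _frequency_grid(span, min_period_h, min(max_period_h, span), oversample)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if _normalized_power(t, perm, freqs).max() >= pr.pn_max:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    pr.p_value = p
    return p


def event_alignment(
    times_s: np.ndarray,
    values: np.ndarray,
    event_times_s: np.ndarray,
    threshold: float,
    window_days: float = 2.0,
) -> float:
    """Fraction of above-threshold values falling within a window of events.

    Generic alignment statistic (e.g. high mobility values within 2 days of
    spring tides); no tide model is built in - event times are an input.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    ev = np.asarray(event_times_s, dtype=float)
    high = v > threshold
    if not np.any(high):
        return float("nan")
    near = np.zeros(len(t), dtype=bool)
    w = window_days * 86400.0
    for e in ev:
        near |= np.abs(t - e) <= w
    return float(np.mean(near[high]))
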