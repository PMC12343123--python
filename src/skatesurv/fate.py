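"""Vertical-movement evidence, activity ordination, and per-tag fate calls.

A skate that is alive and active produces depth excursions larger than the
depth sensor's error band (+/-1% of reading, i.e. +/-13-18 m at 1300-1800 m);
a dead animal's transmitted depth is flat to within that band.  Movement is
therefore judged against the accuracy band at the tag's median benthic
depth, after trimming the post-release descent and any post-detachment
surface drift.  A single one-off downward level shift (an animal or carcass
sliding deeper once, or a bin-boundary artefact) is counted separately and
does not by itself flag movement.

Activity summaries (mean mobility, stillness, tilt, detachment type) are
range-scaled, turned into a Bray-Curtis dissimilarity matrix and ordinated
with non-metric multidimensional scaling as a diagnostic of cluster
structure; the ordination informs but does not decide fate calls.

The fate call itself is a total, ordered rule table:

  R1  vertical movement beyond the error band          -> survivor
  R2  no movement and HMM non-mobile                   -> mortality
  R3  no movement but HMM mobile                       -> ambiguous
  R0  insufficient benthic data / missing evidence     -> ambiguous
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .activity import ActivitySummary
from .tag_model import DepthSeries, SensorModel, DEFAULT_SENSOR, sensor_accuracy

log = logging.getLogger(__name__)

FATES = ("survivor", "mortality", "ambiguous")


@dataclass
class MovementEvidence:
    """Per-tag vertical-movement evidence against the sensor error band."""

    tag_id: str
    benthic_depth_range: float
    error_band: float
    movement_flag: bool
    max_excursion: float
    downward_shifts: int = 0
    insufficient: bool = False
    benthic_hours: float = 0.0


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    tag_ids: list[str] = field(default_factory=list)


@dataclass
class FateCall:
    tag_id: str
    fate: str
    rule_id: str
    evidence: dict


def _benthic_span(
    ds: DepthSeries,
    sm: SensorModel,
    trim_hours: float = 1.0,
    surface_depth_m: float = 100.0,
) -> np.ndarray:
    """Boolean mask of the benthic phase of a transmitted depth series.

    The first ``trim_hours`` after release (descent) and trailing
    post-detachment surface records are dropped; the benthic span then runs
    from the first *stationary* summary window - one whose within-window
    depth range is at most twice the accuracy band at its median, i.e. the
    animal has settled on the bottom - through the end.  Simulator phase
    labels, when present, are honoured.
    """
    n = len(ds.time_s)
    mask = np.ones(n, dtype=bool)
    if ds.phase is not None:
        mask &= np.asarray(ds.phase) == "benthic"
    mask &= ds.time_s >= trim_hours * 3600.0
    # trailing surface drift after detachment
    surface = ds.depth_m < surface_depth_m
    if np.any(surface):
        last_deep = np.flatnonzero(~surface)
        if len(last_deep):
            mask[last_deep[-1] + 1 :] = False
        else:
            return np.zeros(n, dtype=bool)
    if not np.any(mask):
        return mask
    idx = np.flatnonzero(mask)
    win = ds.window_id[idx]
    start = None
    for w in np.unique(win):
        d = ds.depth_m[idx[win == w]]
        med = float(np.median(d))
        if d.max() - d.min() <= 2.0 * sensor_accuracy(med, sm.accuracy_fraction):
            start = idx[win == w][0]
            break
    if start is None:
        return np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    out[start:] = mask[start:]
    return out


def _single_step_split(depth: np.ndarray, band: float) -> tuple[bool, int]:
    """Test whether deviations are explained by one downward level shift.

    Scans changepoints on the window-median series; the series is a single
    downward step when the segments before and after are each flat within
    the error band around their own medians and the level difference
    exceeds the band.  A step falling inside a summary window leaves one
    transition window whose median sits between the two levels, so each
    candidate changepoint is also tried with that single boundary window
    set aside, provided its value lies between the levels.  Returns
    (is_single_down_step, n_downward_shifts).
    """
    n = len(depth)
    if n < 4:
        return False, 0
    for k in range(1, n - 1):
        for skip_boundary in (False, True):
            lo = depth[:k]
            hi = depth[k + 1 :] if skip_boundary else depth[k:]
            if len(lo) < 2 or len(hi) < 2:
                continue
            m1, m2 = np.median(lo), np.median(hi)
            if not (
                np.max(np.abs(lo - m1)) <= band
                and np.max(np.abs(hi - m2)) <= band
                and (m2 - m1) > band
            ):
                continue
            if skip_boundary and not (
                m1 - band <= depth[k] <= m2 + band
            ):
                continue
            return True, 1
    return False, 0


def detect_vertical_movement(
    ds: DepthSeries,
    sm: SensorModel = DEFAULT_SENSOR,
    min_benthic_hours: float = 6.0,
) -> MovementEvidence:
    """Movement evidence for one tag from its transmitted depth series.

    Flags movement when the maximum absolute deviation from the benthic
    median exceeds the accuracy half-width at that median.  A pattern fully
    explained by a single downward level shift is recorded as a shift, not
    movement.  Less than ``min_benthic_hours`` of benthic data yields
    insufficient evidence (fate forced ambiguous downstream).
    """
    mask = _benthic_span(ds, sm)
    benthic_hours = float(mask.sum()) * 150.0 / 3600.0 if np.any(mask) else 0.0
    if benthic_hours < min_benthic_hours:
        return MovementEvidence(
            tag_id=ds.tag_id,
            benthic_depth_range=np.nan,
            error_band=np.nan,
            movement_flag=False,
            max_excursion=np.nan,
            insufficient=True,
            benthic_hours=benthic_hours,
        )
    depth = ds.depth_m[mask]
    median = float(np.median(depth))
    band = float(sensor_accuracy(median, sm.accuracy_fraction))
    max_exc = float(np.max(np.abs(depth - median)))
    flag = max_exc > band
    shifts = 0
    if flag:
        # window medians smooth bin-decode noise before the changepoint scan
        win = ds.window_id[mask]
        uniq = np.unique(win)
        wmed = np.array([np.median(depth[win == w]) for w in uniq])
        is_step, shifts = _single_step_split(wmed, band)
        if is_step:
            flag = False
    return MovementEvidence(
        tag_id=ds.tag_id,
        benthic_depth_range=float(depth.max() - depth.min()),
        error_band=band,
        movement_flag=flag,
        max_excursion=max_exc,
        downward_shifts=shifts,
        benthic_hours=benthic_hours,
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def activity_feature_matrix(
    summaries: Sequence[ActivitySummary],
) -> tuple[np.ndarray, list[str]]:
    """Range-scaled [0, 1] feature matrix for ordination.

    Features: mean mobility, hours tilted, fraction still, and detachment
    type coded early = 1, scheduled / pin-intact = 0.  Range scaling keeps
    hour-scale features from dominating the unit-free ones.
    """
    raw = np.array(
        [
            [
                s.mean_mobility,
                s.hours_tilted,
                s.pct_still,
                1.0 if s.detachment_type == "early" else 0.0,
            ]
            for s in summaries
        ]
    )
    rng_ = raw.max(axis=0) - raw.min(axis=0)
    rng_[rng_ == 0] = 1.0
    scaled = (raw - raw.min(axis=0)) / rng_
    return scaled, [s.tag_id for s in summaries]


def bray_curtis(features: np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix sum|x-y| / sum(x+y) on scaled features."""
    f = np.asarray(features, dtype=float)
    if np.any(f < 0):
        raise ValueError("features must be non-negative after range scaling")
    d = squareform(pdist(f, metric="braycurtis"))
    return np.nan_to_num(d, nan=0.0)  # identical all-zero rows -> 0


def nmds(
    d: np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix; best of ``n_restarts``.

    Stress is Kruskal's stress-1, recomputed from the returned embedding by
    isotonic regression of configuration distances on the input
    dissimilarities; stress 0.009 on well-structured data indicates a
    near-perfect rank fit.  The first restart is initialized from the
    classical (principal-coordinates) solution, the remainder from seeded
    random configurations; the lowest-stress non-degenerate restart wins.
    Rank-only stress admits degenerate zero-stress embeddings that collapse
    distinct points onto each other, so restarts that coincide points with
    clearly non-zero dissimilarity are set aside unless nothing else
    converged.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 4:
        raise ValueError("need a square dissimilarity matrix with n >= 4")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.all(d == 0):
        log.warning("all dissimilarities zero: degenerate ordination")
        return OrdinationResult(np.zeros((n, k)), 0.0, n_restarts, True)

    def _fit(init: str, rs: int) -> np.ndarray:
        common = dict(
            n_components=k,
            n_init=1,
            max_iter=max_iter,
            random_state=rs,
            normalized_stress=True,
            eps=1e-9,
        )
        try:
            mds = MDS(metric="precomputed", metric_mds=False, init=init, **common)
        except TypeError:  # older scikit-learn API, no init parameter
            mds = MDS(metric=False, dissimilarity="precomputed", **common)
        return mds.fit_transform(d)

    iu = np.triu_indices(n, 1)
    scale = d[iu].max()
    best: tuple[float, np.ndarray] | None = None
    best_degen: tuple[float, np.ndarray] | None = None
    for r in range(max(1, n_restarts)):
        init = "classical_mds" if r == 0 else "random"
        coords = _fit(init, seed + r)
        s1 = kruskal_stress1(d, coords)
        emb = squareform(pdist(coords))[iu]
        collapsed = (emb < 1e-9 * max(emb.max(), 1.0)) & (d[iu] > 0.05 * scale)
        degenerate = bool(np.mean(collapsed) > 0.0)
        slot = (s1, coords)
        if degenerate:
            if best_degen is None or s1 < best_degen[0]:
                best_degen = slot
        elif best is None or s1 < best[0]:
            best = slot
    stress, coords = best if best is not None else best_degen  # type: ignore[misc]
    return OrdinationResult(
        coordinates=coords,
        stress=float(stress),
        n_restarts=n_restarts,
        converged=bool(np.isfinite(stress)),
    )


def kruskal_stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (dist - disparity)^2 / sum dist^2)."""
    iu = np.triu_indices(d.shape[0], 1)
    dist = squareform(pdist(coords))[iu]
    diss = d[iu]
    disp = IsotonicRegression().fit_transform(diss, dist)
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


# ---------------------------------------------------------------------------
# Fate rules
# ---------------------------------------------------------------------------

def call_fate(
    ev: MovementEvidence | None,
    hmm_label: str | None,
    act: ActivitySummary | None,
) -> FateCall:
    """Apply the ordered fate rule table to one tag's evidence.

    Exactly one rule fires.  Early detachment is recorded as evidence (a
    strong mortality indicator in practice) but does not itself decide the
    call; vertical movement and the mobility state do.
    """
    tag_id = next(
        (x.tag_id for x in (ev, act) if x is not None), "unknown"
    )
    evidence = {
        "movement_flag": ev.movement_flag if ev is not None else None,
        "downward_shifts": ev.downward_shifts if ev is not None else None,
        "hmm_label": hmm_label,
        "pct_still": act.pct_still if act is not None else None,
        "n_long_still_bouts": act.n_long_still_bouts if act is not None else None,
        "hours_tilted": act.hours_tilted if act is not None else None,
        "detachment_type": act.detachment_type if act is not None else None,
    }
    if ev is None or hmm_label is None or act is None:
        return FateCall(tag_id, "ambiguous", "R0-insufficient-evidence", evidence)
    if ev.insufficient:
        return FateCall(tag_id, "ambiguous", "R0-insufficient-benthic", evidence)
    if ev.movement_flag:
        return FateCall(tag_id, "survivor", "R1-vertical-movement", evidence)
    if hmm_label == "non_mobile":
        return FateCall(tag_id, "mortality", "R2-non-mobile-no-movement", evidence)
    return FateCall(tag_id, "ambiguous", "R3-mobile-no-movement", evidence)


def count_fates(
    calls: Sequence[FateCall],
    ambiguous_as: str = "mortality",
    exclude_controls: Sequence[str] = (),
) -> tuple[int, int]:
    """(survivors k, total n) for the binomial estimate.

    ``ambiguous_as`` maps ambiguous calls to mortality (default, matching
    the headline treatment of the two unresolved tags), survivor, or
    excludes them; control tags are excluded from n.
    """
    if ambiguous_as not in ("mortality", "survivor", "excluded"):
        raise ValueError(f"invalid ambiguous_as: {ambiguous_as!r}")
    k = n = 0
    for c in calls:
        if c.tag_id in exclude_controls:
            continue
        fate = c.fate
        if fate == "ambiguous":
            if ambiguous_as == "excluded":
                continue
            fate = ambiguous_as
        n += 1
        k += fate == "survivor"
    return k, n
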