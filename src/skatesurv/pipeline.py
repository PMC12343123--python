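"""End-to-end orchestration: simulate -> summarize -> classify -> estimate.

Holds the validated pipeline configuration (all the thresholds of the
analysis with their instrument/analysis defaults), the in-memory cohort
classifier used by the tests and drivers, and the staged file pipeline
behind the command-line interface.  Every stage is deterministic given the
configuration and its seeds; a short hash of the canonical configuration is
recorded in the run log and report so outputs can be traced to the exact
settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import fate as fate_mod
from . import mobility_hmm as hmm_mod
from . import survival as surv_mod
from . import synthetic_tags as synth
from . import tag_model as tm

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    seed: int = 7
    composition: dict = field(
        default_factory=lambda: dict(synth.DEFAULT_COMPOSITION)
    )
    window_hours: float = 2.0
    still_cutoff: float = 9.0
    upright_threshold: float = -0.75
    n_steps: int = 16
    long_bout_hours: float = 24.0
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    nmds_restarts: int = 20
    min_benthic_hours: float = 6.0
    ambiguous_as: str = "mortality"
    ci_method: str = "wilson"
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        if self.still_cutoff <= 0:
            raise ConfigError(f"still_cutoff must be > 0, got {self.still_cutoff}")
        if not -1.0 <= self.upright_threshold <= 0.0:
            raise ConfigError(
                f"upright_threshold must lie in [-1, 0] g, got "
                f"{self.upright_threshold}"
            )
        if self.n_steps < 1:
            raise ConfigError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.ambiguous_as not in ("mortality", "survivor", "excluded"):
            raise ConfigError(f"invalid ambiguous_as: {self.ambiguous_as!r}")
        if self.ci_method not in ("wilson", "exact", "normal"):
            raise ConfigError(f"invalid ci_method: {self.ci_method!r}")
        if not 0.5 < self.conf_level < 1.0:
            raise ConfigError(f"conf_level must lie in (0.5, 1), got {self.conf_level}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class CohortClassification:
    """Everything the classifier derives for one cohort, in memory."""

    summaries: list[act.ActivitySummary]
    hmm_fit: hmm_mod.HMMFit
    state_paths: list[hmm_mod.StatePath]
    hmm_labels: dict[str, str]
    evidence: dict[str, fate_mod.MovementEvidence]
    calls: list[fate_mod.FateCall]
    ordination: fate_mod.OrdinationResult | None
    estimate: surv_mod.SurvivalEstimate

    @property
    def fates(self) -> dict[str, str]:
        return {c.tag_id: c.fate for c in self.calls}


def classify_cohort(
    cohort: list[synth.SyntheticDeployment] | list[tuple],
    cfg: PipelineConfig | None = None,
    run_nmds: bool = True,
) -> CohortClassification:
    """Classify a cohort of deployments and estimate survival.

    Accepts either simulated deployments or (TagDeployment, DepthSeries,
    MobilitySeries) triples read from files.
    """
    cfg = cfg or PipelineConfig()
    triples = [
        (c.deployment, c.depth_series, c.mobility_series)
        if isinstance(c, synth.SyntheticDeployment)
        else c
        for c in cohort
    ]
    summaries = [
        act.summarize_activity(
            ms, dep.detachment_type, cfg.still_cutoff, cfg.long_bout_hours
        )
        for dep, _, ms in triples
    ]
    sequences = [ms.mean_mobility for _, _, ms in triples]
    fit = hmm_mod.fit_hmm(sequences, tol=cfg.hmm_tol, max_iter=cfg.hmm_max_iter)
    paths = [
        hmm_mod.decode_states(fit, ms.mean_mobility, ms.tag_id)
        for _, _, ms in triples
    ]
    labels = hmm_mod.classify_tags(paths)
    evidence = {
        ds.tag_id: fate_mod.detect_vertical_movement(
            ds, min_benthic_hours=cfg.min_benthic_hours
        )
        for _, ds, _ in triples
    }
    calls = [
        fate_mod.call_fate(evidence[dep.tag_id], labels[dep.tag_id], s)
        for (dep, _, _), s in zip(triples, summaries)
    ]
    ordination = None
    if run_nmds and len(summaries) >= 4:
        feats, _ = fate_mod.activity_feature_matrix(summaries)
        ordination = fate_mod.nmds(
            fate_mod.bray_curtis(feats), n_restarts=cfg.nmds_restarts, seed=cfg.seed
        )
    controls = [dep.tag_id for dep, _, _ in triples if dep.is_control]
    k, n = fate_mod.count_fates(calls, cfg.ambiguous_as, exclude_controls=controls)
    estimate = surv_mod.survival_estimate(k, n, cfg.conf_level, cfg.ci_method)
    return CohortClassification(
        summaries=summaries,
        hmm_fit=fit,
        state_paths=paths,
        hmm_labels=labels,
        evidence=evidence,
        calls=calls,
        ordination=ordination,
        estimate=estimate,
    )


# ---------------------------------------------------------------------------
# Staged file pipeline
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synth.simulate_cohort(cfg.composition, seed=cfg.seed)
    tm.write_deployments([c.deployment for c in cohort], outdir / "deployments.csv")
    for c in cohort:
        tag = c.deployment.tag_id
        tm.write_depth_series(c.depth_series, outdir / f"series_{tag}.csv")
        tm.write_mobility_series(c.mobility_series, outdir / f"summaries_{tag}.csv")
    synth.truth_table(cohort).to_csv(outdir / "truth.csv", index=False)
    log.info("simulated %d tags into %s", len(cohort), outdir)


def load_cohort(outdir: str | Path) -> list[tuple]:
    outdir = Path(outdir)
    deployments = tm.read_deployments(outdir / "deployments.csv")
    triples = []
    for dep in deployments:
        ds = tm.read_depth_series(outdir / f"series_{dep.tag_id}.csv", dep.tag_id)
        ms = tm.read_mobility_series(
            outdir / f"summaries_{dep.tag_id}.csv", dep.tag_id
        )
        triples.append((dep, ds, ms))
    return triples


def stage_summarize(cfg: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    triples = load_cohort(outdir)
    rows = []
    for dep, _, ms in triples:
        s = act.summarize_activity(
            ms, dep.detachment_type, cfg.still_cutoff, cfg.long_bout_hours
        )
        rows.append(asdict(s))
    pd.DataFrame(rows).to_csv(outdir / "activity.csv", index=False)


def stage_classify(cfg: PipelineConfig, outdir: str | Path) -> CohortClassification:
    outdir = Path(outdir)
    triples = load_cohort(outdir)
    result = classify_cohort(triples, cfg)
    fit = result.hmm_fit
    (outdir / "hmm_fit.json").write_text(
        json.dumps(
            {
                "means": fit.means.tolist(),
                "sds": fit.sds.tolist(),
                "transition": fit.transition.tolist(),
                "initial": fit.initial.tolist(),
                "log_likelihood": fit.log_likelihood,
                "n_iter": fit.n_iter,
                "converged": fit.converged,
                "config_hash": cfg.hash(),
            },
            indent=2,
        )
    )
    for (_, _, ms), path in zip(triples, result.state_paths):
        pd.DataFrame(
            {
                "window_start_s": ms.window_start_s,
                "viterbi_state": np.array(hmm_mod.STATE_NAMES)[path.states],
                "posterior_mobile": path.posterior_mobile,
            }
        ).to_csv(outdir / f"states_{ms.tag_id}.csv", index=False)
    rows = []
    for c in result.calls:
        row = {"tag_id": c.tag_id, "fate": c.fate, "rule_id": c.rule_id}
        row.update(c.evidence)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "fates.csv", index=False)
    if result.ordination is not None:
        ids = [s.tag_id for s in result.summaries]
        pd.DataFrame(
            {
                "tag_id": ids,
                "axis1": result.ordination.coordinates[:, 0],
                "axis2": result.ordination.coordinates[:, 1],
            }
        ).to_csv(outdir / "ordination.csv", index=False)
        log.info("NMDS stress-1 = %.4f", result.ordination.stress)
    return result


def stage_estimate(cfg: PipelineConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    fates = pd.read_csv(outdir / "fates.csv")
    deployments = tm.read_deployments(outdir / "deployments.csv")
    controls = {d.tag_id for d in deployments if d.is_control}
    calls = [
        fate_mod.FateCall(r.tag_id, r.fate, r.rule_id, {})
        for r in fates.itertuples()
    ]
    k, n = fate_mod.count_fates(calls, cfg.ambiguous_as, exclude_controls=controls)
    est = surv_mod.survival_estimate(k, n, cfg.conf_level, cfg.ci_method)
    payload = {
        "k_survivors": est.k_survivors,
        "n": est.n,
        "proportion": est.proportion,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "conf_level": est.conf_level,
        "method": est.method,
        "ambiguous_as": cfg.ambiguous_as,
        "config_hash": cfg.hash(),
    }
    (outdir / "survival.json").write_text(json.dumps(payload, indent=2))
    pc = surv_mod.ci_width_curve(max(est.proportion, 1.0 / (2 * n)), n_ref=n)
    pd.DataFrame({"n": pc.n_grid, "width": pc.widths}).to_csv(
        outdir / "power_curve.csv", index=False
    )
    # survival GLM against capture covariates
    fate_map = dict(zip(fates.tag_id, fates.fate))
    rows = []
    for d in deployments:
        if d.is_control:
            continue
        f = fate_map.get(d.tag_id)
        if f == "ambiguous":
            if cfg.ambiguous_as == "excluded":
                continue
            f = cfg.ambiguous_as
        rows.append(
            {
                "tag_id": d.tag_id,
                "capture_depth_m": d.capture_depth_m,
                "total_length_mm": d.total_length_mm,
                "sex": d.sex,
                "time_out_water_min": d.time_out_water_min,
                "soak_time_h": d.soak_time_h,
                "survived": int(f == "survivor"),
            }
        )
    glm_table = pd.DataFrame(rows)
    try:
        res = surv_mod.fit_survival_glm(glm_table)
        glm_df = pd.DataFrame(
            {
                "term": res.params.index,
                "estimate": res.params.values,
                "se": res.bse.values,
                "p": res.pvalues.values,
            }
        )
        glm_df.attrs["separation_flag"] = res.separation_flag
        payload["separation_flag"] = res.separation_flag
        if res.separation_flag:
            # separated fits have unbounded coefficients: suppress the OR
            log.warning("survival GLM quasi-separated; odds ratio suppressed")
            payload["glm_error"] = (
                "quasi-separation: depth odds ratio not estimable at this n; "
                "a penalized refit would be needed"
            )
        else:
            payload["or_per_100m_shallower"] = res.or_per_100m_shallower
    except Exception as exc:  # small cohorts can separate or degenerate
        log.warning("survival GLM not fitted: %s", exc)
        glm_df = pd.DataFrame({"term": [], "estimate": [], "se": [], "p": []})
        payload["glm_error"] = str(exc)
    glm_df.to_csv(outdir / "glm.csv", index=False)
    (outdir / "survival.json").write_text(json.dumps(payload, indent=2))
    return payload


def stage_report(cfg: PipelineConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    payload = json.loads((outdir / "survival.json").read_text())
    fates = pd.read_csv(outdir / "fates.csv")
    counts = fates["fate"].value_counts().to_dict()
    lines = [
        "# Post-release survival report",
        "",
        f"config hash: `{cfg.hash()}`",
        "",
        "## Fate calls",
        "",
        *(f"- {fate}: {n}" for fate, n in sorted(counts.items())),
        "",
        "## Survival estimate",
        "",
        (
            f"{payload['k_survivors']}/{payload['n']} survivors -> "
            f"{100 * payload['proportion']:.0f}% "
            f"({payload['conf_level']:.0%} {payload['method']} CI "
            f"{100 * payload['ci_low']:.0f}-{100 * payload['ci_high']:.0f}%), "
            f"ambiguous counted as {payload['ambiguous_as']}."
        ),
        "",
    ]
    if "or_per_100m_shallower" in payload:
        lines += [
            "## Depth effect",
            "",
            f"Odds of survival per 100 m shallower: "
            f"{payload['or_per_100m_shallower']:.2f}",
            "",
        ]
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """simulate -> summarize -> classify -> estimate -> report."""
    outdir = Path(outdir)
    stage_simulate(cfg, outdir)
    stage_summarize(cfg, outdir)
    stage_classify(cfg, outdir)
    payload = stage_estimate(cfg, outdir)
    stage_report(cfg, outdir)
    (outdir / "run_log.json").write_text(
        json.dumps({"config_hash": cfg.hash(), "config": asdict(cfg)}, indent=2)
    )
    return payload
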