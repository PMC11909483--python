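"""End-to-end orchestration: simulate -> score -> estimate -> explain.

A run is configured by a :class:`RunConfig` (YAML-loadable) naming either
the four input CSV tables (baseline, arm assignment, weekly usage,
follow-up) or a synthetic-trial generator configuration — exactly one of
the two.  The pipeline stages are ordered so the compliance model only
ever sees baseline covariates (a temporal firewall enforced at run time),
and all randomness is derived from one master seed via per-stage child
seeds, so a rerun of the same configuration is byte-identical.

Outputs: an average-treatment-effect report (per-arm adjusted estimates
with pairwise ARD/AMD contrasts and 2-df overall tests, at 3 and 12
months, for joint remission and mean PHQ-ADS), predicted-compliance
stratified tables with the interaction test, an attrition report, usage
summaries per period, a SHAP attribution report, and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, codebook, compliance, estimation, heterogeneity
from . import shap_explain, superlearner
from . import synthetic_trial as st
from .codebook import ARMS, COVARIATE_NAMES, DOMAIN_MAP
from .estimation import EstimandSpec, EstimatorOptions, ImputationConfig
from .scales import GAD7_MAX, PHQ9_MAX

logger = logging.getLogger(__name__)

#: follow-up symptom fields that must never reach the compliance model
FIREWALLED_COLUMNS = frozenset({
    "gad7", "phq9", "gad7_3", "phq9_3", "gad7_12", "phq9_12",
    "phq_ads_3", "phq_ads_12", "remission_3", "remission_12",
    "completed_3", "completed_12", "completed",
})


@dataclass
class AnalysisOptions:
    estimator_mode: str = "tmle"
    truncation: float = 0.01
    covariates: tuple[str, ...] = estimation.DEFAULT_ADJUSTMENT_COVARIATES
    mi_m: int = 10
    mi_k: int = 5
    outer_folds: int = 10
    inner_folds: int = 10
    top_fraction: float = 0.40
    shap_budget: int = 512
    learner_library: str = "default"
    attrition_predictors: tuple[str, ...] = (
        "country", "sex", "clinic_status", "sexual_orientation",
    )

    def estimator_options(self) -> EstimatorOptions:
        return EstimatorOptions(
            covariates=tuple(self.covariates),
            truncation=self.truncation,
            mode=self.estimator_mode,
        )


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    inputs: dict[str, str] | None = None       # baseline/arms/usage/followup
    generator: dict | None = None              # GeneratorConfig fields
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.generator is None):
            raise ValueError(
                "exactly one of 'inputs' and 'generator' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        analysis = AnalysisOptions(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("analysis", {}) or {}).items()
        })
        return cls(analysis=analysis, **raw)

    def generator_config(self) -> st.GeneratorConfig:
        params = dict(self.generator or {})
        params.setdefault("seed", _stage_seed(self.seed, 0))
        return st.GeneratorConfig(**params)


def _stage_seed(master: int, stage: int) -> int:
    return int(
        np.random.SeedSequence([int(master) % (2**31), stage]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# input validation


def _issue(file: str, kind: str, detail: str, row=None) -> dict:
    d = {"file": file, "kind": kind, "detail": detail}
    if row is not None:
        d["row"] = int(row)
    return d


def validate_tables(
    baseline: pd.DataFrame,
    arms: pd.DataFrame,
    usage: pd.DataFrame,
    followup: pd.DataFrame,
) -> list[dict]:
    """Schema, range and referential-integrity checks on the four tables."""
    issues: list[dict] = []
    if baseline["participant_id"].duplicated().any():
        issues.append(_issue("baseline", "schema", "duplicate participant_id"))
    ids = set(baseline["participant_id"])
    for cov_issue in codebook.validate_covariate_frame(baseline):
        issues.append(_issue("baseline", "schema", cov_issue))
    for col, hi in (("gad7_0", GAD7_MAX), ("phq9_0", PHQ9_MAX)):
        bad = baseline.index[
            (baseline[col] < 0) | (baseline[col] > hi)
        ]
        for r in bad:
            issues.append(_issue(
                "baseline", "range", f"{col} outside 0-{hi}", r))
    ineligible = baseline.index[
        (baseline["gad7_0"] < 10) & (baseline["phq9_0"] < 10)
    ]
    for r in ineligible:
        issues.append(_issue("baseline", "eligibility",
                             "participant below both eligibility thresholds", r))

    bad_arm = arms.index[~arms["arm"].isin(ARMS)]
    for r in bad_arm:
        issues.append(_issue("arms", "schema", f"unknown arm label", r))
    for name, df in (("arms", arms), ("usage", usage), ("followup", followup)):
        unknown = df.index[~df["participant_id"].isin(ids)]
        for r in unknown:
            issues.append(_issue(
                name, "referential_integrity",
                "participant_id not present in baseline", r))

    week_cols = [c for c in usage.columns if c.startswith("week_")]
    if len(week_cols) != st.N_WEEKS:
        issues.append(_issue(
            "usage", "schema", f"expected {st.N_WEEKS} week columns, "
            f"found {len(week_cols)}"))
    else:
        mat = usage[week_cols].to_numpy(dtype=float)
        bad_rows = np.flatnonzero((mat < 0).any(axis=1))
        for r in bad_rows:
            issues.append(_issue("usage", "range", "negative minutes", r))

    if not followup["wave"].isin((3, 12)).all():
        issues.append(_issue("followup", "schema", "wave must be 3 or 12"))
    comp = followup["completed"].astype(bool)
    for col, hi in (("gad7", GAD7_MAX), ("phq9", PHQ9_MAX)):
        vals = followup[col]
        missing_when_completed = followup.index[comp & vals.isna()]
        for r in missing_when_completed:
            issues.append(_issue("followup", "schema",
                                 f"{col} missing on a completed wave", r))
        present_when_missing = followup.index[~comp & vals.notna()]
        for r in present_when_missing:
            issues.append(_issue("followup", "schema",
                                 f"{col} present on a non-completed wave", r))
        bad = followup.index[comp & ((vals < 0) | (vals > hi))]
        for r in bad:
            issues.append(_issue("followup", "range",
                                 f"{col} outside scale bound 0-{hi}", r))
    return issues


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Validate the four input CSVs; returns a machine-readable issue list."""
    tables = {}
    for key in ("baseline", "arms", "usage", "followup"):
        if key not in paths:
            return [_issue(key, "schema", "input file not configured")]
        tables[key] = pd.read_csv(paths[key])
    return validate_tables(**tables)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunResult:
    ate_report: pd.DataFrame
    stratified: pd.DataFrame
    interaction: heterogeneity.InteractionResult
    attrition: list[heterogeneity.AttritionTable]
    usage_summaries: dict[str, compliance.PeriodSummary]
    scores: pd.DataFrame
    cv_r2: float
    cv_r2_se: float
    shap_summary: pd.DataFrame
    shap_ranked: pd.DataFrame
    manifest: dict
    tables: dict[str, pd.DataFrame]


def _ate_rows(spec: EstimandSpec, res) -> list[dict]:
    rows = []
    for arm, e in res.estimates.items():
        rows.append({
            "outcome": spec.outcome, "wave": spec.wave, "kind": "estimate",
            "arm_or_pair": arm, "value": e.value, "se": e.se,
            "chi2": np.nan, "df": np.nan, "p": np.nan, "n": e.n_arm,
        })
    for a, b in (("guided", "self-guided"), ("guided", "TAU"),
                 ("self-guided", "TAU")):
        c = res.contrast(a, b)
        rows.append({
            "outcome": spec.outcome, "wave": spec.wave, "kind": "contrast",
            "arm_or_pair": f"{a} vs {b}", "value": c.difference, "se": c.se,
            "chi2": c.chi2, "df": c.df, "p": c.p, "n": np.nan,
        })
    o = res.overall()
    rows.append({
        "outcome": spec.outcome, "wave": spec.wave, "kind": "overall",
        "arm_or_pair": "all arms", "value": np.nan, "se": np.nan,
        "chi2": o.chi2, "df": o.df, "p": o.p, "n": np.nan,
    })
    return rows


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; raises before any estimation on invalid
    inputs and never produces partial output bundles."""
    t_start = time.time()
    timings: dict[str, float] = {}
    opts = config.analysis
    est_opts = opts.estimator_options()

    # stage 0: inputs
    t0 = time.time()
    if config.generator is not None:
        gcfg = config.generator_config()
        trial = st.generate_trial(gcfg)
        baseline, arms = trial.baseline, trial.arms
        usage, followup = trial.usage, trial.followup
    else:
        baseline = pd.read_csv(config.inputs["baseline"])
        arms = pd.read_csv(config.inputs["arms"])
        usage = pd.read_csv(config.inputs["usage"])
        followup = pd.read_csv(config.inputs["followup"])
    issues = validate_tables(baseline, arms, usage, followup)
    if issues:
        raise ValueError(
            "input validation failed: "
            + "; ".join(f"{i['file']}[{i.get('row', '-')}]: {i['detail']}"
                        for i in issues[:10])
        )
    timings["inputs"] = time.time() - t0

    # stage 1: compliance scoring (temporal firewall: baseline covariates only)
    t0 = time.time()
    target = compliance.compliance_target(usage)
    X_cols = tuple(COVARIATE_NAMES)
    leaked = set(X_cols) & FIREWALLED_COLUMNS
    assert not leaked, f"follow-up fields leaked into the compliance model: {leaked}"
    library = (superlearner.linear_library() if opts.learner_library == "linear"
               else superlearner.default_library())
    predicted, nested, full_model = superlearner.score_all(
        baseline, arms, target, learners=library, covariates=X_cols,
        outer_folds=opts.outer_folds, inner_folds=opts.inner_folds,
        seed=_stage_seed(config.seed, 1),
    )
    scores = pd.DataFrame({
        "participant_id": predicted.scores.index,
        "score": predicted.scores.to_numpy(),
        "provenance": predicted.provenance.to_numpy(),
    })
    timings["compliance_model"] = time.time() - t0

    # stage 2: average treatment effects
    t0 = time.time()
    frame = estimation.build_analysis_frame(baseline, arms, followup)
    ate_rows: list[dict] = []
    for outcome in ("joint_remission", "phq_ads_mean"):
        spec3 = EstimandSpec(outcome, "3mo")
        ate_rows += _ate_rows(spec3, estimation.dr_estimate(frame, spec3,
                                                            options=est_opts))
        spec12 = EstimandSpec(outcome, "12mo")
        has_12_only = (~frame["completed_3"] & frame["completed_12"]).any()
        if has_12_only:
            imputed = estimation.impute_3mo_pmm(
                frame,
                ImputationConfig(opts.mi_m, opts.mi_k,
                                 _stage_seed(config.seed, 2)),
                covariates=tuple(opts.covariates),
            )
            per_imp = [
                estimation.longitudinal_dr_estimate(fi, spec12, options=est_opts)
                for fi in imputed
            ]
            res12 = estimation.pool_rubin_arms(per_imp)
        else:
            res12 = estimation.longitudinal_dr_estimate(frame, spec12,
                                                        options=est_opts)
        ate_rows += _ate_rows(spec12, res12)
    ate_report = pd.DataFrame(ate_rows)
    timings["ate"] = time.time() - t0

    # stage 3: predicted-compliance heterogeneity
    t0 = time.time()
    split = heterogeneity.dichotomize(predicted.scores, opts.top_fraction)
    strat = heterogeneity.stratified_ate(frame, split, options=est_opts)
    inter = heterogeneity.interaction_test(frame, split, options=est_opts)
    timings["heterogeneity"] = time.time() - t0

    # stage 4: attrition and usage summaries
    t0 = time.time()
    attr = heterogeneity.attrition_analysis(
        frame, [p for p in opts.attrition_predictors if p in frame.columns]
    )
    summaries = {
        period: compliance.summarize_usage(usage, arms, period)
        for period in compliance.PERIODS
    }
    timings["descriptives"] = time.time() - t0

    # stage 5: attribution of the compliance model
    t0 = time.time()
    train_ids = arms.loc[arms["arm"] == "self-guided", "participant_id"]
    X_train = baseline.set_index("participant_id").loc[train_ids, list(X_cols)]
    shap_summary = shap_explain.summarize(
        full_model, X_train, domain_map=DOMAIN_MAP,
        coalition_budget=opts.shap_budget, seed=_stage_seed(config.seed, 3),
    )
    ranked = shap_explain.rank_predictors(shap_summary)
    timings["shap"] = time.time() - t0

    manifest = {
        "version": __version__,
        "schema_version": codebook.SCHEMA_VERSION,
        "master_seed": config.seed,
        "stage_seeds": {f"stage_{k}": _stage_seed(config.seed, k)
                        for k in range(4)},
        "config": {
            "generator": (config.generator_config().to_dict()
                          if config.generator is not None else None),
            "inputs": config.inputs,
            "analysis": asdict(opts),
        },
        "input_hashes": {
            name: hashlib.sha256(
                df.to_csv(index=False).encode()
            ).hexdigest()
            for name, df in (("baseline", baseline), ("arms", arms),
                             ("usage", usage), ("followup", followup))
        },
        "cv_r2": nested.cv_r2,
        "cv_r2_se": nested.cv_r2_se,
        "compliance_model": {
            "learners": [ls.name for ls in full_model.learners],
            "weights": [round(float(w), 6) for w in full_model.weights],
            "outer_folds": opts.outer_folds,
            "inner_folds": opts.inner_folds,
            "covariate_schema": hashlib.sha256(
                ",".join(X_cols).encode()).hexdigest()[:16],
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
    }
    return RunResult(
        ate_report=ate_report,
        stratified=strat.table(),
        interaction=inter,
        attrition=attr,
        usage_summaries=summaries,
        scores=scores,
        cv_r2=nested.cv_r2,
        cv_r2_se=nested.cv_r2_se,
        shap_summary=shap_summary,
        shap_ranked=ranked,
        manifest=manifest,
        tables={"baseline": baseline, "arms": arms, "usage": usage,
                "followup": followup},
    )


# ---------------------------------------------------------------------------
# bundle output


def write_simulation(trial: st.SyntheticTrial, outdir: str | Path) -> None:
    """Write the four analysis CSVs, the truth JSON and a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trial.baseline.to_csv(out / "baseline.csv", index=False)
    trial.arms.to_csv(out / "arms.csv", index=False)
    trial.usage.to_csv(out / "usage.csv", index=False, float_format="%.1f")
    trial.followup.to_csv(out / "followup.csv", index=False)
    truth = {
        "arm_means": {
            f"{o}_{w}": trial.truth.arm_means(o, w)
            for o in ("remission", "phqads") for w in ("3", "12")
        }
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest = {
        "version": __version__,
        "schema_version": codebook.SCHEMA_VERSION,
        "generator": trial.config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def write_bundle(result: RunResult, outdir: str | Path) -> None:
    """Write the full result bundle; all files land atomically at the end."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.ate_report.to_csv(out / "ate_report.csv", index=False,
                             float_format="%.6g")
    result.stratified.to_csv(out / "stratified_report.csv", index=False,
                             float_format="%.6g")
    result.scores.to_csv(out / "predicted_compliance.csv", index=False,
                         float_format="%.6g")
    result.shap_summary.to_csv(out / "shap_summary.csv", index=False,
                               float_format="%.6g")
    result.shap_ranked.to_csv(out / "shap_ranked.csv", index=False,
                              float_format="%.6g")
    attr_frames = []
    for t in result.attrition:
        c = t.counts.copy()
        c.insert(0, "predictor", t.predictor)
        attr_frames.append(c)
    pd.concat(attr_frames, ignore_index=True).to_csv(
        out / "attrition_counts.csv", index=False, float_format="%.6g")
    attr_tests = []
    for t in result.attrition:
        c = t.tests.copy()
        c.insert(0, "predictor", t.predictor)
        attr_tests.append(c)
    pd.concat(attr_tests, ignore_index=True).to_csv(
        out / "attrition_tests.csv", index=False, float_format="%.6g")
    usage_json = {
        period: {
            "n": s.n, "mean": s.mean, "sd": s.sd,
            "prop_ge": {str(k): v for k, v in s.prop_ge.items()},
            "chi2": s.chi2, "df": s.df, "p": s.p,
        }
        for period, s in result.usage_summaries.items()
    }
    (out / "usage_summary.json").write_text(json.dumps(usage_json, indent=2))
    inter = result.interaction
    report = {
        "interaction": {
            "chi2": inter.chi2, "df": inter.df, "p": inter.p,
            "delta_high": inter.delta_high, "delta_low": inter.delta_low,
        },
        "cv_r2": result.cv_r2,
        "cv_r2_se": result.cv_r2_se,
    }
    (out / "heterogeneity_report.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))
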