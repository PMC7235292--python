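"""End-to-end orchestration of the synthetic-data analysis pipeline.

Stages run in order — simulate, fit, stats, glm, dcm — each reading only
files written by earlier stages, with per-stage seeds derived
deterministically from the master seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, glm, io, rlfit, stats
from . import task as task_mod

log = logging.getLogger("ctxlearn")

REGIONS = connectivity.NODES


def stage_seed(master_seed: int, stage: str, participant: str = "") -> int:
    """Deterministic sub-stream seed from (master seed, stage, unit)."""
    digest = hashlib.sha256(
        f"{master_seed}|{stage}|{participant}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    master_seed: int = 0
    n_subjects: int = 19
    outdir: str = "ctxlearn-run"
    task: task_mod.TaskConfig = field(default_factory=task_mod.TaskConfig)
    grid: rlfit.ParamGrid = field(default_factory=rlfit.ParamGrid)
    timeline: glm.ScanTimeline = field(default_factory=glm.ScanTimeline)
    hrf: glm.HRFSpec = field(default_factory=glm.HRFSpec)
    param_sampler: task_mod.ParamSampler = field(default_factory=task_mod.ParamSampler)
    trait_model: task_mod.TraitModel = field(default_factory=task_mod.TraitModel)
    rt_model: task_mod.RTModel = field(default_factory=task_mod.RTModel)
    bold_sigma: float = 0.5
    bold_rho: float = 0.3
    true_contrast: float = 0.5
    contrast_subject_sd: float = 0.2
    dcm_runs: int = 2
    dcm_noise: float | str = 0.0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    def config_hash(self) -> str:
        content = self.to_dict()
        content.pop("outdir", None)  # hash covers content, not location
        payload = yaml.safe_dump(content, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    simple = {
        "master_seed", "n_subjects", "outdir", "bold_sigma", "bold_rho",
        "true_contrast", "contrast_subject_sd", "dcm_runs", "dcm_noise",
    }
    for key, value in raw.items():
        if key in simple:
            kwargs[key] = value
        elif key == "task":
            value = dict(value)
            if "contingency" in value:
                value["contingency"] = {
                    tuple(k.split("|")): v
                    for k, v in value["contingency"].items()
                }
            for tup in ("contexts", "actions"):
                if tup in value:
                    value[tup] = tuple(value[tup])
            kwargs["task"] = task_mod.TaskConfig(**value)
        elif key == "timeline":
            kwargs["timeline"] = glm.ScanTimeline(**value)
        elif key == "hrf":
            kwargs["hrf"] = glm.HRFSpec(**value)
        elif key == "grid":
            kwargs["grid"] = rlfit.ParamGrid(
                alpha_values=np.asarray(value["alpha_values"], dtype=float),
                kappa_values=np.asarray(value["kappa_values"], dtype=float),
            )
        elif key == "param_sampler":
            kwargs["param_sampler"] = task_mod.ParamSampler(**value)
        elif key == "trait_model":
            kwargs["trait_model"] = task_mod.TraitModel(**value)
        elif key == "rt_model":
            kwargs["rt_model"] = task_mod.RTModel(**value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict[str, dict]
    created: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _true_beta_vector(
    design: glm.DesignMatrix, contrast: float, rng: np.random.Generator,
    subject_sd: float,
) -> np.ndarray:
    """Ground-truth betas: pain responds more than no-pain by ``contrast``
    (plus between-subject scatter), modest responses elsewhere."""
    base = {
        "outcome_pain": 0.5 + contrast + subject_sd * rng.standard_normal(),
        "outcome_nopain": 0.5,
        "shape_A": 0.3,
        "shape_B": 0.3,
        "selection": 0.2,
        "rpe_pain": 0.3,
        "rpe_nopain": 0.3,
        "state_value": 0.2,
    }
    return np.array([base.get(lab, 0.0) for lab in design.labels])


def run_all(config: RunConfig) -> RunManifest:
    """Execute simulate -> fit -> stats -> glm -> dcm; write the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.master_seed
    stages: dict[str, dict] = {}

    # --- simulate ---------------------------------------------------------
    seed = stage_seed(master, "simulate")
    log.info("stage simulate (seed %d)", seed)
    sessions, traits = task_mod.simulate_cohort(
        n_subjects=config.n_subjects,
        config=config.task,
        param_sampler=config.param_sampler,
        trait_model=config.trait_model,
        rt_model=config.rt_model,
        seed=seed,
    )
    io.write_trials(sessions, out / "trials.tsv")
    io.write_latents(sessions, out / "latents.tsv")
    io.write_traits(traits, out / "traits.tsv")
    stages["simulate"] = {
        "seed": seed,
        "outputs": ["trials.tsv", "latents.tsv", "traits.tsv"],
    }

    # --- fit --------------------------------------------------------------
    log.info("stage fit")
    fits = rlfit.fit_cohort(sessions, config.grid)
    io.write_tsv(fits, out / "fits.tsv")
    stages["fit"] = {"inputs": ["trials.tsv"], "outputs": ["fits.tsv"]}

    # --- stats ------------------------------------------------------------
    log.info("stage stats")
    summary, results, text = stats.behavior_report(sessions)
    io.write_tsv(summary, out / "choice_summary.tsv")
    rows = [
        {
            "name": name,
            "test": r.test,
            "statistic": r.statistic,
            "df": str(r.df),
            "pvalue": r.pvalue,
        }
        for name, r in results.items()
    ]
    io.write_tsv(pd.DataFrame(rows), out / "behavior_stats.tsv")
    (out / "behavior_summary.txt").write_text(text + "\n")
    stages["stats"] = {
        "inputs": ["trials.tsv"],
        "outputs": [
            "choice_summary.tsv", "behavior_stats.tsv",
            "behavior_summary.txt",
        ],
    }

    # --- glm --------------------------------------------------------------
    log.info("stage glm")
    if abs(config.task.duration_s - config.timeline.duration_s) > 1e-6:
        raise ValueError(
            f"task duration {config.task.duration_s} s does not tile the "
            f"scan timeline {config.timeline.duration_s} s"
        )
    contrasts, glm_rows = [], []
    for sess in sessions:
        pid = sess.participant
        sseed = stage_seed(master, "glm", pid)
        rng = np.random.default_rng(sseed)
        fit_row = fits[fits["participant"] == pid].iloc[0]
        hat = task_mod.AgentParams(
            alpha=float(fit_row["alpha_hat"]),
            kappa=min(float(fit_row["kappa_hat"]), 0.0),
        )
        latents = rlfit.extract_latents(sess, hat)
        events = glm.events_from_session(sess, latents)
        motion = glm.simulate_motion(
            config.timeline, seed=stage_seed(master, "motion", pid)
        )
        design = glm.build_design(
            events, config.timeline, config.hrf, motion=motion
        )
        beta_true = _true_beta_vector(
            design, config.true_contrast, rng, config.contrast_subject_sd
        )
        bold = glm.simulate_roi_bold(
            design, beta_true, sigma=config.bold_sigma,
            rho=config.bold_rho, seed=int(rng.integers(0, 2**31 - 1)),
        )
        fitted = glm.fit_glm(bold, design)
        contrasts.append(fitted.contrast)
        glm_rows.append(
            {
                "participant": pid,
                "contrast": fitted.contrast,
                "beta_rpe_pain": fitted.betas.get("rpe_pain", np.nan),
                "beta_state_value": fitted.betas.get("state_value", np.nan),
                "residual_variance": fitted.residual_variance,
            }
        )
    glm_table = pd.DataFrame(glm_rows)
    io.write_tsv(glm_table, out / "glm_contrasts.tsv")
    group_rows = []
    try:
        g = glm.group_level(contrasts)
        group_rows.append(
            {
                "effect": "pain_minus_nopain",
                "t": g.statistic,
                "df": g.df,
                "pvalue": g.pvalue,
            }
        )
    except (ValueError, stats.DegenerateDataError) as exc:
        log.warning("group-level contrast test skipped: %s", exc)
    io.write_tsv(
        pd.DataFrame(group_rows, columns=["effect", "t", "df", "pvalue"]),
        out / "group_stats.tsv",
    )
    trait_rows = pd.DataFrame()
    if config.n_subjects >= 3:
        effect = glm_table.set_index("participant")["contrast"]
        trait_rows = stats.trait_correlations(effect, traits)
        io.write_tsv(trait_rows, out / "trait_correlations.tsv")
    stages["glm"] = {
        "inputs": ["trials.tsv", "fits.tsv", "traits.tsv"],
        "outputs": [
            "glm_contrasts.tsv", "group_stats.tsv",
            "trait_correlations.tsv",
        ],
    }

    # --- dcm --------------------------------------------------------------
    log.info("stage dcm")
    dcm_seed = stage_seed(master, "dcm")
    dcm = connectivity.recovery_experiment(
        n_runs=config.dcm_runs,
        noise=config.dcm_noise,
        seed=dcm_seed,
        timeline=config.timeline,
        config=config.task,
    )
    io.write_tsv(dcm, out / "dcm_recovery.tsv")
    stages["dcm"] = {
        "seed": dcm_seed,
        "outputs": ["dcm_recovery.tsv"],
        "p1_accuracy": dcm.attrs["p1_accuracy"],
        "p2_accuracy": dcm.attrs["p2_accuracy"],
    }

    manifest = RunManifest(
        version="0.1.0",
        config_hash=config.config_hash(),
        stages=stages,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def validate_files(paths: list[str | Path]) -> list[str]:
    """Schema-check known table types; returns line-numbered problems."""
    report: list[str] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            report.append(f"{p}: file not found")
            continue
        try:
            df = io.read_tsv(p)
        except Exception as exc:  # malformed file: report, don't raise
            report.append(f"{p}: unreadable ({exc})")
            continue
        cols = set(df.columns)
        if set(io.TRIAL_COLUMNS).issubset(cols):
            problems = io.validate_trial_table(df)
        elif {"p_left", "p_right", "rpe"}.issubset(cols):
            problems = io.validate_latent_table(df)
        elif {"participant"}.issubset(cols) and any(
            s in cols for s in task_mod.TRAIT_SCALES
        ):
            problems = io.validate_trait_table(df)
        elif "volume" in cols:
            expected = 6 if set(glm.MOTION_LABELS).issubset(cols) else None
            problems = io.validate_numeric_table(
                df, expected_cols=expected, name=p.name
            )
        else:
            problems = [f"unrecognized table schema (columns {sorted(cols)})"]
        report.extend(f"{p}: {msg}" for msg in problems)
    return report
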