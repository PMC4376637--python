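"""End-to-end orchestration: simulate -> fit -> compare -> staircase -> report.

Everything is driven by a :class:`PipelineConfig` (YAML-loadable, unknown
keys rejected) and a single seed; two runs with the same config produce
byte-identical outputs and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bms import EvidenceTable, rfx_bms
from .cohort import Agent, design_exp1_stimuli, simulate_cohort, simulate_exp2_session
from .io import write_fit_table, write_trials
from .models import MODEL_NAMES, get_model
from .regress import choice_logistic_regression, fatigue_tests, parameter_correlations
from .staircase import (
    StaircaseConfig,
    classify_concavity,
    estimate_indifference_points,
    transform_indifference,
)
from .vb import default_prior, fit_model, predicted_choice_accuracy

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject/model."""


@dataclass
class PipelineConfig:
    """All knobs of a full synthetic study run.

    ``effort_generator``/``delay_generator`` name the models the two cohorts'
    agents are drawn from; ``param_ranges`` gives per-parameter (low, high)
    sampling ranges (log-uniform for positive parameters, uniform for the
    turning point).
    """

    seed: int = 1
    outdir: str = "out"
    n_subjects: int = 8
    trials_per_block: int = 100
    n_blocks: int = 2
    models: tuple[str, ...] = ("hyperbolic", "sigmoidal")
    effort_generator: str = "sigmoidal"
    delay_generator: str = "hyperbolic"
    param_ranges: dict = field(
        default_factory=lambda: {
            "sigmoidal": {"k": (5.0, 20.0), "p": (0.4, 0.9)},
            "hyperbolic": {"k": (1.0, 15.0)},
            "beta": (0.3, 1.0),
        }
    )
    n_init_per_param: int = 3
    alpha0: float = 1.0
    xp_samples: int = 100_000
    realized_fraction: float = 0.3
    exp2_subjects: int = 3
    fatigue_permutations: int = 5000

    def __post_init__(self) -> None:
        for name in tuple(self.models) + (self.effort_generator, self.delay_generator):
            if name not in MODEL_NAMES:
                raise ValueError(f"unknown model name {name!r} in config")
        if self.n_subjects < 1 or self.trials_per_block < 1:
            raise ValueError("n_subjects and trials_per_block must be >= 1")
        self.models = tuple(self.models)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d


def _sample_agents(config: PipelineConfig, model: str, rng: np.random.Generator) -> list[Agent]:
    spec = get_model(model)
    ranges = config.param_ranges.get(model, {})
    blo, bhi = config.param_ranges.get("beta", (0.3, 1.0))
    agents = []
    for i in range(config.n_subjects):
        params = {}
        for par in spec.params:
            lo, hi = ranges.get(par, (0.5, 10.0))
            if spec.transforms[par] == "log":
                params[par] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[par] = float(rng.uniform(lo, hi))
        beta = float(np.exp(rng.uniform(np.log(blo), np.log(bhi))))
        agents.append(Agent(model=model, params=params, beta=beta, subject=f"s{i + 1:02d}"))
    return agents


def _stage(name: str, subject: str = "", model: str = ""):
    ctx = " ".join(x for x in (name, subject, model) if x)

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {ctx!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _fit_cohort(datasets, config: PipelineConfig, defaults_log: dict) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for model in config.models:
            with _stage("fit", ds.subject, model):
                fit = fit_model(ds, model, n_init_per_param=config.n_init_per_param)
                row = {
                    "subject": ds.subject,
                    "cost_type": ds.cost_type,
                    "model": model,
                    "free_energy": fit.free_energy,
                    "accuracy": fit.accuracy,
                    "complexity": fit.complexity,
                    "predicted_accuracy": predicted_choice_accuracy(fit, ds),
                }
                for name, value in fit.params_native.items():
                    row[f"param_{name}"] = value
                rows.append(row)
    defaults_log.setdefault("priors", {m: {
        "names": list(default_prior(m).names),
        "mean": default_prior(m).mean.tolist(),
        "variances": np.diag(default_prior(m).cov).tolist(),
    } for m in config.models})
    return pd.DataFrame(rows)


def _bms_frame(fit_frame: pd.DataFrame, config: PipelineConfig, seed: int):
    table = EvidenceTable.from_frame(fit_frame)
    result = rfx_bms(table, alpha0=config.alpha0, xp_samples=config.xp_samples, seed=seed)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole synthetic study and write a report bundle.

    Stages: stimulus design, cohort simulation for an effort-like and a
    delay-like task, per-subject model fitting, group model comparison,
    staircase sessions with indifference-point analysis, auxiliary statistics
    and a manifest (versions, seeds, defaults used, output checksums).
    Returns the manifest dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ["stimuli", "effort_agents", "delay_agents", "effort_sim", "delay_sim", "bms", "exp2", "stats"],
        root.spawn(8),
    )}
    defaults_log: dict = {
        "effort_levels": list(StaircaseConfig().effort_levels),
        "pest_rules": "halve on reversal; double from 4th same-direction step (capped at "
        "initial); re-initialize at step <= initial/4 with jittered magnitude",
    }
    paths: dict[str, Path] = {}

    with _stage("design_stimuli"):
        stimuli = design_exp1_stimuli(
            n_per_block=config.trials_per_block,
            n_blocks=config.n_blocks,
            seed=int(seeds["stimuli"].generate_state(1)[0]),
        )

    cohorts = {}
    for task, gen, agent_seed, sim_seed in (
        ("effort", config.effort_generator, "effort_agents", "effort_sim"),
        ("delay", config.delay_generator, "delay_agents", "delay_sim"),
    ):
        with _stage("simulate", model=gen):
            agents = _sample_agents(config, gen, np.random.default_rng(seeds[agent_seed]))
            import dataclasses as _dc

            task_stimuli = _dc.replace(stimuli, cost_type=task)
            datasets = simulate_cohort(
                agents,
                task_stimuli,
                seed=int(seeds[sim_seed].generate_state(1)[0]),
                realized_fraction=config.realized_fraction if task == "effort" else 0.0,
            )
            cohorts[task] = {"agents": agents, "datasets": datasets}
            paths[f"trials_{task}"] = outdir / f"trials_{task}.csv"
            write_trials(datasets, paths[f"trials_{task}"])

    fit_frames = {}
    for task in ("effort", "delay"):
        frame = _fit_cohort(cohorts[task]["datasets"], config, defaults_log)
        fit_frames[task] = frame
        paths[f"fits_{task}"] = outdir / f"fits_{task}.csv"
        write_fit_table(frame.to_dict("records"), paths[f"fits_{task}"])

    bms_results = {}
    for task in ("effort", "delay"):
        with _stage("bms", model=task):
            res = _bms_frame(fit_frames[task], config, seed=int(seeds["bms"].generate_state(1)[0]))
            bms_results[task] = res
            paths[f"bms_{task}"] = outdir / f"bms_{task}.csv"
            res.to_frame().to_csv(paths[f"bms_{task}"], index=False)

    # Experiment-2-style staircase sessions on the first few effort agents
    exp2_rows = []
    exp2_datasets = []
    exp2_streams = seeds["exp2"].spawn(max(config.exp2_subjects, 1))
    for agent, ss in zip(cohorts["effort"]["agents"][: config.exp2_subjects], exp2_streams):
        with _stage("staircase", agent.subject):
            session, traces = simulate_exp2_session(agent, seed=int(ss.generate_state(1)[0]))
            exp2_datasets.append(session)
            sc = StaircaseConfig()
            for bi, blk in enumerate(sc.blocks, start=1):
                choices = {
                    lvl: list(zip(traces[(bi, lvl)]["offered"], traces[(bi, lvl)]["accepted"]))
                    for lvl in sc.effort_levels
                }
                curve = estimate_indifference_points(choices, blk.default_magnitude)
                mult = transform_indifference(curve, "multiplicative")
                add = transform_indifference(curve, "additive")
                verdict = (
                    classify_concavity(mult, curve.levels) if np.all(np.isfinite(mult)) else None
                )
                for i, lvl in enumerate(curve.levels):
                    exp2_rows.append(
                        {
                            "subject": agent.subject,
                            "block": bi,
                            "level": lvl,
                            "x50": curve.x50[i],
                            "slope": curve.slope[i],
                            "status": curve.status[i],
                            "raw": curve.x50[i],
                            "multiplicative": mult[i],
                            "additive": add[i],
                            "concave": None if verdict is None else verdict.concave,
                            "n_above_chord": None if verdict is None else verdict.n_above_chord,
                        }
                    )
    if exp2_datasets:
        paths["exp2_trials"] = outdir / "exp2_trials.csv"
        write_trials(exp2_datasets, paths["exp2_trials"])
        paths["indifference"] = outdir / "indifference.csv"
        pd.DataFrame(exp2_rows).to_csv(paths["indifference"], index=False)

    # auxiliary statistics on the effort cohort
    with _stage("report"):
        stats_seed = int(seeds["stats"].generate_state(1)[0])
        reg_rows = []
        for ds in cohorts["effort"]["datasets"]:
            coefs = choice_logistic_regression(ds)
            row = {"subject": ds.subject, "separated": coefs.attrs["separated"]}
            for name in coefs.index:
                row[f"beta_{name}"] = coefs.loc[name, "estimate"]
            reg_rows.append(row)
        paths["choice_regression"] = outdir / "choice_regression.csv"
        pd.DataFrame(reg_rows).to_csv(paths["choice_regression"], index=False)

        fat = fatigue_tests(
            cohorts["effort"]["datasets"][0], n_perm=config.fatigue_permutations, seed=stats_seed
        )
        fat_rows = [
            {"test": name, **{k: v for k, v in res.items()}} for name, res in fat.tests.items()
        ]
        paths["fatigue"] = outdir / "fatigue.csv"
        pd.DataFrame(fat_rows).to_csv(paths["fatigue"], index=False)

        def _params_frame(task):
            f = fit_frames[task]
            cols = [c for c in f.columns if c.startswith("param_") and c != "param_beta"]
            wide = f.pivot(index="subject", columns="model", values=cols)
            wide.columns = [f"{m}_{c.removeprefix('param_')}" for c, m in wide.columns]
            return wide.dropna(axis=1)

        corr = parameter_correlations(_params_frame("effort"), _params_frame("delay"))
        paths["correlations"] = outdir / "correlations.csv"
        corr.to_csv(paths["correlations"], index=False)

    summary_lines = [f"costdiscount {__version__} pipeline summary", ""]
    for task in ("effort", "delay"):
        res = bms_results[task]
        summary_lines.append(f"[{task}] generator={getattr(config, f'{task}_generator')}")
        for m, a, mp, xp in zip(res.models, res.alpha, res.mp, res.xp):
            summary_lines.append(f"  {m:<12} alpha={a:8.3f}  mp={mp:.4f}  xp={xp:.4f}")
    summary_lines.append("")
    summary_lines.append(f"defaults: {json.dumps(defaults_log, sort_keys=True)}")
    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text("\n".join(summary_lines) + "\n")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "defaults": defaults_log,
        "checksums": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in sorted(paths.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"] = {name: str(p) for name, p in paths.items()}
    return manifest
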