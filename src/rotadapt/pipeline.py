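"""Pipeline orchestration: config, trial-table I/O, report generation.

A persisted config plus its root seed fully determines every output (MCMC
summaries are reproducible because chain seeds are derived substreams).
Stages: simulate -> preprocess -> fit -> summarize (-> samplesize when the
precision block is enabled); each stage writes CSV/JSON artefacts and the
run ends with a manifest of versions, seeds and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import PrecisionCriteria, evaluate_precision, predictive_datasets
from .equivalence import results_table
from .kinematics import assign_epochs, summarize_experiment
from .model import PriorConfig, build_model, diagnose, sample_posterior
from .synthetic_data import GroupParams, default_group_params, make_design, simulate_experiment

log = logging.getLogger("rotadapt")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_trials", "render_report"]

SAMPLE_COLUMNS = ["subject_id", "group", "phase", "trial", "target_deg", "t_ms", "x_cm", "y_cm"]
TRIAL_COLUMNS = ["subject_id", "group", "phase", "trial", "target_deg", "movement_direction_deg"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "rotadapt_out"
    design: dict = field(default_factory=dict)
    groups: list[dict] | None = None          # GroupParams overrides; None -> defaults
    simulate: dict = field(default_factory=lambda: {
        "n_per_group": 25, "trajectories": False, "invalid_rate": 0.01})
    model: dict = field(default_factory=lambda: {
        "chains": 4, "draws": 10000, "burn_in": 1000})
    rope: dict = field(default_factory=lambda: {"low": -3.0, "high": 3.0, "mass": 0.95})
    precision: dict = field(default_factory=lambda: {"enabled": False})
    logging_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def group_params(self) -> list[GroupParams]:
        if self.groups is None:
            return default_group_params()
        return [GroupParams(**g) for g in self.groups]

    def prior_config(self) -> PriorConfig:
        keys = {f.name for f in dataclasses.fields(PriorConfig)}
        opts = {k: v for k, v in self.model.items() if k in keys}
        for tup in ("delta_scale_ig", "subject_scale_ig", "subject_epoch_scale_ig",
                    "tau_shape_lognorm", "tau_rate_gamma"):
            if tup in opts:
                opts[tup] = tuple(opts[tup])
        return PriorConfig(**opts)


def load_trials(path, dialect: str = "auto") -> tuple[pd.DataFrame, str]:
    """Load a trial table; returns (table, dialect).

    Two dialects: ``sample`` (one row per time sample, trajectory columns)
    and ``trial`` (one row per trial with a precomputed movement direction,
    skipping the trajectory operations).  Malformed rows are rejected with
    their row numbers.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if dialect == "auto":
        if {"t_ms", "x_cm", "y_cm"} <= cols:
            dialect = "sample"
        elif "movement_direction_deg" in cols:
            dialect = "trial"
        else:
            raise ValueError(
                "cannot infer dialect: need t_ms/x_cm/y_cm (sample-level) "
                "or movement_direction_deg (trial-level)")
    required = SAMPLE_COLUMNS if dialect == "sample" else TRIAL_COLUMNS
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{dialect}-level table is missing columns: {missing}")
    numeric = [c for c in required if c not in ("subject_id", "group", "phase")]
    bad_rows: list[int] = []
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad_rows.extend(df.index[vals.isna()].tolist())
        df[c] = vals
    if bad_rows:
        rows = sorted(set(bad_rows))[:20]
        raise ValueError(f"malformed numeric values in rows {rows}")
    return df, dialect


def _records_from_samples(df: pd.DataFrame):
    """Rebuild TrialRecord objects from a sample-level table."""
    from .synthetic_data import TrialRecord

    records = []
    for (sid, grp, phase, trial, tgt), sub in df.groupby(
            ["subject_id", "group", "phase", "trial", "target_deg"], sort=False):
        sub = sub.sort_values("t_ms")
        traj = sub[["t_ms", "x_cm", "y_cm"]].to_numpy(float)
        records.append(TrialRecord(
            subject_id=str(sid), group_label=str(grp), phase=str(phase),
            trial_index=int(trial), target_angle_deg=float(tgt),
            feedback_mode="veridical", target_onset_ms=0.0,
            hand_direction_deg=float("nan"), trajectory=traj))
    records.sort(key=lambda r: (r.subject_id, r.trial_index))
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> preprocess -> fit -> summarize (-> samplesize).

    Returns the report bundle: in-memory objects plus the paths of every
    artefact written under ``config.out_dir``.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.logging_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"paths": {}, "seed": config.seed}

    def write_df(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        bundle["paths"][name] = str(p)
        return p

    def write_json(name: str, obj) -> Path:
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)
        bundle["paths"][name] = str(p)
        return p

    # --- simulate ---------------------------------------------------------
    try:
        design = make_design(config.design, seed=config.seed)
        groups = config.group_params()
        sim = config.simulate
        experiment = simulate_experiment(
            design, groups, int(sim.get("n_per_group", 25)), config.seed,
            trajectories=bool(sim.get("trajectories", False)),
            invalid_rate=float(sim.get("invalid_rate", 0.01)))
        write_df("trials.csv", experiment.trial_table)
        write_json("ground_truth.json", experiment.ground_truth)
        bundle["experiment"] = experiment
        log.info("simulate: %d trials, %d subjects", len(experiment.records),
                 experiment.trial_table["subject_id"].nunique())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrapped with stage info
        raise PipelineError("simulate", "E_SIMULATE", str(exc)) from exc

    # --- preprocess -------------------------------------------------------
    try:
        if sim.get("trajectories", False):
            kin = summarize_experiment(experiment.records)
            write_df("kinematics.csv", kin)
            trial_table = kin[["subject_id", "group", "phase", "trial",
                               "movement_direction_deg", "valid"]]
        else:
            trial_table = experiment.trial_table.assign(valid=True)
        epoched = assign_epochs(trial_table)
        write_df("epoched.csv", epoched)
        bundle["epoched"] = epoched
        # observed learning curve: adaptation-bin group means
        adapt = epoched[epoched["epoch"].str.startswith("adaptation_") & epoched["valid"]]
        curve = (adapt.groupby(["group", "epoch"])["movement_direction_deg"]
                 .mean().reset_index().rename(columns={"movement_direction_deg": "mean_deg"}))
        write_df("learning_curve.csv", curve)
        bundle["learning_curve"] = curve
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", "E_PREPROCESS", str(exc)) from exc

    # --- fit --------------------------------------------------------------
    try:
        mc = config.model
        spec = build_model(epoched, priors=config.prior_config())
        samples = sample_posterior(
            spec, chains=int(mc.get("chains", 4)), burn_in=int(mc.get("burn_in", 1000)),
            draws=int(mc.get("draws", 10000)), seed=config.seed)
        report = diagnose(samples)
        samples.write_csv(out / "posterior.csv")
        bundle["paths"]["posterior.csv"] = str(out / "posterior.csv")
        write_json("convergence.json", {
            "passed": report.passed, "max_rhat": report.max_rhat,
            "chain_agreement": report.chain_agreement,
            "rhat_threshold": report.rhat_threshold})
        bundle["posterior"] = samples
        bundle["convergence"] = report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", "E_FIT", str(exc)) from exc

    # --- summarize --------------------------------------------------------
    try:
        rope = (float(config.rope.get("low", -3.0)), float(config.rope.get("high", 3.0)))
        mass = float(config.rope.get("mass", 0.95))
        table = results_table(samples, rope=rope, mass=mass)
        write_df("results.csv", table)
        write_json("results.json", table.to_dict(orient="records"))
        bundle["results"] = table
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("summarize", "E_SUMMARIZE", str(exc)) from exc

    # --- samplesize (optional) --------------------------------------------
    if config.precision.get("enabled", False):
        try:
            pc = config.precision
            criteria = PrecisionCriteria(
                mean_width_max=float(pc.get("mean_width_max", 2.0)),
                diff_width_max=float(pc.get("diff_width_max", 2.5)),
                percentile=float(pc.get("percentile", 90.0)))
            mode = pc.get("mode", "generator")
            source = samples if mode == "predictive" else groups
            datasets = predictive_datasets(
                source, n_list=pc.get("n_list", (10, 15, 20, 25, 30)),
                reps=int(pc.get("reps", 10)), seed=config.seed, design=design)
            curve = evaluate_precision(
                datasets, criteria, seed=config.seed,
                chains=int(pc.get("chains", 2)), draws=int(pc.get("draws", 2500)),
                burn_in=int(pc.get("burn_in", 500)),
                epochs_subset=pc.get("epochs_subset"))
            write_df("precision_widths.csv", curve.widths)
            write_df("precision_percentiles.csv", curve.percentiles)
            write_json("precision_decision.json", curve.verdicts)
            bundle["precision_curve"] = curve
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("samplesize", "E_SAMPLESIZE", str(exc)) from exc

    # --- figures ------------------------------------------------------------
    try:
        for name, path in _save_figures(bundle, out).items():
            bundle["paths"][name] = str(path)
    except Exception as exc:  # noqa: BLE001
        log.warning("figure rendering failed: %s", exc)

    # --- report + manifest --------------------------------------------------
    report_md = render_report(bundle)
    (out / "report.md").write_text(report_md)
    bundle["paths"]["report.md"] = str(out / "report.md")
    manifest = {
        "rotadapt_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "checksums": {name: _sha256(Path(p)) for name, p in bundle["paths"].items()
                      if name.endswith((".csv", ".json"))},
    }
    write_json("manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle


def _save_figures(bundle: dict, out: Path) -> dict[str, Path]:
    """Learning curve, differences with ROPE band, and precision curve as PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    curve = bundle.get("learning_curve")
    if curve is not None and len(curve):
        fig, ax = plt.subplots(figsize=(7, 4))
        for g, sub in curve.groupby("group"):
            sub = sub.sort_values("epoch")
            ax.plot(range(1, len(sub) + 1), sub["mean_deg"], marker="o", ms=3, label=g)
        ax.set_xlabel("adaptation bin (8 trials)")
        ax.set_ylabel("movement direction (deg)")
        ax.legend(title="group")
        fig.tight_layout()
        p = out / "learning_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["learning_curve.png"] = p

    results = bundle.get("results")
    if results is not None:
        diffs = results[results["quantity"] == "difference"]
        if len(diffs):
            fig, ax = plt.subplots(figsize=(7, 4))
            x = np.arange(len(diffs))
            ax.axhspan(-3.0, 3.0, color="0.9", label="ROPE")
            ax.errorbar(x, diffs["posterior_mean"],
                        yerr=[diffs["posterior_mean"] - diffs["hdi_low"],
                              diffs["hdi_high"] - diffs["posterior_mean"]],
                        fmt="o", capsize=3)
            ax.axhline(0.0, color="k", lw=0.8)
            ax.set_xticks(x, diffs["epoch_set"] + "\n" + diffs["label"], fontsize=7)
            ax.set_ylabel("difference (deg, mean and 95% HDI)")
            ax.legend()
            fig.tight_layout()
            p = out / "differences.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written["differences.png"] = p

    pc = bundle.get("precision_curve")
    if pc is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
        for ax, kind, crit in ((axes[0], "group_mean", pc.criteria.mean_width_max),
                               (axes[1], "difference", pc.criteria.diff_width_max)):
            sub = pc.percentiles[pc.percentiles["kind"] == kind]
            for q, qsub in sub.groupby("quantity"):
                ax.plot(qsub["n"], qsub["width_pctl"], marker="o", ms=3, label=q)
            ax.axhline(crit, color="k", ls="--", lw=0.8)
            ax.set_title(kind)
            ax.set_xlabel("subjects per group")
            ax.legend(fontsize=7)
        axes[0].set_ylabel(f"{pc.criteria.percentile:.0f}th pct. HDI width (deg)")
        fig.tight_layout()
        p = out / "precision_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["precision_curve.png"] = p
    return written


def render_report(bundle: dict) -> str:
    """Human-readable markdown report; partial bundles yield partial reports."""
    if not bundle or not bundle.get("paths"):
        raise ValueError("empty bundle")
    lines = ["# Visuomotor rotation analysis report", ""]
    warnings = []

    curve = bundle.get("learning_curve")
    if curve is not None and len(curve):
        lines += ["## Learning curve (adaptation-bin group means)", "",
                  curve.to_string(index=False), ""]
    else:
        warnings.append("learning curve missing")

    conv = bundle.get("convergence")
    if conv is not None:
        lines += ["## Convergence", "",
                  f"- pass: {conv.passed} (max split R-hat {conv.max_rhat:.4f}, "
                  f"threshold {conv.rhat_threshold})", ""]

    results = bundle.get("results")
    if results is not None:
        lines += ["## Group means and differences (mean, 95% HDI, ROPE)", "",
                  results.round(3).to_string(index=False), ""]
        diffs = results[results["quantity"] == "difference"]
        if len(diffs):
            lines += ["Differences are reported with the full 95% HDI width "
                      "(the `hdi_width` column); `mass_in_rope_pct` is the "
                      "posterior mass inside the ROPE.", ""]
    else:
        warnings.append("results table missing")

    pc = bundle.get("precision_curve")
    if pc is not None:
        lines += ["## Criterial-precision sample-size curve", "",
                  pc.percentiles.round(3).to_string(index=False), "",
                  f"Recommended n per group: {pc.recommended_n} "
                  f"(mean criterion: {pc.verdicts.get('mean_criterion_n')}, "
                  f"difference criterion: {pc.verdicts.get('diff_criterion_n')})", ""]

    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    return "\n".join(lines)
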