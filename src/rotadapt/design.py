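"""Criterial-precision sample-size procedure.

Simulated datasets are generated at candidate per-group sample sizes
(default 10, 15, 20, 25, 30; 10 replicates each), the hierarchical ANOVA is
refitted to each, and the 95% HDI widths of the early-aftereffect group
means and pairwise group differences are aggregated at a percentile (default
the 90th, nearest-rank).  The recommended sample size is the smallest n
whose percentile widths satisfy the stopping criteria (default: 2 deg per
group mean and 2.5 deg per difference).

Datasets can come from the posterior predictive distribution of a previous
fit (the sequential-design procedure proper) or from the synthetic-data
generator (no prior fit needed; the default for testing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import spawn_seeds, substream
from .epochs import epoch_labels_for_phase
from .equivalence import default_pairs, hdi
from .kinematics import assign_epochs
from .model import (PosteriorSamples, PriorConfig, build_model, cell_means,
                    diagnose, sample_posterior)
from .synthetic_data import ExperimentDesign, make_design, simulate_experiment

__all__ = [
    "PrecisionCriteria",
    "PrecisionCurve",
    "PredictiveDataset",
    "predictive_datasets",
    "evaluate_precision",
    "stopping_decision",
    "nearest_rank_percentile",
]


@dataclass(frozen=True)
class PrecisionCriteria:
    mean_width_max: float = 2.0      # deg, per-group mean HDI width
    diff_width_max: float = 2.5      # deg, pairwise-difference HDI width
    percentile: float = 90.0         # nearest-rank percentile over replicates
    epochs: tuple[str, ...] = ("early_aftereffect",)

    def __post_init__(self):
        if self.mean_width_max <= 0 or self.diff_width_max <= 0:
            raise ValueError("width criteria must be positive")
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError("percentile must be in (0, 100]")


@dataclass
class PredictiveDataset:
    n_per_group: int
    replicate: int
    epoched: pd.DataFrame


@dataclass
class PrecisionCurve:
    n_list: list[int]
    reps: int
    criteria: PrecisionCriteria
    widths: pd.DataFrame       # columns: n, replicate, quantity, kind, width
    percentiles: pd.DataFrame  # columns: n, quantity, kind, width_pctl
    recommended_n: int | None
    verdicts: dict = field(default_factory=dict)
    n_excluded: int = 0


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    rank = max(int(math.ceil(percentile / 100.0 * x.size)), 1)
    return float(x[rank - 1])


def _epoch_counts(design: ExperimentDesign) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in design.phase_schedule:
        for lab in epoch_labels_for_phase(p.name, p.n_trials):
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def _predictive_from_posterior(samples: PosteriorSamples, n: int, seed: int,
                               design: ExperimentDesign) -> pd.DataFrame:
    """One posterior-predictive dataset with ``n`` new subjects per group.

    A joint parameter draw is selected at random; new subjects get fresh
    hierarchical effects u ~ N(0, sigma_u), v ~ N(0, sigma_v) and precisions
    tau ~ Gamma(a_tau, b_tau); trial counts per epoch follow the design.
    """
    rng = substream(seed, "predictive")
    c = int(rng.integers(samples.n_chains))
    d = int(rng.integers(samples.n_draws))
    post = samples.posterior
    m = post["cell_mean"][c, d]                        # (E, G)
    sigma_u = float(post["sigma_u"][c, d])
    sigma_v = float(post["sigma_v"][c, d])
    a_tau = float(post["a_tau"][c, d])
    b_tau = float(post["b_tau"][c, d])
    counts = _epoch_counts(design)

    rows = []
    for g, glabel in enumerate(samples.groups):
        u = rng.normal(0.0, sigma_u, size=n)
        tau = rng.gamma(a_tau, 1.0 / b_tau, size=n)
        sigma_s = 1.0 / np.sqrt(np.maximum(tau, 1e-12))
        for s in range(n):
            sid = f"{glabel}_{s:03d}"
            for e, elabel in enumerate(samples.epochs):
                ne = counts.get(elabel, 0)
                if ne == 0:
                    continue
                v = rng.normal(0.0, sigma_v)
                y = rng.normal(m[e, g] + u[s] + v, sigma_s[s], size=ne)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "group": glabel, "epoch": elabel,
                    "movement_direction_deg": y, "valid": True}))
    return pd.concat(rows, ignore_index=True)


def predictive_datasets(source, n_list: Sequence[int] = (10, 15, 20, 25, 30),
                        reps: int = 10, seed: int = 0,
                        design: ExperimentDesign | None = None) -> list[PredictiveDataset]:
    """``reps`` independent datasets per candidate n; reproducible under seed.

    ``source`` is either a fitted :class:`PosteriorSamples`
    (posterior-predictive mode) or a sequence of :class:`GroupParams`
    (generator mode, via :func:`simulate_experiment` without trajectories).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_list = [int(n) for n in n_list]
    if not n_list:
        raise ValueError("n_list must not be empty")
    design = design or make_design(seed=seed)
    seeds = spawn_seeds(seed, "predictive-datasets", len(n_list) * reps)

    datasets = []
    k = 0
    for n in n_list:
        for rep in range(reps):
            if isinstance(source, PosteriorSamples):
                epoched = _predictive_from_posterior(source, n, seeds[k], design)
            else:
                exp = simulate_experiment(design, list(source), n, seeds[k],
                                          trajectories=False, invalid_rate=0.0)
                epoched = assign_epochs(exp.trial_table)
            datasets.append(PredictiveDataset(n_per_group=n, replicate=rep,
                                              epoched=epoched))
            k += 1
    return datasets


def evaluate_precision(datasets: Sequence[PredictiveDataset],
                       criteria: PrecisionCriteria | None = None, *,
                       priors: PriorConfig | None = None,
                       chains: int = 2, draws: int = 2500, burn_in: int = 500,
                       seed: int = 0, epochs_subset: Sequence[str] | None = None,
                       check_convergence: bool = True) -> PrecisionCurve:
    """Refit the hierarchical model to every dataset and build the width curves.

    Reduced sampler settings (2 chains x 2500 draws by default) keep the
    50-dataset sweep desk-scale; pass larger values for full fidelity.
    Non-convergent refits (split R-hat above threshold) are excluded with a
    logged count.  ``epochs_subset`` optionally restricts the fit to a subset
    of epochs (the target epochs must be included).
    """
    criteria = criteria or PrecisionCriteria()
    target_epochs = list(criteria.epochs)
    fit_seeds = spawn_seeds(seed, "precision-fits", len(datasets))

    rows = []
    n_excluded = 0
    for ds, fseed in zip(datasets, fit_seeds):
        epoched = ds.epoched
        if epochs_subset is not None:
            keep = set(epochs_subset) | set(target_epochs)
            epoched = epoched[epoched["epoch"].isin(keep)]
        spec = build_model(epoched, priors=priors)
        samples = sample_posterior(spec, chains=chains, burn_in=burn_in,
                                   draws=draws, seed=fseed)
        if check_convergence and chains >= 2:
            report = diagnose(samples, var_names=("cell_mean",))
            if report.passed is False and report.max_rhat > 1.05:
                n_excluded += 1
                continue
        cm = cell_means(samples, target_epochs)   # (chains, draws, G)
        for g, glabel in enumerate(samples.groups):
            rows.append({"n": ds.n_per_group, "replicate": ds.replicate,
                         "quantity": glabel, "kind": "group_mean",
                         "width": hdi(cm[:, :, g].ravel()).width})
        for a, b in default_pairs(samples.groups):
            ia, ib = samples.groups.index(a), samples.groups.index(b)
            diff = (cm[:, :, ia] - cm[:, :, ib]).ravel()
            rows.append({"n": ds.n_per_group, "replicate": ds.replicate,
                         "quantity": f"{a}-{b}", "kind": "difference",
                         "width": hdi(diff).width})
    widths = pd.DataFrame(rows)
    if widths.empty:
        raise RuntimeError("all refits were excluded as non-convergent")

    pct = (widths.groupby(["n", "quantity", "kind"])["width"]
           .apply(lambda w: nearest_rank_percentile(w, criteria.percentile))
           .reset_index().rename(columns={"width": "width_pctl"}))

    n_list = sorted(widths["n"].unique())
    curve = PrecisionCurve(n_list=[int(n) for n in n_list],
                           reps=int(widths["replicate"].max()) + 1,
                           criteria=criteria, widths=widths, percentiles=pct,
                           recommended_n=None, n_excluded=n_excluded)
    decision = stopping_decision(curve, criteria)
    curve.recommended_n = decision["recommended_n"]
    curve.verdicts = decision
    return curve


def stopping_decision(curve: PrecisionCurve, criteria: PrecisionCriteria | None = None,
                      policy: str = "all") -> dict:
    """Smallest candidate n meeting the width criteria at the stated percentile.

    Returns separate verdicts for the mean-width and difference-width
    criteria (these can disagree) plus a combined recommendation:
    ``policy='all'`` (default) requires both; ``policy='mean'`` or ``'diff'``
    use a single criterion.  When no candidate qualifies, ``recommended_n``
    is None and the closest n (smallest worst-case excess) is reported.
    """
    criteria = criteria or curve.criteria
    pct = curve.percentiles
    mean_ok, diff_ok, excess = {}, {}, {}
    for n in curve.n_list:
        sub = pct[pct["n"] == n]
        wm = sub[sub["kind"] == "group_mean"]["width_pctl"]
        wd = sub[sub["kind"] == "difference"]["width_pctl"]
        mean_ok[n] = bool((wm <= criteria.mean_width_max).all()) if len(wm) else False
        diff_ok[n] = bool((wd <= criteria.diff_width_max).all()) if len(wd) else False
        excess[n] = max(
            float((wm - criteria.mean_width_max).max()) if len(wm) else math.inf,
            float((wd - criteria.diff_width_max).max()) if len(wd) else math.inf)

    def smallest(ok: dict) -> int | None:
        passing = [n for n in curve.n_list if ok[n]]
        return min(passing) if passing else None

    n_mean = smallest(mean_ok)
    n_diff = smallest(diff_ok)
    if policy == "mean":
        rec = n_mean
    elif policy == "diff":
        rec = n_diff
    else:
        both = [n for n in curve.n_list if mean_ok[n] and diff_ok[n]]
        rec = min(both) if both else None
    closest = min(excess, key=lambda n: excess[n]) if rec is None else None
    return {"recommended_n": rec, "mean_criterion_n": n_mean,
            "diff_criterion_n": n_diff, "closest_n": closest,
            "mean_ok": mean_ok, "diff_ok": diff_ok, "policy": policy}
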