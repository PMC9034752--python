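"""Highest-density intervals, ROPE equivalence decisions and summary tables.

The 95% HDI is the shortest interval containing 95% of the posterior draws —
every point inside is more credible than any point outside.  Group
differences are assessed against a region of practical equivalence (ROPE,
default -3 to +3 deg around zero difference): the decision is *equivalent*
when the HDI lies entirely inside the ROPE, *not_equivalent* when entirely
outside, otherwise *undecided*.  Both the fraction of posterior mass inside
the ROPE and the fraction of HDI length inside the ROPE are reported; the
mass fraction is the primary decision statistic.

Note on the "±" convention used in summary tables: a value reported as
``mean ± w`` carries the full 95% HDI *width* w, not a standard deviation;
outputs label it ``hdi_width`` explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorSamples, group_epoch_draws

__all__ = [
    "Interval",
    "RopeReport",
    "DifferenceSummary",
    "hdi",
    "rope_assessment",
    "group_difference",
    "results_table",
    "default_pairs",
]


@dataclass(frozen=True)
class Interval:
    low: float
    high: float
    mass: float = 0.95

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("interval low must be <= high")

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass
class RopeReport:
    rope_low: float
    rope_high: float
    posterior_mass_in_rope: float   # percent
    hdi_fraction_in_rope: float     # percent of HDI length
    hdi: Interval
    decision: str                   # equivalent | not_equivalent | undecided


@dataclass
class DifferenceSummary:
    pair: str                       # e.g. "SD-MD" meaning mean(SD) - mean(MD)
    epoch_set: str
    posterior_mean: float
    hdi: Interval
    rope: RopeReport


def hdi(draws, mass: float = 0.95) -> Interval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties in the shortest-window scan are broken by the lowest starting index
    (deterministic).
    """
    x = np.asarray(draws, dtype=float).ravel()
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    if x.size < 20:
        raise ValueError("need at least 20 draws for an HDI")
    if np.isnan(x).any():
        raise ValueError("draws contain NaN")
    x = np.sort(x)
    k = int(math.ceil(mass * x.size))
    widths = x[k - 1:] - x[: x.size - k + 1]
    i = int(np.argmin(widths))  # first minimum -> lowest start
    return Interval(float(x[i]), float(x[i + k - 1]), mass)


def rope_assessment(draws, rope: tuple[float, float] = (-3.0, 3.0),
                    mass: float = 0.95) -> RopeReport:
    """ROPE equivalence assessment of a posterior sample.

    Reports both the percentage of posterior mass inside the ROPE and the
    percentage of the HDI's length inside the ROPE; mass inside and outside
    sum to 100% exactly.
    """
    lo, hi = float(rope[0]), float(rope[1])
    if not lo < hi:
        raise ValueError("rope must satisfy low < high")
    x = np.asarray(draws, dtype=float).ravel()
    interval = hdi(x, mass)
    mass_in = float(np.mean((x >= lo) & (x <= hi)) * 100.0)
    if interval.width == 0.0:
        frac = 100.0 if lo <= interval.low <= hi else 0.0
    else:
        overlap = max(0.0, min(interval.high, hi) - max(interval.low, lo))
        frac = 100.0 * overlap / interval.width
    if interval.low >= lo and interval.high <= hi:
        decision = "equivalent"
    elif interval.high < lo or interval.low > hi:
        decision = "not_equivalent"
    else:
        decision = "undecided"
    return RopeReport(rope_low=lo, rope_high=hi, posterior_mass_in_rope=mass_in,
                      hdi_fraction_in_rope=frac, hdi=interval, decision=decision)


def default_pairs(groups: list[str]) -> list[tuple[str, str]]:
    """All ordered pairs (A, B), A before B, e.g. SD-MD, SD-LD, MD-LD."""
    return [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]


def group_difference(draws_by_group: dict[str, np.ndarray], pair: tuple[str, str],
                     epoch_set: str = "", rope: tuple[float, float] = (-3.0, 3.0),
                     mass: float = 0.95) -> DifferenceSummary:
    """Posterior of mean(A) - mean(B) for a pair of groups, with HDI and ROPE.

    The difference is formed draw-wise, so Delta(A,B) = -Delta(B,A) exactly.
    """
    a, b = pair
    for label in pair:
        if label not in draws_by_group:
            raise KeyError(f"unknown group in pair: {label!r}")
    diff = np.asarray(draws_by_group[a], float) - np.asarray(draws_by_group[b], float)
    return DifferenceSummary(
        pair=f"{a}-{b}", epoch_set=epoch_set,
        posterior_mean=float(diff.mean()),
        hdi=hdi(diff, mass),
        rope=rope_assessment(diff, rope, mass))


def results_table(samples: PosteriorSamples,
                  epoch_sets: dict[str, list[str]] | None = None,
                  rope: tuple[float, float] = (-3.0, 3.0),
                  mass: float = 0.95) -> pd.DataFrame:
    """Group means and pairwise differences per epoch set.

    One row per group x epoch set (posterior mean, HDI, HDI width) and one
    per pair x epoch set (difference mean, HDI, ROPE percentages, decision).
    ``epoch_sets`` maps a summary name to the epochs averaged per draw; the
    default summarises each aftereffect epoch and the adaptation asymptote
    (mean of the last three adaptation bins) when present.
    """
    if epoch_sets is None:
        epoch_sets = {}
        for e in ("early_baseline", "late_baseline", "early_aftereffect",
                  "late_aftereffect", "washout"):
            if e in samples.epochs:
                epoch_sets[e] = [e]
        adapt = [e for e in samples.epochs if e.startswith("adaptation_")]
        if len(adapt) >= 3:
            epoch_sets["asymptote"] = adapt[-3:]

    rows = []
    for set_name, epochs in epoch_sets.items():
        draws = group_epoch_draws(samples, epochs)
        for g, x in draws.items():
            iv = hdi(x, mass)
            rows.append({"quantity": "group_mean", "epoch_set": set_name, "label": g,
                         "posterior_mean": float(np.mean(x)), "hdi_low": iv.low,
                         "hdi_high": iv.high, "hdi_width": iv.width,
                         "mass_in_rope_pct": np.nan, "hdi_in_rope_pct": np.nan,
                         "decision": ""})
        for pair in default_pairs(samples.groups):
            ds = group_difference(draws, pair, set_name, rope, mass)
            rows.append({"quantity": "difference", "epoch_set": set_name,
                         "label": ds.pair, "posterior_mean": ds.posterior_mean,
                         "hdi_low": ds.hdi.low, "hdi_high": ds.hdi.high,
                         "hdi_width": ds.hdi.width,
                         "mass_in_rope_pct": ds.rope.posterior_mass_in_rope,
                         "hdi_in_rope_pct": ds.rope.hdi_fraction_in_rope,
                         "decision": ds.rope.decision})
    return pd.DataFrame(rows)
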