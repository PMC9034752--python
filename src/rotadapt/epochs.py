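"""Epoch structure of the four-phase visuomotor rotation experiment.

The analysis treats contiguous blocks of trials as factor levels ("epochs"):
baseline split in two halves, the rotation (adaptation) phase binned into
8-trial epochs, the no-feedback aftereffect phase split into early/late
halves, and washout as a single epoch.  With the default 80/240/40/40 design
this yields the canonical 35 epoch types: early/late baseline, 30 adaptation
bins, early/late aftereffect, washout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "ADAPTATION_BIN",
    "default_epoch_names",
    "epoch_labels_for_phase",
    "assign_epoch_column",
]

PHASES = ("baseline", "rotation", "aftereffect", "washout")
ADAPTATION_BIN = 8  # trials per adaptation epoch


def default_epoch_names(n_adaptation_bins: int = 30) -> list[str]:
    """Ordered epoch names for a design with the given number of adaptation bins."""
    names = ["early_baseline", "late_baseline"]
    names += [f"adaptation_{i + 1:02d}" for i in range(n_adaptation_bins)]
    names += ["early_aftereffect", "late_aftereffect", "washout"]
    return names


def epoch_labels_for_phase(phase: str, n_trials: int) -> list[str]:
    """Epoch label for each of ``n_trials`` consecutive trials of one phase.

    Baseline and aftereffect are split at the midpoint; adaptation is binned
    into consecutive blocks of :data:`ADAPTATION_BIN` trials; washout is one
    epoch.  Defaults reproduce epoch sizes (40, 40, 8x30, 20, 20, 40).
    """
    if phase == "baseline":
        half = n_trials // 2
        return ["early_baseline"] * half + ["late_baseline"] * (n_trials - half)
    if phase == "rotation":
        return [f"adaptation_{i // ADAPTATION_BIN + 1:02d}" for i in range(n_trials)]
    if phase == "aftereffect":
        half = n_trials // 2
        return ["early_aftereffect"] * half + ["late_aftereffect"] * (n_trials - half)
    if phase == "washout":
        return ["washout"] * n_trials
    raise ValueError(f"unknown phase label: {phase!r}")


def assign_epoch_column(trials: pd.DataFrame) -> pd.Series:
    """Epoch label per row of a trial-level table.

    ``trials`` must contain ``subject_id``, ``phase`` and ``trial`` (trial
    index within the experiment); rows are labelled by their position within
    their phase, per subject, in trial order.
    """
    required = {"subject_id", "phase", "trial"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    unknown = set(trials["phase"].unique()) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase label(s): {sorted(unknown)}")

    out = pd.Series(index=trials.index, dtype=object)
    order = trials.sort_values("trial").groupby(["subject_id", "phase"], sort=False)
    for (_, phase), sub in order:
        labels = epoch_labels_for_phase(phase, len(sub))
        out.loc[sub.index] = labels
    return out


def n_adaptation_bins(n_rotation_trials: int) -> int:
    return int(np.ceil(n_rotation_trials / ADAPTATION_BIN))
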