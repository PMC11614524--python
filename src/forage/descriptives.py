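"""Aggregate run statistics and their reconciliation with model parameters.

A "run" is a maximal streak of consecutive selections of the same target
class; the traditional foraging descriptives are the maximum run length
and the total number of runs per trial.  The stick parameter of the
generative model maps onto these measures: participants with larger stick
random effects switch less, so their fitted offsets should correlate
negatively with their observed switch counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import Dataset
from .inference import PosteriorDraws

__all__ = ["RunStats", "run_stats", "dataset_run_stats", "stick_effect_vs_switches"]


@dataclass(frozen=True)
class RunStats:
    max_run_length: int
    n_runs: int

    @property
    def n_switches(self) -> int:
        return self.n_runs - 1


def run_stats(labels: Sequence[str]) -> RunStats:
    """Maximal-block decomposition of a class-label sequence."""
    if len(labels) == 0:
        raise ValueError("run statistics undefined for an empty sequence")
    runs = [1]
    for a, b in zip(labels, labels[1:]):
        if a == b:
            runs[-1] += 1
        else:
            runs.append(1)
    return RunStats(max_run_length=max(runs), n_runs=len(runs))


def dataset_run_stats(dataset: Dataset) -> pd.DataFrame:
    """Per-trial run statistics for the complete (non-terminated) trials."""
    rows = []
    for t in dataset.trials:
        if t.terminated:
            continue
        rs = run_stats(t.sequence.class_labels(t.display))
        rows.append(
            {
                "participant_id": t.participant_id,
                "difficulty": t.condition.difficulty,
                "ratio_condition": t.condition.ratio,
                "trial": t.trial,
                "max_run_length": rs.max_run_length,
                "n_runs": rs.n_runs,
                "n_switches": rs.n_switches,
            }
        )
    return pd.DataFrame(rows)


def stick_effect_vs_switches(
    draws: PosteriorDraws, dataset: Dataset
) -> Tuple[float, pd.DataFrame]:
    """Spearman correlation between per-participant stick random-effect
    posterior means and observed total switch counts.

    Higher stick effects mean fewer switches, so the expected sign is
    negative.  Returns the correlation and the per-participant table.
    """
    per_trial = dataset_run_stats(dataset)
    if per_trial.empty:
        raise ValueError("dataset has no complete trials")
    switches = per_trial.groupby("participant_id")["n_switches"].sum()

    rows = []
    for pid in draws.participants:
        if pid not in switches.index:
            raise ValueError(f"participant {pid} in draws but not in dataset")
        us = [
            float(np.mean(draws.flat(f"u[b_S|{pid}|{c}]")))
            for c in draws.conditions
            if draws.has(f"u[b_S|{pid}|{c}]")
        ]
        rows.append(
            {
                "participant_id": pid,
                "stick_effect": float(np.mean(us)),
                "n_switches": int(switches.loc[pid]),
            }
        )
    table = pd.DataFrame(rows)
    rho = float(spearmanr(table["stick_effect"], table["n_switches"]).statistic)
    return rho, table
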