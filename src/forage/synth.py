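"""Synthetic foraging experiments with hierarchical participant variability.

Generates jittered-grid displays (40 items: 20 targets in a 5:15 / 10:10 /
15:5 class split plus 20 distractors, in a 1000x1000 px area) and full
simulated experiments in which every participant's four model parameters
are the condition's group mean plus an independent normal random effect.
The default design mirrors the power-analysis setting used to plan the
experiment: 36 participants, five trials per condition, six conditions,
with feature-search group parameters (b_S=1, sigma_rho=15, sigma_d=-1)
differing from conjunction search (b_S=2, sigma_rho=10, sigma_d=-1) and a
scarcity bias of p_A=0.6 (b_A=0.405) toward the rarer class in the scarce
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import Dataset, TrialRecord
from .model import (
    ALL_CONDITIONS,
    ConditionKey,
    Item,
    ModelParams,
    SelectionSequence,
    TrialDisplay,
    logit,
    simulate_trial,
)

__all__ = [
    "DisplayGeometry",
    "ExperimentDesign",
    "GroupParams",
    "power_analysis_group_params",
    "generate_display",
    "simulate_experiment",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Stimulus-layout parameters of the jittered grid."""

    width: float = 1000.0
    height: float = 1000.0
    grid_rows: int = 7
    grid_cols: int = 6
    jitter_sd: float = 12.0
    min_separation: float = 60.0
    item_radius: float = 25.0

    def __post_init__(self) -> None:
        if self.min_separation < 2 * self.item_radius:
            raise ValueError("min_separation must be at least twice the item radius")

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts defining the experiment: who, how often, what displays."""

    n_participants: int = 36
    trials_per_condition: int = 5
    conditions: Tuple[ConditionKey, ...] = ALL_CONDITIONS
    n_targets_total: int = 20
    n_distractors: int = 20
    scarce_count: int = 5
    equal_count: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.scarce_count < self.n_targets_total:
            raise ValueError("scarce_count must be between 0 and n_targets_total")
        if self.equal_count * 2 != self.n_targets_total:
            raise ValueError("equal_count must be half of n_targets_total")

    @property
    def n_items(self) -> int:
        return self.n_targets_total + self.n_distractors

    def n_class_a(self, ratio: str) -> int:
        return {
            "scarceA": self.scarce_count,
            "equal": self.equal_count,
            "scarceB": self.n_targets_total - self.scarce_count,
        }[ratio]


#: Default random-effect standard deviations: modest heterogeneity on the
#: two log-odds parameters, wider on the two tuning parameters whose
#: posterior scales are several units.
DEFAULT_RE_SD: Mapping[str, float] = {
    "b_A": 0.5,
    "b_S": 0.5,
    "sigma_rho": 2.0,
    "sigma_d": 2.0,
}


@dataclass(frozen=True)
class GroupParams:
    """Group-level means per condition plus random-effect sds per parameter."""

    means: Mapping[ConditionKey, ModelParams]
    re_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RE_SD))

    def __post_init__(self) -> None:
        for name in ModelParams.PARAM_NAMES:
            if self.re_sd[name] < 0:
                raise ValueError(f"re_sd[{name}] must be non-negative")

    def re_sd_array(self) -> np.ndarray:
        return np.array([self.re_sd[n] for n in ModelParams.PARAM_NAMES])


def power_analysis_group_params(
    conditions: Sequence[ConditionKey] = ALL_CONDITIONS,
    scarce_bias: float = logit(0.6),
    re_sd: Optional[Mapping[str, float]] = None,
) -> GroupParams:
    """The generating parameter set of the sample-size simulation.

    Feature conditions use b_S=1 (p_S=0.73), sigma_rho=15, sigma_d=-1;
    conjunction conditions b_S=2, sigma_rho=10, sigma_d=-1.  The class bias
    favours the rarer class by ``scarce_bias`` log-odds (default
    logit(0.6) = 0.405) in the scarce conditions and is zero in the equal
    conditions.
    """
    by_difficulty = {
        "feature": dict(b_S=1.0, sigma_rho=15.0, sigma_d=-1.0),
        "conjunction": dict(b_S=2.0, sigma_rho=10.0, sigma_d=-1.0),
    }
    bias = {"scarceA": scarce_bias, "equal": 0.0, "scarceB": -scarce_bias}
    means = {
        c: ModelParams(b_A=bias[c.ratio], **by_difficulty[c.difficulty])
        for c in conditions
    }
    return GroupParams(means=means, re_sd=dict(re_sd) if re_sd is not None else dict(DEFAULT_RE_SD))


def generate_display(
    condition: ConditionKey,
    geometry: DisplayGeometry,
    design: ExperimentDesign,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> TrialDisplay:
    """One jittered-grid display for the given condition.

    Items occupy a random subset of the grid cells; positions are cell
    centres plus isotropic Gaussian jitter, re-drawn wholesale when any
    pair falls closer than ``min_separation``.  Class labels are assigned
    to positions uniformly at random with the counts the condition
    dictates.
    """
    n = design.n_items
    if geometry.n_cells < n:
        raise ValueError(
            f"geometry has {geometry.n_cells} cells but the design needs {n} items"
        )
    cw = geometry.width / geometry.grid_cols
    ch = geometry.height / geometry.grid_rows
    lo = geometry.item_radius
    for _ in range(max_retries):
        cells = rng.choice(geometry.n_cells, size=n, replace=False)
        cx = (cells % geometry.grid_cols + 0.5) * cw
        cy = (cells // geometry.grid_cols + 0.5) * ch
        xy = np.column_stack([cx, cy]) + rng.normal(0.0, geometry.jitter_sd, (n, 2))
        xy[:, 0] = np.clip(xy[:, 0], lo, geometry.width - lo)
        xy[:, 1] = np.clip(xy[:, 1], lo, geometry.height - lo)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        d2[np.diag_indices(n)] = np.inf
        if d2.min() >= geometry.min_separation**2:
            break
    else:
        raise RuntimeError(
            f"could not place {n} items at min_separation="
            f"{geometry.min_separation} within {max_retries} attempts"
        )

    n_a = design.n_class_a(condition.ratio)
    n_b = design.n_targets_total - n_a
    n_da = design.n_distractors // 2
    n_db = design.n_distractors - n_da
    labels = (
        [("A", True)] * n_a
        + [("B", True)] * n_b
        + [("DA", False)] * n_da
        + [("DB", False)] * n_db
    )
    order = rng.permutation(n)
    items = tuple(
        Item(item_id=i, x=float(xy[i, 0]), y=float(xy[i, 1]), item_class=labels[k][0], is_target=labels[k][1])
        for i, k in zip(range(n), order)
    )
    return TrialDisplay(
        items=items, width=geometry.width, height=geometry.height, condition=condition
    )


def _selection_times(
    n: int, rng: np.random.Generator, mean_interval: float, shape: float = 4.0
) -> Tuple[float, ...]:
    gaps = rng.gamma(shape, mean_interval / shape, size=n)
    return tuple(float(v) for v in np.cumsum(gaps))


def simulate_experiment(
    group: GroupParams,
    design: ExperimentDesign,
    geometry: DisplayGeometry = DisplayGeometry(),
    rng: Optional[np.random.Generator] = None,
    mean_interval: float = 0.8,
    error_rate: float = 0.0,
) -> Dataset:
    """Simulate a full experiment under the hierarchical generative model.

    Each participant's effective parameters in condition ``k`` are the
    group means plus independent centred-normal offsets with the
    per-parameter ``re_sd`` (one offset per participant per condition).
    Timestamps are cumulative gamma inter-selection intervals with the
    given mean, so timing-based exclusion filters are exercisable.  With
    ``error_rate > 0`` a trial may first produce a terminated attempt
    (truncated uniformly, as if a distractor was clicked) before the
    complete one.  The returned dataset carries the generating group
    parameters and every participant's true effective parameters for
    recovery testing.
    """
    if rng is None:
        rng = np.random.default_rng()
    trials: List[TrialRecord] = []
    truths: Dict[Tuple[str, ConditionKey], ModelParams] = {}
    re_sd = group.re_sd_array()
    width = len(str(design.n_participants))
    for j in range(design.n_participants):
        pid = f"P{j + 1:0{width}d}"
        trial_no = 0
        for block, cond in enumerate(design.conditions, start=1):
            mu = group.means[cond].as_array()
            theta = ModelParams.from_array(mu + re_sd * rng.normal(size=4))
            truths[(pid, cond)] = theta
            for _ in range(design.trials_per_condition):
                trial_no += 1
                display = generate_display(cond, geometry, design, rng)
                seq = simulate_trial(display, theta, rng)
                times = _selection_times(len(seq), rng, mean_interval)
                attempt = 1
                if error_rate > 0.0 and rng.random() < error_rate:
                    cut = int(rng.integers(1, len(seq)))
                    trials.append(
                        TrialRecord(
                            participant_id=pid,
                            condition=cond,
                            block=block,
                            trial=trial_no,
                            attempt=attempt,
                            terminated=True,
                            display=display,
                            sequence=SelectionSequence(
                                seq.selected_ids[:cut], times[:cut]
                            ),
                        )
                    )
                    attempt += 1
                    seq = simulate_trial(display, theta, rng)
                    times = _selection_times(len(seq), rng, mean_interval)
                trials.append(
                    TrialRecord(
                        participant_id=pid,
                        condition=cond,
                        block=block,
                        trial=trial_no,
                        attempt=attempt,
                        terminated=False,
                        display=display,
                        sequence=SelectionSequence(seq.selected_ids, times),
                    )
                )
    return Dataset(
        trials=trials,
        provenance="simulated",
        generating=group,
        true_participant_params=truths,
    )
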