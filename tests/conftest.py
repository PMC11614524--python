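"""Shared fixtures: small simulated experiments and their fits.

The heavy fixtures are session-scoped simulate-then-fit pipelines at
reduced problem sizes (fewer participants/trials, smaller displays,
shorter chains) so the whole suite stays fast while still exercising the
full hierarchy.
"""

from __future__ import annotations

import numpy as np
import pytest

from forage.data import Dataset, TrialRecord
from forage.inference import McmcConfig, fit_model
from forage.model import ConditionKey, ModelParams, SelectionSequence, simulate_trial
from forage.synth import (
    DisplayGeometry,
    ExperimentDesign,
    GroupParams,
    generate_display,
    power_analysis_group_params,
    simulate_experiment,
)

FEATURE_RATIOS = tuple(ConditionKey("feature", r) for r in ("scarceA", "equal", "scarceB"))

#: Small display geometry for fast fits: 20 items on a 5x5 grid.
SMALL_GEOMETRY = DisplayGeometry(
    width=1000.0,
    height=1000.0,
    grid_rows=5,
    grid_cols=5,
    jitter_sd=12.0,
    min_separation=60.0,
    item_radius=25.0,
)

SMALL_DESIGN_KWARGS = dict(n_targets_total=10, n_distractors=10, scarce_count=3, equal_count=5)


def simulate_with_params(
    per_participant: dict[tuple[str, ConditionKey], ModelParams],
    design: ExperimentDesign,
    geometry: DisplayGeometry,
    rng: np.random.Generator,
    group: GroupParams,
) -> Dataset:
    """Simulate with explicit per-participant effective parameters."""
    trials = []
    pids = sorted({p for p, _ in per_participant})
    for pid in pids:
        trial_no = 0
        for block, cond in enumerate(design.conditions, start=1):
            theta = per_participant[(pid, cond)]
            for _ in range(design.trials_per_condition):
                trial_no += 1
                display = generate_display(cond, geometry, design, rng)
                seq = simulate_trial(display, theta, rng)
                gaps = rng.gamma(4.0, 0.2, size=len(seq))
                trials.append(
                    TrialRecord(
                        participant_id=pid,
                        condition=cond,
                        block=block,
                        trial=trial_no,
                        attempt=1,
                        terminated=False,
                        display=display,
                        sequence=SelectionSequence(seq.selected_ids, tuple(np.cumsum(gaps))),
                    )
                )
    return Dataset(
        trials=trials,
        provenance="simulated",
        generating=group,
        true_participant_params=dict(per_participant),
    )


@pytest.fixture(scope="session")
def planted_fit():
    """Fit to feature-difficulty data with one planted scarcity-biased
    participant (class-bias offsets +1 / 0 / -1 across the ratio
    conditions) and strong stick heterogeneity (re_sd(b_S) = 1)."""
    rng = np.random.default_rng(20240613)
    design = ExperimentDesign(
        n_participants=8, trials_per_condition=5, conditions=FEATURE_RATIOS
    )
    re_sd = {"b_A": 0.3, "b_S": 1.0, "sigma_rho": 2.0, "sigma_d": 1.0}
    group = power_analysis_group_params(conditions=FEATURE_RATIOS, re_sd=re_sd)
    sds = np.array([re_sd[p] for p in ModelParams.PARAM_NAMES])
    per_participant = {}
    for j in range(design.n_participants):
        pid = f"P{j + 1}"
        for cond in FEATURE_RATIOS:
            mu = group.means[cond].as_array()
            theta = mu + sds * rng.normal(size=4)
            if pid == "P1":
                theta[0] = mu[0] + {"scarceA": 1.0, "equal": 0.0, "scarceB": -1.0}[cond.ratio]
            per_participant[(pid, cond)] = ModelParams.from_array(theta)
    dataset = simulate_with_params(
        per_participant, design, DisplayGeometry(), rng, group
    )
    draws, diag = fit_model(
        dataset, cfg=McmcConfig(n_chains=2, n_warmup=500, n_samples=600, seed=7)
    )
    return dataset, draws, diag


@pytest.fixture(scope="session")
def homogeneous_null_fit():
    """Fit to a population with no heterogeneity (re_sd = 0) and no
    scarcity effect (b_A = 0 everywhere)."""
    rng = np.random.default_rng(991)
    design = ExperimentDesign(
        n_participants=6, trials_per_condition=4, conditions=FEATURE_RATIOS,
        **SMALL_DESIGN_KWARGS,
    )
    re_sd = {p: 0.0 for p in ModelParams.PARAM_NAMES}
    group = power_analysis_group_params(
        conditions=FEATURE_RATIOS, scarce_bias=0.0, re_sd=re_sd
    )
    dataset = simulate_experiment(group, design, SMALL_GEOMETRY, rng)
    draws, diag = fit_model(
        dataset, cfg=McmcConfig(n_chains=2, n_warmup=400, n_samples=500, seed=8)
    )
    return dataset, draws, diag


@pytest.fixture(scope="session")
def null_replicate_fits():
    """Twenty scaled-down simulate-fit replicates with zero scarcity effect.

    Used both for the type-I behaviour of the scarcity criterion and for
    credible-interval calibration of the group means.
    """
    results = []
    design = ExperimentDesign(
        n_participants=6, trials_per_condition=5, conditions=FEATURE_RATIOS,
        **SMALL_DESIGN_KWARGS,
    )
    group = power_analysis_group_params(conditions=FEATURE_RATIOS, scarce_bias=0.0)
    for rep in range(20):
        rng = np.random.default_rng(5000 + rep)
        dataset = simulate_experiment(group, design, SMALL_GEOMETRY, rng)
        draws, diag = fit_model(
            dataset,
            cfg=McmcConfig(n_chains=2, n_warmup=300, n_samples=400, seed=6000 + rep),
        )
        results.append((dataset, draws, diag))
    return results
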