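"""Posterior-contrast decision criteria.

Each hypothesis is decided by the posterior probability that a contrast
between fitted parameters exceeds zero, compared with a decision threshold
(0.99 throughout the planned analyses):

* H1 (scarcity): the class-bias log-odds is larger when class A is scarce
  and smaller when class B is scarce, i.e. both
  ``Pr(b_A(scarceA) - b_A(equal) > 0)`` and
  ``Pr(b_A(equal) - b_A(scarceB) > 0)`` exceed the threshold,
  marginalising over the feature and conjunction conditions (the two
  difficulties' group-mean draws are averaged draw-by-draw before
  contrasting);
* H2 (stickiness): larger stick log-odds in conjunction than feature;
* H3 (proximity): larger proximity tuning in feature than conjunction,
  plus a large (>10) proximity bias in both difficulties;
* H4 (direction): the direction-tuning posterior is negative.

Per-participant scarcity effects apply the H1 contrasts to group mean +
participant offset draws, flagging participants with scarcity (or
anti-scarcity) biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .inference import PARAMS, PosteriorDraws
from .model import ConditionKey, DIFFICULTIES, RATIOS

__all__ = [
    "ContrastResult",
    "H1Result",
    "SecondaryResults",
    "ParticipantEffects",
    "contrast_prob",
    "contrast",
    "evaluate_h1",
    "evaluate_h2_h3",
    "evaluate_h4",
    "participant_effects",
    "participant_effect_correlations",
]

Expr = Union[str, Sequence[str], np.ndarray]


@dataclass(frozen=True)
class ContrastResult:
    """Decision on one posterior contrast ``lhs - rhs > 0``."""

    name: str
    prob_positive: float
    threshold: float
    n_draws: int

    @property
    def decision(self) -> bool:
        return self.prob_positive > self.threshold

    def __str__(self) -> str:
        verdict = "PASS" if self.decision else "fail"
        return f"{self.name}: Pr(>0) = {self.prob_positive:.3f} [{verdict} at {self.threshold}]"


def _resolve(draws: PosteriorDraws, expr: Expr) -> np.ndarray:
    """Per-draw scalar values of a parameter expression.

    A string names a parameter; a sequence of names averages them
    draw-by-draw (used to marginalise over difficulties); an array is
    taken as-is.
    """
    if isinstance(expr, str):
        return draws.flat(expr)
    if isinstance(expr, np.ndarray):
        return expr.reshape(-1)
    return np.mean([draws.flat(n) for n in expr], axis=0)


def contrast_prob(draws: PosteriorDraws, lhs: Expr, rhs: Expr) -> float:
    """Fraction of draws with lhs - rhs strictly positive (ties fail)."""
    a = _resolve(draws, lhs)
    b = _resolve(draws, rhs)
    return float(np.mean(a > b))


def contrast(
    draws: PosteriorDraws, name: str, lhs: Expr, rhs: Expr, threshold: float = 0.99
) -> ContrastResult:
    a = _resolve(draws, lhs)
    return ContrastResult(
        name=name,
        prob_positive=contrast_prob(draws, lhs, rhs),
        threshold=threshold,
        n_draws=a.size,
    )


def _ba_names(draws: PosteriorDraws, ratio: str, difficulties: Sequence[str]) -> List[str]:
    names = []
    for d in difficulties:
        key = f"b_A[{ConditionKey(d, ratio)}]"
        if not draws.has(key):
            raise KeyError(f"draws lack the condition parameter {key}")
        names.append(key)
    return names


def _present_difficulties(draws: PosteriorDraws) -> List[str]:
    return [d for d in DIFFICULTIES if any(c.difficulty == d for c in draws.conditions)]


@dataclass
class H1Result:
    """The scarcity decision: both contrasts must exceed the threshold."""

    scarceA_vs_equal: ContrastResult
    equal_vs_scarceB: ContrastResult
    per_difficulty: Dict[str, Tuple[ContrastResult, ContrastResult]] = field(
        default_factory=dict
    )

    @property
    def passed(self) -> bool:
        return self.scarceA_vs_equal.decision and self.equal_vs_scarceB.decision


def evaluate_h1(
    draws: PosteriorDraws, threshold: float = 0.99, marginalize: bool = True
) -> H1Result:
    """Scarcity criterion on the class-bias group means.

    With ``marginalize`` the overall contrasts average the feature and
    conjunction draws (both difficulties must be present); otherwise the
    overall decision uses the single difficulty present, and per-difficulty
    results are reported either way.
    """
    diffs = _present_difficulties(draws)
    if marginalize and len(diffs) < 2:
        raise ValueError("marginalized H1 needs both feature and conjunction conditions")
    if not diffs:
        raise ValueError("draws contain no class-bias parameters")

    per_diff = {}
    for d in diffs:
        c1 = contrast(
            draws,
            f"H1[{d}]: b_A(scarceA) - b_A(equal)",
            _ba_names(draws, "scarceA", [d]),
            _ba_names(draws, "equal", [d]),
            threshold,
        )
        c2 = contrast(
            draws,
            f"H1[{d}]: b_A(equal) - b_A(scarceB)",
            _ba_names(draws, "equal", [d]),
            _ba_names(draws, "scarceB", [d]),
            threshold,
        )
        per_diff[d] = (c1, c2)

    if marginalize:
        overall = (
            contrast(
                draws,
                "H1: b_A(scarceA) - b_A(equal), marginal",
                _ba_names(draws, "scarceA", diffs),
                _ba_names(draws, "equal", diffs),
                threshold,
            ),
            contrast(
                draws,
                "H1: b_A(equal) - b_A(scarceB), marginal",
                _ba_names(draws, "equal", diffs),
                _ba_names(draws, "scarceB", diffs),
                threshold,
            ),
        )
    elif len(diffs) == 1:
        overall = per_diff[diffs[0]]
    else:
        raise ValueError("with both difficulties present, use marginalize=True")
    return H1Result(overall[0], overall[1], per_diff)


def _difficulty_mean_names(draws: PosteriorDraws, param: str, difficulty: str) -> List[str]:
    names = [
        f"{param}[{c}]" for c in draws.conditions if c.difficulty == difficulty
    ]
    if not names:
        raise KeyError(f"no {param} parameters for difficulty {difficulty!r}")
    return names


@dataclass
class SecondaryResults:
    h2: ContrastResult
    h3a: ContrastResult
    h3b: Dict[str, ContrastResult]


def evaluate_h2_h3(draws: PosteriorDraws, threshold: float = 0.99) -> SecondaryResults:
    """Stickiness (H2) and proximity (H3) contrasts between difficulties.

    H2: b_S(conjunction) > b_S(feature); H3a: sigma_rho(feature) >
    sigma_rho(conjunction); H3b: Pr(sigma_rho > 10) within each
    difficulty.  Parameters are averaged over the ratio conditions of each
    difficulty, draw-by-draw.
    """
    h2 = contrast(
        draws,
        "H2: b_S(conjunction) - b_S(feature)",
        _difficulty_mean_names(draws, "b_S", "conjunction"),
        _difficulty_mean_names(draws, "b_S", "feature"),
        threshold,
    )
    h3a = contrast(
        draws,
        "H3a: sigma_rho(feature) - sigma_rho(conjunction)",
        _difficulty_mean_names(draws, "sigma_rho", "feature"),
        _difficulty_mean_names(draws, "sigma_rho", "conjunction"),
        threshold,
    )
    h3b = {}
    for d in _present_difficulties(draws):
        vals = _resolve(draws, _difficulty_mean_names(draws, "sigma_rho", d))
        h3b[d] = ContrastResult(
            name=f"H3b[{d}]: sigma_rho > 10",
            prob_positive=float(np.mean(vals > 10.0)),
            threshold=threshold,
            n_draws=vals.size,
        )
    return SecondaryResults(h2=h2, h3a=h3a, h3b=h3b)


def evaluate_h4(draws: PosteriorDraws, threshold: float = 0.99) -> ContrastResult:
    """Direction criterion: Pr(sigma_d < 0), marginalised over conditions."""
    names = [f"sigma_d[{c}]" for c in draws.conditions]
    vals = _resolve(draws, names)
    return ContrastResult(
        name="H4: sigma_d < 0, marginal",
        prob_positive=float(np.mean(vals < 0.0)),
        threshold=threshold,
        n_draws=vals.size,
    )


def _participant_ba(draws: PosteriorDraws, pid: str, cond: ConditionKey) -> Optional[np.ndarray]:
    name = f"u[b_A|{pid}|{cond}]"
    if not draws.has(name):
        return None
    return draws.group_mean("b_A", cond) + draws.flat(name)


@dataclass
class ParticipantEffects:
    """Per-participant scarcity and anti-scarcity contrasts."""

    results: Dict[str, Dict[str, Tuple[ContrastResult, ContrastResult]]]
    anti: Dict[str, Dict[str, Tuple[ContrastResult, ContrastResult]]]
    threshold: float

    def flagged(self, scope: str = "marginal") -> List[str]:
        """Participants whose both scarcity contrasts pass in ``scope``."""
        return [
            pid
            for pid, scopes in self.results.items()
            if scope in scopes
            and scopes[scope][0].decision
            and scopes[scope][1].decision
        ]

    def anti_flagged(self, scope: str = "marginal") -> List[str]:
        return [
            pid
            for pid, scopes in self.anti.items()
            if scope in scopes
            and scopes[scope][0].decision
            and scopes[scope][1].decision
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, scopes in self.results.items():
            for scope, (c1, c2) in scopes.items():
                rows.append(
                    {
                        "participant": pid,
                        "scope": scope,
                        "p_scarceA_gt_equal": c1.prob_positive,
                        "p_equal_gt_scarceB": c2.prob_positive,
                        "scarcity": c1.decision and c2.decision,
                        "anti_scarcity": pid in self.anti
                        and scope in self.anti[pid]
                        and self.anti[pid][scope][0].decision
                        and self.anti[pid][scope][1].decision,
                    }
                )
        return pd.DataFrame(rows)


def participant_effects(
    draws: PosteriorDraws, threshold: float = 0.99
) -> ParticipantEffects:
    """Scarcity contrasts at the participant level (group mean + offset).

    For each participant and difficulty with complete ratio coverage, the
    H1 contrast pair is evaluated on the participant's effective class
    bias; a "marginal" scope averages the difficulties.  Reversed
    contrasts screen for anti-scarcity participants.
    """
    results: Dict[str, Dict[str, Tuple[ContrastResult, ContrastResult]]] = {}
    anti: Dict[str, Dict[str, Tuple[ContrastResult, ContrastResult]]] = {}
    for pid in draws.participants:
        scopes: Dict[str, Dict[str, np.ndarray]] = {}
        for d in _present_difficulties(draws):
            vals = {
                r: _participant_ba(draws, pid, ConditionKey(d, r)) for r in RATIOS
            }
            if all(v is not None for v in vals.values()):
                scopes[d] = vals
        if not scopes:
            continue
        if len(scopes) > 1:
            scopes["marginal"] = {
                r: np.mean([scopes[d][r] for d in scopes if d != "marginal"], axis=0)
                for r in RATIOS
            }
        results[pid] = {}
        anti[pid] = {}
        for scope, vals in scopes.items():
            mk = lambda nm, a, b: ContrastResult(
                name=nm,
                prob_positive=float(np.mean(a > b)),
                threshold=threshold,
                n_draws=a.size,
            )
            results[pid][scope] = (
                mk(f"u_A[{pid}|{scope}]: scarceA - equal", vals["scarceA"], vals["equal"]),
                mk(f"u_A[{pid}|{scope}]: equal - scarceB", vals["equal"], vals["scarceB"]),
            )
            anti[pid][scope] = (
                mk(f"u_A[{pid}|{scope}]: equal - scarceA", vals["equal"], vals["scarceA"]),
                mk(f"u_A[{pid}|{scope}]: scarceB - equal", vals["scarceB"], vals["equal"]),
            )
    return ParticipantEffects(results=results, anti=anti, threshold=threshold)


def participant_effect_correlations(draws: PosteriorDraws) -> Dict[str, float]:
    """Spearman correlation of participant scarcity effects with the other
    random effects (posterior means, offsets averaged over conditions)."""
    pids = []
    effects = []
    others: Dict[str, List[float]] = {p: [] for p in PARAMS if p != "b_A"}
    for pid in draws.participants:
        per_diff = []
        for d in _present_difficulties(draws):
            a = _participant_ba(draws, pid, ConditionKey(d, "scarceA"))
            b = _participant_ba(draws, pid, ConditionKey(d, "scarceB"))
            if a is not None and b is not None:
                per_diff.append(float(np.mean(a - b)) / 2.0)
        if not per_diff:
            continue
        pids.append(pid)
        effects.append(float(np.mean(per_diff)))
        for p in others:
            us = [
                np.mean(draws.flat(f"u[{p}|{pid}|{c}]"))
                for c in draws.conditions
                if draws.has(f"u[{p}|{pid}|{c}]")
            ]
            others[p].append(float(np.mean(us)) if us else float("nan"))
    out = {}
    for p, vals in others.items():
        rho = spearmanr(effects, vals).statistic
        out[p] = float(rho) if np.isfinite(rho) else 0.0
    return out
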