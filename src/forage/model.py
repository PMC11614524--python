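"""Generative sampling-without-replacement model of visual foraging.

A display contains target items of two classes (A and B) plus distractors.
Foraging is modelled as weighted sampling without replacement over the
remaining targets: after every selection the weights of the remaining
targets are recomputed from four parameters,

* ``b_A``       -- class-bias log-odds, ``b_A = logit(p_A)``; preference for
                   class A over class B all else being equal (``b_B = -b_A``),
* ``b_S``       -- stick log-odds, ``b_S = logit(p_S)``; preference for the
                   class of the previously selected item,
* ``sigma_rho`` -- proximity tuning; larger values weight selection towards
                   items near the last selection,
* ``sigma_d``   -- direction tuning; positive values prefer items "ahead of"
                   the current movement direction, negative values "behind".

The unnormalised weight of a remaining target is the product of a class
term, a stick term (once a previous selection exists), a proximity kernel
``exp(-sigma_rho * d)`` with ``d`` the Euclidean distance from the last
selection normalised by the display diagonal, and a direction kernel
``exp(sigma_d * cos(phi))`` with ``phi`` the angle between the movement
vector (previous -> last selection) and the candidate vector (last ->
candidate).  Weights are renormalised over the remaining targets after
every pick.

In log space the per-item weight is linear in the parameters, which the
inference machinery exploits; see :mod:`forage.likelihood`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "TARGET_CLASSES",
    "DISTRACTOR_CLASSES",
    "DIFFICULTIES",
    "RATIOS",
    "Item",
    "ConditionKey",
    "ALL_CONDITIONS",
    "TrialDisplay",
    "ModelParams",
    "SelectionSequence",
    "SelectionState",
    "logit",
    "inv_logit",
    "selection_weights",
    "simulate_trial",
    "trial_loglik",
    "enumerate_trial_probs",
]

TARGET_CLASSES = ("A", "B")
DISTRACTOR_CLASSES = ("DA", "DB")
DIFFICULTIES = ("feature", "conjunction")
RATIOS = ("scarceA", "equal", "scarceB")

#: Maximum number of targets for which full enumeration of orderings is allowed.
MAX_ENUMERATION_TARGETS = 7


def logit(p: float) -> float:
    """Log-odds of a probability ``p`` in the open interval (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit requires 0 < p < 1, got {p!r}")
    return math.log(p / (1.0 - p))


def inv_logit(x: float) -> float:
    """Inverse logit (logistic function); maps a finite log-odds to (0, 1)."""
    if not math.isfinite(x):
        raise ValueError(f"inv_logit requires a finite value, got {x!r}")
    return float(expit(x))


@dataclass(frozen=True)
class Item:
    """One display item: a target of class A/B or a distractor (DA/DB)."""

    item_id: int
    x: float
    y: float
    item_class: str
    is_target: bool

    def __post_init__(self) -> None:
        if self.is_target and self.item_class not in TARGET_CLASSES:
            raise ValueError(
                f"target item {self.item_id} has class {self.item_class!r}; "
                f"expected one of {TARGET_CLASSES}"
            )
        if not self.is_target and self.item_class not in DISTRACTOR_CLASSES:
            raise ValueError(
                f"distractor item {self.item_id} has class {self.item_class!r}; "
                f"expected one of {DISTRACTOR_CLASSES}"
            )

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True, order=True)
class ConditionKey:
    """Experimental condition: difficulty x target-class ratio (6 in total)."""

    difficulty: str
    ratio: str

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTIES:
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.ratio not in RATIOS:
            raise ValueError(f"unknown ratio {self.ratio!r}")

    def __str__(self) -> str:
        return f"{self.difficulty}:{self.ratio}"

    @classmethod
    def parse(cls, text: str) -> "ConditionKey":
        difficulty, _, ratio = text.partition(":")
        return cls(difficulty, ratio)


ALL_CONDITIONS: Tuple[ConditionKey, ...] = tuple(
    ConditionKey(d, r) for d in DIFFICULTIES for r in RATIOS
)

#: Number of class-A targets per ratio level, out of 20 targets total.
RATIO_A_COUNTS: Mapping[str, int] = {"scarceA": 5, "equal": 10, "scarceB": 15}


@dataclass(frozen=True)
class TrialDisplay:
    """The item layout of one trial."""

    items: Tuple[Item, ...]
    width: float
    height: float
    condition: Optional[ConditionKey] = None

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError("item_id values must be unique within a display")
        for it in self.items:
            if not (0.0 <= it.x <= self.width and 0.0 <= it.y <= self.height):
                raise ValueError(
                    f"item {it.item_id} at ({it.x}, {it.y}) lies outside the "
                    f"{self.width}x{self.height} display"
                )

    @property
    def targets(self) -> Tuple[Item, ...]:
        return tuple(it for it in self.items if it.is_target)

    @property
    def distractors(self) -> Tuple[Item, ...]:
        return tuple(it for it in self.items if not it.is_target)

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def target_by_id(self, item_id: int) -> Item:
        for it in self.targets:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no target with item_id {item_id} in display")


@dataclass(frozen=True)
class ModelParams:
    """One setting of the four foraging parameters.

    ``b_A`` and ``b_S`` are log-odds (so ``p_A = inv_logit(b_A)``,
    ``p_S = inv_logit(b_S)``); ``sigma_rho`` and ``sigma_d`` are
    dimensionless tuning strengths on diagonal-normalised distance and on
    the cosine of the relative direction angle.
    """

    b_A: float = 0.0
    b_S: float = 0.0
    sigma_rho: float = 0.0
    sigma_d: float = 0.0

    PARAM_NAMES = ("b_A", "b_S", "sigma_rho", "sigma_d")

    def __post_init__(self) -> None:
        for name in self.PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    @property
    def p_A(self) -> float:
        return inv_logit(self.b_A)

    @property
    def p_S(self) -> float:
        return inv_logit(self.b_S)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.b_A, self.b_S, self.sigma_rho, self.sigma_d], dtype=float
        )

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ModelParams":
        b_A, b_S, sigma_rho, sigma_d = (float(v) for v in theta)
        return cls(b_A=b_A, b_S=b_S, sigma_rho=sigma_rho, sigma_d=sigma_d)

    def relabelled(self) -> "ModelParams":
        """Parameters after swapping the class labels A <-> B."""
        return ModelParams(-self.b_A, self.b_S, self.sigma_rho, self.sigma_d)


@dataclass(frozen=True)
class SelectionSequence:
    """The ordered target selections of one trial attempt.

    ``times`` (optional) are seconds from trial onset, strictly increasing.
    """

    selected_ids: Tuple[int, ...]
    times: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selection sequence contains a repeated item_id")
        if self.times is not None:
            if len(self.times) != len(self.selected_ids):
                raise ValueError("times must align with selected_ids")
            if any(b <= a for a, b in zip(self.times, self.times[1:])):
                raise ValueError("selection times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.selected_ids)

    def class_labels(self, display: TrialDisplay) -> Tuple[str, ...]:
        return tuple(display.target_by_id(i).item_class for i in self.selected_ids)

    def validate_against(self, display: TrialDisplay) -> None:
        target_ids = {it.item_id for it in display.targets}
        for i in self.selected_ids:
            if i not in target_ids:
                raise ValueError(f"selected id {i} is not a target of the display")


@dataclass
class SelectionState:
    """Mutable cursor over a trial: remaining targets and selection history."""

    remaining: list
    last: Optional[Item] = None
    prev: Optional[Item] = None

    @classmethod
    def initial(cls, display: TrialDisplay) -> "SelectionState":
        return cls(remaining=list(display.targets))

    def advance(self, item: Item) -> None:
        self.remaining = [it for it in self.remaining if it.item_id != item.item_id]
        self.prev = self.last
        self.last = item


def _cosine_direction(prev: Item, last: Item, candidate: Item) -> float:
    """cos(angle) between the movement vector prev->last and last->candidate.

    Degenerate (zero-length) vectors are direction-neutral: cos = 0.
    """
    v = np.array([last.x - prev.x, last.y - prev.y])
    u = np.array([candidate.x - last.x, candidate.y - last.y])
    nv = np.linalg.norm(v)
    nu = np.linalg.norm(u)
    if nv == 0.0 or nu == 0.0:
        return 0.0
    return float(np.dot(v, u) / (nv * nu))


def selection_log_weights(
    state: SelectionState, params: ModelParams, width: float, height: float
) -> np.ndarray:
    """Unnormalised log-weights over ``state.remaining`` (same order).

    Log-linear form of the product of the class, stick, proximity and
    direction terms; additive constants that are shared by every remaining
    item (e.g. ``log(1 - p_A)``) are dropped as they cancel on
    normalisation.
    """
    if not state.remaining:
        raise ValueError("selection weights undefined for an empty remaining set")
    diag = math.hypot(width, height)
    lw = np.zeros(len(state.remaining))
    for i, it in enumerate(state.remaining):
        if it.item_class == "A":
            lw[i] += params.b_A
        if state.last is not None:
            if it.item_class == state.last.item_class:
                lw[i] += params.b_S
            d = math.hypot(it.x - state.last.x, it.y - state.last.y) / diag
            lw[i] -= params.sigma_rho * d
            if state.prev is not None:
                lw[i] += params.sigma_d * _cosine_direction(state.prev, state.last, it)
    return lw


def selection_weights(
    state: SelectionState, params: ModelParams, width: float, height: float
) -> np.ndarray:
    """Normalised selection probabilities over ``state.remaining``."""
    lw = selection_log_weights(state, params, width, height)
    lw -= lw.max()
    w = np.exp(lw)
    return w / w.sum()


def simulate_trial(
    display: TrialDisplay, params: ModelParams, rng: np.random.Generator
) -> SelectionSequence:
    """Simulate one complete trial: every target selected exactly once.

    Each selection is drawn from :func:`selection_weights` of the current
    state; reproducible given the ``rng`` state.
    """
    state = SelectionState.initial(display)
    order: list[int] = []
    while state.remaining:
        w = selection_weights(state, params, display.width, display.height)
        idx = int(rng.choice(len(state.remaining), p=w))
        chosen = state.remaining[idx]
        order.append(chosen.item_id)
        state.advance(chosen)
    return SelectionSequence(selected_ids=tuple(order))


def trial_loglik(
    display: TrialDisplay, seq: SelectionSequence, params: ModelParams
) -> float:
    """Log-probability of an observed selection sequence under the model.

    Sum over selections of the log of that selection's normalised weight.
    The first selection (class term only) is included.
    """
    seq.validate_against(display)
    state = SelectionState.initial(display)
    ll = 0.0
    for item_id in seq.selected_ids:
        lw = selection_log_weights(state, params, display.width, display.height)
        idx = next(
            i for i, it in enumerate(state.remaining) if it.item_id == item_id
        )
        ll += lw[idx] - logsumexp(lw)
        state.advance(state.remaining[idx])
    return float(ll)


def enumerate_trial_probs(
    display: TrialDisplay, params: ModelParams
) -> dict[Tuple[int, ...], float]:
    """Brute-force oracle: probability of every complete selection ordering.

    Only feasible for small displays; refuses more than
    ``MAX_ENUMERATION_TARGETS`` targets.  The returned probabilities sum to
    one up to floating-point error.
    """
    targets = display.targets
    if len(targets) > MAX_ENUMERATION_TARGETS:
        raise ValueError(
            f"enumeration limited to {MAX_ENUMERATION_TARGETS} targets; "
            f"display has {len(targets)}"
        )
    out: dict[Tuple[int, ...], float] = {}
    for perm in itertools.permutations(targets):
        order = tuple(it.item_id for it in perm)
        out[order] = math.exp(
            trial_loglik(display, SelectionSequence(order), params)
        )
    return out
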