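"""Precomputed design tensors for fast trial log-likelihoods.

The unnormalised log-weight of a candidate item is linear in the four model
parameters:

    log w = b_A * 1[class A]  +  b_S * 1[same class as last]
            - sigma_rho * d_norm  +  sigma_d * cos(phi)

so each selection step of an observed sequence is a conditional-logit
(softmax) observation with a fixed 4-column feature matrix over the
remaining targets.  For a fixed (display, sequence) pair all features are
data only; this module precomputes them once so that evaluating the
log-likelihood for new parameter values reduces to a batched matrix
product plus a masked log-sum-exp.  The MCMC sampler re-evaluates the
likelihood tens of thousands of times, which makes this the hot path.

Feature column order is ``(1[A], 1[same-as-last], -d_norm, cos(phi))`` so
that the coefficient vector is exactly ``(b_A, b_S, sigma_rho, sigma_d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

from .model import SelectionSequence, TrialDisplay

__all__ = ["TrialDesign", "build_trial_design", "stack_trials", "TrialBatch"]

N_FEATURES = 4


@dataclass(frozen=True)
class TrialDesign:
    """Feature tensors of one (display, sequence) pair.

    ``features`` has shape (n_steps, n_targets, 4); ``valid`` marks which
    (step, item) pairs are still in the remaining set; ``chosen`` gives the
    row index (within the target axis) selected at each step.
    """

    features: np.ndarray
    valid: np.ndarray
    chosen: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.features.shape[0]

    def loglik(self, theta: Sequence[float]) -> float:
        scores = self.features @ np.asarray(theta, dtype=float)
        scores = np.where(self.valid, scores, -np.inf)
        m = scores.max(axis=1)
        lse = m + np.log(np.exp(scores - m[:, None]).sum(axis=1))
        return float(
            (scores[np.arange(self.n_steps), self.chosen] - lse).sum()
        )


def build_trial_design(display: TrialDisplay, seq: SelectionSequence) -> TrialDesign:
    """Precompute the softmax feature tensor of one observed trial."""
    seq.validate_against(display)
    targets = display.targets
    n = len(targets)
    steps = len(seq)
    idx_of = {it.item_id: i for i, it in enumerate(targets)}
    xy = np.array([[it.x, it.y] for it in targets])
    is_a = np.array([1.0 if it.item_class == "A" else 0.0 for it in targets])
    classes = np.array([it.item_class for it in targets])
    diag = display.diagonal

    features = np.zeros((steps, n, N_FEATURES))
    valid = np.ones((steps, n), dtype=bool)
    chosen = np.zeros(steps, dtype=np.intp)

    remaining = np.ones(n, dtype=bool)
    last = prev = None  # target-array indices
    for s, item_id in enumerate(seq.selected_ids):
        j = idx_of[item_id]
        valid[s] = remaining
        chosen[s] = j
        features[s, :, 0] = is_a
        if last is not None:
            features[s, :, 1] = (classes == classes[last]).astype(float)
            delta = xy - xy[last]
            dist = np.hypot(delta[:, 0], delta[:, 1])
            features[s, :, 2] = -dist / diag
            if prev is not None:
                v = xy[last] - xy[prev]
                nv = math.hypot(v[0], v[1])
                nu = dist
                with np.errstate(invalid="ignore", divide="ignore"):
                    cos = delta @ v / (nu * nv)
                cos[~np.isfinite(cos)] = 0.0  # coincident positions: neutral
                if nv == 0.0:
                    cos[:] = 0.0
                features[s, :, 3] = cos
        remaining = remaining.copy()
        remaining[j] = False
        prev, last = last, j
    return TrialDesign(features=features, valid=valid, chosen=chosen)


@dataclass(frozen=True)
class TrialBatch:
    """A stack of trial designs padded to common (steps, targets) shape.

    Evaluates the summed log-likelihood of many trials, for one parameter
    vector (``loglik``) or one parameter vector per trial group
    (``loglik_by_group``, used for per-participant parameters).
    """

    features: np.ndarray  # (n_trials, max_steps, max_targets, 4)
    valid: np.ndarray  # (n_trials, max_steps, max_targets)
    chosen: np.ndarray  # (n_trials, max_steps)
    step_mask: np.ndarray  # (n_trials, max_steps) real (non-padding) steps

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    def loglik(self, theta: Sequence[float]) -> float:
        theta = np.asarray(theta, dtype=float)
        return float(self._step_logliks(self.features @ theta).sum())

    def loglik_per_trial(self, theta_per_trial: np.ndarray) -> np.ndarray:
        """Summed step log-liks per trial; ``theta_per_trial`` is (n_trials, 4).

        Uses a compiled kernel (this sits on the samplers' hot path); the
        pure-numpy evaluation is kept as ``loglik_per_trial_numpy`` and the
        two are verified against each other in the test suite.
        """
        theta_per_trial = np.ascontiguousarray(theta_per_trial, dtype=np.float64)
        return _loglik_kernel(
            self.features, self.valid, self.chosen, self.step_mask, theta_per_trial
        )

    def loglik_per_trial_numpy(self, theta_per_trial: np.ndarray) -> np.ndarray:
        scores = np.einsum("tsnf,tf->tsn", self.features, theta_per_trial)
        return self._step_logliks(scores).sum(axis=1)

    def _step_logliks(self, scores: np.ndarray) -> np.ndarray:
        scores = np.where(self.valid, scores, -np.inf)
        m = scores.max(axis=-1)
        lse = m + np.log(np.exp(scores - m[..., None]).sum(axis=-1))
        t = np.arange(self.n_trials)[:, None]
        s = np.arange(self.features.shape[1])[None, :]
        step_ll = scores[t, s, self.chosen] - lse
        return np.where(self.step_mask, step_ll, 0.0)


@numba.njit(cache=True, fastmath=True)
def _loglik_kernel(features, valid, chosen, step_mask, theta):  # pragma: no cover
    n_trials, n_steps, n_items, _ = features.shape
    out = np.zeros(n_trials)
    for t in range(n_trials):
        b0, b1, b2, b3 = theta[t, 0], theta[t, 1], theta[t, 2], theta[t, 3]
        acc = 0.0
        for s in range(n_steps):
            if not step_mask[t, s]:
                break  # padded steps are trailing
            m = -1e300
            for n in range(n_items):
                if valid[t, s, n]:
                    sc = (
                        features[t, s, n, 0] * b0
                        + features[t, s, n, 1] * b1
                        + features[t, s, n, 2] * b2
                        + features[t, s, n, 3] * b3
                    )
                    if sc > m:
                        m = sc
            tot = 0.0
            for n in range(n_items):
                if valid[t, s, n]:
                    sc = (
                        features[t, s, n, 0] * b0
                        + features[t, s, n, 1] * b1
                        + features[t, s, n, 2] * b2
                        + features[t, s, n, 3] * b3
                    )
                    tot += math.exp(sc - m)
            c = chosen[t, s]
            sc = (
                features[t, s, c, 0] * b0
                + features[t, s, c, 1] * b1
                + features[t, s, c, 2] * b2
                + features[t, s, c, 3] * b3
            )
            acc += sc - m - math.log(tot)
        out[t] = acc
    return out


def stack_trials(designs: Sequence[TrialDesign]) -> TrialBatch:
    """Pad a list of :class:`TrialDesign` into one batch tensor."""
    if not designs:
        raise ValueError("cannot stack an empty list of trials")
    max_steps = max(d.n_steps for d in designs)
    max_targets = max(d.features.shape[1] for d in designs)
    n = len(designs)
    features = np.zeros((n, max_steps, max_targets, N_FEATURES))
    valid = np.zeros((n, max_steps, max_targets), dtype=bool)
    chosen = np.zeros((n, max_steps), dtype=np.intp)
    step_mask = np.zeros((n, max_steps), dtype=bool)
    for t, d in enumerate(designs):
        s, k = d.features.shape[:2]
        features[t, :s, :k] = d.features
        valid[t, :s, :k] = d.valid
        chosen[t, :s] = d.chosen
        step_mask[t, :s] = True
    # padded steps need one valid column so log-sum-exp stays finite
    valid[~step_mask, 0] = True
    return TrialBatch(features=features, valid=valid, chosen=chosen, step_mask=step_mask)
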