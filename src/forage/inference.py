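"""Hierarchical Bayesian fitting of the four-parameter foraging model.

Model
-----
For each experimental condition ``k`` there are group-level means
``b_A(k), b_S(k), sigma_rho(k), sigma_d(k)``.  Each participant ``j`` has
an independent normal offset per parameter and condition (random-effect
correlations are not modelled), with one standard deviation per parameter
shared across conditions:

    theta_p(j, k) = mu_p(k) + sd_p * z_p(j, k),     z ~ N(0, 1)

The likelihood is the sum of trial log-likelihoods of the generative
sampling-without-replacement model under each participant's effective
parameters.  Weakly informative priors: N(0,1) on the two log-odds group
means, N(15,5) on proximity tuning, N(0,1) on direction tuning;
half-normal(1) / half-normal(5) on the log-odds / tuning random-effect
standard deviations.

Sampler
-------
A blocked adaptive random-walk Metropolis (Metropolis-within-Gibbs)
sampler.  Per iteration:

1. joint random-walk update of each condition's four group means
   (conditions are conditionally independent given offsets and scales, so
   all condition blocks are evaluated in one batched likelihood call);
2. joint random-walk update of the four log random-effect scales;
3. per-cell random-walk update of each (participant, condition) offset
   vector (cells are conditionally independent, batched likewise);
4. exact Gibbs "recentering" of each group mean along the non-centred
   ridge (participant-level effective parameters are held fixed, so no
   likelihood evaluation is needed);
5. an interweaving move on each random-effect scale, again holding the
   effective parameters fixed.

Proposal scales adapt during warmup (Robbins-Monro on the acceptance rate,
component scales from running posterior-sd estimates) and are frozen
afterwards.  Convergence is summarised by the split-chain potential scale
reduction factor R-hat (fits with any R-hat >= 1.01 are flagged, not
rejected) and bulk effective sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Dataset
from .likelihood import TrialBatch, build_trial_design, stack_trials
from .model import ConditionKey, ModelParams

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "Diagnostics",
    "fit_model",
    "rhat",
    "posterior_summary",
    "log_posterior",
    "ModelData",
]

PARAMS = ModelParams.PARAM_NAMES
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on group means; half-normal on RE scales."""

    group_mean: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "b_A": (0.0, 1.0),
            "b_S": (0.0, 1.0),
            "sigma_rho": (15.0, 5.0),
            "sigma_d": (0.0, 1.0),
        }
    )
    re_scale: Mapping[str, float] = field(
        default_factory=lambda: {"b_A": 1.0, "b_S": 1.0, "sigma_rho": 5.0, "sigma_d": 5.0}
    )

    def __post_init__(self) -> None:
        for p in PARAMS:
            if self.group_mean[p][1] <= 0 or self.re_scale[p] <= 0:
                raise ValueError("prior standard deviations must be positive")

    def mean_loc(self) -> np.ndarray:
        return np.array([self.group_mean[p][0] for p in PARAMS])

    def mean_sd(self) -> np.ndarray:
        return np.array([self.group_mean[p][1] for p in PARAMS])

    def scale(self) -> np.ndarray:
        return np.array([self.re_scale[p] for p in PARAMS])


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1
    seed: int = 0
    sampler: str = "adaptive_metropolis"

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples, self.thin) <= 0:
            raise ValueError("chain counts must be positive")
        if self.sampler == "nuts":
            raise NotImplementedError(
                "no gradient-based backend is available; use sampler='adaptive_metropolis'"
            )
        if self.sampler != "adaptive_metropolis":
            raise ValueError(f"unknown sampler {self.sampler!r}")


class ModelData:
    """Dataset compiled into batched likelihood tensors.

    One "cell" is a (participant, condition) pair with at least one valid
    (non-terminated) trial; cells own their per-participant parameters.
    """

    def __init__(self, dataset: Dataset):
        from .model import ALL_CONDITIONS

        trials = [t for t in dataset.trials if not t.terminated]
        cell_keys = sorted({(t.participant_id, t.condition) for t in trials})
        self.cells: List[Tuple[str, ConditionKey]] = cell_keys
        # an empty dataset still defines a prior-only model over the
        # standard six conditions
        self.conditions: List[ConditionKey] = (
            sorted({c for _, c in cell_keys}) if cell_keys else list(ALL_CONDITIONS)
        )
        self.participants: List[str] = sorted({p for p, _ in cell_keys})
        cell_idx = {key: i for i, key in enumerate(cell_keys)}
        cond_idx = {c: i for i, c in enumerate(self.conditions)}
        self.cond_of_cell = np.array(
            [cond_idx[c] for _, c in cell_keys], dtype=np.intp
        )
        self.n_cells = len(cell_keys)
        self.n_conditions = len(self.conditions)
        if trials:
            order = sorted(
                trials, key=lambda t: (cell_idx[(t.participant_id, t.condition)], t.trial)
            )
            self.batch: Optional[TrialBatch] = stack_trials(
                [build_trial_design(t.display, t.sequence) for t in order]
            )
            self.trial_cell = np.array(
                [cell_idx[(t.participant_id, t.condition)] for t in order], dtype=np.intp
            )
        else:
            self.batch = None
            self.trial_cell = np.zeros(0, dtype=np.intp)

    def cell_logliks(self, theta_cells: np.ndarray) -> np.ndarray:
        """Summed trial log-likelihood per cell; ``theta_cells`` is (n_cells, 4)."""
        if self.batch is None:
            return np.zeros(0)
        per_trial = self.batch.loglik_per_trial(theta_cells[self.trial_cell])
        return np.bincount(self.trial_cell, weights=per_trial, minlength=self.n_cells)


def _halfnormal_logpdf(x: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (
        0.5 * math.log(2.0 / math.pi) - np.log(scale) - 0.5 * (x / scale) ** 2
    )


def log_posterior(
    data: ModelData,
    priors: PriorSpec,
    mu: np.ndarray,
    log_sd: np.ndarray,
    z: np.ndarray,
) -> float:
    """Joint log-density of the hierarchical model (the sampler's target).

    ``mu`` is (n_conditions, 4), ``log_sd`` (4,), ``z`` (n_cells, 4).  The
    random-effect scales are parameterised on the log scale; the density
    includes the Jacobian term of that transform.
    """
    sd = np.exp(log_sd)
    theta = mu[data.cond_of_cell] + sd * z if data.n_cells else np.zeros((0, 4))
    ll = float(data.cell_logliks(theta).sum())
    lp = float(
        (-0.5 * ((mu - priors.mean_loc()) / priors.mean_sd()) ** 2
         - np.log(priors.mean_sd()) - 0.5 * math.log(2 * math.pi)).sum()
    )
    lp += float((_halfnormal_logpdf(sd, priors.scale()) + log_sd).sum())
    lp += float((-0.5 * z**2 - 0.5 * math.log(2 * math.pi)).sum())
    return ll + lp


class PosteriorDraws:
    """MCMC draws with chain structure and structured parameter access.

    Parameter names: ``b_A[feature:scarceA]`` (group means),
    ``sd[b_A]`` (random-effect sds), ``u[b_A|P01|feature:scarceA]``
    (participant offsets).  ``truth`` maps names to generating values when
    the fitted dataset was simulated.
    """

    def __init__(
        self,
        array: np.ndarray,
        names: Sequence[str],
        conditions: Sequence[ConditionKey],
        participants: Sequence[str],
        truth: Optional[Dict[str, float]] = None,
    ):
        if array.ndim != 3 or array.shape[2] != len(names):
            raise ValueError("draws array must be (chains, iterations, parameters)")
        if not np.isfinite(array).all():
            raise ValueError("posterior draws contain non-finite values")
        self.array = array
        self.names = list(names)
        self._index = {n: i for i, n in enumerate(self.names)}
        self.conditions = list(conditions)
        self.participants = list(participants)
        self.truth = truth or {}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        if name not in self._index:
            raise KeyError(f"unknown parameter {name!r}")
        return self.array[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def group_mean(self, param: str, condition: ConditionKey | str) -> np.ndarray:
        return self.flat(f"{param}[{condition}]")

    def re_sd(self, param: str) -> np.ndarray:
        return self.flat(f"sd[{param}]")

    def offset(self, param: str, pid: str, condition: ConditionKey | str) -> np.ndarray:
        return self.flat(f"u[{param}|{pid}|{condition}]")

    def has(self, name: str) -> bool:
        return name in self._index

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) frame."""
        c, d, p = self.array.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d * p),
                "iteration": np.tile(np.repeat(np.arange(d), p), c),
                "parameter": np.tile(self.names, c * d),
                "value": self.array.reshape(-1),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        names = list(dict.fromkeys(df["parameter"]))
        chains = sorted(df["chain"].unique())
        iters = sorted(df["iteration"].unique())
        arr = (
            df.pivot_table(
                index=["chain", "iteration"], columns="parameter", values="value", sort=False
            )
            .reindex(columns=names)
            .to_numpy()
            .reshape(len(chains), len(iters), len(names))
        )
        conditions = sorted(
            {
                ConditionKey.parse(n[n.index("[") + 1 : -1])
                for n in names
                if "[" in n and not n.startswith(("sd[", "u["))
            }
        )
        participants = sorted(
            {n.split("|")[1] for n in names if n.startswith("u[")}
        )
        return cls(arr, names, conditions, participants)


@dataclass
class Diagnostics:
    """Convergence summary: split R-hat, bulk ESS, acceptance rates."""

    rhat: Dict[str, float]
    ess: Dict[str, float]
    accept_rates: Dict[str, float]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else 1.0

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.rhat), "rhat": list(self.rhat.values()),
             "ess": [self.ess.get(p, float("nan")) for p in self.rhat]}
        )


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, iterations) with at least two chains and
    four iterations.  Chains are split in half; R-hat compares the
    between- and within-half variances.  Zero-variance (constant) draws
    return exactly 1 by convention.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat requires draws with shape (chains >= 2, iterations)")
    if draws.shape[1] < 4:
        raise ValueError("rhat requires at least 4 iterations per chain")
    if draws.min() == draws.max():
        return 1.0  # constant draws: converged by convention
    n = draws.shape[1] // 2
    halves = np.concatenate([draws[:, :n], draws[:, n : 2 * n]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_hat = (n - 1) / n * within + between / n
    return float(math.sqrt(var_hat / within))


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter mean, sd, median and central 53% / 97% intervals."""
    qs = [0.235, 0.765, 0.015, 0.985]
    rows = []
    for name in draws.names:
        x = draws.flat(name)
        q = np.quantile(x, qs)
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "median": np.median(x),
                "ci53_low": q[0],
                "ci53_high": q[1],
                "ci97_low": q[2],
                "ci97_high": q[3],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# sampler internals


class _Adapt:
    """Robbins-Monro step-size and running-sd adaptation for one block set."""

    def __init__(self, shape, target: float, init_scale):
        self.log_lam = np.zeros(shape[:1] if len(shape) > 1 else shape)
        self.target = target
        self.mean = np.zeros(shape)
        self.m2 = np.zeros(shape)
        self.count = 0
        self.init_scale = np.broadcast_to(np.asarray(init_scale, dtype=float), shape).copy()

    def step(self, values: np.ndarray) -> np.ndarray:
        """Proposal sds: lam (per block) times per-component scale."""
        lam = np.exp(self.log_lam)
        if self.count >= 50:
            comp = np.sqrt(self.m2 / max(self.count - 1, 1)) + 1e-3
        else:
            comp = self.init_scale
        return (lam[..., None] if comp.ndim > 1 else lam) * comp

    def update(self, accepted: np.ndarray, values: np.ndarray, t: int) -> None:
        gamma = (t + 1) ** -0.6
        self.log_lam += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_lam, -6.0, 3.0, out=self.log_lam)
        self.count += 1
        delta = values - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (values - self.mean)


def _slice_log_scale(
    ls0: float,
    resid2: float,
    n_cells: int,
    hn_scale: float,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Slice-sample the conditional of one log random-effect scale.

    With the participant-level effective parameters held fixed, the
    conditional density of ``ls = log(sd)`` is

        f(ls) = -exp(2 ls) / (2 h^2) + (1 - C) ls - S exp(-2 ls) / 2

    where ``S`` is the summed squared offset residual over the ``C`` cells
    and ``h`` the half-normal prior scale (the ``(1 - C) ls`` term collects
    the log-parameterisation Jacobian and the change of variables from
    offsets to effective parameters).  Standard stepping-out plus
    shrinkage; the density is unimodal.
    """

    def f(ls: float) -> float:
        if abs(ls) > 12.0:
            return -np.inf
        return (
            -math.exp(2 * ls) / (2 * hn_scale**2)
            + (1 - n_cells) * ls
            - resid2 * math.exp(-2 * ls) / 2
        )

    y = f(ls0) - rng.exponential()
    lo = ls0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if f(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if f(hi) <= y:
            break
        hi += width
    for _ in range(max_steps):
        ls1 = lo + (hi - lo) * rng.uniform()
        if f(ls1) > y:
            return ls1
        if ls1 < ls0:
            lo = ls1
        else:
            hi = ls1
    return ls0


def _run_chain(
    data: ModelData,
    priors: PriorSpec,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict[str, float]]:
    """One chain; returns (mu, sd, u) draw arrays and acceptance rates."""
    K, C = data.n_conditions, data.n_cells
    m0, s0 = priors.mean_loc(), priors.mean_sd()
    hn_scale = priors.scale()

    mu = m0 + 0.1 * s0 * rng.normal(size=(K, 4))
    log_sd = np.log(0.5 * hn_scale) + 0.1 * rng.normal(size=4)
    z = 0.01 * rng.normal(size=(C, 4))

    sd = np.exp(log_sd)
    theta = mu[data.cond_of_cell] + sd * z if C else np.zeros((0, 4))
    cell_ll = data.cell_logliks(theta)

    adapt_mu = _Adapt((K, 4), 0.25, 0.2 * s0)
    adapt_sd = _Adapt((4,), 0.44, 0.2)
    # coordinate-wise adaptation for the per-cell offsets
    log_lam_z = np.zeros((C, 4))
    z_mean = np.zeros((C, 4))
    z_m2 = np.zeros((C, 4))
    z_count = 0

    n_iter = cfg.n_warmup + cfg.n_samples * cfg.thin
    out_mu = np.empty((cfg.n_samples, K, 4))
    out_sd = np.empty((cfg.n_samples, 4))
    out_u = np.empty((cfg.n_samples, C, 4))
    acc_tally = {"mu": 0.0, "sd": 0.0, "z": 0.0}
    n_kept = 0

    cells_per_cond = np.bincount(data.cond_of_cell, minlength=K).astype(float)

    for t in range(n_iter):
        warm = t < cfg.n_warmup

        # --- 1. group means, one 4-d block per condition (batched) -------
        step = adapt_mu.step(mu)
        prop_mu = mu + step * rng.normal(size=(K, 4))
        d_prior = (
            -0.5 * ((prop_mu - m0) / s0) ** 2 + 0.5 * ((mu - m0) / s0) ** 2
        ).sum(axis=1)
        if C:
            prop_theta = prop_mu[data.cond_of_cell] + sd * z
            prop_ll = data.cell_logliks(prop_theta)
            d_ll = np.bincount(data.cond_of_cell, weights=prop_ll - cell_ll, minlength=K)
        else:
            d_ll = np.zeros(K)
        acc = np.log(rng.uniform(size=K)) < d_prior + d_ll
        mu[acc] = prop_mu[acc]
        if C:
            cell_acc = acc[data.cond_of_cell]
            cell_ll[cell_acc] = prop_ll[cell_acc]
            theta = mu[data.cond_of_cell] + sd * z
        if warm:
            adapt_mu.update(acc, mu, t)
        else:
            acc_tally["mu"] += acc.mean() if K else 0.0

        # --- 2. log random-effect scales, coordinate-wise ----------------
        # With the offsets z held fixed this move rescales every cell's
        # residual together ("funnel breathing"); one coordinate at a time
        # so a hard rejection on one scale cannot veto the others.
        step = adapt_sd.step(log_sd)
        sd_acc = np.zeros(4, dtype=bool)
        for p in range(4):
            prop_ls = log_sd.copy()
            prop_ls[p] += step[p] * rng.normal()
            if abs(prop_ls[p]) >= 8.0:
                continue
            prop_sd = np.exp(prop_ls)
            d_prior = float(
                _halfnormal_logpdf(prop_sd[p], hn_scale[p]) + prop_ls[p]
                - _halfnormal_logpdf(sd[p], hn_scale[p]) - log_sd[p]
            )
            if C:
                prop_theta = mu[data.cond_of_cell] + prop_sd * z
                prop_ll = data.cell_logliks(prop_theta)
                d_ll_tot = float((prop_ll - cell_ll).sum())
            else:
                d_ll_tot = 0.0
            if math.log(rng.uniform()) < d_prior + d_ll_tot:
                sd_acc[p] = True
                log_sd, sd = prop_ls, prop_sd
                if C:
                    cell_ll = prop_ll
                    theta = prop_theta
        if warm:
            adapt_sd.update(sd_acc, log_sd, t)
        else:
            acc_tally["sd"] += sd_acc.mean()

        # --- 3. per-cell offsets, coordinate-wise (batched over cells) ---
        if C:
            if z_count >= 50:
                z_comp = np.sqrt(z_m2 / max(z_count - 1, 1)) + 1e-3
            else:
                z_comp = np.full((C, 4), 0.5)
            step = np.exp(log_lam_z) * z_comp
            gamma = (t + 1) ** -0.6
            acc_frac = 0.0
            for p in range(4):
                prop_z = z.copy()
                prop_z[:, p] += step[:, p] * rng.normal(size=C)
                prop_theta = mu[data.cond_of_cell] + sd * prop_z
                prop_ll = data.cell_logliks(prop_theta)
                d_post = prop_ll - cell_ll - 0.5 * (prop_z[:, p] ** 2 - z[:, p] ** 2)
                acc = np.log(rng.uniform(size=C)) < d_post
                z[acc, p] = prop_z[acc, p]
                cell_ll[acc] = prop_ll[acc]
                if warm:
                    log_lam_z[:, p] += gamma * (acc.astype(float) - 0.44)
                else:
                    acc_frac += acc.mean() / 4.0
            np.clip(log_lam_z, -6.0, 3.0, out=log_lam_z)
            theta = mu[data.cond_of_cell] + sd * z
            if warm:
                z_count += 1
                delta = z - z_mean
                z_mean += delta / z_count
                z_m2 += delta * (z - z_mean)
            else:
                acc_tally["z"] += acc_frac

        # --- 3b. independence refresh of one offset coordinate -----------
        # Proposing z from its N(0,1) prior (prior cancels against the
        # proposal, so the ratio is pure likelihood) gives global jumps
        # that de-correlate weakly identified offsets; coordinates cycle.
        if C:
            for p in (t % 4, (t + 2) % 4):
                prop_z = z.copy()
                prop_z[:, p] = rng.normal(size=C)
                prop_theta = mu[data.cond_of_cell] + sd * prop_z
                prop_ll = data.cell_logliks(prop_theta)
                acc = np.log(rng.uniform(size=C)) < prop_ll - cell_ll
                z[acc, p] = prop_z[acc, p]
                cell_ll[acc] = prop_ll[acc]
            theta = mu[data.cond_of_cell] + sd * z

        # --- 4. exact Gibbs recentering of group means -------------------
        # Effective parameters theta are held fixed, so the conditional of
        # mu given theta is Gaussian: prior x product of N(z) terms.
        if C:
            sums = np.stack(
                [
                    np.bincount(data.cond_of_cell, weights=theta[:, p], minlength=K)
                    for p in range(4)
                ],
                axis=1,
            )
            prec = 1.0 / s0**2 + cells_per_cond[:, None] / sd**2
            mean = (m0 / s0**2 + sums / sd**2) / prec
            mu = mean + rng.normal(size=(K, 4)) / np.sqrt(prec)
            z = (theta - mu[data.cond_of_cell]) / sd
        else:
            mu = m0 + s0 * rng.normal(size=(K, 4))

        # --- 5. interweaving on the scales: exact slice draw from the
        #        conditional of each log-scale given the effective
        #        parameters (theta fixed, so no likelihood evaluation) ----
        resid2 = (
            ((theta - mu[data.cond_of_cell]) ** 2).sum(axis=0) if C else np.zeros(4)
        )
        for p in range(4):
            log_sd[p] = _slice_log_scale(log_sd[p], resid2[p], C, hn_scale[p], rng)
        sd = np.exp(log_sd)
        if C:
            z = (theta - mu[data.cond_of_cell]) / sd

        if not warm and (t - cfg.n_warmup) % cfg.thin == cfg.thin - 1:
            out_mu[n_kept] = mu
            out_sd[n_kept] = sd
            out_u[n_kept] = sd * z if C else np.zeros((0, 4))
            n_kept += 1

    rates = {k: v / (cfg.n_samples * cfg.thin) for k, v in acc_tally.items()}
    return out_mu, out_sd, out_u, rates


def _attach_truth(dataset: Dataset, data: ModelData) -> Dict[str, float]:
    truth: Dict[str, float] = {}
    group = dataset.generating
    if group is None:
        return truth
    for k in data.conditions:
        mp = group.means[k]
        for p in PARAMS:
            truth[f"{p}[{k}]"] = getattr(mp, p)
    for p in PARAMS:
        truth[f"sd[{p}]"] = group.re_sd[p]
    if dataset.true_participant_params:
        for (pid, k), mp in dataset.true_participant_params.items():
            if (pid, k) in set(data.cells):
                for p in PARAMS:
                    truth[f"u[{p}|{pid}|{k}]"] = getattr(mp, p) - getattr(
                        group.means[k], p
                    )
    return truth


def fit_model(
    dataset: Dataset,
    priors: PriorSpec = PriorSpec(),
    cfg: McmcConfig = McmcConfig(),
) -> Tuple[PosteriorDraws, Diagnostics]:
    """Fit the hierarchical model; returns posterior draws and diagnostics.

    An empty dataset is legal and yields prior-only sampling of the group
    means and scales.  Non-convergence (any split R-hat >= 1.01) is
    flagged in the diagnostics, not raised.
    """
    data = ModelData(dataset)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains_mu, chains_sd, chains_u = [], [], []
    rates_acc: Dict[str, float] = {}
    for ss in seeds:
        m, s, u, rates = _run_chain(data, priors, cfg, np.random.default_rng(ss))
        chains_mu.append(m)
        chains_sd.append(s)
        chains_u.append(u)
        for k, v in rates.items():
            rates_acc[k] = rates_acc.get(k, 0.0) + v / cfg.n_chains

    names: List[str] = []
    for k in data.conditions:
        names += [f"{p}[{k}]" for p in PARAMS]
    names += [f"sd[{p}]" for p in PARAMS]
    for pid, k in data.cells:
        names += [f"u[{p}|{pid}|{k}]" for p in PARAMS]

    n_ch, n_dr = cfg.n_chains, cfg.n_samples
    arr = np.empty((n_ch, n_dr, len(names)))
    K, C = data.n_conditions, data.n_cells
    for c in range(n_ch):
        arr[c, :, : 4 * K] = chains_mu[c].reshape(n_dr, -1)
        arr[c, :, 4 * K : 4 * K + 4] = chains_sd[c]
        if C:
            arr[c, :, 4 * K + 4 :] = chains_u[c].reshape(n_dr, -1)

    draws = PosteriorDraws(
        arr,
        names,
        data.conditions,
        data.participants,
        truth=_attach_truth(dataset, data),
    )
    rh = {name: rhat(draws.get(name)) for name in names}
    ess = _bulk_ess(arr, names)
    return draws, Diagnostics(rhat=rh, ess=ess, accept_rates=rates_acc)


def _bulk_ess(arr: np.ndarray, names: Sequence[str]) -> Dict[str, float]:
    import arviz as az

    ds = az.convert_to_dataset(
        {n: arr[:, :, i] for i, n in enumerate(names)}
    )
    ess = az.ess(ds)
    return {n: float(ess[n].values) for n in names}
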