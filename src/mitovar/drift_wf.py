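"""Neutral Wright-Fisher drift of mtDNA heteroplasmy within a cell.

A cell carries a fixed number M of mitochondrial genome copies.  Each cell
division resamples the mutant copy number of a segregating site binomially:
X' ~ Binomial(M, X/M), with absorbing boundaries at X = 0 (loss) and X = M
(homoplasmy).  New mutations arise at a uniform rate mu per base pair per
cell division over a genome of L sites and enter on a single genome copy
(X = 1).  Under neutrality the fixation probability of an allele at copy
number X is rho = X/M, the expected conditional time to fixation is about
2M generations, and the expected number of homoplasmic mutations after T
generations is E[N] = mu * L * (T - 2M): linear accumulation delayed by the
drift transient.  Sites drift independently (single-site marginal model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DriftParams",
    "DriftResult",
    "wf_simulate",
    "wf_absorption",
    "wf_trajectories",
    "expected_homoplasmic",
    "fixation_time_check",
]


@dataclass(frozen=True)
class DriftParams:
    """Parameters of the within-cell drift model.

    M: mtDNA copies per cell; mu: mutation rate per bp per cell division;
    L: genome length in bp; T: number of cell generations; reps: Monte-Carlo
    replicates.
    """

    M: int
    mu: float
    L: int
    T: int
    reps: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class DriftResult:
    """Outcome of a multi-replicate drift simulation.

    ``homoplasmic_counts[r]`` is the number of sites fixed at X = M in
    replicate r after T generations; ``segregating_counts`` the number still
    heteroplasmic; ``fixation_times`` the generations from origination to
    fixation for every fixation event (pooled over replicates).
    """

    params: DriftParams
    homoplasmic_counts: np.ndarray
    segregating_counts: np.ndarray
    fixation_times: np.ndarray

    @property
    def mean_homoplasmic(self) -> float:
        return float(self.homoplasmic_counts.mean())


def wf_absorption(
    M: int,
    x0: int,
    reps: int,
    seed: Optional[int] = None,
    max_generations: Optional[int] = None,
    horizon: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drift ``reps`` independent alleles from copy number ``x0`` to absorption.

    Returns (final copy numbers, absorption generation; -1 when still
    segregating at the horizon).  ``horizon`` optionally caps each replicate
    at its own number of generations; ``max_generations`` is a global cap
    (default 100 * M, ample since conditional absorption takes O(M)).
    """
    if not 0 <= x0 <= M:
        raise ValueError("x0 must lie in [0, M]")
    rng = np.random.default_rng(seed)
    if max_generations is None:
        max_generations = 100 * M
    if horizon is None:
        horizon = np.full(reps, max_generations, dtype=np.int64)
    else:
        horizon = np.minimum(np.asarray(horizon, dtype=np.int64), max_generations)
    x = np.full(reps, x0, dtype=np.int64)
    t_abs = np.full(reps, -1, dtype=np.int64)
    active = (x > 0) & (x < M) & (horizon > 0)
    gen = 0
    while active.any():
        gen += 1
        idx = np.flatnonzero(active)
        x[idx] = rng.binomial(M, x[idx] / M)
        absorbed = idx[(x[idx] == 0) | (x[idx] == M)]
        t_abs[absorbed] = gen
        active[absorbed] = False
        active[idx[horizon[idx] <= gen]] = False
    return x, t_abs


def wf_trajectories(
    M: int, x0: int, reps: int, generations: int, seed: Optional[int] = None
) -> np.ndarray:
    """Full copy-number trajectories, shape (generations + 1, reps).

    Absorbing states persist once reached.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((generations + 1, reps), dtype=np.int64)
    out[0] = x0
    x = np.full(reps, x0, dtype=np.int64)
    for g in range(1, generations + 1):
        seg = (x > 0) & (x < M)
        x[seg] = rng.binomial(M, x[seg] / M)
        out[g] = x
    return out


def wf_simulate(params: DriftParams) -> DriftResult:
    """Simulate mutation accumulation and drift to homoplasmy.

    Per replicate and generation, Poisson(mu * L * M) new mutations arise,
    each on one genome copy (X = 1) at its own site (infinite-sites within a
    run: multiple hits are not modelled).  Each segregating site then drifts
    by binomial resampling until loss, fixation or the horizon T.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    theta = p.mu * p.L * p.M  # expected new mutations per cell division
    # Arrivals pooled over replicates and generations, then drifted jointly.
    n_new = rng.poisson(theta, size=(p.reps, p.T)) if p.T > 0 else np.zeros((p.reps, 0), int)
    rep_idx = np.repeat(np.arange(p.reps), n_new.sum(axis=1))
    gen_idx = np.concatenate(
        [np.repeat(np.arange(p.T), n_new[r]) for r in range(p.reps)]
    ) if rep_idx.size else np.empty(0, dtype=int)
    remaining = p.T - gen_idx  # generations left to drift after origination
    sub_seed = int(rng.integers(2**31 - 1))
    x_final, t_abs = wf_absorption(
        p.M, 1, rep_idx.size, seed=sub_seed, horizon=remaining,
        max_generations=max(p.T, 1),
    ) if rep_idx.size else (np.empty(0, int), np.empty(0, int))

    fixed = x_final == p.M
    segregating = (x_final > 0) & (x_final < p.M)
    hom = np.bincount(rep_idx[fixed], minlength=p.reps)
    seg = np.bincount(rep_idx[segregating], minlength=p.reps)
    return DriftResult(
        params=p,
        homoplasmic_counts=hom,
        segregating_counts=seg,
        fixation_times=t_abs[fixed].astype(np.int64),
    )


def expected_homoplasmic(mu: float, L: int, T: float, M: int) -> float:
    """Closed-form expected homoplasmic mutation count mu * L * (T - 2M).

    The 2M term is the drift delay (mean conditional fixation time).  For
    T < 2M the approximation would be negative; 0 is returned with a warning
    since no mutation has had time to fix.
    """
    if mu < 0 or L < 1 or M < 1 or T < 0:
        raise ValueError("negative or degenerate drift parameters")
    if T < 2 * M:
        warnings.warn(
            "T < 2M: the delayed-accumulation approximation returns 0",
            stacklevel=2,
        )
        return 0.0
    return mu * L * (T - 2 * M)


def fixation_time_check(
    M: int, reps: int, seed: Optional[int] = None
) -> dict[str, float]:
    """Monte-Carlo mean time to fixation of a new mutant (X0 = 1),
    conditioned on fixation, alongside the 2M reference value.

    Returns mean, standard error, number of fixation events and the
    reference 2M.  With M = 1 every new mutation is instantly homoplasmic.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if M == 1:
        return {"mean_fixation_time": 0.0, "se": 0.0, "n_fixed": float(reps), "reference_2m": 2.0}
    x, t = wf_absorption(M, 1, reps, seed=seed)
    times = t[x == M].astype(float)
    if times.size == 0:
        warnings.warn("no fixation events; increase reps", stacklevel=2)
        return {"mean_fixation_time": float("nan"), "se": float("nan"), "n_fixed": 0.0, "reference_2m": float(2 * M)}
    return {
        "mean_fixation_time": float(times.mean()),
        "se": float(times.std(ddof=1) / np.sqrt(times.size)) if times.size > 1 else float("nan"),
        "n_fixed": float(times.size),
        "reference_2m": float(2 * M),
    }
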