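"""Practical identifiability: posterior sampling, intervals and sweeps.

The posterior over free model parameters (flat prior on the fitting box,
likelihood from :mod:`ctldyn.inference`) is explored with an adaptive
Metropolis parallel hierarchical sampler: a main chain targets the
posterior while auxiliary chains run adaptive Metropolis on tempered
versions of it and periodically propose exchange moves up the
temperature ladder.  Proposal covariances adapt from each chain's own
history (Haario-style scaled empirical covariance).  Sampling operates
on log10-transformed parameters, matching the fitting transform.

Downstream utilities compute 1-99% credible intervals (flagging bounds
that escape to the prior box as undetermined), one-dimensional
likelihood sweeps, and posterior-predictive trajectory ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import NegativeLogLikelihood
from .model import SimulationError, initial_state, simulate_fast
from .observations import ObservationSet
from .params import TumorImmuneParams


@dataclass(frozen=True)
class AMPHSSettings:
    """Sampler settings.

    ``n_steps`` of 100,000 with 20 auxiliary chains reproduces the
    study-scale analysis; the defaults here are CI-scale.  Half of the
    main chain is retained (burn-in discarded).
    """

    n_steps: int = 5000
    n_aux_chains: int = 20
    temperature_factor: float = 1.5   #: chain i is tempered by beta = factor^-i
    adapt_start: int = 200            #: step at which covariance adaptation begins
    adapt_interval: int = 25          #: cholesky refresh cadence
    exchange_interval: int = 5        #: steps between exchange proposals
    initial_step_frac: float = 0.02   #: pre-adaptation proposal sd, fraction of box
    seed: int = 0


@dataclass
class PosteriorSamples:
    """Retained main-chain draws (natural parameter scale) plus metadata."""

    draws: np.ndarray                 # (n_retained, d)
    names: tuple[str, ...]
    bounds: np.ndarray                # (d, 2) natural scale
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.names):
            raise ValueError("draws must be (n, d) matching names")
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.draws < lo - 1e-12) or np.any(self.draws > hi + 1e-12):
            raise ValueError("draws outside bounds")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def am_phs_sample(log_post, init_sets: np.ndarray, bounds: np.ndarray,
                  names, settings: AMPHSSettings | None = None) -> PosteriorSamples:
    """Adaptive Metropolis parallel hierarchical sampling.

    ``log_post`` maps a natural-scale parameter vector to the
    log-posterior density (up to a constant) *with respect to log10
    parameter volume*; ``init_sets`` must provide one starting vector
    for the main chain and each auxiliary chain (``n_aux_chains + 1``
    rows, e.g. the best multistart optima).  Deterministic given the
    settings seed.
    """
    settings = settings if settings is not None else AMPHSSettings()
    init_sets = np.asarray(init_sets, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    n_chains = settings.n_aux_chains + 1
    d = bounds.shape[0]
    if init_sets.shape[0] < n_chains:
        raise ValueError(
            f"need {n_chains} initial parameter sets "
            f"(main + {settings.n_aux_chains} auxiliary), got {init_sets.shape[0]}")
    if init_sets.shape[1] != d:
        raise ValueError("initial sets do not match bounds dimension")

    rng = np.random.default_rng(settings.seed)
    log_lo, log_hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    span = log_hi - log_lo

    beta = settings.temperature_factor ** -np.arange(n_chains)
    x = np.log10(init_sets[:n_chains]).copy()
    lp = np.array([log_post(10.0 ** xi) for xi in x])

    # running moments per chain for Haario-style adaptation
    mean = x.copy()
    m2 = np.zeros((n_chains, d, d))
    count = np.ones(n_chains)
    chol = np.empty((n_chains, d, d))
    base_step = settings.initial_step_frac * span
    for c in range(n_chains):
        chol[c] = np.diag(base_step)
    scale = (2.38 ** 2) / d

    n_accept = np.zeros(n_chains)
    n_exchange = 0
    n_exchange_acc = 0
    main_chain = np.empty((settings.n_steps, d))

    for step in range(settings.n_steps):
        for c in range(n_chains):
            prop = x[c] + chol[c] @ rng.standard_normal(d)
            if np.all(prop >= log_lo) and np.all(prop <= log_hi):
                lp_prop = log_post(10.0 ** prop)
                if np.log(rng.uniform()) < beta[c] * (lp_prop - lp[c]):
                    x[c] = prop
                    lp[c] = lp_prop
                    n_accept[c] += 1
            else:
                rng.uniform()  # keep the draw stream aligned
            # update running mean / scatter
            count[c] += 1
            delta = x[c] - mean[c]
            mean[c] += delta / count[c]
            m2[c] += np.outer(delta, x[c] - mean[c])
            if (step >= settings.adapt_start
                    and step % settings.adapt_interval == 0):
                cov = m2[c] / (count[c] - 1)
                cov = scale * cov + 1e-10 * np.eye(d)
                try:
                    chol[c] = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        if step % settings.exchange_interval == 0 and n_chains > 1:
            j = int(rng.integers(n_chains - 1))
            log_r = (beta[j] - beta[j + 1]) * (lp[j + 1] - lp[j])
            n_exchange += 1
            if np.log(rng.uniform()) < log_r:
                x[[j, j + 1]] = x[[j + 1, j]]
                lp[[j, j + 1]] = lp[[j + 1, j]]
                n_exchange_acc += 1
        main_chain[step] = x[0]

    n_retained = settings.n_steps // 2
    draws = 10.0 ** main_chain[settings.n_steps - n_retained:]
    acc = n_accept / settings.n_steps
    return PosteriorSamples(
        draws=draws, names=tuple(names), bounds=bounds,
        meta={"n_steps": settings.n_steps, "n_retained": n_retained,
              "n_aux_chains": settings.n_aux_chains,
              "acceptance_rates": acc.tolist(),
              "exchange_acceptance": (n_exchange_acc / n_exchange
                                      if n_exchange else float("nan")),
              "seed": settings.seed,
              "temperature_factor": settings.temperature_factor})


def sample_posterior(observations: ObservationSet, fit_top_sets,
                     variant: str = "all",
                     base_params: TumorImmuneParams | None = None,
                     v0: float = 100.0,
                     settings: AMPHSSettings | None = None) -> PosteriorSamples:
    """Sample the model posterior starting from multistart optima.

    ``fit_top_sets`` is the ``top_sets`` attribute of a
    :class:`~ctldyn.inference.FitResult` (best parameter sets first).
    The prior is flat on the fitting box in log10 space.
    """
    nll = NegativeLogLikelihood(observations, variant, base_params, v0)
    names = nll.free
    bounds = np.array([nll.base.bounds[n] for n in names], dtype=float)
    init = np.array([[vals[n] for n in names] for _, vals in fit_top_sets])

    def log_post(theta_natural):
        x = np.log10(theta_natural)
        return -nll(x)

    return am_phs_sample(log_post, init, bounds, names, settings)


def credible_intervals(samples: PosteriorSamples,
                       levels: tuple[float, float] = (0.01, 0.99),
                       bound_tol: float = 0.01) -> pd.DataFrame:
    """Per-parameter credible intervals from retained draws.

    Empirical quantiles at ``levels`` (1% and 99% by default).  An
    interval end lying within ``bound_tol`` of the prior box (as a
    fraction of the log10 span) is reported as undetermined: the data do
    not constrain that side of the parameter.
    """
    if samples.draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws")
    lo_q, hi_q = np.quantile(samples.draws, levels, axis=0)
    log_lo = np.log10(samples.bounds[:, 0])
    log_hi = np.log10(samples.bounds[:, 1])
    span = np.maximum(log_hi - log_lo, 1e-12)
    rows = []
    for i, name in enumerate(samples.names):
        low_ok = (np.log10(lo_q[i]) - log_lo[i]) / span[i] > bound_tol
        high_ok = (log_hi[i] - np.log10(hi_q[i])) / span[i] > bound_tol
        rows.append({"parameter": name,
                     "low": lo_q[i] if low_ok else np.nan,
                     "high": hi_q[i] if high_ok else np.nan,
                     "low_determined": bool(low_ok),
                     "high_determined": bool(high_ok)})
    return pd.DataFrame(rows)


def likelihood_sweep(params: TumorImmuneParams, which: str, values,
                     observations: ObservationSet, variant: str = "all",
                     v0: float = 100.0) -> pd.DataFrame:
    """Profile the log likelihood along one parameter.

    All other parameters stay at ``params``; returns a
    ``(parameter, value, logL)`` table for plotting.
    """
    nll = NegativeLogLikelihood(observations, variant, base_params=params,
                                v0=v0)
    if which not in nll.free and which not in ("kl", "kt", "kp"):
        raise ValueError(f"unknown or fixed parameter {which!r}")
    rows = []
    for v in np.asarray(values, dtype=float):
        p = params.with_values(**{which: float(v)})
        with np.errstate(divide="ignore"):
            # zeroed checkpoint weights map to -inf, i.e. 10**x == 0
            x = np.log10([getattr(p, n) for n in nll.free])
        rows.append({"parameter": which, "value": float(v), "logL": -nll(x)})
    return pd.DataFrame(rows)


def posterior_predictive(samples: PosteriorSamples, n_draws: int, seed: int,
                         base_params: TumorImmuneParams,
                         times=None, v0: float = 100.0) -> dict:
    """Simulate the model for posterior draws.

    Returns ``{"trajectories": [(draw_index, (times, states))...],
    "failures": [(draw_index, message)...]}``; simulation failures are
    recorded per draw rather than aborting the ensemble.
    """
    if times is None:
        times = np.linspace(-1.0, 14.0, 76)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n_total = samples.draws.shape[0]
    if n_draws <= 0:
        return {"trajectories": [], "failures": []}
    idx = rng.choice(n_total, size=min(n_draws, n_total), replace=False)
    trajectories = []
    failures = []
    for i in sorted(int(j) for j in idx):
        values = dict(zip(samples.names, samples.draws[i]))
        params = base_params.with_values(**values)
        init = initial_state(params, v0=v0, t0=min(times[0], 0.0))
        try:
            ys = simulate_fast(params, init, times)
            trajectories.append((i, (times, ys)))
        except SimulationError as exc:
            failures.append((i, str(exc)))
    return {"trajectories": trajectories, "failures": failures}
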