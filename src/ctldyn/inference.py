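"""Likelihood-based inference for the CTL-melanoma model.

Maps model trajectories onto the eight experimental observables,
evaluates the Gaussian log likelihood over all included observations
simultaneously, fits checkpoint model variants by multistart bounded
maximum likelihood (Latin-hypercube starts + L-BFGS-B in log space),
ranks variants by AIC, and runs the exhaustive killing-vs-arrest grid
search for the input-forced basic model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import _fast
from .calibration import basal_growth_rate, steady_state_ratio
from .model import (InputSignals, SimulationError, initial_state,
                    simulate_fast)
from .observations import ObservationSet
from .params import TumorImmuneParams

#: Coefficients of the housekeeping-gene noise regression used to assign
#: standard deviations to single-sample checkpoint expression values.
SD_INTERCEPT = 0.054
SD_SLOPE = 0.29

_PENALTY = 1e10
_RESID_PENALTY = 1e6

_EXPRESSION_MAP = {"ifng": "I", "pdcd1": "P", "cd274": "PL",
                   "lag3": "L", "havcr2": "H"}


def checkpoint_sd(mean_expr):
    """Standard deviation assigned to a normalized expression value.

    Linear mean-sd relation estimated from stable housekeeping
    transcripts: ``sd = 0.054 + 0.29 * mean``.
    """
    mean_expr = np.asarray(mean_expr, dtype=float)
    if np.any(mean_expr < 0):
        raise ValueError("mean expression must be nonnegative")
    out = SD_INTERCEPT + SD_SLOPE * mean_expr
    return float(out) if out.ndim == 0 else out


def log_likelihood(predictions, observations: ObservationSet) -> float:
    """Gaussian log likelihood ``-1/2 sum ((y - ybar)/sd)^2``.

    Only observations flagged ``include`` contribute; excluded points
    are ignored entirely.
    """
    pred = np.asarray(predictions, dtype=float)
    df = observations.data
    if len(pred) != len(df):
        raise ValueError("one prediction per observation row required")
    mask = df["include"].astype(bool).to_numpy()
    sd = df["sd"].to_numpy(dtype=float)[mask]
    if np.any(sd <= 0):
        raise ValueError("included observations must have sd > 0")
    resid = (pred[mask] - df["mean"].to_numpy(dtype=float)[mask]) / sd
    return float(-0.5 * np.sum(resid ** 2))


class ObservationMapper:
    """Precomputed index mapping trajectories onto observation rows.

    Treated-condition rows are read from a full-model simulation started
    at the earliest needed day; untreated rows are basal-model
    predictions (constant growth rate, steady-state cycle ratio).
    """

    def __init__(self, observations: ObservationSet, v0: float = 100.0):
        self.observations = observations
        self.v0 = v0
        df = observations.data
        times: set[float] = set()
        for _, row in df.iterrows():
            if row["condition"] != "treated":
                continue
            if row["observable"] == "growth_rate":
                times.add(float(row["day_start"]))
                times.add(float(row["day_end"]))
            else:
                times.add(float(row["day"]))
        self.t_eval = np.array(sorted(times), dtype=float)
        self.t_start = min(self.t_eval[0], 0.0) if len(self.t_eval) else 0.0
        index = {t: i for i, t in enumerate(self.t_eval)}

        kinds, i0, i1, dt = [], [], [], []
        for _, row in df.iterrows():
            obs_name, cond = row["observable"], row["condition"]
            if cond == "treated":
                if obs_name == "growth_rate":
                    kinds.append("growth")
                    i0.append(index[float(row["day_start"])])
                    i1.append(index[float(row["day_end"])])
                    dt.append(float(row["day_end"]) - float(row["day_start"]))
                    continue
                kinds.append(obs_name)
                i0.append(index[float(row["day"])])
                i1.append(-1)
                dt.append(0.0)
            else:
                if obs_name == "growth_rate":
                    kinds.append("basal_growth")
                elif obs_name == "ratio_sgm_g1":
                    kinds.append("basal_ratio")
                else:
                    raise ValueError(
                        f"untreated condition unsupported for {obs_name!r}")
                i0.append(-1)
                i1.append(-1)
                dt.append(0.0)
        self.kinds = np.array(kinds)
        self.i0 = np.array(i0, dtype=np.int64)
        self.i1 = np.array(i1, dtype=np.int64)
        self.dt = np.array(dt, dtype=float)

    def predict(self, params: TumorImmuneParams, rtol: float = 1e-8,
                atol: float = 1e-10) -> np.ndarray:
        """Model prediction for every observation row."""
        init = initial_state(params, v0=self.v0, t0=self.t_start)
        ys = simulate_fast(params, init, self.t_eval, rtol=rtol, atol=atol)
        return self._map(ys, params)

    def _map(self, ys: np.ndarray, params: TumorImmuneParams) -> np.ndarray:
        S, G, E, I = ys[:, 0], ys[:, 1], ys[:, 2], ys[:, 3]
        V = S + G
        if np.any(~np.isfinite(V)):
            raise SimulationError("non-finite trajectory", float(self.t_eval[-1]))
        g_basal = basal_growth_rate(params.kgs, params.ksg)
        r_basal = steady_state_ratio(params.kgs, params.ksg)
        out = np.empty(len(self.kinds))
        for m, kind in enumerate(self.kinds):
            j = self.i0[m]
            if kind == "growth":
                v0, v1 = V[j], V[self.i1[m]]
                if v0 <= 0 or v1 <= 0:
                    raise SimulationError("tumor volume vanished", self.t_eval[j])
                out[m] = np.log(v1 / v0) / self.dt[m]
            elif kind == "ctl_density":
                out[m] = E[j]
            elif kind == "ratio_sgm_g1":
                if G[j] <= 0:
                    raise SimulationError("empty G1 compartment", self.t_eval[j])
                out[m] = S[j] / G[j]
            elif kind in _EXPRESSION_MAP:
                if V[j] <= 0:
                    raise SimulationError("tumor volume vanished", self.t_eval[j])
                col = {"I": I, "P": ys[:, 4], "PL": ys[:, 5],
                       "L": ys[:, 6], "H": ys[:, 7]}[_EXPRESSION_MAP[kind]]
                out[m] = col[j] / V[j]
            elif kind == "basal_growth":
                out[m] = g_basal
            elif kind == "basal_ratio":
                out[m] = r_basal
            else:  # pragma: no cover
                raise ValueError(f"unmapped kind {kind!r}")
        return out


def map_observables(trajectory: pd.DataFrame, observations: ObservationSet,
                    params: TumorImmuneParams) -> np.ndarray:
    """Map a tidy trajectory frame onto observation rows.

    The trajectory must contain every treated observation time (growth
    intervals reference both endpoints); untreated rows are basal-model
    constants.  Raises if an observation time is missing.
    """
    mapper = ObservationMapper(observations)
    t = trajectory["time"].to_numpy(dtype=float)
    idx = []
    for te in mapper.t_eval:
        hits = np.nonzero(np.isclose(t, te, atol=1e-9))[0]
        if not len(hits):
            raise ValueError(f"trajectory does not cover observation time {te}")
        idx.append(hits[0])
    ys = trajectory[["S", "G", "E", "I", "P", "PL", "L", "H"]].to_numpy()[idx]
    return mapper._map(ys, params)


# ---------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    """Outcome of a (multistart) maximum-likelihood fit."""

    variant: str
    params: TumorImmuneParams
    logL: float
    n_free_params: int
    free_names: tuple[str, ...]
    converged: bool
    n_starts: int
    seed: int
    obs_hash: str
    best_start_index: int
    top_sets: list = field(default_factory=list)  # [(logL, {name: value})]

    @property
    def AIC(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.logL

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.to_dict(),
            "logL": self.logL,
            "AIC": self.AIC,
            "n_free_params": self.n_free_params,
            "free_names": list(self.free_names),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "obs_hash": self.obs_hash,
            "best_start_index": self.best_start_index,
            "top_sets": [[ll, dict(vals)] for ll, vals in self.top_sets],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, doc: dict) -> "FitResult":
        doc = dict(doc)
        doc.pop("AIC", None)
        doc["params"] = TumorImmuneParams.from_dict(doc["params"])
        doc["free_names"] = tuple(doc["free_names"])
        doc["top_sets"] = [(ll, vals) for ll, vals in doc.get("top_sets", [])]
        return cls(**doc)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class NegativeLogLikelihood:
    """Objective over log10-transformed free parameters of one variant."""

    def __init__(self, observations: ObservationSet, variant: str = "all",
                 base_params: TumorImmuneParams | None = None,
                 v0: float = 100.0, rtol: float = 1e-8, atol: float = 1e-10):
        base = base_params if base_params is not None else TumorImmuneParams()
        self.base = base.apply_variant(variant)
        self.variant = variant
        self.free = self.base.free_names(variant)
        self.mapper = ObservationMapper(observations, v0=v0)
        self.rtol, self.atol = rtol, atol
        df = observations.data
        self._mask = df["include"].astype(bool).to_numpy()
        self._mean = df["mean"].to_numpy(dtype=float)[self._mask]
        self._sd = df["sd"].to_numpy(dtype=float)[self._mask]
        self.log_bounds = np.array(
            [np.log10(self.base.bounds[n]) for n in self.free])

    def params_from_x(self, x_log10) -> TumorImmuneParams:
        values = dict(zip(self.free, 10.0 ** np.asarray(x_log10, dtype=float)))
        return self.base.with_values(**values)

    def residuals(self, x_log10) -> np.ndarray:
        """Weighted residual vector over included observations."""
        with np.errstate(all="ignore"):
            try:
                params = self.params_from_x(x_log10)
                pred = self.mapper.predict(params, rtol=self.rtol, atol=self.atol)
            except (SimulationError, ValueError, FloatingPointError):
                return np.full(self._mean.shape, _RESID_PENALTY)
            resid = (pred[self._mask] - self._mean) / self._sd
            return np.where(np.isfinite(resid),
                            np.clip(resid, -_RESID_PENALTY, _RESID_PENALTY),
                            _RESID_PENALTY)

    def __call__(self, x_log10) -> float:
        resid = self.residuals(x_log10)
        nll = 0.5 * float(np.sum(resid ** 2))
        return nll if np.isfinite(nll) else _PENALTY


def multistart_fit(observations: ObservationSet, variant: str = "all",
                   n_starts: int = 200, seed: int = 0,
                   base_params: TumorImmuneParams | None = None,
                   v0: float = 100.0, top_k: int = 21,
                   rtol: float = 1e-8, atol: float = 1e-10,
                   method: str = "trf", max_nfev_per_start: int = 300,
                   n_polish: int = 3, polish_nfev: int = 3000) -> FitResult:
    """Multistart bounded maximum-likelihood fit of one model variant.

    ``n_starts`` Latin-hypercube points in log10-parameter space are each
    refined locally under the box bounds, and the ``n_polish`` best local
    optima are re-optimised with a larger evaluation budget.  The default
    per-start optimiser is trust-region-reflective least squares
    (``method="trf"``), which exploits the sum-of-squares structure of
    the objective; ``method="lbfgsb"`` selects bounded quasi-Newton with
    numerical gradients instead.  Returns the best optimum together with
    the ``top_k`` best parameter sets (used to seed the posterior
    sampler).  Deterministic given ``seed``.
    """
    nll = NegativeLogLikelihood(observations, variant, base_params, v0,
                                rtol, atol)
    d = len(nll.free)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(n_starts)
    lo, hi = nll.log_bounds[:, 0], nll.log_bounds[:, 1]
    starts = lo + unit * (hi - lo)

    def local_opt(x0, budget):
        if method == "trf":
            res = optimize.least_squares(
                nll.residuals, x0, bounds=(lo, hi), method="trf",
                x_scale="jac", max_nfev=budget)
            return float(res.cost), res.x.copy(), bool(res.status > 0)
        if method == "lbfgsb":
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
                options={"maxiter": budget})
            return float(res.fun), res.x.copy(), bool(res.success)
        raise ValueError(f"unknown optimiser {method!r}")

    results = []
    failures = []
    for i in range(n_starts):
        try:
            fun, x, ok = local_opt(starts[i], max_nfev_per_start)
            results.append((fun, i, x, ok))
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            failures.append((i, repr(exc)))
    if not results:
        raise RuntimeError(f"all {n_starts} starts failed: {failures[:5]}")

    results.sort(key=lambda r: (r[0], r[1]))
    for rank in range(min(n_polish, len(results))):
        fun0, i0, x0, _ = results[rank]
        if fun0 >= _PENALTY:
            continue
        try:
            fun, x, ok = local_opt(x0, polish_nfev)
        except Exception:  # noqa: BLE001 - keep the unpolished optimum
            continue
        if fun < fun0:
            results[rank] = (fun, i0, x, ok)
    results.sort(key=lambda r: (r[0], r[1]))
    best_fun, best_i, best_x, best_ok = results[0]
    best_params = nll.params_from_x(best_x)
    top = [(-fun, dict(zip(nll.free, 10.0 ** x)))
           for fun, _, x, _ in results[:top_k]]
    return FitResult(
        variant=variant,
        params=best_params,
        logL=-best_fun,
        n_free_params=d,
        free_names=nll.free,
        converged=best_ok and best_fun < _PENALTY,
        n_starts=n_starts,
        seed=seed,
        obs_hash=observations.content_hash(),
        best_start_index=best_i,
        top_sets=top,
    )


def compare_variants(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted variants by AIC (= 2k - 2 logL), ascending."""
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.obs_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different observation sets")
    rows = [{"variant": f.variant, "n_free_params": f.n_free_params,
             "logL": f.logL, "AIC": f.AIC} for f in fits]
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable")
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    return table.reset_index(drop=True)


_ABLATION_WEIGHTS = {"lag3": "kl", "havcr2": "kt", "pdcd1": "kp"}


def ablate_inhibitor(fit: FitResult, which: str, times=None,
                     v0: float = 100.0) -> pd.DataFrame:
    """Re-simulate with one checkpoint weight zeroed; report divergence.

    Divergence per observable is the RMS difference between the intact
    and ablated trajectories, normalised by the RMS of the intact signal
    (or absolute when the intact signal is flat zero).
    """
    if which == "all":
        updates = {w: 0.0 for w in _ABLATION_WEIGHTS.values()}
    elif which in _ABLATION_WEIGHTS:
        updates = {_ABLATION_WEIGHTS[which]: 0.0}
    else:
        raise ValueError(f"unknown checkpoint {which!r}; "
                         f"expected one of {sorted(_ABLATION_WEIGHTS)} or 'all'")
    if times is None:
        times = np.linspace(-1.0, 14.0, 151)
    times = np.asarray(times, dtype=float)
    intact = fit.params
    ablated = intact.with_values(**updates)
    init = initial_state(intact, v0=v0, t0=min(times[0], 0.0))
    ys_a = simulate_fast(intact, init, times)
    ys_b = simulate_fast(ablated, init, times)

    def observable_series(ys):
        V = ys[:, 0] + ys[:, 1]
        Vsafe = np.where(V > 0, V, np.nan)
        G = np.where(ys[:, 1] > 0, ys[:, 1], np.nan)
        return {"volume": V, "ctl_density": ys[:, 2],
                "ratio_sgm_g1": ys[:, 0] / G, "ifng": ys[:, 3] / Vsafe,
                "pdcd1": ys[:, 4] / Vsafe, "cd274": ys[:, 5] / Vsafe,
                "lag3": ys[:, 6] / Vsafe, "havcr2": ys[:, 7] / Vsafe}

    sa, sb = observable_series(ys_a), observable_series(ys_b)
    rows = []
    for name in sa:
        a, b = sa[name], sb[name]
        ok = np.isfinite(a) & np.isfinite(b)
        diff = np.sqrt(np.mean((a[ok] - b[ok]) ** 2))
        scale = np.sqrt(np.mean(a[ok] ** 2))
        rows.append({"observable": name, "rms_divergence": diff,
                     "relative_divergence": diff / scale if scale > 0 else diff})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# grid search for the input-forced basic model


@dataclass
class GridSearchResult:
    ke_grid: np.ndarray
    ki_grid: np.ndarray
    surface: np.ndarray  # logL, shape (len(ke_grid), len(ki_grid))
    best_ke: float
    best_ki: float
    best_logL: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format surface for CSV export / heatmap plotting."""
        ke, ki = np.meshgrid(self.ke_grid, self.ki_grid, indexing="ij")
        return pd.DataFrame({"ke": ke.ravel(), "ki": ki.ravel(),
                             "logL": self.surface.ravel()})


def grid_search_basic(observations: ObservationSet, inputs: InputSignals,
                      kgs: float = 1.64, ksg: float = 0.66,
                      v0: float = 100.0, ke_max: float = 20.0,
                      ki_max: float = 20.0, step: float = 0.1,
                      rtol: float = 1e-8, atol: float = 1e-10) -> GridSearchResult:
    """Exhaustive (ke, ki) grid search for the input-forced model.

    Evaluates the log likelihood of the two-state tumor model driven by
    interpolated CTL/IFNG inputs at every grid combination (default
    0..20 at step 0.1, i.e. a 201 x 201 grid) against the treated
    growth-rate and cycle-ratio observations, and returns the argmax
    plus the full surface.
    """
    ke_grid = np.round(np.arange(0.0, ke_max + step / 2, step), 10)
    ki_grid = np.round(np.arange(0.0, ki_max + step / 2, step), 10)
    if not len(ke_grid) or not len(ki_grid):
        raise ValueError("empty parameter grid")

    df = observations.data
    treated = (df["condition"] == "treated") & df["include"].astype(bool)
    growth = df[treated & (df["observable"] == "growth_rate")]
    ratio = df[treated & (df["observable"] == "ratio_sgm_g1")]
    if growth.empty and ratio.empty:
        raise ValueError("need treated growth-rate or ratio observations")

    times: set[float] = set()
    for _, row in growth.iterrows():
        times.update((float(row["day_start"]), float(row["day_end"])))
    for _, row in ratio.iterrows():
        times.add(float(row["day"]))
    t_eval = np.array(sorted(times), dtype=float)
    index = {t: i for i, t in enumerate(t_eval)}

    gr_i0 = np.array([index[float(r["day_start"])] for _, r in growth.iterrows()],
                     dtype=np.int64)
    gr_i1 = np.array([index[float(r["day_end"])] for _, r in growth.iterrows()],
                     dtype=np.int64)
    gr_dt = (growth["day_end"] - growth["day_start"]).to_numpy(dtype=float)
    ratio_idx = np.array([index[float(r["day"])] for _, r in ratio.iterrows()],
                         dtype=np.int64)

    t0 = min(t_eval[0], 0.0)
    g = basal_growth_rate(kgs, ksg)
    r_ss = steady_state_ratio(kgs, ksg)
    v_t0 = v0 * np.exp(g * t0)
    y0 = np.array([v_t0 * r_ss / (1 + r_ss), v_t0 / (1 + r_ss)])

    tE = np.array([k[0] for k in inputs.e_knots], dtype=float)
    vE = np.array([k[1] for k in inputs.e_knots], dtype=float)
    tI = np.array([k[0] for k in inputs.i_knots], dtype=float)
    vI = np.array([k[1] for k in inputs.i_knots], dtype=float)

    surface = _fast.grid_loglik_surface(
        ke_grid, ki_grid, kgs, ksg, y0, t0, t_eval, tE, vE, tI, vI,
        gr_i0, gr_i1, gr_dt, growth["mean"].to_numpy(dtype=float),
        growth["sd"].to_numpy(dtype=float), ratio_idx,
        ratio["mean"].to_numpy(dtype=float), ratio["sd"].to_numpy(dtype=float),
        rtol, atol)
    a, b = np.unravel_index(np.argmax(surface), surface.shape)
    return GridSearchResult(ke_grid=ke_grid, ki_grid=ki_grid, surface=surface,
                            best_ke=float(ke_grid[a]), best_ki=float(ki_grid[b]),
                            best_logL=float(surface[a, b]))
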