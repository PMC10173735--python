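"""Calibration of the basal tumor-growth model from untreated data.

An exponentially growing tumor whose cells cycle between G1 and S-G2-M
compartments is fully determined by two quantities: the volumetric
growth rate ``g`` and the steady-state S-G2-M:G1 ratio ``r``.  This
module provides the algebra relating ``(g, r)`` to the cycle transition
rates ``(kgs, ksg)``, the per-interval growth-rate transformation of raw
volume series, the pooled exponential fit, and the CTL-count vs
cell-cycle-ratio correlation statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def basal_growth_rate(kgs: float, ksg: float) -> float:
    """Asymptotic exponential growth rate of the two-compartment cycle model.

    Dominant eigenvalue of ``[[-ksg, kgs], [2*ksg, -kgs]]`` acting on
    ``(S, G)``.
    """
    if kgs < 0 or ksg < 0:
        raise ValueError("rates must be nonnegative")
    tr = -(kgs + ksg)
    det = ksg * kgs - 2.0 * ksg * kgs  # = -kgs*ksg
    disc = tr * tr - 4.0 * det
    return 0.5 * (tr + np.sqrt(disc))


def steady_state_ratio(kgs: float, ksg: float) -> float:
    """Steady-state S-G2-M : G1 ratio of the basal cycle model.

    From the dominant eigenvector: ``r = kgs / (g + ksg)`` with ``g`` the
    asymptotic growth rate; equivalently ``g = ksg * r / (1 + r)``.
    """
    if kgs <= 0 or ksg <= 0:
        raise ValueError("rates must be positive")
    g = basal_growth_rate(kgs, ksg)
    return kgs / (g + ksg)


def cycle_rates_from_growth(g: float, ratio: float) -> tuple[float, float]:
    """Invert the basal model: ``(g, r) -> (kgs, ksg)``.

    ``ksg = g (1 + r) / r`` and ``kgs = g (1 + 2 r)``; round-trips with
    :func:`steady_state_ratio` / :func:`basal_growth_rate`.
    """
    if g <= 0 or ratio <= 0:
        raise ValueError("growth rate and ratio must be positive")
    ksg = g * (1.0 + ratio) / ratio
    kgs = g * (1.0 + 2.0 * ratio)
    return kgs, ksg


def invert_cycle_rates(g: float, kgs: float) -> tuple[float, float]:
    """Recover ``(ratio, ksg)`` from the growth rate and ``kgs``.

    Uses ``kgs = g (1 + 2 r)`` to solve for the steady-state ratio, then
    the companion relation for ``ksg``.
    """
    if g <= 0 or kgs <= g:
        raise ValueError("need kgs > g > 0")
    ratio = (kgs / g - 1.0) / 2.0
    _, ksg = cycle_rates_from_growth(g, ratio)
    return ratio, ksg


@dataclass
class GrowthEstimate:
    """Exponential growth-rate estimate for a cohort of mice."""

    g: float
    per_mouse: pd.DataFrame  # mouse_id, g, n_points
    intervals: pd.DataFrame  # mouse_id, cohort, day, rate (day = midpoint)
    diagnostics: dict = field(default_factory=dict)


def interval_growth_rates(volumes: pd.DataFrame) -> pd.DataFrame:
    """Per-interval growth rates ``ln(V2/V1)/(t2-t1)`` for each mouse.

    ``volumes`` is long format with columns ``mouse_id, day, volume_mm3``
    (a ``cohort`` column is carried through if present).  Rates are
    reported at the interval midpoint, alongside the interval endpoints.
    """
    required = {"mouse_id", "day", "volume_mm3"}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"volume table missing columns: {sorted(missing)}")
    if (volumes["volume_mm3"] <= 0).any():
        bad = volumes.index[volumes["volume_mm3"] <= 0].tolist()
        raise ValueError(f"nonpositive volumes at rows {bad}")
    rows = []
    for mouse, grp in volumes.groupby("mouse_id", sort=False):
        grp = grp.sort_values("day")
        t = grp["day"].to_numpy(dtype=float)
        v = grp["volume_mm3"].to_numpy(dtype=float)
        cohort = grp["cohort"].iloc[0] if "cohort" in grp.columns else ""
        for i in range(len(t) - 1):
            rows.append({
                "mouse_id": mouse,
                "cohort": cohort,
                "day": 0.5 * (t[i] + t[i + 1]),
                "day_start": t[i],
                "day_end": t[i + 1],
                "rate": np.log(v[i + 1] / v[i]) / (t[i + 1] - t[i]),
            })
    return pd.DataFrame(rows)


def fit_exponential_growth(volumes: pd.DataFrame) -> GrowthEstimate:
    """Pooled exponential growth fit across mice.

    Ordinary least squares of log-volume on time with a separate
    intercept per mouse and one shared slope (the population growth
    rate); per-mouse slopes are also reported.  Mice with fewer than two
    timepoints are excluded with a warning.
    """
    import statsmodels.api as sm

    if (volumes["volume_mm3"] <= 0).any():
        raise ValueError("volumes must be positive for log-linear fitting")
    counts = volumes.groupby("mouse_id")["day"].nunique()
    singles = counts[counts < 2].index.tolist()
    if singles:
        warnings.warn(f"excluding single-timepoint mice: {singles}")
        volumes = volumes[~volumes["mouse_id"].isin(singles)]
    if volumes.empty:
        raise ValueError("no mice with >= 2 timepoints")

    logv = np.log(volumes["volume_mm3"].to_numpy(dtype=float))
    day = volumes["day"].to_numpy(dtype=float)
    mouse = volumes["mouse_id"].to_numpy()
    # design: shared slope + one intercept per mouse
    mice = pd.unique(mouse)
    X = np.zeros((len(day), 1 + len(mice)))
    X[:, 0] = day
    for j, m in enumerate(mice):
        X[mouse == m, 1 + j] = 1.0
    fit = sm.OLS(logv, X).fit()
    g = float(fit.params[0])

    per_mouse = []
    for m in mice:
        sel = mouse == m
        slope, _, rvalue, _, stderr = stats.linregress(day[sel], logv[sel])
        per_mouse.append({"mouse_id": m, "g": slope, "n_points": int(sel.sum()),
                          "stderr": stderr})
    intervals = interval_growth_rates(volumes)
    return GrowthEstimate(
        g=g,
        per_mouse=pd.DataFrame(per_mouse),
        intervals=intervals,
        diagnostics={"rsquared": float(fit.rsquared),
                     "g_stderr": float(fit.bse[0]),
                     "n_mice": len(mice),
                     "excluded": singles},
    )


def correlate_ctl_ratio(ctl_counts, ratios) -> dict:
    """Pearson correlation between per-image CTL counts and S-G2-M:G1 ratios.

    Returns the coefficient, its Fisher-z 95% confidence interval, and
    the two-sided p-value for the null of no correlation.
    """
    x = np.asarray(ctl_counts, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired one-dimensional samples required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return {"r": float(res.statistic), "ci_low": float(ci.low),
            "ci_high": float(ci.high), "p": float(res.pvalue), "n": len(x)}
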