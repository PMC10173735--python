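"""Synthetic study generator emulating the adoptive-transfer experiment.

Produces per-mouse tumor-volume tables, per-cryosection cell counts and
an Agilent-style probe x sample expression matrix with above-background
flags, all driven by one ground-truth parameter set and one seed, plus
the summarised :class:`~ctldyn.observations.ObservationSet` consumed by
the fitting code.  The default design mirrors the study layout: two
untreated experiments of 5 mice, three treated experiments of 5/5/2
mice (the 2-mouse arm followed to day 14), cryosection imaging on days
1/3/5/7/10/14, and one pooled expression sample per timepoint and
condition on days 1/3/5/7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import basal_growth_rate, interval_growth_rates
from .inference import checkpoint_sd
from .model import initial_state, simulate
from .observations import (EXPRESSION_OBSERVABLES, ObservationSet, make_row)
from .params import TumorImmuneParams, reference_parameters

DEFAULT_VOLUME_DAYS = (-1.0, 1.0, 3.0, 5.0, 7.0)
EXTENDED_VOLUME_DAYS = (-1.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0)

#: Growth-rate intervals whose start falls at or after this day are
#: excluded from fitting (only the 2-mouse arm reaches them, giving the
#: points an artificially small standard deviation).
LATE_INTERVAL_CUTOFF = 10.0
EXCLUSION_REASON = "late-interval-small-cohort"


@dataclass(frozen=True)
class NoiseModel:
    """Noise configuration of the generator.

    ``volume_sd``/``init_sd`` are lognormal sigmas for per-measurement
    noise and the per-mouse initial-volume factor; ``count_dispersion``
    is the negative-binomial excess-dispersion of cryosection counts
    (variance ``mu + phi mu^2``; 0 gives Poisson); ``expression_noise``
    scales the housekeeping-derived mean-sd relation; ``pool_sd`` is the
    tumor-to-tumor lognormal spread inside a pooled RNA sample;
    ``sample_scale_sd`` is the per-sample raw-intensity scale factor
    removed by percentile normalization.
    """

    volume_sd: float = 0.15
    init_sd: float = 0.25
    count_dispersion: float = 0.05
    counts_sampled: bool = True
    expression_noise: float = 1.0
    pool_sd: float = 0.10
    sample_scale_sd: float = 0.15

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free limit: tables carry exact model observables."""
        return cls(volume_sd=0.0, init_sd=0.0, count_dispersion=0.0,
                   counts_sampled=False, expression_noise=0.0, pool_sd=0.0,
                   sample_scale_sd=0.0)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes, measurement days and summarisation constants."""

    untreated_experiments: tuple[int, ...] = (5, 5)
    treated_experiments: tuple[int, ...] = (5, 5, 2)
    untreated_days: tuple[float, ...] = DEFAULT_VOLUME_DAYS
    treated_days: tuple[tuple[float, ...], ...] = (
        DEFAULT_VOLUME_DAYS, DEFAULT_VOLUME_DAYS, EXTENDED_VOLUME_DAYS)
    imaging_days: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 10.0, 14.0)
    images_per_day: int = 4
    expression_days: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    pool_sizes: tuple[int, ...] = (3, 4, 3, 4)
    v0: float = 100.0               #: mean treated tumor volume at transfer (mm^3)
    nuclei_per_unit: float = 10.0   #: cryosection nuclei counts per mm^3-equivalent
    growth_sd_floor: float = 0.10   #: day^-1, applied when replicate spread vanishes
    ratio_sd_floor: float = 0.05
    ctl_sd_floor: float = 1.0

    def __post_init__(self):
        if len(self.treated_days) != len(self.treated_experiments):
            raise ValueError("one day grid per treated experiment required")


def _simulate_treated(truth: TumorImmuneParams, design: StudyDesign,
                      days) -> pd.DataFrame:
    days = np.unique(np.asarray(days, dtype=float))
    init = initial_state(truth, v0=design.v0, t0=min(days[0], -1.0))
    return simulate(truth, init, days)


# ---------------------------------------------------------------------
# raw tables


def generate_volumes(truth: TumorImmuneParams, design: StudyDesign,
                     noise: NoiseModel, seed: int) -> pd.DataFrame:
    """Per-mouse tumor-volume table for both conditions.

    Treated cohorts follow the full model (CTL infiltration from day 0);
    untreated cohorts grow at the basal exponential rate.  Mouse-level
    lognormal initial-volume factors scale whole trajectories (the model
    is homogeneous in the state), and measurements get multiplicative
    lognormal noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    g = basal_growth_rate(truth.kgs, truth.ksg)
    rows = []

    def emit(condition, exp_idx, mouse_idx, days, model_v):
        mouse = f"{condition[0]}{exp_idx + 1}m{mouse_idx + 1}"
        init_f = (np.exp(rng.normal(0.0, noise.init_sd))
                  if noise.init_sd > 0 else 1.0)
        for day, v in zip(days, model_v):
            meas = (np.exp(rng.normal(0.0, noise.volume_sd))
                    if noise.volume_sd > 0 else 1.0)
            rows.append({"mouse_id": mouse, "cohort": f"{condition}_{exp_idx + 1}",
                         "condition": condition, "day": day,
                         "volume_mm3": v * init_f * meas})

    for e, n_mice in enumerate(design.untreated_experiments):
        days = np.asarray(design.untreated_days, dtype=float)
        model_v = design.v0 * np.exp(g * days)
        for m in range(n_mice):
            emit("untreated", e, m, days, model_v)

    for e, n_mice in enumerate(design.treated_experiments):
        days = np.asarray(design.treated_days[e], dtype=float)
        traj = _simulate_treated(truth, design, days)
        model_v = traj.set_index("time").loc[days, "V"].to_numpy()
        for m in range(n_mice):
            emit("treated", e, m, days, model_v)
    return pd.DataFrame(rows)


def generate_cryosections(truth: TumorImmuneParams, design: StudyDesign,
                          noise: NoiseModel, seed: int) -> pd.DataFrame:
    """Per-image counts of G1 nuclei, S-G2-M nuclei and CTLs.

    Count means are proportional to the model G, S and E at the imaging
    day; sampling is negative-binomial with excess dispersion
    ``count_dispersion`` (Poisson at 0; exact means when sampling is
    disabled).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    traj = _simulate_treated(truth, design, design.imaging_days)
    traj = traj.set_index("time")

    def draw(mu):
        if not noise.counts_sampled:
            return float(mu)
        if mu <= 0:
            return 0.0
        phi = noise.count_dispersion
        if phi > 0:
            # gamma-poisson mixture: var = mu + phi mu^2
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        else:
            lam = mu
        return float(rng.poisson(lam))

    c = design.nuclei_per_unit
    rows = []
    for day in design.imaging_days:
        state = traj.loc[day]
        for i in range(design.images_per_day):
            rows.append({
                "image_id": f"d{day:g}_img{i + 1}",
                "day": float(day),
                "g1_count": draw(c * state["G"]),
                "sgm_count": draw(c * state["S"]),
                "ctl_count": draw(state["E"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# expression matrix


def default_probe_table() -> pd.DataFrame:
    """Probe annotation: signal probes, trackers, housekeeping, flagged.

    ``target`` names the model observable feeding the probe ("none" for
    housekeeping/flagged probes); fitted observables use scale 1 (their
    arbitrary units are absorbed by the model parameters), trackers get
    nominal scales.  ``hk_mean`` is the constant housekeeping level.
    """
    rows = []

    def add(probe, gene, target, scale=1.0, baseline=0.0, hk_mean=0.0,
            flag_pattern="all"):
        rows.append({"probe": probe, "gene": gene, "target": target,
                     "scale": scale, "baseline": baseline, "hk_mean": hk_mean,
                     "flag_pattern": flag_pattern})

    for i in range(4):
        add(f"Ifng_p{i + 1}", "Ifng", "ifng", baseline=0.20)
    for i in range(2):
        add(f"Cd8a_p{i + 1}", "Cd8a", "ctl_density", scale=0.05, baseline=0.30)
        add(f"Stat1_p{i + 1}", "Stat1", "ifng", scale=0.50, baseline=0.80)
        add(f"Socs1_p{i + 1}", "Socs1", "ifng", scale=0.30, baseline=0.40)
    add("Pdcd1_p1", "Pdcd1", "pdcd1", baseline=0.10)
    add("Cd274_p1", "Cd274", "cd274", baseline=0.30)
    add("Lag3_p1", "Lag3", "lag3", baseline=0.10)
    add("Havcr2_p1", "Havcr2", "havcr2", baseline=0.10)
    # a dense housekeeping background keeps the per-sample 75th
    # percentile pinned, as on a full-size array
    hk_means = np.geomspace(0.1, 10.0, 150)
    for i, mu in enumerate(hk_means):
        add(f"hk_{i + 1:03d}", f"Hk{i + 1}", "none", hk_mean=float(mu))
    for i in range(6):
        add(f"absent_{i + 1}", f"Absent{i + 1}", "none", hk_mean=0.05,
            flag_pattern="none")
    add("faint_1", "Faint1", "none", hk_mean=0.08, flag_pattern="partial")
    return pd.DataFrame(rows)


#: Which probes map to fitted model observables (expression summaries).
_FITTED_TARGETS = set(EXPRESSION_OBSERVABLES)

# trackers: Cd8a follows the CTL count; Stat1/Socs1 follow IFNG signalling
_TRACKER_TARGETS = {"ctl_density"}


@dataclass
class ExpressionBundle:
    """Raw probe x sample matrix with per-sample flags and metadata."""

    values: pd.DataFrame       # probes x samples, raw intensities
    flags: pd.DataFrame        # probes x samples, gIsWellAboveBG 0/1
    samples: pd.DataFrame      # sample, condition, day, pool_size
    probe_table: pd.DataFrame


def generate_expression(truth: TumorImmuneParams, design: StudyDesign,
                        noise: NoiseModel, seed: int,
                        probe_table: pd.DataFrame | None = None) -> ExpressionBundle:
    """Probe x sample expression matrix with above-background flags.

    Each sample pools 3-4 simulated tumors; signal probes track their
    mapped model observable (IFNG and checkpoints as intratumoral
    concentrations X/V, Cd8a as CTL count) on top of a constant
    baseline; Gaussian noise follows ``sd = 0.054 + 0.29 * mean``.
    Per-sample lognormal scale factors emulate raw-intensity differences
    removed by 75th-percentile normalization.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    if probe_table is None:
        probe_table = default_probe_table()
    known = _FITTED_TARGETS | _TRACKER_TARGETS | {"none"}
    unknown = set(probe_table["target"]) - known
    if unknown:
        raise ValueError(f"unmapped probe targets: {sorted(unknown)}")

    traj = _simulate_treated(truth, design, design.expression_days)
    traj = traj.set_index("time")

    def observable(target, condition, day):
        if condition == "untreated" or target == "none":
            return 0.0
        state = traj.loc[day]
        if target == "ctl_density":
            return float(state["E"])
        if state["V"] <= 0:
            raise ValueError(f"tumor volume vanished at day {day}")
        col = {"ifng": "I", "pdcd1": "P", "cd274": "PL",
               "lag3": "L", "havcr2": "H"}[target]
        return float(state[col] / state["V"])

    samples = []
    for condition in ("treated", "untreated"):
        for j, day in enumerate(design.expression_days):
            samples.append({"sample": f"{condition}_d{day:g}",
                            "condition": condition, "day": float(day),
                            "pool_size": design.pool_sizes[j % len(design.pool_sizes)]})
    samples = pd.DataFrame(samples)

    values = np.empty((len(probe_table), len(samples)))
    flags = np.empty_like(values, dtype=int)
    for sj, sample in samples.iterrows():
        scale_f = (np.exp(rng.normal(0.0, noise.sample_scale_sd))
                   if noise.sample_scale_sd > 0 else 1.0)
        for pi, probe in probe_table.iterrows():
            if probe["target"] == "none":
                mean = probe["hk_mean"]
            else:
                obs = observable(probe["target"], sample["condition"],
                                 sample["day"])
                if noise.pool_sd > 0:
                    factors = np.exp(rng.normal(0.0, noise.pool_sd,
                                                size=sample["pool_size"]))
                    obs = obs * factors.mean()
                mean = probe["baseline"] + probe["scale"] * obs
            if noise.expression_noise > 0:
                sd = noise.expression_noise * checkpoint_sd(max(mean, 0.0))
                mean = mean + rng.normal(0.0, sd)
            values[pi, sj] = max(mean, 0.0) * scale_f
            pattern = probe["flag_pattern"]
            flags[pi, sj] = 0 if pattern == "none" else (
                sj % 2 if pattern == "partial" else 1)

    index = pd.Index(probe_table["probe"], name="probe")
    return ExpressionBundle(
        values=pd.DataFrame(values, index=index, columns=samples["sample"]),
        flags=pd.DataFrame(flags, index=index, columns=samples["sample"]),
        samples=samples, probe_table=probe_table)


def preprocess_microarray(values: pd.DataFrame,
                          flags: pd.DataFrame) -> pd.DataFrame:
    """Flag filtering and 75th-percentile normalization.

    Probes whose above-background flag is zero in *every* sample are
    discarded (a probe above background in any sample is retained);
    each sample is then rescaled so its 75th percentile equals the
    across-sample mean of 75th percentiles.
    """
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    if not values.index.equals(flags.index) or not values.columns.equals(flags.columns):
        raise ValueError("values and flags must share probes and samples")
    keep = (flags != 0).any(axis=1)
    kept = values.loc[keep]
    if (kept.sum(axis=0) == 0).any():
        bad = kept.columns[kept.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero intensities: {bad}")
    q75 = kept.quantile(0.75, axis=0)
    return kept * (q75.mean() / q75)


# ---------------------------------------------------------------------
# summarisation


def build_observations(volumes: pd.DataFrame, cryosections: pd.DataFrame,
                       expression: pd.DataFrame, samples: pd.DataFrame,
                       probe_table: pd.DataFrame,
                       design: StudyDesign) -> ObservationSet:
    """Summarise raw tables into the fitting ObservationSet.

    Growth rates are per-interval transforms pooled across mice (late
    intervals starting at or after day 10 flagged excluded); CTL counts
    and S-G2-M:G1 ratios are per-day image summaries; expression
    observables are baseline-corrected against the untreated condition,
    with single-probe standard deviations from the housekeeping mean-sd
    relation.
    """
    rows = []

    rates = interval_growth_rates(volumes.assign(
        cohort=volumes["condition"]))
    for (cond, d0, d1), grp in rates.groupby(["cohort", "day_start", "day_end"]):
        include = d0 < LATE_INTERVAL_CUTOFF
        sd = float(grp["rate"].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(make_row(
            "growth_rate", day=0.5 * (d0 + d1),
            mean=float(grp["rate"].mean()),
            sd=max(sd, design.growth_sd_floor), n=len(grp), condition=cond,
            include=include, reason="" if include else EXCLUSION_REASON,
            day_start=d0, day_end=d1))

    for day, grp in cryosections.groupby("day"):
        sd_c = float(grp["ctl_count"].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(make_row("ctl_density", day=float(day),
                             mean=float(grp["ctl_count"].mean()),
                             sd=max(sd_c, design.ctl_sd_floor), n=len(grp)))
        countable = grp[grp["g1_count"] > 0]
        if len(countable):
            ratio = countable["sgm_count"] / countable["g1_count"]
            sd_r = float(ratio.std(ddof=1)) if len(countable) > 1 else 0.0
            rows.append(make_row("ratio_sgm_g1", day=float(day),
                                 mean=float(ratio.mean()),
                                 sd=max(sd_r, design.ratio_sd_floor),
                                 n=len(countable)))
        else:
            rows.append(make_row("ratio_sgm_g1", day=float(day), mean=0.0,
                                 sd=design.ratio_sd_floor, n=0, include=False,
                                 reason="no-countable-g1-nuclei"))

    meta = samples.set_index("sample")
    for target in EXPRESSION_OBSERVABLES:
        probes = probe_table.loc[(probe_table["target"] == target)
                                 & (probe_table["scale"] == 1.0), "probe"]
        probes = [p for p in probes if p in expression.index]
        if not probes:
            raise ValueError(f"no probes available for observable {target!r}")
        sub = expression.loc[probes]
        untreated = meta.index[meta["condition"] == "untreated"]
        baseline = sub[untreated].mean(axis=1)  # per-probe untreated level
        for day in design.expression_days:
            col = f"treated_d{day:g}"
            corrected = sub[col] - baseline
            raw_mean = float(sub[col].mean())
            sd = float(corrected.std(ddof=1)) if len(probes) > 1 else 0.0
            if sd <= 0:
                sd = float(checkpoint_sd(max(raw_mean, 0.0)))
            rows.append(make_row(target, day=float(day),
                                 mean=float(corrected.mean()), sd=sd,
                                 n=len(probes)))
    return ObservationSet(pd.DataFrame(rows))


@dataclass
class SyntheticBundle:
    """All raw tables plus the summarised observations of one dataset."""

    volumes: pd.DataFrame
    cryosections: pd.DataFrame
    expression: ExpressionBundle
    expression_normalized: pd.DataFrame
    observations: ObservationSet
    truth: TumorImmuneParams
    design: StudyDesign
    noise: NoiseModel
    seed: int


def generate_full_dataset(truth: TumorImmuneParams | None = None,
                          design: StudyDesign | None = None,
                          seed: int = 0,
                          noise: NoiseModel | None = None) -> SyntheticBundle:
    """Generate volumes, cryosections, expression and the ObservationSet.

    One seed determines every table.  Without per-sample raw-intensity
    scale factors the expression matrix is already on the normalized
    scale, so only the flag filter is applied before summarisation.
    """
    truth = truth if truth is not None else reference_parameters("all")
    design = design if design is not None else StudyDesign()
    noise = noise if noise is not None else NoiseModel()

    volumes = generate_volumes(truth, design, noise, seed)
    cryo = generate_cryosections(truth, design, noise, seed)
    expr = generate_expression(truth, design, noise, seed)
    if noise.sample_scale_sd > 0:
        normalized = preprocess_microarray(expr.values, expr.flags)
    else:
        normalized = expr.values.loc[(expr.flags != 0).any(axis=1)]
    observations = build_observations(volumes, cryo, normalized,
                                      expr.samples, expr.probe_table, design)
    return SyntheticBundle(volumes=volumes, cryosections=cryo, expression=expr,
                           expression_normalized=normalized,
                           observations=observations, truth=truth,
                           design=design, noise=noise, seed=seed)
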