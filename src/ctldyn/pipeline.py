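"""End-to-end analysis pipeline: synth -> calibrate -> gridsearch ->
variant fits -> AIC comparison -> posterior sampling -> report.

Every stage writes versioned outputs under the configured directory and
appends an entry (with output hashes and the seeds in effect) to a
machine-readable run manifest; a failed stage halts the run with the
manifest recording what completed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .calibration import (correlate_ctl_ratio, cycle_rates_from_growth,
                          fit_exponential_growth)
from .config import PipelineConfig
from .identifiability import (AMPHSSettings, credible_intervals,
                              posterior_predictive, sample_posterior)
from .inference import (FitResult, compare_variants, grid_search_basic,
                        multistart_fit)
from .model import InputSignals
from .params import TumorImmuneParams, reference_parameters
from .synthetic import NoiseModel, StudyDesign, generate_full_dataset

log = logging.getLogger("ctldyn.pipeline")

STAGES = ("synth", "calibrate", "gridsearch", "fit", "compare", "mcmc",
          "report")


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _truth_params(config: PipelineConfig) -> TumorImmuneParams:
    name = config.synth.truth
    if name.endswith(".json"):
        return TumorImmuneParams.from_json(name)
    return reference_parameters(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {"seed": config.seed, "outdir": str(outdir),
                           "v0": config.v0,
                           "noise": config.synth.noise,
                           "truth": config.synth.truth,
                           "variants": list(config.fit.variants),
                           "n_starts": config.fit.n_starts,
                           "mcmc_steps": config.mcmc.n_steps},
                "stages": []}

    def record(stage, outputs, seed=None):
        manifest["stages"].append({
            "name": stage, "status": "complete", "seed": seed,
            "outputs": {str(p): io.file_sha256(p) for p in outputs}})
        io.write_json(manifest, outdir / "manifest.json")
        log.info("stage %s complete (%d outputs)", stage, len(outputs))

    try:
        # ---- synth ------------------------------------------------
        seed = _stage_seed(config.seed, "synth")
        noise = NoiseModel() if config.synth.noise == "default" else NoiseModel.none()
        bundle = generate_full_dataset(_truth_params(config), StudyDesign(v0=config.v0),
                                       seed=seed, noise=noise)
        vol_path = outdir / "volumes.csv"
        cryo_path = outdir / "cryosections.csv"
        expr_path = outdir / "expression.tsv"
        obs_path = outdir / "observations.csv"
        bundle.volumes.to_csv(vol_path, index=False)
        bundle.cryosections.to_csv(cryo_path, index=False)
        io.write_expression(bundle.expression.values, bundle.expression.flags,
                            expr_path)
        bundle.observations.to_csv(obs_path)
        record("synth", [vol_path, cryo_path, expr_path, obs_path], seed)

        # ---- calibrate --------------------------------------------
        volumes = io.read_volumes(vol_path)
        cryo = io.read_cryosections(cryo_path)
        obs = io.read_observations(obs_path)
        untreated = volumes[volumes["condition"] == "untreated"]
        growth = fit_exponential_growth(untreated)
        # basal cycle ratio from late imaging days (arrest has resolved);
        # images without countable G1 nuclei carry no ratio information
        countable = cryo[cryo["g1_count"] > 0]
        if countable.empty:
            raise RuntimeError("no cryosection image with countable G1 nuclei")
        late = countable[countable["day"] >= 10]
        src = late if len(late) else countable
        ratio_est = float((src["sgm_count"] / src["g1_count"]).mean())
        kgs, ksg = cycle_rates_from_growth(growth.g, ratio_est)
        corr = correlate_ctl_ratio(countable["ctl_count"],
                                   countable["sgm_count"] / countable["g1_count"])
        calib_path = outdir / "calibration.json"
        io.write_json({"g": growth.g, "ratio": ratio_est, "kgs": kgs,
                       "ksg": ksg, "correlation": corr,
                       "per_mouse_g_mean": float(growth.per_mouse["g"].mean())},
                      calib_path)
        record("calibrate", [calib_path])

        # ---- gridsearch -------------------------------------------
        ctl_means = cryo.groupby("day")["ctl_count"].mean()
        ifng = obs.data[(obs.data["observable"] == "ifng")
                        & (obs.data["condition"] == "treated")]
        inputs = InputSignals.from_means(
            ctl_means.index.to_numpy(), ctl_means.to_numpy(),
            ifng["day"].to_numpy(), np.clip(ifng["mean"].to_numpy(), 0, None))
        grid = grid_search_basic(obs, inputs, kgs=kgs, ksg=ksg, v0=config.v0,
                                 ke_max=config.gridsearch.kmax,
                                 ki_max=config.gridsearch.kmax,
                                 step=config.gridsearch.step)
        grid_path = outdir / "gridsearch.csv"
        grid.to_frame().to_csv(grid_path, index=False)
        best_path = outdir / "gridsearch_best.json"
        io.write_json({"ke": grid.best_ke, "ki": grid.best_ki,
                       "logL": grid.best_logL}, best_path)
        heat_path = outdir / "gridsearch_heatmap.png"
        _render_heatmap(grid, heat_path)
        record("gridsearch", [grid_path, best_path])

        # ---- fit ---------------------------------------------------
        base = TumorImmuneParams().with_values(kgs=kgs, ksg=ksg)
        fits: list[FitResult] = []
        fit_paths = []
        for i, variant in enumerate(config.fit.variants):
            fseed = (_stage_seed(config.seed, "fit") + i) % (2 ** 31)
            fit = multistart_fit(obs, variant, n_starts=config.fit.n_starts,
                                 seed=fseed, base_params=base, v0=config.v0,
                                 method=config.fit.method)
            path = outdir / f"fit_{variant}.json"
            fit.to_json(path)
            fits.append(fit)
            fit_paths.append(path)
        record("fit", fit_paths, _stage_seed(config.seed, "fit"))

        # ---- compare ----------------------------------------------
        table = compare_variants(fits)
        aic_path = outdir / "aic.csv"
        table.to_csv(aic_path, index=False)
        record("compare", [aic_path])

        # ---- mcmc --------------------------------------------------
        best = fits[int(np.argmin([f.AIC for f in fits]))]
        n_aux = min(config.mcmc.n_aux_chains, len(best.top_sets) - 1)
        mseed = _stage_seed(config.seed, "mcmc")
        samples = sample_posterior(
            obs, best.top_sets, variant=best.variant, base_params=base,
            v0=config.v0,
            settings=AMPHSSettings(n_steps=config.mcmc.n_steps,
                                   n_aux_chains=n_aux, seed=mseed))
        draws_path = outdir / "posterior_draws.csv"
        samples.to_csv(draws_path)
        meta_path = outdir / "posterior_meta.json"
        io.write_json(samples.meta, meta_path)
        ci = credible_intervals(samples)
        ci_path = outdir / "credible_intervals.csv"
        ci.to_csv(ci_path, index=False)
        record("mcmc", [draws_path, meta_path, ci_path], mseed)

        # ---- report -----------------------------------------------
        pp = posterior_predictive(samples, config.mcmc.posterior_draws,
                                  seed=_stage_seed(config.seed, "report"),
                                  base_params=best.params.apply_variant(best.variant),
                                  v0=config.v0)
        report_path = outdir / "report.json"
        io.write_json({
            "best_variant": best.variant,
            "aic": {r["variant"]: r["AIC"] for _, r in table.iterrows()},
            "posterior_predictive": {
                "n_trajectories": len(pp["trajectories"]),
                "n_failures": len(pp["failures"])},
            "calibration": {"g": growth.g, "kgs": kgs, "ksg": ksg},
            "gridsearch_best": {"ke": grid.best_ke, "ki": grid.best_ki},
        }, report_path)
        record("report", [report_path], _stage_seed(config.seed, "report"))
    except Exception:
        manifest["stages"].append({"name": "FAILED", "status": "failed"})
        io.write_json(manifest, outdir / "manifest.json")
        raise
    return manifest


def _render_heatmap(grid, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    finite = grid.surface[np.isfinite(grid.surface)]
    vmin = np.percentile(finite, 5) if len(finite) else None
    im = ax.imshow(grid.surface.T, origin="lower", aspect="auto",
                   extent=(grid.ke_grid[0], grid.ke_grid[-1],
                           grid.ki_grid[0], grid.ki_grid[-1]),
                   vmin=vmin, cmap="viridis")
    ax.plot(grid.best_ke, grid.best_ki, "ko", ms=6, mfc="none")
    ax.set_xlabel("killing rate $k_e$ (CTL$^{-1}$ day$^{-1}$)")
    ax.set_ylabel("arrest sensitivity $k_i$ (IFN$^{-1}$ mm$^3$)")
    fig.colorbar(im, ax=ax, label="log likelihood")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
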