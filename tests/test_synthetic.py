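"""Synthetic study generator: determinism, noise models, preprocessing,
summarisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctldyn.calibration import (basal_growth_rate, correlate_ctl_ratio,
                                interval_growth_rates)
from ctldyn.inference import NegativeLogLikelihood
from ctldyn.model import initial_state, simulate
from ctldyn.observations import OBSERVABLES
from ctldyn.params import TumorImmuneParams
from ctldyn.synthetic import (EXCLUSION_REASON, NoiseModel, StudyDesign,
                              default_probe_table, generate_cryosections,
                              generate_expression, generate_full_dataset,
                              generate_volumes, preprocess_microarray)


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self, ref_params):
        a = generate_full_dataset(ref_params, seed=11)
        b = generate_full_dataset(ref_params, seed=11)
        assert a.volumes.to_csv(index=False) == b.volumes.to_csv(index=False)
        assert a.cryosections.to_csv(index=False) == b.cryosections.to_csv(index=False)
        assert a.expression.values.to_csv() == b.expression.values.to_csv()
        assert (a.observations.data.to_csv(index=False)
                == b.observations.data.to_csv(index=False))

    def test_different_seeds_differ(self, ref_params):
        a = generate_full_dataset(ref_params, seed=11)
        b = generate_full_dataset(ref_params, seed=12)
        assert a.volumes.to_csv(index=False) != b.volumes.to_csv(index=False)


class TestVolumes:
    def test_noiseless_untreated_is_exactly_exponential(self, ref_params):
        design = StudyDesign()
        vols = generate_volumes(ref_params, design, NoiseModel.none(), seed=0)
        u = vols[vols["condition"] == "untreated"]
        g = basal_growth_rate(ref_params.kgs, ref_params.ksg)
        expected = design.v0 * np.exp(g * u["day"].to_numpy())
        np.testing.assert_allclose(u["volume_mm3"], expected, rtol=1e-9)

    def test_cohort_layout_matches_design(self, ref_params):
        vols = generate_volumes(ref_params, StudyDesign(), NoiseModel.none(),
                                seed=0)
        counts = vols.groupby(["condition", "cohort"])["mouse_id"].nunique()
        assert counts["untreated"].tolist() == [5, 5]
        assert counts["treated"].tolist() == [5, 5, 2]
        extended = vols[(vols["cohort"] == "treated_3")]["day"].max()
        assert extended == 14.0

    def test_interval_rate_dispersion_matches_lognormal_theory(self, ref_params):
        # iid lognormal measurement noise: sd(rate) = sqrt(2)*sigma/dt
        design = StudyDesign(untreated_experiments=(200,),
                             untreated_days=(0.0, 1.0),
                             treated_experiments=(1,),
                             treated_days=((0.0, 1.0),))
        vols = generate_volumes(ref_params, design,
                                NoiseModel(volume_sd=0.2, init_sd=0.0), seed=5)
        rates = interval_growth_rates(vols[vols["condition"] == "untreated"])
        theory = np.sqrt(2) * 0.2
        assert rates["rate"].std(ddof=1) == pytest.approx(theory, rel=0.15)


class TestCryosections:
    def test_noiseless_counts_equal_scaled_model_states(self, ref_params):
        design = StudyDesign()
        cryo = generate_cryosections(ref_params, design, NoiseModel.none(),
                                     seed=0)
        times = np.array(design.imaging_days)
        traj = simulate(ref_params, initial_state(ref_params, t0=-1.0),
                        np.unique(np.append(-1.0, times))).set_index("time")
        day1 = cryo[cryo["day"] == 1.0].iloc[0]
        assert day1["ctl_count"] == pytest.approx(traj.loc[1.0, "E"], rel=1e-6)
        assert (day1["sgm_count"] / day1["g1_count"]
                == pytest.approx(traj.loc[1.0, "ratio_SG"], rel=1e-6))

    def test_poisson_limit_ratio_matches_model(self, mild_params):
        # zero excess dispersion, large counts: empirical ratio -> S/G
        design = StudyDesign(images_per_day=60, nuclei_per_unit=50.0)
        cryo = generate_cryosections(mild_params, design,
                                     NoiseModel(count_dispersion=0.0), seed=8)
        traj = simulate(mild_params, initial_state(mild_params, t0=-1.0),
                        [-1.0, *design.imaging_days]).set_index("time")
        day = 3.0
        grp = cryo[cryo["day"] == day]
        ratio = grp["sgm_count"].sum() / grp["g1_count"].sum()
        assert ratio == pytest.approx(traj.loc[day, "ratio_SG"], rel=0.02)

    def test_arrested_dynamics_anticorrelate_ctl_and_ratio(self):
        # a CTL pulse arresting the cycle then resolving: images with many
        # CTLs show depressed S-G2-M:G1 ratios (negative Pearson r)
        truth = TumorImmuneParams(
            s0=0.01, se=3.0, dE=1.0, di=1.0, kgs=1.64, ksg=0.66, ki=15.0,
            ke=0.2, kl=0.0, kt=0.5, kp=0.0, dl=0.5, dt=0.05, dp=2.0, dpl=2.0)
        cryo = generate_cryosections(truth, StudyDesign(), NoiseModel(),
                                     seed=4)
        ok = cryo[cryo["g1_count"] > 0]
        res = correlate_ctl_ratio(ok["ctl_count"],
                                  ok["sgm_count"] / ok["g1_count"])
        assert res["r"] < -0.3
        assert res["ci_high"] < 0


class TestExpression:
    def test_unmapped_probe_target_rejected(self, ref_params):
        table = default_probe_table()
        table.loc[0, "target"] = "mystery_gene"
        with pytest.raises(ValueError, match="mystery"):
            generate_expression(ref_params, StudyDesign(), NoiseModel(), 0,
                                probe_table=table)

    def test_sd_mean_regression_recovers_noise_model(self, ref_params):
        # self-consistency of the housekeeping noise relation
        slopes, intercepts = [], []
        for seed in (1, 2, 3, 4):
            eb = generate_expression(ref_params, StudyDesign(),
                                     NoiseModel(sample_scale_sd=0.0), seed)
            hk = eb.probe_table[(eb.probe_table["target"] == "none")
                                & (eb.probe_table["flag_pattern"] == "all")]
            sub = eb.values.loc[hk["probe"]]
            m, s = sub.mean(axis=1), sub.std(axis=1, ddof=1)
            fit = stats.linregress(m, s)
            slopes.append(fit.slope)
            intercepts.append(fit.intercept)
        assert np.mean(slopes) == pytest.approx(0.29, abs=0.05)
        assert np.mean(intercepts) == pytest.approx(0.054, abs=0.05)

    def test_flagged_probes_filtered_exactly(self, ref_params):
        eb = generate_expression(ref_params, StudyDesign(), NoiseModel(), 3)
        kept = preprocess_microarray(eb.values, eb.flags)
        absent = set(eb.probe_table.loc[eb.probe_table["flag_pattern"] == "none",
                                        "probe"])
        assert absent
        assert absent.isdisjoint(kept.index)
        assert set(eb.values.index) - set(kept.index) == absent

    def test_probe_flagged_in_some_samples_is_retained(self, ref_params):
        # the filter drops a probe only when its flag is zero everywhere
        eb = generate_expression(ref_params, StudyDesign(), NoiseModel(), 3)
        kept = preprocess_microarray(eb.values, eb.flags)
        assert "faint_1" in kept.index


class TestPreprocess:
    def toy(self):
        values = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0, 5.0], "s2": [2.0, 4.0, 6.0, 8.0, 10.0]},
            index=pd.Index([f"p{i}" for i in range(5)], name="probe"))
        flags = pd.DataFrame(
            {"s1": [1, 1, 1, 0, 0], "s2": [0, 1, 1, 0, 0]}, index=values.index)
        return values, flags

    def test_all_zero_flag_probes_dropped(self):
        values, flags = self.toy()
        kept = preprocess_microarray(values, flags)
        assert list(kept.index) == ["p0", "p1", "p2"]

    def test_scale_invariance(self):
        # rescaling one raw sample must not change the normalized matrix
        # beyond the single global factor set by the across-sample target
        values, flags = self.toy()
        ref = preprocess_microarray(values, flags)
        doubled = values.copy()
        doubled["s1"] = doubled["s1"] * 2
        out = preprocess_microarray(doubled, flags)
        ratio = (out / ref).to_numpy()
        np.testing.assert_allclose(ratio, ratio[0, 0])
        # and per-sample relative structure is exactly preserved
        np.testing.assert_allclose(out.div(out.iloc[0], axis=1),
                                   ref.div(ref.iloc[0], axis=1))

    def test_all_zero_sample_rejected(self):
        values, flags = self.toy()
        values["s1"] = 0.0
        with pytest.raises(ValueError, match="s1"):
            preprocess_microarray(values, flags)


class TestObservationBundle:
    def test_contains_all_eight_observables(self, noiseless_bundle):
        present = set(noiseless_bundle.observations.data["observable"])
        assert present == set(OBSERVABLES)

    def test_late_growth_intervals_flagged_excluded(self, noiseless_bundle):
        df = noiseless_bundle.observations.data
        growth = df[df["observable"] == "growth_rate"]
        late = growth[growth["day_start"] >= 10]
        assert len(late) == 1
        assert not late["include"].any()
        assert (late["reason"] == EXCLUSION_REASON).all()
        early = growth[growth["day_start"] < 10]
        assert early["include"].all()

    def test_noiseless_means_sit_at_model_observables(self, noiseless_bundle):
        # the generating parameters reproduce every included mean
        nll = NegativeLogLikelihood(noiseless_bundle.observations, "all")
        x = np.log10([getattr(noiseless_bundle.truth, n) for n in nll.free])
        assert nll(x) < 1e-3

    def test_small_noise_keeps_likelihood_surface_centred(self, noisy_bundle):
        # with default noise the truth still fits to within a few sd per point
        nll = NegativeLogLikelihood(noisy_bundle.observations, "all")
        x = np.log10([getattr(noisy_bundle.truth, n) for n in nll.free])
        n_included = int(noisy_bundle.observations.included().shape[0])
        assert nll(x) / n_included < 50.0
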