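"""Generator contracts: trajectory shapes, censoring, determinism, effects."""

import numpy as np
import pandas as pd
import pytest

from cfpreg import qpcr_io
from cfpreg import synthetic_cohort as sc


def rise_model(**kw):
    base = dict(gene="G", group="placental", shape="rise", amplitude=2.0,
                onset_week=22.0, steepness=0.3, baseline=-1.2, noise_sd=0.2)
    base.update(kw)
    return sc.GeneModel(**base)


class TestGeneTrajectory:
    def test_postpartum_collapse_to_baseline(self):
        m = rise_model()
        assert sc.gene_trajectory(m, 42.0, 40.0) == pytest.approx(m.baseline)

    def test_zero_amplitude_is_baseline_everywhere(self):
        m = rise_model(amplitude=0.0)
        ga = np.linspace(0, 45, 40)
        np.testing.assert_allclose(sc.gene_trajectory(m, ga, 40.0),
                                   m.baseline)

    def test_rise_is_monotone_nondecreasing_antepartum(self):
        m = rise_model()
        ga = np.arange(0, 40, 0.25)
        traj = sc.gene_trajectory(m, ga, 40.0)
        assert np.all(np.diff(traj) >= 0)

    def test_early_peak_argmax_matches_grid_oracle(self):
        m = rise_model(shape="early_peak", onset_week=9.0, steepness=2.2)
        ga = np.arange(0.0, 13.01, 0.1)
        traj = sc.gene_trajectory(m, ga, 40.0)
        # grid-search oracle over the closed-form curve
        assert ga[np.argmax(traj)] == pytest.approx(9.0, abs=0.05)
        # unimodal: rises to the peak, decays after it
        peak = np.argmax(traj)
        assert np.all(np.diff(traj[1:peak + 1]) > 0)
        assert np.all(np.diff(traj[peak:]) < 0)

    def test_negative_ga_rejected(self):
        with pytest.raises(ValueError, match="gestational age"):
            sc.gene_trajectory(rise_model(), -1.0, 40.0)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            rise_model(amplitude=-1.0)
        with pytest.raises(ValueError):
            rise_model(noise_sd=-0.1)
        with pytest.raises(ValueError):
            rise_model(shape="sawtooth")


class TestSimulateCohort:
    def test_zero_noise_reproduces_trajectories_exactly(self, mini_panel):
        panel = [sc.GeneModel(m.gene, m.group, m.shape, m.amplitude,
                              m.onset_week, m.steepness, m.baseline, 0.0)
                 for m in mini_panel]
        config = sc.SimulationConfig(
            seed=1, lod=-10.0,
            cohorts=(sc.CohortDesign("c", 4, scheme="weekly",
                                     preterm_fraction=0.0),))
        samples, outcomes = sc.simulate_cohort(config, panel)
        ga_del = outcomes.set_index("subject_id")["ga_delivery"]
        models = {m.gene: m for m in panel}
        expected = [
            sc.gene_trajectory(models[row.gene], row.ga_weeks,
                               ga_del[row.subject_id])
            for row in samples.itertuples()]
        np.testing.assert_allclose(samples["value_log10"], expected)

    def test_same_seed_is_byte_identical(self, weekly_config, mini_panel):
        a = sc.simulate_cohort(weekly_config, mini_panel)
        b = sc.simulate_cohort(weekly_config, mini_panel)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_weekly_draw_count_by_enumeration(self, mini_panel):
        # enrollment at week 5, delivery at 40 -> weeks 5..40 + 1 postpartum
        rng = np.random.default_rng(0)
        design = sc.CohortDesign("c", 1, scheme="weekly",
                                 enroll_window=(5, 5), preterm_fraction=0.0)
        ga, pp = sc._subject_draws(rng, design, ga_del=40.0)
        assert (~pp).sum() == 36 and pp.sum() == 1
        np.testing.assert_allclose(ga[:-1], np.arange(5, 41))
        assert ga[-1] == pytest.approx(41.0)

        # and through the full simulation, counts follow the same rule
        config = sc.SimulationConfig(
            seed=3,
            cohorts=(sc.CohortDesign("c", 3, scheme="weekly",
                                     enroll_window=(5, 5),
                                     preterm_fraction=0.0),))
        samples, outcomes = sc.simulate_cohort(config, mini_panel)
        per_draw = samples.drop_duplicates(["subject_id", "ga_weeks"])
        for sid, grp in per_draw.groupby("subject_id"):
            ga_del = outcomes.set_index("subject_id").loc[sid, "ga_delivery"]
            assert (~grp["postpartum_flag"]).sum() == int(ga_del) - 5 + 1
            assert grp["postpartum_flag"].sum() == 1

    def test_placental_risers_undetected_postpartum(self, weekly_cohort):
        samples, _ = weekly_cohort
        pp = samples[samples["postpartum_flag"]
                     & (samples["gene"].isin(["PLA1", "CGB"]))]
        assert len(pp) > 0
        assert not pp["detected"].any()

    def test_sparse_draws_truncated_at_delivery(self, mini_panel):
        config = sc.SimulationConfig(
            seed=5, preterm_fraction=1.0,
            preterm_delivery_low=28.0, preterm_delivery_high=30.0,
            cohorts=(sc.CohortDesign("c", 3, scheme="sparse", n_draws=2,
                                     window=(25.0, 36.0)),))
        samples, outcomes = sc.simulate_cohort(config, mini_panel)
        merged = samples.merge(outcomes, on="subject_id")
        assert (merged["ga_weeks"] < merged["ga_delivery"]).all()

    def test_empty_panel_rejected(self, weekly_config):
        with pytest.raises(ValueError, match="nonempty"):
            sc.simulate_cohort(weekly_config, [])


@pytest.fixture(scope="module")
def cohort(mini_panel):
    config = sc.SimulationConfig(
        seed=9, preterm_fraction=0.4,
        cohorts=(sc.CohortDesign("c", 30, scheme="sparse", n_draws=1,
                                 window=(20.0, 28.0)),))
    return sc.simulate_cohort(config, mini_panel)


class TestInjectPretermEffect:
    def test_zero_effect_is_identity(self, cohort):
        samples, outcomes = cohort
        out = sc.inject_preterm_effect(samples, outcomes, ["OTH1"], 0.0)
        pd.testing.assert_frame_equal(out, samples)

    def test_term_subjects_untouched(self, cohort):
        samples, outcomes = cohort
        out = sc.inject_preterm_effect(samples, outcomes, ["OTH1"], 1.0)
        term = outcomes.loc[outcomes["label"] == "term", "subject_id"]
        mask = samples["subject_id"].isin(term)
        pd.testing.assert_series_equal(out.loc[mask, "value_log10"],
                                       samples.loc[mask, "value_log10"])

    def test_unknown_gene_rejected(self, cohort):
        samples, outcomes = cohort
        with pytest.raises(ValueError, match="not present"):
            sc.inject_preterm_effect(samples, outcomes, ["NOPE"], 1.0)

    def test_no_preterm_subjects_rejected(self, weekly_cohort):
        samples, outcomes = weekly_cohort
        with pytest.raises(ValueError, match="preterm"):
            sc.inject_preterm_effect(samples, outcomes, ["OTH1"], 1.0)

    def test_effect_size_recovered(self):
        """Injected standardized shift is re-estimated near its target."""
        from cfpreg.preterm_classifier import hedges_g
        panel = [sc.GeneModel("OTH1", "other", "rise_with_baseline", 0.0,
                              20.0, 0.2, baseline=1.0, noise_sd=0.3)]
        est = []
        for seed in range(5):
            config = sc.SimulationConfig(
                seed=seed, preterm_fraction=0.5,
                cohorts=(sc.CohortDesign("c", 400, scheme="sparse",
                                         n_draws=1, window=(20.0, 28.0)),))
            samples, outcomes = sc.simulate_cohort(config, panel)
            out = sc.inject_preterm_effect(samples, outcomes, ["OTH1"], 0.8)
            labels = out["subject_id"].map(
                outcomes.set_index("subject_id")["label"])
            est.append(hedges_g(out.loc[labels == "preterm", "value_log10"],
                                out.loc[labels == "term", "value_log10"]))
        assert np.mean(est) == pytest.approx(0.8, abs=0.1)


class TestSimulateCountMatrix:
    def make_config(self, n, seed=0):
        return sc.SimulationConfig(
            seed=seed, preterm_fraction=0.0,
            cohorts=(sc.CohortDesign("c", n, scheme="sparse", n_draws=1,
                                     window=(20.0, 28.0)),))

    def test_fixed_seed_identical(self, mini_panel):
        cfg = self.make_config(6, seed=4)
        a, _ = sc.simulate_count_matrix(cfg, mini_panel, 0.2)
        b, _ = sc.simulate_count_matrix(cfg, mini_panel, 0.2)
        pd.testing.assert_frame_equal(a, b)

    def test_poisson_limit_variance_mean_ratio(self):
        panel = [sc.GeneModel("G", "other", "rise_with_baseline", 0.0, 20.0,
                              0.2, baseline=1.5, noise_sd=0.0)]
        counts, _ = sc.simulate_count_matrix(
            self.make_config(2000), panel, 0.0, mean_library=500.0,
            lib_sigma=0.0)
        v = counts.iloc[0].var(ddof=1)
        m = counts.iloc[0].mean()
        assert v / m == pytest.approx(1.0, rel=0.15)

    def test_nb_moments_match_dispersion(self):
        """Sample variance tracks mu + phi mu^2 (moment oracle)."""
        panel = [sc.GeneModel("G", "other", "rise_with_baseline", 0.0, 20.0,
                              0.2, baseline=1.5, noise_sd=0.0)]
        phi = 0.3
        counts, _ = sc.simulate_count_matrix(
            self.make_config(2000, seed=8), panel, phi, mean_library=500.0,
            lib_sigma=0.0)
        x = counts.iloc[0].to_numpy(dtype=float)
        m = x.mean()
        expected = m + phi * m ** 2
        assert x.var(ddof=1) == pytest.approx(expected, rel=0.2)

    def test_negative_dispersion_rejected(self, mini_panel):
        with pytest.raises(ValueError, match="dispersion"):
            sc.simulate_count_matrix(self.make_config(4), mini_panel, -0.1)

    def test_preterm_fold_change_applied(self):
        panel = [sc.GeneModel("G", "other", "rise_with_baseline", 0.0, 20.0,
                              0.2, baseline=1.5, noise_sd=0.0),
                 sc.GeneModel("REF", "other", "rise_with_baseline", 0.0,
                              20.0, 0.2, baseline=1.5, noise_sd=0.0)]
        cfg = sc.SimulationConfig(
            seed=2, preterm_fraction=0.5,
            cohorts=(sc.CohortDesign("c", 400, scheme="sparse", n_draws=1,
                                     window=(20.0, 28.0)),))
        counts, outcomes = sc.simulate_count_matrix(
            cfg, panel, 0.0, mean_library=2000.0,
            effect_log2fc={"G": 1.0})
        pre = outcomes.set_index("subject_id")["label"] == "preterm"
        ratio = counts.loc["G"] / counts.loc["REF"]
        fc = ratio[pre.values].mean() / ratio[~pre.values].mean()
        assert fc == pytest.approx(2.0, rel=0.1)


class TestGroupStructure:
    def test_within_group_unity_and_cross_below_on_shared_curves(self):
        """One shared trajectory per group: within r = 1, cross r < 1."""
        from cfpreg import temporal_structure as ts
        panel = []
        for i in range(3):
            panel.append(sc.GeneModel(f"P{i}", "placental", "rise", 2.0,
                                      26.0, 0.35, baseline=-1.2, noise_sd=0.0))
            panel.append(sc.GeneModel(f"I{i}", "immune", "rise_with_baseline",
                                      0.6, 12.0, 0.12, baseline=0.8,
                                      noise_sd=0.0))
        config = sc.SimulationConfig(
            seed=11, lod=-10.0,
            cohorts=(sc.CohortDesign("c", 6, scheme="weekly",
                                     preterm_fraction=0.0),))
        samples, _ = sc.simulate_cohort(config, panel)
        matrix = qpcr_io.from_long_frame(samples,
                                         {m.gene: m.group for m in panel})
        res = ts.pairwise_pearson(matrix)
        res = ts.group_median_correlations(res,
                                           {m.gene: m.group for m in panel})
        assert res.group_medians["placental"] == pytest.approx(1.0)
        assert res.group_medians["immune"] == pytest.approx(1.0)
        cross = res.cross_medians[("immune", "placental")]
        assert cross < res.group_medians["placental"]
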