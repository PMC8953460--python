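"""Virtual population generation, trials and synthetic observations."""

import numpy as np
import pandas as pd
import pytest

import antapbpk as ap
from antapbpk.engine import build_model, elephant1_regimen, simulate
from antapbpk.ivive import build_clearance_breakdown
from antapbpk.nca import auc_fold_spread, average_fold_difference
from antapbpk.population import (
    ELEPHANT_SAMPLING_SCHEDULE,
    PopulationSpec,
    generate_population,
    run_virtual_trial,
    synthesize_observations,
)


def _zero_cv_spec(n=3, seed=0, **kw):
    return PopulationSpec(
        n_subjects=n, seed=seed, age_sd=0.0, proportion_female=0.0,
        body_weight_cv=0.0, hematocrit_sd=0.0, cardiac_output_cv=0.0,
        mppgl_cv=0.0, abundance_cv=0.0, metabolite_clearance_cv=0.0,
        cyp2d6_frequencies={"EM": 1.0}, **kw)


class TestGeneration:
    def test_seed_determinism(self):
        spec = PopulationSpec(n_subjects=20, seed=99)
        a = generate_population(spec)
        b = generate_population(spec)
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_zero_cv_single_phenotype_identical_to_reference(self, subject):
        pop = generate_population(_zero_cv_spec())
        for sub in pop:
            assert sub.body_weight == pytest.approx(subject.body_weight)
            assert sub.liver.mppgl == pytest.approx(40.0)
            assert sub.liver.enzyme_abundances["CYP2D6"] == pytest.approx(8.0)
            assert sub.liver.enzyme_abundances["CYP2C19"] == pytest.approx(14.0)
            assert sub.cardiac_output == pytest.approx(subject.cardiac_output)

    def test_lognormal_cv_recovered_at_large_n(self):
        spec = PopulationSpec(n_subjects=2000, seed=4, abundance_cv=0.30)
        pop = generate_population(spec)
        ab = np.array([s.liver.enzyme_abundances["CYP2C19"] for s in pop])
        cv = ab.std(ddof=1) / ab.mean()
        assert abs(cv - 0.30) < 0.03

    def test_patient_trial_demographics(self):
        """AF-patient-like specification reproduces the enrolled cohort's
        sex split and age distribution."""
        spec = PopulationSpec(
            n_subjects=18, seed=12, age_mean=59.0, age_sd=14.0,
            proportion_female=6 / 18,
            body_weight_mean={"M": 88.0, "F": 88.0})
        pop = generate_population(spec)
        sexes = [s.sex for s in pop]
        assert sexes.count("F") == 6 and sexes.count("M") == 12
        ages = np.array([s.age for s in pop])
        assert abs(ages.mean() - 59.0) < 3 * 14.0 / np.sqrt(18)
        weights = np.array([s.body_weight for s in pop])
        assert abs(weights.mean() - 88.0) < 3 * 13.0 / np.sqrt(18)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(Exception, match="sum to 1"):
            PopulationSpec(n_subjects=2, seed=0,
                           cyp2d6_frequencies={"EM": 0.5, "PM": 0.2})

    def test_flows_sum_to_cardiac_output(self):
        pop = generate_population(PopulationSpec(n_subjects=10, seed=3))
        for sub in pop:
            assert sum(sub.blood_flows.values()) == pytest.approx(
                sub.cardiac_output, rel=1e-9)


class TestTrial:
    def test_single_reference_subject_equals_direct_simulation(
            self, parent, metabolite, subject):
        pop = generate_population(_zero_cv_spec(n=1))
        grid = np.linspace(0.0, 12.0, 200)
        trial = run_virtual_trial(pop, parent, metabolite,
                                  elephant1_regimen(), duration=12.0,
                                  grid=grid)
        model = build_model(parent, metabolite, subject,
                            ap.predict_kp_set(parent),
                            ap.predict_kp_set(metabolite))
        direct = simulate(model, elephant1_regimen(), duration=12.0,
                          grid=grid)
        for analyte in direct.plasma_conc:
            np.testing.assert_allclose(
                trial.results[0].plasma_conc[analyte],
                direct.plasma_conc[analyte], rtol=1e-9)

    def test_percentile_bands_bracket_individuals(self, trial_100):
        bands = trial_100.percentiles["antazoline"]
        mat = np.vstack([r.plasma_conc["antazoline"]
                         for r in trial_100.results])
        late = trial_100.results[0].time > 0.5
        inside = ((mat[:, late] >= bands.p5.to_numpy()[late])
                  & (mat[:, late] <= bands.p95.to_numpy()[late]))
        assert inside.mean() > 0.85

    def test_fast_metabolizers_show_high_metabolite_exposure(self, trial_100):
        """CYP2D6 activity trades parent exposure for metabolite exposure."""
        m = trial_100.metrics
        parent_auc = m[m.analyte == "antazoline"].set_index("subject").auc_inf
        met_auc = m[m.analyte == "hydroxyantazoline"].set_index(
            "subject").auc_last
        pheno = m[m.analyte == "antazoline"].set_index(
            "subject").cyp2d6_phenotype
        pm = pheno[pheno == "PM"].index
        em = pheno[pheno == "EM"].index
        if len(pm) == 0:
            pytest.skip("no PM drawn in this population")
        assert parent_auc[pm].mean() > 2 * parent_auc[em].mean()
        assert met_auc[pm].mean() < met_auc[em].mean()

    def test_auc_spread_driven_by_pm_frequency(self, parent):
        """Closed-form per-subject AUC (dose/CL): poor metabolizers widen
        the population fold spread far beyond the PM-free baseline."""
        dose = elephant1_regimen().total_base_dose
        spreads = {}
        for pm in (0.0, 0.08, 0.25):
            freqs = {"PM": pm, "IM": 0.30, "UM": 0.03,
                     "EM": 1.0 - pm - 0.33}
            spec = PopulationSpec(n_subjects=300, seed=8,
                                  cyp2d6_frequencies=freqs)
            pop = generate_population(spec)
            aucs = [dose * 1000.0
                    / build_clearance_breakdown(parent, s.liver).total_plasma_cl
                    for s in pop]
            spreads[pm] = auc_fold_spread(aucs)
        assert spreads[0.0] < 0.5 * spreads[0.08]
        assert spreads[0.0] < 0.5 * spreads[0.25]


class TestObservations:
    def test_zero_error_reproduces_predictions(self, trial_100):
        obs = synthesize_observations(trial_100, error_cv=0.0, seed=5)
        res = trial_100.results[0]
        sub = trial_100.subjects[0].id
        sel = obs.data[(obs.data.subject == sub)
                       & (obs.data.analyte == "antazoline")]
        pred = np.interp(sel.time_h, res.time,
                         res.plasma_conc["antazoline"])
        np.testing.assert_allclose(sel.conc_ng_ml, pred, rtol=1e-12)

    def test_schedule_has_six_samples(self, trial_100):
        obs = synthesize_observations(trial_100, seed=5)
        counts = obs.data.groupby(["subject", "analyte"]).size()
        assert (counts == len(ELEPHANT_SAMPLING_SCHEDULE)).all()
        assert obs.data.below_lloq.dtype == bool

    def test_seed_determinism(self, trial_100):
        a = synthesize_observations(trial_100, seed=11)
        b = synthesize_observations(trial_100, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_afe_unbiased_at_20pct_cv(self, trial_100):
        """Predictions vs observations synthesized from them: the average
        fold difference is centred at 1."""
        obs = synthesize_observations(trial_100, error_cv=0.20, seed=13)
        bands = trial_100.percentiles["antazoline"]
        obs_mean = (obs.data[obs.data.analyte == "antazoline"]
                    .groupby("time_h").conc_ng_ml.mean())
        tpts = np.array([t for t in obs_mean.index if t > 0])
        pred = np.interp(tpts, bands.time_h, bands["mean"])
        afe, _, _ = average_fold_difference(pred, obs_mean.loc[tpts])
        assert 0.9 < afe < 1.1

    def test_schedule_beyond_span_rejected(self, trial_100):
        with pytest.raises(ValueError, match="span"):
            synthesize_observations(trial_100, schedule_h=[0.0, 100.0],
                                    seed=1)
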