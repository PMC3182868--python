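"""Virtual-cohort generator: determinism, noise structure, censoring."""

import numpy as np
import pytest

import il21pkpd as il
from il21pkpd.pd import drug_free_logistic
from il21pkpd.synthetic import (
    EUTHANASIA_MM3,
    CohortSpec,
    NoiseModel,
    bundle_from_manifest,
    default_ground_truth,
    generate_pk_profiles,
    generate_tumor_cohort,
    make_training_bundle,
)

DT = 0.004


@pytest.fixture(scope="module")
def truth():
    return default_ground_truth(routes=("SC", "IP", "IV"))


class TestPKProfiles:
    def test_zero_noise_reproduces_simulation_exactly(self, truth):
        times = [0.05, 0.1, 0.25, 0.5, 1.0]
        ds = generate_pk_profiles("SC", 50.0, times, truth.topologies["SC"],
                                  truth.pk_params["SC"],
                                  NoiseModel(0.0, 0.0, 0.0), seed=1, dt=DT)
        traj = il.simulate_single_dose(truth.topologies["SC"],
                                       truth.pk_params["SC"], 50.0, 1.0, dt=DT)
        assert np.allclose(ds.mean, traj.at(times, traj.plasma_conc))
        assert np.all(ds.sem < 1e-12)

    def test_same_seed_identical_dataset(self, truth):
        kw = dict(route="IV", dose_ug=50.0, sampling_times=[0.0, 0.1, 0.5],
                  topology=truth.topologies["IV"],
                  pk_params=truth.pk_params["IV"], seed=9, dt=DT)
        a = generate_pk_profiles(**kw)
        b = generate_pk_profiles(**kw)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sem, b.sem)

    def test_iv_initial_mean_near_dose_over_plasma_volume(self, truth):
        ds = generate_pk_profiles("IV", 50.0, [0.0, 0.1],
                                  truth.topologies["IV"],
                                  truth.pk_params["IV"],
                                  NoiseModel(0.05, 0.0, 0.05), n_mice=50,
                                  seed=3, dt=DT)
        assert ds.mean[0] == pytest.approx(25.0, rel=0.1)

    def test_nonpositive_dose_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_pk_profiles("SC", 0.0, [0.1], truth.topologies["SC"],
                                 truth.pk_params["SC"])


class TestTumorCohorts:
    def test_noise_free_pbs_equals_logistic_until_censoring(self, truth):
        spec = CohortSpec(regimen=il.standard_b16_regimen().replace(
            dose_ug=0.0, n_doses=0, label="PBS"),
            n_mice=4, noise=NoiseModel(0.0, 0.0, 0.0), seed=2)
        ds, animals = generate_tumor_cohort(spec, truth, dt=DT)
        expected = drug_free_logistic(truth.pd_params, truth.t0_cells,
                                      ds.times) / 1e6
        assert np.allclose(ds.mean, expected, rtol=1e-6)
        # once the curve crosses 1000 mm3 the cohort thins out
        crossed = expected >= EUTHANASIA_MM3
        if crossed.any():
            assert ds.times[-1] == ds.times[crossed][0]

    def test_censoring_removes_all_later_measurements(self, truth):
        spec = CohortSpec(regimen=il.standard_b16_regimen().replace(
            dose_ug=0.0, n_doses=0), n_mice=12, seed=5)
        ds, animals = generate_tumor_cohort(spec, truth, dt=DT)
        for _, grp in animals.groupby("animal"):
            over = grp["tumor_mm3"].values >= EUTHANASIA_MM3
            if over.any():
                # the crossing measurement is the animal's last record
                assert over.argmax() == len(grp) - 1

    def test_sem_is_sd_over_sqrt_n(self, truth):
        spec = CohortSpec(regimen=il.standard_b16_regimen(), n_mice=6, seed=8)
        ds, animals = generate_tumor_cohort(spec, truth, dt=DT)
        day = ds.times[3]
        obs = animals.loc[animals.time_days == day, "tumor_mm3"].values
        assert ds.sem[3] == pytest.approx(obs.std(ddof=1) / np.sqrt(len(obs)))
        assert ds.n[3] == len(obs)

    def test_nk_neutralized_grows_at_least_as_fast_as_full_arm(self, truth):
        kw = dict(regimen=il.standard_b16_regimen(), n_mice=6,
                  noise=NoiseModel(0.0, 0.0, 0.0), seed=11)
        full, _ = generate_tumor_cohort(CohortSpec(**kw), truth, dt=DT)
        neut, _ = generate_tumor_cohort(
            CohortSpec(neutralization="NK", **kw), truth, dt=DT)
        common = np.intersect1d(full.times, neut.times)
        f = full.mean[np.isin(full.times, common)]
        n = neut.mean[np.isin(neut.times, common)]
        assert np.all(n >= f - 1e-9)

    def test_ctl_dominant_truth_orders_neutralized_arms(self, truth):
        """With k2 = 10*k1, removing T cells hurts more than removing NKs."""
        kw = dict(regimen=il.standard_b16_regimen(), n_mice=4,
                  noise=NoiseModel(0.0, 0.0, 0.0), seed=1)
        tneut, _ = generate_tumor_cohort(
            CohortSpec(neutralization="Tcell", **kw), truth, dt=DT)
        nkneut, _ = generate_tumor_cohort(
            CohortSpec(neutralization="NK", **kw), truth, dt=DT)
        common = np.intersect1d(tneut.times, nkneut.times)
        t = tneut.mean[np.isin(tneut.times, common)]
        n = nkneut.mean[np.isin(nkneut.times, common)]
        assert t[-1] > n[-1]

    def test_empirical_noise_matches_nominal_level(self, truth):
        """Across many replicate cohorts the spread of a mid-study reading
        converges to the generator's nominal noise magnitude."""
        nm = NoiseModel(proportional_cv=0.10, additive_sd=0.0, animal_cv=0.0)
        vals = []
        spec0 = CohortSpec(regimen=il.standard_b16_regimen(), n_mice=1,
                           noise=nm, seed=0,
                           measurement_days=(6.0, 10.0))
        for rep in range(400):
            ds, animals = generate_tumor_cohort(
                CohortSpec(regimen=spec0.regimen, n_mice=1, noise=nm,
                           seed=1000 + rep, measurement_days=(6.0, 10.0)),
                truth, dt=0.01)
            vals.append(animals.iloc[0]["tumor_mm3"])
        vals = np.asarray(vals)
        cv = vals.std(ddof=1) / vals.mean()
        # 400 replicates: sample CV of a 10% CV reading within ~±15%
        assert cv == pytest.approx(0.10, rel=0.15)


@pytest.fixture(scope="module")
def bundle_and_manifest():
    truth = default_ground_truth(routes=("SC", "IP"))
    return make_training_bundle(truth, seed=21, dt=DT)


class TestTrainingBundle:

    def test_contains_every_training_arm(self, bundle_and_manifest):
        bundle, _ = bundle_and_manifest
        assert set(bundle.pk_profiles) == {"SC", "IP"}
        assert set(bundle.treated) == {"SC", "IP"}
        assert len(bundle.pbs_control) and len(bundle.tcell_neutralized)
        assert {"late_onset", "low_dose"} <= set(bundle.validation)

    def test_manifest_round_trip_regenerates_identical_bundle(self,
                                                              bundle_and_manifest):
        bundle, manifest = bundle_and_manifest
        again = bundle_from_manifest(manifest)
        assert np.array_equal(again.pbs_control.mean, bundle.pbs_control.mean)
        assert np.array_equal(again.treated["SC"].mean, bundle.treated["SC"].mean)
        assert np.array_equal(again.pk_profiles["IP"].sem,
                              bundle.pk_profiles["IP"].sem)

    def test_neutralized_arms_reflect_ctl_dominance(self, bundle_and_manifest):
        bundle, _ = bundle_and_manifest
        t_final = bundle.tcell_neutralized.mean[-1]
        nk_final = bundle.nk_neutralized.mean[-1]
        assert t_final > nk_final
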