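"""Tests of the synthetic-data generators."""
import numpy as np
import pytest

from gispbbm import simulate_gis
from gispbbm.synth import (
    PerfusionTruth,
    SynthSpec,
    make_gis_profiles,
    make_perfusion_data,
    make_plasma_profiles,
    mean_profiles,
    oral_two_compartment_conc,
)


class TestGISProfiles:
    def test_zero_noise_equals_simulator_output(self, codiovan_invitro):
        sc = codiovan_invitro
        spec = SynthSpec(seed=3, noise_cv=0.0, n_replicates=2,
                         formulation=sc.formulation, gis_config=sc.gis)
        reps = make_gis_profiles(spec)
        sim = simulate_gis(sc.gis, sc.formulation,
                           times=np.arange(0.0, sc.gis.t_end + 1e-9, 10.0))
        for rep in reps:
            for prof in rep:
                clean = sim.trajectory[f"dissolved_{prof.chamber}"].to_numpy()
                np.testing.assert_array_equal(prof.amount_dissolved, clean)

    def test_seeded_generation_is_bit_for_bit_reproducible(self, codiovan_invitro):
        sc = codiovan_invitro
        spec = SynthSpec(seed=11, noise_cv=0.05, n_replicates=3,
                         formulation=sc.formulation, gis_config=sc.gis)
        a, b = make_gis_profiles(spec), make_gis_profiles(spec)
        for rep_a, rep_b in zip(a, b):
            for pa, pb in zip(rep_a, rep_b):
                np.testing.assert_array_equal(pa.amount_dissolved, pb.amount_dissolved)

    def test_replicates_draw_from_disjoint_streams(self, codiovan_invitro):
        sc = codiovan_invitro
        spec = SynthSpec(seed=11, noise_cv=0.05, n_replicates=2,
                         formulation=sc.formulation, gis_config=sc.gis)
        reps = make_gis_profiles(spec)
        jej = [rep[-1].amount_dissolved for rep in reps]
        assert not np.array_equal(jej[0], jej[1])

    def test_replicate_mean_tracks_truth_pointwise(self, codiovan_invitro):
        # with CV c and n tablets the replicate mean should sit within
        # ~2c/sqrt(n) of the truth at the vast majority of grid points
        sc = codiovan_invitro
        cv, n = 0.03, 4
        spec = SynthSpec(seed=17, noise_cv=cv, n_replicates=n,
                         formulation=sc.formulation, gis_config=sc.gis)
        mean = mean_profiles(make_gis_profiles(spec))
        sim = simulate_gis(sc.gis, sc.formulation,
                           times=np.arange(0.0, sc.gis.t_end + 1e-9, 10.0))
        hits = total = 0
        for prof in mean:
            truth = sim.trajectory[f"dissolved_{prof.chamber}"].to_numpy()
            mask = truth > 1e-6
            band = 2 * cv / np.sqrt(n) * truth[mask]
            hits += int(np.sum(np.abs(prof.amount_dissolved[mask] - truth[mask]) <= band))
            total += int(mask.sum())
        assert hits / total >= 0.85


class TestPerfusionData:
    def test_no_reabsorption_gives_plain_exponential_samples(self):
        truth = PerfusionTruth(C0=0.1, ka=0.01, k0=0.0, V0=10.0)
        spec = SynthSpec(seed=5, noise_cv=0.0, n_replicates=1, perfusion=truth)
        ds = make_perfusion_data(spec)[0]
        expected = 0.1 * np.exp(-0.01 * ds.times)
        np.testing.assert_allclose(ds.measured_conc, expected, rtol=1e-12)

    def test_back_transformation_exercises_volume_correction(self):
        truth = PerfusionTruth(C0=0.1, ka=0.01, k0=0.03, V0=10.0)
        spec = SynthSpec(seed=5, noise_cv=0.0, n_replicates=1, perfusion=truth)
        ds = make_perfusion_data(spec)[0]
        vt = truth.V0 - truth.k0 * ds.times
        corrected = ds.measured_conc * vt / truth.V0
        np.testing.assert_allclose(corrected, 0.1 * np.exp(-0.01 * ds.times), rtol=1e-12)

    def test_volume_bookkeeping_matches_truth(self):
        truth = PerfusionTruth(k0=0.02, V0=10.4, t_end=30.0)
        ds = make_perfusion_data(SynthSpec(seed=0, perfusion=truth))[0]
        assert ds.Vend == pytest.approx(10.4 - 0.02 * 30.0)


class TestPlasmaProfiles:
    def test_closed_form_starts_at_zero_and_is_positive(self, pk_params):
        t = np.linspace(0.0, 2880.0, 200)
        c = oral_two_compartment_conc(t, 320.0, 0.0123, pk_params)
        assert c[0] == pytest.approx(0.0, abs=1e-15)
        assert np.all(c >= 0.0)

    def test_zero_noise_profiles_equal_closed_form(self, pk_params):
        spec = SynthSpec(seed=7, noise_cv=0.0, n_replicates=2, pk=pk_params)
        profs = make_plasma_profiles(spec)
        clean = oral_two_compartment_conc(profs[0].times, spec.dose,
                                          spec.ka_oral, pk_params)
        for p in profs:
            np.testing.assert_array_equal(p.conc, clean)

    def test_disposition_parameters_recoverable_from_noisy_cohort(self, pk_params):
        # simulated bioequivalence-style cohort: 24 subjects, 10% CV;
        # refitting the closed form to the cohort mean recovers the
        # generating constants
        from scipy.optimize import curve_fit

        spec = SynthSpec(seed=7, noise_cv=0.1, n_replicates=24, pk=pk_params)
        profs = make_plasma_profiles(spec)
        t = profs[0].times
        mean = np.mean([p.conc for p in profs], axis=0)

        def model(t, ka, k10, k12, k21, v):
            pk = pk_params.model_copy(update={
                "k10": k10, "k12": k12, "k21": k21, "Vc_over_Fsys": v})
            return oral_two_compartment_conc(t, spec.dose, ka, pk)

        p0 = [spec.ka_oral * 1.5, pk_params.k10 * 0.7, pk_params.k12 * 1.3,
              pk_params.k21 * 0.8, pk_params.Vc_over_Fsys * 1.2]
        popt, _ = curve_fit(model, t, mean, p0=p0, maxfev=20000)
        ka_hat, k10_hat = popt[0], popt[1]
        assert ka_hat == pytest.approx(spec.ka_oral, rel=0.15)
        assert k10_hat == pytest.approx(pk_params.k10, rel=0.15)
        assert popt[4] == pytest.approx(pk_params.Vc_over_Fsys, rel=0.15)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SynthSpec(noise_cv=-0.1)
    with pytest.raises(ValueError):
        SynthSpec(n_replicates=0)
    with pytest.raises(ValueError, match="formulation"):
        make_gis_profiles(SynthSpec())
    with pytest.raises(ValueError, match="pk"):
        make_plasma_profiles(SynthSpec())
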