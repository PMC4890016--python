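"""Variational-Laplace inversion: priors, posterior behavior, evidence."""

import numpy as np
import pytest

from facedcm.cohort import CohortConfig, generate_cohort
from facedcm.dcm import DCM, default_priors, log_evidence, variational_laplace
from facedcm.forward import DCMParams, DCMSpec
from facedcm.modelspace import DEFAULT_FAMILIES, build_endogenous_skeleton, make_spec

FAMS = {f.family_id: f for f in DEFAULT_FAMILIES}


@pytest.fixture(scope="module")
def rh_cohort():
    """Six right-handers, 120-scan sessions at SNR 1."""
    cfg = CohortConfig(
        n_per_group=6, seed=11, groups=("RH",), n_reps=1, block_scans=10,
        n_runs=1, break_scans=0, microtime_bins=8, a_diag_sd=0.0,
        include_pupil=False, include_li=False,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def rh_fits(rh_cohort):
    """Generating-model inversions of the six subjects (haemodynamics fixed)."""
    out = []
    for s, inp in zip(rh_cohort.subjects, rh_cohort.inputs_by_subject):
        pri = default_priors(s.spec, hemo_free=False)
        out.append(DCM(s.bold, inp, s.spec, priors=pri).fit(max_iter=32,
                                                            tol=1e-3))
    return out


class TestPriors:
    def test_dimensionality_counts_masks(self):
        spec = make_spec(FAMS["B"], ("S", "F"))
        pri = default_priors(spec)
        n_b = int(spec.b_masks.sum())
        assert pri.n_params == 16 + 6 + n_b + 2 + 12
        pri0 = default_priors(spec, hemo_free=False)
        assert pri0.n_params == 16 + 6 + n_b + 2

    def test_self_connection_prior_mean(self):
        pri = default_priors(build_endogenous_skeleton())
        diag = [m for m, ix in zip(pri.mu, pri.index)
                if ix[0] == "a" and ix[1] == ix[2]]
        assert len(diag) == 6
        assert all(m == -0.5 for m in diag)

    def test_only_masked_parameters_included(self):
        spec = make_spec(FAMS["A"], ("S", "S"))
        pri = default_priors(spec)
        for ix in pri.index:
            if ix[0] == "a":
                assert spec.a_mask[ix[1], ix[2]] == 1
            elif ix[0] == "b":
                assert spec.b_masks[ix[1], ix[2], ix[3]] == 1
            elif ix[0] == "c":
                assert spec.c_mask[ix[1], ix[2]] == 1


class TestPosterior:
    def test_uninformative_data_stays_at_prior(self, small_inputs):
        # data simulated from the prior mean itself carry no information
        spec = make_spec(FAMS["B"], ("S", "F"))
        pri = default_priors(spec, hemo_free=False)
        from facedcm.forward import simulate_bold

        packer_params = DCMParams(-0.5 * np.eye(6), np.zeros((5, 6, 6)),
                                  np.zeros((6, 5)))
        ds = simulate_bold(spec, packer_params, small_inputs, noise_sd=1e-3,
                           seed=0)
        res = DCM(ds, small_inputs, spec, priors=pri).fit(max_iter=16,
                                                          tol=1e-3)
        z = np.abs(res.params - pri.mu) / np.sqrt(pri.var)
        assert z.max() < 1.0

    def test_linearized_regime_matches_conjugate_oracle(self, small_inputs):
        # tiny inputs, haemodynamics frozen, known noise precision, and all
        # coupling parameters pinned: the response is linear in the two
        # driving strengths, so the posterior must match the closed-form
        # conjugate Gaussian linear-regression posterior
        spec = make_spec(FAMS["B"], ("S", "F"))
        pri = default_priors(spec, hemo_free=False)
        free = np.array([ix[0] == "c" for ix in pri.index])
        pri.var = np.where(free, pri.var, 0.0)   # zero variance = fixed
        sigma = 1e-4
        pri.h0 = float(np.log(1.0 / sigma ** 2))
        pri.var_h = 1e-10

        truth = pri.mu.copy()
        truth[free] = [0.03, 0.02]               # tiny driving inputs
        rng = np.random.default_rng(3)
        model = DCM(np.zeros((small_inputs.n_scans, 6)), small_inputs, spec,
                    priors=pri)
        y = model._predict_batch(truth[None])[0]
        y = y + sigma * rng.standard_normal(y.shape)
        model = DCM(y, small_inputs, spec, priors=pri)
        res = model.fit(max_iter=64, tol=1e-10)

        g0, J = model._jacobian(pri.mu, 1e-4)
        Jm = J.reshape(-1, pri.n_params)[:, free]
        lam = 1.0 / sigma ** 2
        S0inv = np.diag(1.0 / pri.var[free])
        H = lam * Jm.T @ Jm + S0inv
        mean_oracle = pri.mu[free] + np.linalg.solve(
            H, lam * Jm.T @ (y - g0).ravel())
        np.testing.assert_allclose(res.params[free], mean_oracle, atol=1e-3)
        np.testing.assert_allclose(res.params[~free], pri.mu[~free],
                                   atol=1e-6)

    def test_parameter_recovery_correlation(self):
        # reduced version of the recovery study: 3 subjects, 240 scans, SNR 1
        cfg = CohortConfig(
            n_per_group=3, seed=21, groups=("RH",), n_reps=2, n_runs=1,
            break_scans=0, a_diag_sd=0.0, include_pupil=False,
            include_li=False,
        )
        cohort = generate_cohort(cfg)
        true_all, rec_all = [], []
        for s, inp in zip(cohort.subjects, cohort.inputs_by_subject):
            res = DCM(s.bold, inp, s.spec,
                      priors=default_priors(s.spec)).fit(max_iter=64,
                                                         tol=1e-4)
            post = res.to_dcm_params()
            off = (s.spec.a_mask == 1) & ~np.eye(6, dtype=bool)
            true_all += [s.params.A[off], s.params.B[s.spec.b_masks == 1],
                         s.params.C[s.spec.c_mask == 1]]
            rec_all += [post.A[off], post.B[s.spec.b_masks == 1],
                        post.C[s.spec.c_mask == 1]]
        r = np.corrcoef(np.concatenate(true_all), np.concatenate(rec_all))[0, 1]
        assert r >= 0.9

    def test_posterior_covariance_psd(self, rh_fits):
        for res in rh_fits:
            ev = np.linalg.eigvalsh(res.cov_params())
            assert ev.min() >= -1e-10

    def test_retained_free_energy_monotone(self, rh_fits):
        for res in rh_fits:
            assert np.all(np.diff(res.trace) >= -1e-6)

    def test_shrinkage_prior_variance_sweep(self, rh_cohort):
        # as the prior variance shrinks, the posterior mean of a strong
        # driving parameter moves monotonically toward the prior mean (0)
        s = rh_cohort.subjects[0]
        inp = rh_cohort.inputs_by_subject[0]
        devs = []
        for var_c in (1.0, 1.0 / 16.0, 1e-4):
            pri = default_priors(s.spec, hemo_free=False, var_c=var_c)
            res = DCM(s.bold, inp, s.spec, priors=pri).fit(max_iter=24,
                                                           tol=1e-3)
            c_post = [abs(res.params[k]) for k, ix in enumerate(pri.index)
                      if ix[0] == "c"]
            devs.append(max(c_post))
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.05


class TestEvidence:
    def test_identical_inversion_identical_F(self, rh_cohort):
        s = rh_cohort.subjects[1]
        inp = rh_cohort.inputs_by_subject[1]
        pri = default_priors(s.spec, hemo_free=False)
        F1 = DCM(s.bold, inp, s.spec, priors=pri).fit(max_iter=16,
                                                      tol=1e-3).free_energy
        F2 = DCM(s.bold, inp, s.spec, priors=pri).fit(max_iter=16,
                                                      tol=1e-3).free_energy
        assert F1 == F2

    def test_log_evidence_is_free_energy(self, rh_fits):
        assert log_evidence(rh_fits[0]) == rh_fits[0].free_energy

    def test_irrelevant_parameter_lowers_evidence_on_average(self, rh_cohort):
        # family F adds EVC->FFA face modulations whose true value is 0 for
        # right-hander data: the extra free parameters should cost evidence
        spec_b = make_spec(FAMS["B"], ("S", "F"))
        spec_f = make_spec(FAMS["F"], ("S", "F"))
        dF = []
        for s, inp in zip(rh_cohort.subjects, rh_cohort.inputs_by_subject):
            Fb = DCM(s.bold, inp, spec_b,
                     priors=default_priors(spec_b, hemo_free=False)).fit(
                max_iter=32, tol=1e-3).free_energy
            Ff = DCM(s.bold, inp, spec_f,
                     priors=default_priors(spec_f, hemo_free=False)).fit(
                max_iter=32, tol=1e-3).free_energy
            dF.append(Ff - Fb)
        assert np.mean(dF) < 0

    def test_generating_model_beats_model_missing_driving_input(self, rh_cohort, rh_fits):
        # dropping the RVF driving input removes a strong true effect
        wins = 0
        for s, inp, full in zip(rh_cohort.subjects,
                                rh_cohort.inputs_by_subject, rh_fits):
            reduced_c = s.spec.c_mask.copy()
            reduced_c[0, 0] = 0
            spec_red = DCMSpec(s.spec.a_mask, s.spec.b_masks, reduced_c,
                               input_labels=s.spec.input_labels)
            Fr = DCM(s.bold, inp, spec_red,
                     priors=default_priors(spec_red, hemo_free=False)).fit(
                max_iter=32, tol=1e-3).free_energy
            wins += full.free_energy >= Fr
        assert wins >= 5   # >= 5 of 6 subjects

    def test_functional_front_door(self, rh_cohort):
        s = rh_cohort.subjects[0]
        inp = rh_cohort.inputs_by_subject[0]
        res = variational_laplace(s.spec, s.bold, inp,
                                  priors=default_priors(s.spec,
                                                        hemo_free=False),
                                  max_iter=8, tol=1e-2)
        assert np.isfinite(res.free_energy)
        assert res.summary().shape[0] == res.params.size
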