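"""Tests of the HMM layer: taxonomy, transitions, emissions, Viterbi."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nipthmm.hmm import (
    EmissionFitError,
    HmmModel,
    SEVEN_STATES,
    StateSpace,
    build_transitions,
    expected_allelic_ratio,
    fit_emissions,
    label_loci,
    model_from_dict,
    model_to_dict,
    rc_state_space,
    seven_state_space,
    state_frequencies,
    viterbi_decode,
    viterbi_decode_batch,
)
from nipthmm.simulate import SimulationConfig, simulate_cohort


class TestExpectedRatios:
    # dosage-enumeration oracle values at ff = 0.1
    @pytest.mark.parametrize(
        "state,expected",
        [
            ("E1", 1.0),
            ("E2", 1.1 / 0.9),
            ("E3", 19.0),
            ("T1", 1.1),
            ("T2", 1.2 / 0.9),
            ("T3", 20.0),
            ("P1", 9.5),
        ],
    )
    def test_closed_forms_at_ff_10(self, state, expected):
        assert expected_allelic_ratio(state, 0.10) == pytest.approx(expected)

    def test_t3_p1_separable(self):
        assert expected_allelic_ratio("T3", 0.1) == pytest.approx(20.0)
        assert expected_allelic_ratio("P1", 0.1) == pytest.approx(9.5)

    def test_e1_is_one_at_any_ff(self):
        for ff in (0.01, 0.1, 0.4):
            assert expected_allelic_ratio("E1", ff) == 1.0

    def test_ff_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_allelic_ratio("E3", 0.0)


class TestStateLabels:
    def test_full_genotype_enumeration(self):
        cases = {
            # (m_b, f_b, f_total) -> state label or None
            (1, 1, 2): "E1",
            (1, 0, 2): "E2",
            (1, 2, 2): "E2",
            (0, 1, 2): "E3",
            (2, 1, 2): "E3",
            (0, 0, 2): None,
            (2, 2, 2): None,
            (1, 1, 3): "T1",
            (1, 2, 3): "T1",
            (1, 0, 3): "T2",
            (1, 3, 3): "T2",
            (0, 1, 3): "T3",  # mother AA, fetus AAB: 2 maternal copies
            (2, 2, 3): "T3",
            (0, 2, 3): "P1",  # mother AA, fetus ABB: 1 maternal copy
            (2, 1, 3): "P1",
            (0, 0, 3): None,
            (2, 3, 3): None,
        }
        m, f, t = map(np.array, zip(*cases))
        got = label_loci(m, f, t)
        for (key, expected), g in zip(cases.items(), got):
            if expected is None:
                assert g == -1, key
            else:
                assert SEVEN_STATES[g] == expected, key


class TestTransitions:
    def test_rc_matrix_exact(self):
        np.testing.assert_allclose(
            build_transitions(rc_state_space(), 10),
            np.array([[10 / 11, 1 / 11], [1 / 11, 10 / 11]]),
        )

    def test_seven_state_e1_row(self):
        t = build_transitions(seven_state_space(), 10)
        np.testing.assert_allclose(
            t[0], np.array([10, 10, 10, 1, 1, 1, 1]) / 34.0
        )

    def test_rows_stochastic(self):
        for space in (rc_state_space(), seven_state_space("RCAR")):
            t = build_transitions(space, 10)
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)


class TestEmissionFitting:
    def test_rc_moments_match_count_model(self, training_cohorts):
        # RD 1000, FF 0.10: EUP ~ N(1000, 3000), TRI ~ N(1050, 3150)
        model = fit_emissions(training_cohorts, "RC")
        assert model.means[0, 0] == pytest.approx(1000, rel=0.01)
        assert model.means[1, 0] == pytest.approx(1050, rel=0.01)
        assert model.variances[0, 0] == pytest.approx(3000, rel=0.10)
        assert model.variances[1, 0] == pytest.approx(3150, rel=0.10)

    def test_ar_e1_mean_is_one(self, training_cohorts):
        model = fit_emissions(training_cohorts, "AR")
        assert model.means[0, 0] == pytest.approx(1.0, abs=0.15)

    def test_rcar_is_bivariate_diagonal(self, training_cohorts):
        model = fit_emissions(training_cohorts, "RCAR")
        assert model.means.shape == (7, 2)
        assert model.variances.shape == (7, 2)
        assert (model.variances > 0).all()

    def test_scale_consistency_in_rd(self):
        # doubling RD doubles the RC state means
        models = []
        for rd in (1000, 2000):
            cfg = SimulationConfig(read_depth=rd, condition="maternal_trisomy")
            cohort = simulate_cohort(cfg, 50, np.random.default_rng(5))
            eup = simulate_cohort(cfg.replace(condition="euploidy"), 50,
                                  np.random.default_rng(6))
            models.append(fit_emissions([cohort, eup], "RC"))
        np.testing.assert_allclose(
            2 * models[0].means, models[1].means, rtol=0.02
        )

    def test_missing_state_error_names_state(self, training_cohorts):
        euploid_only = [c for c in training_cohorts if c.condition == "euploidy"]
        with pytest.raises(EmissionFitError, match="T1"):
            fit_emissions(euploid_only, "AR")

    def test_model_json_round_trip(self, training_cohorts):
        model = fit_emissions(training_cohorts, "RCAR")
        clone = model_from_dict(model_to_dict(model))
        np.testing.assert_allclose(clone.means, model.means)
        np.testing.assert_allclose(clone.transmat, model.transmat)
        assert clone.space == model.space
        assert clone.ratio_cap == pytest.approx(model.ratio_cap)


def toy_rc_model(mu0=0.0, mu1=5.0, var=1.0, stay=10.0):
    space = rc_state_space()
    return HmmModel(
        space=space,
        startprob=np.full(2, 0.5),
        transmat=build_transitions(space, stay),
        means=np.array([[mu0], [mu1]]),
        variances=np.array([[var], [var]]),
    )


class TestViterbi:
    def test_constant_observations_give_constant_path(self):
        model = toy_rc_model()
        path = viterbi_decode(np.zeros(100), model)
        assert (path == 0).all()

    def test_switch_point_located_at_midpoint(self):
        model = toy_rc_model(mu0=0.0, mu1=5.0)
        obs = np.concatenate([np.zeros(50), np.full(50, 5.0)])
        path = viterbi_decode(obs, model)
        switches = np.flatnonzero(np.diff(path))
        assert len(switches) == 1
        assert abs(switches[0] + 1 - 50) <= 2

    @given(
        seed=st.integers(0, 10_000),
        t=st.integers(1, 8),
        s=st.integers(2, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_enumeration(self, brute_force, seed, t, s):
        rng = np.random.default_rng(seed)
        space = StateSpace(
            kind="RC",
            states=tuple(f"S{i}" for i in range(s)),
            conditions=tuple(["euploidy", "trisomy", "paternal_trisomy"][:s]),
        )
        trans = rng.dirichlet(np.ones(s), size=s)
        model = HmmModel(
            space=space,
            startprob=np.full(s, 1.0 / s),
            transmat=trans,
            means=rng.normal(0, 3, (s, 1)),
            variances=rng.uniform(0.5, 2.0, (s, 1)),
        )
        obs = rng.normal(0, 3, t)
        expected_path, expected_score = brute_force(obs, model)
        path = viterbi_decode(obs, model)
        _, scores = viterbi_decode_batch(obs[None, :, None], model)
        assert scores[0] == pytest.approx(expected_score)
        np.testing.assert_array_equal(path, expected_path)

    def test_agrees_with_hmmlearn_reference(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = toy_rc_model(mu0=0.0, mu1=2.0, var=1.5, stay=10.0)
        rng = np.random.default_rng(17)
        obs = rng.normal(1.0, 2.0, 200)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.means
        ref.covars_ = model.variances
        _, ref_path = ref.decode(obs[:, None], algorithm="viterbi")
        np.testing.assert_array_equal(viterbi_decode(obs, model), ref_path)

    def test_batch_respects_lengths(self):
        model = toy_rc_model()
        obs = np.zeros((2, 10, 1))
        obs[1, 5:] = 5.0  # beyond sample 1's length: must be ignored
        paths, _ = viterbi_decode_batch(obs, model, lengths=np.array([10, 5]))
        assert (paths[1, :5] == 0).all()

    def test_non_finite_observations_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            viterbi_decode(np.array([0.0, np.nan]), toy_rc_model())

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            viterbi_decode_batch(np.empty((1, 0, 1)), toy_rc_model())


class TestStateFrequencies:
    def test_histogram_and_metadata(self):
        space = rc_state_space()
        path = np.array([0] * 600 + [1] * 400)
        prof = state_frequencies(path, space, rd=1000, ff=0.1)
        np.testing.assert_allclose(prof.frequencies, [0.6, 0.4])
        assert prof.n_loci == 1000

    def test_sum_to_one_for_random_paths(self):
        rng = np.random.default_rng(2)
        space = seven_state_space()
        for _ in range(10):
            path = rng.integers(0, 7, 500)
            prof = state_frequencies(path, space, rd=1, ff=0.1)
            assert prof.frequencies.sum() == pytest.approx(1.0)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            state_frequencies(np.array([], dtype=int), rc_state_space(), 1, 0.1)
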