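"""HMM core: likelihoods, constrained EM, Viterbi, serialization."""

import numpy as np
import pytest

from epigene.grid import BinGrid
from epigene.hmm import (
    EPS,
    HMMError,
    HMMParameters,
    InfeasiblePathError,
    ObservationSequence,
    StateMeta,
    baum_welch,
    emission_loglik,
    forward_backward,
    load_model,
    save_model,
    viterbi,
)
from epigene.simulate import simulate_class_matrix
from _oracles import enumerate_paths, random_obs, random_params


class TestEmissionLoglik:
    def test_uniform_emission_constant(self, rng):
        p = random_params(3, 4, rng)
        p.emission = np.full((3, 4), 0.5)
        obs = random_obs(6, 4, rng)
        np.testing.assert_allclose(emission_loglik(p, obs), 4 * np.log(0.5))

    def test_perfect_match_near_zero(self, rng):
        p = random_params(1, 2, rng)
        p.emission = np.array([[1 - EPS, EPS]])
        obs = ObservationSequence(np.array([[1, 0]], dtype=np.uint8))
        assert emission_loglik(p, obs)[0, 0] == pytest.approx(2 * np.log(1 - EPS), abs=1e-9)

    def test_matches_per_element_product_oracle(self, rng):
        p = random_params(4, 3, rng)
        obs = random_obs(6, 3, rng)
        ll = emission_loglik(p, obs)
        for t in range(6):
            for s in range(4):
                direct = np.prod(
                    np.where(obs.values[t] == 1, p.emission[s], 1 - p.emission[s])
                )
                assert ll[t, s] == pytest.approx(np.log(direct), abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(HMMError):
            emission_loglik(random_params(2, 3, rng), random_obs(4, 2, rng))


class TestForwardBackward:
    def test_single_state_degenerate(self, rng):
        p = random_params(1, 2, rng)
        obs = random_obs(5, 2, rng)
        ll, post = forward_backward(p, obs)
        np.testing.assert_allclose(post, 1.0)
        assert ll == pytest.approx(emission_loglik(p, obs).sum(), abs=1e-10)

    def test_matches_path_enumeration(self, rng):
        for _ in range(20):
            k, n, T = rng.integers(2, 5), rng.integers(1, 4), rng.integers(2, 8)
            p = random_params(int(k), int(n), rng)
            obs = random_obs(int(T), int(n), rng)
            ll, post = forward_backward(p, obs)
            ll_enum, _, _ = enumerate_paths(p, obs)
            assert ll == pytest.approx(ll_enum, abs=1e-10)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_structural_zeros_exclude_paths(self, rng):
        """Paths through masked transitions contribute exactly zero mass."""
        for _ in range(10):
            p = random_params(3, 2, rng)
            zero = np.zeros((3, 3), dtype=bool)
            zero[0, 1] = zero[2, 0] = True
            p.transition[zero] = 0.0
            p.transition /= p.transition.sum(axis=1, keepdims=True)
            p.structural_zero = zero
            p.free_transition = ~zero
            obs = random_obs(6, 2, rng)
            ll, _ = forward_backward(p, obs)
            ll_enum, _, _ = enumerate_paths(p, obs)
            assert ll == pytest.approx(ll_enum, abs=1e-10)

    def test_long_sequence_no_underflow(self, rng):
        p = random_params(3, 2, rng)
        obs = random_obs(200_000, 2, rng)
        ll, post = forward_backward(p, obs)
        assert np.isfinite(ll)
        assert np.isfinite(post).all()


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        p = random_params(1, 2, rng)
        path, _ = viterbi(p, random_obs(5, 2, rng))
        assert path.tolist() == [0] * 5

    def test_matches_enumerated_maximum(self, rng):
        for _ in range(20):
            p = random_params(3, 2, rng)
            obs = random_obs(6, 2, rng)
            path, lp = viterbi(p, obs)
            _, best, best_path = enumerate_paths(p, obs)
            assert lp == pytest.approx(best, abs=1e-10)

    def test_recovers_planted_path(self, rng):
        """Near-deterministic emissions tracking a planted path recover it."""
        k, n, T = 3, 3, 40
        p = random_params(k, n, rng)
        p.emission = np.clip(np.eye(k, n), EPS, 1 - EPS)
        planted = rng.integers(0, k, size=T)
        obs = ObservationSequence(np.eye(n, dtype=np.uint8)[planted])
        path, _ = viterbi(p, obs)
        np.testing.assert_array_equal(path, planted)

    def test_zero_probability_start_raises_named_bin(self, rng):
        """A start distribution with no feasible state names bin 0.

        Valid row-stochastic parameters always admit some path, so the
        degenerate distribution is installed after construction.
        """
        p = random_params(2, 2, rng)
        p.initial = np.array([0.0, 0.0])
        with pytest.raises(InfeasiblePathError, match="bin 0"):
            viterbi(p, random_obs(3, 2, rng))
        with pytest.raises(InfeasiblePathError, match="bin 0"):
            forward_backward(p, random_obs(3, 2, rng))


class TestBaumWelch:
    def test_all_clamped_is_identity(self, rng):
        p = random_params(3, 2, rng)
        p.free_transition = np.zeros((3, 3), bool)
        p.free_emission = np.zeros((3, 2), bool)
        p.free_initial = np.zeros(3, bool)
        fit, trace = baum_welch(p, [random_obs(50, 2, rng)], max_iter=10)
        np.testing.assert_array_equal(fit.emission, p.emission)
        np.testing.assert_array_equal(fit.transition, p.transition)
        np.testing.assert_array_equal(fit.initial, p.initial)
        np.testing.assert_allclose(np.diff(trace), 0, atol=1e-9)

    def test_partial_clamping_contract(self, rng):
        """Clamped TU-like rows stay bit-identical; free rows move; every
        transition row still sums to 1."""
        p = random_params(4, 3, rng)
        p.free_emission = np.zeros((4, 3), bool)
        p.free_emission[2:] = True  # states 2,3 free ("background")
        p.free_transition = np.zeros((4, 4), bool)
        p.free_transition[2:, :] = True
        obs = [random_obs(400, 3, rng)]
        before = p.copy()
        fit, trace = baum_welch(p, obs, max_iter=100, tol=0.0)
        np.testing.assert_array_equal(fit.emission[:2], before.emission[:2])
        np.testing.assert_array_equal(fit.transition[:2], before.transition[:2])
        np.testing.assert_allclose(fit.transition.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(trace) >= -1e-8).all()

    def test_free_entries_share_remaining_row_mass(self, rng):
        """In a mixed row the clamped entries keep their values and the free
        entries redistribute exactly the leftover mass."""
        p = random_params(3, 2, rng)
        free = np.zeros((3, 3), bool)
        free[0, 1] = free[0, 2] = True  # row 0: entry 0 clamped
        p.free_transition = free
        clamped_val = p.transition[0, 0]
        fit, _ = baum_welch(p, [random_obs(300, 2, rng)], max_iter=20, tol=0.0)
        assert fit.transition[0, 0] == clamped_val
        assert fit.transition[0, 1:].sum() == pytest.approx(1 - clamped_val, abs=1e-12)

    def test_two_state_recovery_up_to_relabeling(self, rng):
        true = random_params(2, 2, rng)
        true.emission = np.array([[0.9, 0.15], [0.2, 0.85]])
        true.transition = np.array([[0.95, 0.05], [0.08, 0.92]])
        true.initial = np.array([0.5, 0.5])
        grid = BinGrid([("c", 200 * 50_000)], 200)
        cm, _ = simulate_class_matrix(true, grid, rng=7)
        start = random_params(2, 2, np.random.default_rng(3))
        fit, _ = baum_welch(
            start, [ObservationSequence(cm.values)], max_iter=300, tol=1e-8
        )
        errs = []
        for perm in ([0, 1], [1, 0]):
            errs.append(np.abs(fit.emission[perm] - true.emission).max())
        assert min(errs) < 0.02

    def test_clamped_mass_one_with_free_entries_rejected(self, rng):
        p = random_params(2, 2, rng)
        p.transition = np.array([[1.0, 0.0], [0.5, 0.5]])
        free = np.zeros((2, 2), bool)
        free[0, 1] = True  # free entry in a row whose clamped mass is 1
        with pytest.raises(HMMError, match="clamped"):
            HMMParameters(
                emission=p.emission, transition=p.transition, initial=p.initial,
                structural_zero=np.zeros((2, 2), bool), free_transition=free,
                free_emission=p.free_emission, free_initial=p.free_initial,
            )

    def test_no_sequences_rejected(self, rng):
        with pytest.raises(HMMError):
            baum_welch(random_params(2, 2, rng), [])


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        p = random_params(3, 2, rng)
        p.state_meta = [
            StateMeta("TSS", "TSS", "na"),
            StateMeta("exon1+", "exon1", "+"),
            StateMeta("bg1", "background", "na"),
        ]
        p.marks = ["H3K4me3", "H3K36me3"]
        path = tmp_path / "model.json"
        save_model(p, path)
        q = load_model(path)
        np.testing.assert_array_equal(q.emission, p.emission)
        np.testing.assert_array_equal(q.transition, p.transition)
        np.testing.assert_array_equal(q.initial, p.initial)
        np.testing.assert_array_equal(q.free_transition, p.free_transition)
        assert q.state_meta == p.state_meta
        assert q.marks == p.marks

    def test_unknown_version_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}\n')
        with pytest.raises(HMMError, match="version"):
            load_model(path)
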