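"""Unit and property tests for the grade-of-membership EM core."""

import itertools
import math

import numpy as np
import pytest

import ecomotifs as em
from conftest import random_valid_fit


# ---------------------------------------------------------------------------
# multinomial model
# ---------------------------------------------------------------------------


def test_k1_map_equals_column_proportions(block_counts):
    fit = em.fit_multinomial_gom(block_counts, K=1, seed=0)
    assert np.allclose(fit.omega, 1.0)
    assert np.allclose(fit.theta, [[0.5, 0.5]], atol=1e-9)
    assert fit.log_bf == 0.0


def test_block_diagonal_separates(block_counts):
    fit = em.multistart_fit(block_counts, K=2, n_starts=5, seed=0)
    # align so motif 1 is the one loaded on row "a"
    order = np.argsort(-fit.omega[0])
    omega = fit.omega[:, order]
    theta = fit.theta[order]
    assert np.allclose(omega, np.eye(2), atol=0.02)
    assert np.allclose(theta, np.eye(2), atol=0.02)


def test_multinomial_recovery_from_simulation():
    counts, truth = em.simulate_gom(N=100, G=50, K=3, depth=500, seed=1)
    fit = em.multistart_fit(counts, 3, n_starts=5, seed=1)
    err = em.recovery_error(fit, truth)
    assert err["omega_mae"] < 0.10


def test_fit_rejects_bad_arguments(small_counts):
    with pytest.raises(ValueError, match="K"):
        em.fit_multinomial_gom(small_counts, K=0)
    with pytest.raises(ValueError, match="exceeds"):
        em.fit_multinomial_gom(small_counts, K=100)
    with pytest.raises(ValueError, match="tol"):
        em.fit_multinomial_gom(small_counts, K=2, tol=0)


def test_transposed_matrix_fits_without_modification(small_counts):
    """Feature-side motifs: fitting the transpose yields G x K memberships."""
    t = small_counts.transpose()
    fit = em.fit_multinomial_gom(t, K=2, seed=0)
    assert fit.omega.shape == (small_counts.n_cols, 2)
    assert np.allclose(fit.omega.sum(axis=1), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# bernoulli model
# ---------------------------------------------------------------------------


def test_bernoulli_all_ones_degenerate():
    m = em.PresenceMatrix(np.ones((3, 4), dtype=int))
    fit = em.fit_bernoulli_gom(m, K=1, seed=0)
    assert np.allclose(fit.theta, 1.0, atol=1e-6)
    assert np.allclose(fit.omega, 1.0)


def test_bernoulli_disjoint_blocks():
    vals = np.zeros((10, 8), dtype=int)
    vals[:5, :4] = 1
    vals[5:, 4:] = 1
    m = em.PresenceMatrix(vals)
    fit = em.multistart_fit(m, 2, n_starts=5, seed=0)
    order = np.argsort(-fit.omega[0])
    omega = fit.omega[:, order]
    hard = np.zeros((10, 2))
    hard[:5, 0] = 1
    hard[5:, 1] = 1
    assert np.abs(omega - hard).max() < 0.05


def test_bernoulli_recovery_from_simulation():
    presence, truth = em.simulate_gom(
        N=200, G=100, K=2, model_kind="bernoulli", seed=7
    )
    fit = em.multistart_fit(presence, 2, n_starts=5, seed=7)
    err = em.recovery_error(fit, truth)
    assert err["theta_rmse"] < 0.10


def test_bernoulli_requires_presence_matrix(small_counts):
    with pytest.raises(TypeError):
        em.fit_bernoulli_gom(small_counts, K=2)


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------


def test_loglik_hand_value():
    m = em.CountMatrix([[1, 1]])
    fit = em.MotifFit(
        model_kind="multinomial", K=1, omega=np.ones((1, 1)),
        theta=np.array([[0.5, 0.5]]), loglik_trace=np.empty(0),
        log_bf=0.0, seed=None, converged=True,
    )
    assert em.loglik(fit, m) == pytest.approx(2 * math.log(0.5), abs=1e-9)


def _brute_force_loglik(fit, data):
    """Entrywise summation with scalar math — independent of the package path."""
    P = [[sum(fit.omega[n][k] * fit.theta[k][g] for k in range(fit.K))
          for g in range(data.n_cols)] for n in range(data.n_rows)]
    total = 0.0
    if fit.model_kind == "multinomial":
        for n in range(data.n_rows):
            for g in range(data.n_cols):
                c = int(data.values[n][g])
                if c > 0:
                    total += c * math.log(P[n][g])
    else:
        for n in range(data.n_rows):
            for g in range(data.n_cols):
                total += math.log(P[n][g]) if data.values[n][g] == 1 else math.log(1 - P[n][g])
    return total


@pytest.mark.parametrize("model_kind", ["multinomial", "bernoulli"])
def test_loglik_matches_brute_force(model_kind, rng):
    if model_kind == "multinomial":
        data = em.CountMatrix(rng.integers(0, 9, size=(3, 4)) + 1)
    else:
        vals = rng.integers(0, 2, size=(3, 4))
        vals[:, 0] = 1
        data = em.PresenceMatrix(vals)
    fit = random_valid_fit(3, 4, 2, model_kind, rng)
    assert em.loglik(fit, data) == pytest.approx(_brute_force_loglik(fit, data), abs=1e-10)


def test_loglik_zero_probability_is_neg_inf():
    data = em.CountMatrix([[5, 5]])
    fit = em.MotifFit(
        model_kind="multinomial", K=1, omega=np.ones((1, 1)),
        theta=np.array([[1.0, 0.0]]), loglik_trace=np.empty(0),
        log_bf=0.0, seed=None, converged=True,
    )
    assert em.loglik(fit, data) == -np.inf  # reported, not raised


def test_k1_loglik_maximised_by_column_proportions(small_counts, rng):
    """MLE property: no K=1 theta beats the column-proportion theta."""
    props = small_counts.values.sum(axis=0) / small_counts.values.sum()
    def ll(theta):
        fit = em.MotifFit(
            model_kind="multinomial", K=1,
            omega=np.ones((small_counts.n_rows, 1)), theta=theta[None, :],
            loglik_trace=np.empty(0), log_bf=0.0, seed=None, converged=True,
        )
        return em.loglik(fit, small_counts)
    best = ll(props)
    for _ in range(25):
        assert ll(rng.dirichlet(np.ones(small_counts.n_cols))) <= best + 1e-9


def test_loglik_invariant_to_motif_relabeling(small_counts, rng):
    fit = em.fit_multinomial_gom(small_counts, K=3, seed=0)
    base = em.loglik(fit, small_counts)
    for perm in itertools.permutations(range(3)):
        permuted = em.apply_motif_permutation(fit, list(perm))
        assert em.loglik(permuted, small_counts) == pytest.approx(base, abs=1e-10)


def test_loglik_dimension_mismatch(small_counts):
    fit = em.fit_multinomial_gom(small_counts, K=2, seed=0)
    other = em.CountMatrix([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="match"):
        em.loglik(fit, other)


# ---------------------------------------------------------------------------
# EM monotonicity (the key convergence invariant)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("model_kind", ["multinomial", "bernoulli"])
@pytest.mark.parametrize("seed", range(10))
def test_em_objective_monotone(model_kind, seed):
    data, _ = em.simulate_gom(N=15, G=12, K=2, model_kind=model_kind,
                              depth=80, seed=seed)
    fit = em.fit_gom(data, 3, seed=seed, max_iter=60)
    trace = fit.loglik_trace
    drops = np.diff(trace) < -1e-8 * np.abs(trace[:-1])
    assert not drops.any()


# ---------------------------------------------------------------------------
# Bayes factors / model selection
# ---------------------------------------------------------------------------


def test_log_bf_zero_at_k1(small_counts):
    fit = em.fit_multinomial_gom(small_counts, K=1, seed=0)
    assert em.log_bayes_factor(fit, small_counts) == 0.0


def test_log_bf_prefers_true_structure():
    """K=3 fits of K=3 data beat the K=1 baseline in >= 9/10 seeds."""
    wins = 0
    for seed in range(10):
        counts, _ = em.simulate_gom(N=60, G=40, K=3, depth=1000, seed=seed)
        fit = em.multistart_fit(counts, 3, n_starts=3, seed=seed)
        wins += fit.log_bf > 0
    assert wins >= 9


def test_log_bf_paired_structured_vs_unstructured():
    """K=3 fits score far higher on K=3-structured data than on K=1 data
    of identical size (paired seeds)."""
    for seed in range(3):
        flat, _ = em.simulate_gom(N=60, G=40, K=1, depth=1000, seed=200 + seed)
        structured, _ = em.simulate_gom(N=60, G=40, K=3, depth=1000, seed=200 + seed)
        bf_flat = em.multistart_fit(flat, 3, n_starts=3, seed=seed).log_bf
        bf_struct = em.multistart_fit(structured, 3, n_starts=3, seed=seed).log_bf
        assert bf_flat < bf_struct


# ---------------------------------------------------------------------------
# multistart
# ---------------------------------------------------------------------------


def test_multistart_single_start_reduces_to_plain_fit(small_counts):
    best = em.multistart_fit(small_counts, 2, n_starts=1, seed=5)
    single = em.fit_multinomial_gom(small_counts, 2, seed=5)
    assert np.array_equal(best.omega, single.omega)
    assert best.log_bf == single.log_bf


def test_multistart_deterministic(small_counts):
    a = em.multistart_fit(small_counts, 2, n_starts=4, seed=9)
    b = em.multistart_fit(small_counts, 2, n_starts=4, seed=9)
    assert np.array_equal(a.omega, b.omega)  # bit-identical


def test_multistart_more_starts_never_worse(small_counts):
    one = em.multistart_fit(small_counts, 3, n_starts=1, seed=2)
    ten = em.multistart_fit(small_counts, 3, n_starts=10, seed=2)
    assert ten.log_bf >= one.log_bf


# ---------------------------------------------------------------------------
# constrained partition competitor
# ---------------------------------------------------------------------------


def test_constrained_fit_matches_true_blocks(block_counts):
    labels = em.PartitionLabels([1, 2])
    fit = em.constrained_partition_fit(block_counts, labels)
    assert np.allclose(fit.omega, np.eye(2))
    assert np.allclose(fit.theta, np.eye(2), atol=1e-9)


def test_constrained_fit_dominated_by_unconstrained():
    counts, _ = em.simulate_gom(N=30, G=20, K=2, separation=1.0,
                                alpha_omega=0.05, depth=300, seed=6)
    free = em.multistart_fit(counts, 2, n_starts=5, seed=6)
    wrong = em.PartitionLabels(np.tile([1, 2], 15))  # alternating split
    constrained = em.constrained_partition_fit(counts, wrong)
    assert em.loglik(constrained, counts) <= em.loglik(free, counts) + 1e-9


def test_constrained_fit_requires_full_cover(block_counts):
    with pytest.raises(ValueError, match="no assigned rows"):
        em.constrained_partition_fit(
            block_counts, em.PartitionLabels([2, 2])
        )


# ---------------------------------------------------------------------------
# motif alignment
# ---------------------------------------------------------------------------


def test_align_identity_and_swap(rng):
    fit = random_valid_fit(5, 8, 3, "multinomial", rng)
    assert list(em.align_motifs(fit, fit)) == [0, 1, 2]
    swapped = em.apply_motif_permutation(fit, [2, 0, 1])
    perm = em.align_motifs(fit, swapped)
    # motif k of `fit` sits at position perm[k] of `swapped`
    assert np.allclose(swapped.theta[perm], fit.theta)


def test_align_matches_exhaustive_search(rng):
    def corr(u, v):
        return np.corrcoef(u, v)[0, 1]
    for _ in range(10):
        a = random_valid_fit(4, 9, 3, "multinomial", rng)
        b = random_valid_fit(4, 9, 3, "multinomial", rng)
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(3)):
            score = sum(corr(a.theta[k], b.theta[perm[k]]) for k in range(3))
            if score > best_score:
                best_perm, best_score = perm, score
        got = em.align_motifs(a, b)
        got_score = sum(corr(a.theta[k], b.theta[got[k]]) for k in range(3))
        assert got_score == pytest.approx(best_score, abs=1e-12)


def test_align_rejects_mismatched_features(rng):
    a = random_valid_fit(4, 9, 3, "multinomial", rng)
    b = random_valid_fit(4, 7, 3, "multinomial", rng)
    with pytest.raises(ValueError, match="feature"):
        em.align_motifs(a, b)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_fit_save_load_round_trip(tmp_path, small_counts):
    fit = em.fit_multinomial_gom(small_counts, K=2, seed=3)
    em.save_fit(fit, tmp_path / "fit")
    back = em.load_fit(tmp_path / "fit")
    assert back.K == fit.K and back.model_kind == fit.model_kind
    assert np.allclose(back.omega, fit.omega, atol=1e-12)
    assert np.allclose(back.theta, fit.theta, atol=1e-12)
    assert back.log_bf == pytest.approx(fit.log_bf)
    assert back.row_ids == fit.row_ids and back.col_ids == fit.col_ids
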