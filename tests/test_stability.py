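import numpy as np
import pytest
from scipy.stats import multivariate_normal

from envnet.errors import ParameterError, ValidationError
from envnet.network_io import InteractionNetwork
from envnet.stability import (
    CompetitionSpec,
    omega,
    omega_2d_closed_form,
    overlap_competition_matrix,
    stability_bundle,
)
from tests.conftest import random_incidence

SQRT_HALF = 1 / np.sqrt(2)


def random_overlap_matrix(rng, S, rho=0.6):
    """Competition matrix from a random bipartite incidence."""
    while True:
        B = (rng.random((S, S + 3)) < 0.5).astype(int)
        if (B.sum(axis=1) > 0).all() and (B.sum(axis=0) > 0).all():
            return overlap_competition_matrix(B, CompetitionSpec(rho=rho))


class TestOverlapCompetitionMatrix:
    def test_shared_partner_normalization(self):
        # B = [[1,1],[1,0]]: O = [[2,1],[1,1]], unit-diagonal gives 1/sqrt(2)
        B = np.array([[1, 1], [1, 0]])
        A = overlap_competition_matrix(B, CompetitionSpec(rho=1.0))
        assert A == pytest.approx(np.array([[1, SQRT_HALF], [SQRT_HALF, 1]]))

    def test_rho_zero_gives_identity(self):
        B = np.array([[1, 1], [1, 0]])
        A = overlap_competition_matrix(B, CompetitionSpec(rho=0.0))
        assert A == pytest.approx(np.eye(2))

    def test_blending_is_linear_in_rho(self):
        B = np.array([[1, 1], [1, 0]])
        A = overlap_competition_matrix(B, CompetitionSpec(rho=0.5))
        assert A[0, 1] == pytest.approx(0.5 * SQRT_HALF)  # 0.35355...

    def test_unpruned_guild_rejected(self):
        B = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValidationError):
            overlap_competition_matrix(B, CompetitionSpec(guild="rows", rho=0.5))

    def test_rank_deficient_pure_overlap_refused(self):
        # 3 rows sharing a single partner column: Ahat is all-ones, rank 1
        B = np.array([[1], [1], [1]])
        with pytest.raises(ParameterError):
            overlap_competition_matrix(B, CompetitionSpec(rho=1.0))

    def test_positive_definite_for_rho_below_one(self, rng):
        for _ in range(10):
            A = random_overlap_matrix(rng, 6, rho=0.9)
            assert np.linalg.eigvalsh(A).min() > 0


class TestOmega:
    def test_identity_orthant_exact(self):
        for S in range(2, 11):
            est = omega(np.eye(S), n_draws=2000, seed=0)
            assert est.value == pytest.approx(2.0 ** -S, abs=1e-6)

    def test_two_dimensional_closed_form(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        exact = np.arccos(0.8) / (2 * np.pi)  # 0.102416...
        assert omega_2d_closed_form(A) == pytest.approx(exact)
        assert omega(A, n_draws=20_000, seed=1).value == pytest.approx(exact, abs=1e-4)

    def test_closed_form_on_random_pd_matrices(self, rng):
        for k in range(100):
            A = random_overlap_matrix(rng, 2, rho=float(rng.uniform(0.1, 0.9)))
            est = omega(A, n_draws=8192, seed=k)
            assert est.value == pytest.approx(omega_2d_closed_form(A), abs=1e-4)

    def test_orthant_matches_montecarlo_oracle(self, rng):
        for S in range(2, 7):
            A = random_overlap_matrix(rng, S)
            qmc_est = omega(A, n_draws=20_000, seed=3)
            mc_est = omega(A, method="montecarlo", n_draws=200_000, seed=4)
            tol = 3 * np.hypot(qmc_est.stderr, mc_est.stderr) + 1e-6
            assert abs(qmc_est.value - mc_est.value) <= tol

    def test_orthant_matches_scipy_gaussian_cdf(self, rng):
        # independent cross-check: positive-orthant mass of N(0, (A A)^-1)
        A = random_overlap_matrix(rng, 4)
        Sigma = np.linalg.inv(A @ A)
        ref = multivariate_normal(mean=np.zeros(4), cov=Sigma, seed=0).cdf(np.zeros(4))
        assert omega(A, n_draws=20_000, seed=5).value == pytest.approx(ref, abs=2e-3)

    def test_invariant_to_positive_column_scaling(self, rng):
        A = random_overlap_matrix(rng, 5)
        D = np.diag(rng.uniform(0.2, 3.0, size=5))
        a = omega(A, n_draws=4096, seed=6).value
        b = omega(A @ D, n_draws=4096, seed=6).value
        assert a == pytest.approx(b, rel=1e-10)

    def test_invariant_to_simultaneous_permutation(self, rng):
        A = random_overlap_matrix(rng, 5)
        p = rng.permutation(5)
        a = omega(A, n_draws=20_000, seed=7).value
        b = omega(A[np.ix_(p, p)], n_draws=20_000, seed=7).value
        assert a == pytest.approx(b, abs=3e-3)

    def test_non_increasing_in_competition_strength(self, rng):
        for _ in range(10):
            B = random_incidence(rng, m_range=(4, 7), n_range=(4, 7), p=0.5)
            B = B[B.sum(axis=1) > 0][:, B.sum(axis=0) > 0]
            if B.shape[0] < 2:
                continue
            values = [
                omega(overlap_competition_matrix(B, CompetitionSpec(rho=r)),
                      n_draws=8192, seed=8).value
                for r in (0.0, 0.3, 0.6, 0.9)
            ]
            assert all(a >= b - 1e-3 for a, b in zip(values, values[1:]))

    def test_montecarlo_deterministic_under_seed(self):
        A = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert omega(A, method="montecarlo", n_draws=5000, seed=9) == omega(
            A, method="montecarlo", n_draws=5000, seed=9)

    def test_one_by_one_half_line_convention(self):
        with pytest.warns(UserWarning, match="half-line"):
            assert omega(np.eye(1), n_draws=1000, seed=0).value == 0.5

    def test_non_pd_rejected(self):
        with pytest.raises(ValidationError):
            omega(np.array([[1.0, 2.0], [2.0, 1.0]]), n_draws=1000, seed=0)


class TestStabilityBundle:
    def test_disjoint_pairs_identity_competition(self):
        net = InteractionNetwork(id="d", incidence=np.eye(2, dtype=int))
        sb = stability_bundle(net, CompetitionSpec(guild="rows", rho=0.7),
                              n_draws=2000, seed=0)
        assert sb.omega_raw == pytest.approx(0.25, abs=1e-9)
        assert sb.omega_norm == pytest.approx(0.5, abs=1e-9)

    def test_deterministic_under_seed(self, tiny_net):
        a = stability_bundle(tiny_net, n_draws=2000, seed=5)
        b = stability_bundle(tiny_net, n_draws=2000, seed=5)
        assert a == b

    def test_both_guilds_reported_with_geometric_mean(self, tiny_net):
        sb = stability_bundle(tiny_net, CompetitionSpec(guild="both", rho=0.5),
                              n_draws=2000, seed=1)
        assert set(sb.per_guild) == {"rows", "cols"}
        expected = np.sqrt(sb.per_guild["rows"]["omega_raw"]
                           * sb.per_guild["cols"]["omega_raw"])
        assert sb.omega_raw == pytest.approx(expected)

    def test_isolated_species_pruned_before_overlap(self):
        net = InteractionNetwork(id="iso", incidence=np.array([[1, 1, 0], [0, 0, 0],
                                                               [1, 0, 0]]))
        sb = stability_bundle(net, n_draws=2000, seed=2)
        assert sb.S_guild == 2  # one zero row dropped
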