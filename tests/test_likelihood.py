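import numpy as np
import pytest

from gmcoda import (
    BlockStructure,
    CompositionDataset,
    SampleMoments,
    build_P,
    build_R,
    compute_moments,
    majorizer,
    neg_log_likelihood,
    penalized_objective,
    surrogate_covariance,
)

from helpers import gcoda_neg_loglik, random_pd


def direct_likelihood(omega, S, structure):
    """Term-by-term evaluation through raw inverses/slogdet (independent path)."""
    R = build_R(structure)
    M = R.T @ omega @ R
    Q = omega - omega @ R @ np.linalg.inv(M) @ R.T @ omega
    return (
        -np.linalg.slogdet(omega)[1]
        + np.linalg.slogdet(M)[1]
        + np.trace(S @ Q)
    )


class TestComputeMoments:
    def test_identical_samples_zero_covariance(self, two_blocks):
        row = np.array([0.2, 0.8, 0.3, 0.7])
        data = CompositionDataset(np.vstack([row, row]), two_blocks)
        mom = compute_moments(data)
        assert np.allclose(mom.S, 0.0, atol=1e-12)

    def test_hand_covariance_single_pair_block(self):
        x = np.array([[0.2, 0.8], [0.5, 0.5]])
        data = CompositionDataset(x, BlockStructure((2,)))
        mom = compute_moments(data)
        logs = np.log(x)
        expected = (logs - logs.mean(0)).T @ (logs - logs.mean(0)) / 2
        assert np.allclose(mom.S, expected, atol=1e-12)
        assert mom.n == 2

    def test_centered_logs_have_zero_block_means(self, small_sim):
        mom = compute_moments(small_sim.data)
        for sl in small_sim.data.structure.slices:
            assert np.allclose(mom.centered_logs[:, sl].sum(1), 0.0, atol=1e-10)

    def test_invariant_to_per_sample_scaling(self, two_blocks, rng):
        """Multiplying underlying counts by per-sample constants changes nothing."""
        counts = rng.uniform(1, 100, size=(5, 4))
        scaled = counts * rng.uniform(0.5, 50, size=(5, 1))

        def closure(c):
            out = c.copy()
            for sl in two_blocks.slices:
                out[:, sl] /= out[:, sl].sum(1, keepdims=True)
            return out

        m1 = compute_moments(CompositionDataset(closure(counts), two_blocks))
        m2 = compute_moments(CompositionDataset(closure(scaled), two_blocks))
        assert np.allclose(m1.S, m2.S, atol=1e-12)


class TestNegLogLikelihood:
    def test_closed_form_identity_single_block(self):
        """S = I, Omega = I: L = ln p + (p - 1) for one block of size p."""
        bs = BlockStructure((2,))
        mom = SampleMoments(np.eye(2), 10, np.zeros((10, 2)))
        L = neg_log_likelihood(np.eye(2), mom, bs)
        assert L == pytest.approx(np.log(2) + 1, abs=1e-10)

    def test_closed_form_identity_two_blocks(self):
        bs = BlockStructure((2, 2))
        mom = SampleMoments(np.eye(4), 10, np.zeros((10, 4)))
        L = neg_log_likelihood(np.eye(4), mom, bs)
        assert L == pytest.approx(2 * np.log(2) + 2, abs=1e-10)

    def test_matches_direct_term_by_term_oracle(self, rng):
        bs = BlockStructure((3, 3))
        mom = SampleMoments(random_pd(6, rng), 20, np.zeros((20, 6)))
        omega = random_pd(6, rng)
        ours = neg_log_likelihood(omega, mom, bs)
        assert ours == pytest.approx(direct_likelihood(omega, mom.S, bs), abs=1e-8)

    def test_single_block_reduces_to_gcoda(self, rng):
        """d=1 likelihood equals the ones-vector gcoda formula."""
        bs = BlockStructure((6,))
        S = random_pd(6, rng)
        mom = SampleMoments(S, 15, np.zeros((15, 6)))
        omega = random_pd(6, rng)
        assert neg_log_likelihood(omega, mom, bs) == pytest.approx(
            gcoda_neg_loglik(omega, S), abs=1e-10
        )

    def test_non_pd_omega_raises(self, rng):
        bs = BlockStructure((3,))
        mom = SampleMoments(np.eye(3), 5, np.zeros((5, 3)))
        bad = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="positive definite"):
            neg_log_likelihood(bad, mom, bs)


class TestSurrogateCovariance:
    def test_identity_inputs_give_identity(self):
        """Omega = I, S = I, d=1: S_Omega = P + 11'/p = I."""
        bs = BlockStructure((4,))
        mom = SampleMoments(np.eye(4), 10, np.zeros((10, 4)))
        S_om = surrogate_covariance(np.eye(4), mom, bs)
        P = build_P(bs)
        assert np.allclose(S_om, P + np.ones((4, 4)) / 4, atol=1e-10)
        assert np.allclose(S_om, np.eye(4), atol=1e-10)

    def test_symmetric_psd(self, rng):
        bs = BlockStructure((3, 4))
        mom = SampleMoments(random_pd(7, rng), 10, np.zeros((10, 7)))
        S_om = surrogate_covariance(random_pd(7, rng), mom, bs)
        assert np.allclose(S_om, S_om.T, atol=1e-10)
        assert np.linalg.eigvalsh(S_om).min() > -1e-8

    def test_rewritten_likelihood_identity(self, rng):
        """L(Om) = -ln|Om/R'OmR| + Tr([S_Om - R(R'OmR)^-1 R']Om) at Om itself."""
        bs = BlockStructure((3, 3))
        S = random_pd(6, rng)
        mom = SampleMoments(S, 12, np.zeros((12, 6)))
        omega = random_pd(6, rng)
        R = build_R(bs)
        M = R.T @ omega @ R
        S_om = surrogate_covariance(omega, mom, bs)
        rewritten = (
            -np.linalg.slogdet(omega)[1]
            + np.linalg.slogdet(M)[1]
            + np.sum((S_om - R @ np.linalg.inv(M) @ R.T) * omega)
        )
        assert rewritten == pytest.approx(
            neg_log_likelihood(omega, mom, bs), abs=1e-8
        )


class TestMajorizer:
    def test_anchor_equality(self, rng):
        """g(Om_k | Om_k) = f(Om_k)."""
        bs = BlockStructure((2, 3))
        mom = SampleMoments(random_pd(5, rng), 10, np.zeros((10, 5)))
        omega_k = random_pd(5, rng)
        lam = 0.1
        g = majorizer(omega_k, omega_k, mom, bs, lam)
        f = penalized_objective(omega_k, mom, bs, lam)
        assert g == pytest.approx(f, abs=1e-8)

    def test_majorization_inequality_random_draws(self, rng):
        """g(Om | Om_k) >= f(Om) over 100 random PD pairs."""
        bs = BlockStructure((2, 3))
        lam = 0.1
        for _ in range(100):
            mom = SampleMoments(random_pd(5, rng), 10, np.zeros((10, 5)))
            omega = random_pd(5, rng)
            omega_k = random_pd(5, rng)
            g = majorizer(omega, omega_k, mom, bs, lam)
            f = penalized_objective(omega, mom, bs, lam)
            assert g >= f - 1e-8

    def test_reduces_to_likelihood_at_identity(self):
        """lam=0, Om=Om_k=I, S=I, d=1, p=2: g = L(I) = ln 2 + 1."""
        bs = BlockStructure((2,))
        mom = SampleMoments(np.eye(2), 10, np.zeros((10, 2)))
        g = majorizer(np.eye(2), np.eye(2), mom, bs, lam=0.0)
        assert g == pytest.approx(np.log(2) + 1, abs=1e-10)

    def test_negative_lambda_rejected(self, rng):
        bs = BlockStructure((2,))
        mom = SampleMoments(np.eye(2), 5, np.zeros((5, 2)))
        with pytest.raises(ValueError):
            majorizer(np.eye(2), np.eye(2), mom, bs, lam=-0.1)
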