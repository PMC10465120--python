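"""Closed-form covariance/correlation calculus against independent oracles."""

import numpy as np
import pytest

from genomni import (
    LatentDistribution,
    build_forward_R,
    build_generator_R,
    averaged_estimator_covariance,
    block_covariance,
    classical_coefficients,
    closed_form_correlation,
    dampened_coefficients,
    difference_covariance,
    effective_sample_size,
    limiting_correlation,
    pair_preserving_coefficients,
    second_moment,
    sigma_x,
    total_average_coefficients,
    weight_profile,
    weighted_pairwise_coefficients,
)


def random_valid_R(m: int, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative PSD correlation structure via a random generator vector."""
    return build_generator_R(rng.random(m)).R


class TestSecondMomentAndKernel:
    def test_two_block_trace(self, two_block_mixture):
        Delta = second_moment(two_block_mixture).Delta
        assert np.trace(Delta) == pytest.approx(0.6, abs=1e-12)
        assert np.allclose(Delta, Delta.T)

    def test_single_atom_rank_one(self):
        F = LatentDistribution(atoms=[[0.5]], weights=[1.0])
        assert second_moment(F).Delta == pytest.approx(0.25)

    def test_degenerate_gram_rejected(self):
        # two identical atoms in 2-d: Δ has rank 1 < d
        F = LatentDistribution(
            atoms=[[np.sqrt(0.5), 0.0], [np.sqrt(0.5), 0.0]], weights=[0.5, 0.5]
        )
        with pytest.raises(ValueError):
            second_moment(F)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.7])
    def test_scalar_kernel_closed_form(self, p):
        """d=1 point mass at √p evaluated at x=√p gives Σ = 1 − p."""
        F = LatentDistribution(atoms=[[np.sqrt(p)]], weights=[1.0])
        assert sigma_x(F, [np.sqrt(p)])[0, 0] == pytest.approx(1 - p, abs=1e-12)

    def test_kernel_matches_bruteforce_sum(self, two_block_mixture):
        F = two_block_mixture
        x = F.atoms[0]
        # independent brute-force evaluation of the sandwiched expectation
        Delta = sum(w * np.outer(a, a) for w, a in zip(F.weights, F.atoms))
        E = np.zeros((2, 2))
        for w, a in zip(F.weights, F.atoms):
            t = float(x @ a)
            E += w * (t - t**2) * np.outer(a, a)
        expected = np.linalg.inv(Delta) @ E @ np.linalg.inv(Delta)
        assert np.allclose(sigma_x(F, x), expected, atol=1e-12)

    def test_kernel_vanishes_at_deterministic_edges(self):
        F = LatentDistribution(atoms=[[1.0], [0.0]], weights=[0.5, 0.5])
        # x·ξ ∈ {0, 1} for every atom ⇒ zero Bernoulli variance everywhere
        with pytest.raises(ValueError):
            second_moment(LatentDistribution(atoms=[[0.0]], weights=[1.0]))
        assert np.allclose(sigma_x(F, [1.0]), 0.0, atol=1e-12)

    def test_kernel_psd_on_support(self, two_block_mixture, rng):
        for atom in two_block_mixture.atoms:
            evals = np.linalg.eigvalsh(sigma_x(two_block_mixture, atom))
            assert evals.min() >= -1e-10


class TestBlockCovariance:
    @pytest.mark.parametrize("m", range(2, 9))
    def test_classical_method_coefficient(self, m, two_block_mixture):
        parts = block_covariance(
            weight_profile(classical_coefficients(m)), np.eye(m), 0,
            two_block_mixture, two_block_mixture.atoms[0],
        )
        assert parts.method_coefficient == pytest.approx((m + 3) / (4 * m), abs=1e-12)
        assert parts.model_coefficient == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m", range(2, 9))
    def test_total_average_method_coefficient(self, m, two_block_mixture):
        parts = block_covariance(
            weight_profile(total_average_coefficients(m)), np.eye(m), 0,
            two_block_mixture, two_block_mixture.atoms[0],
        )
        assert parts.method_coefficient == pytest.approx(
            (m**2 + m - 1) / m**3, abs=1e-12
        )

    def test_perfect_correlation_collapses_to_one(self, two_block_mixture, rng):
        m = 5
        alpha = weight_profile(weighted_pairwise_coefficients(rng.random(m) + 0.5))
        parts = block_covariance(
            alpha, np.ones((m, m)), 2, two_block_mixture, two_block_mixture.atoms[0]
        )
        total = parts.method_coefficient + parts.model_coefficient
        assert total == pytest.approx(1.0, abs=1e-10)


class TestDifferenceCovarianceAndCorrelation:
    def test_same_block_gives_zero(self, two_block_mixture):
        S = difference_covariance(
            weight_profile(classical_coefficients(3)), np.eye(3), 1, 1,
            two_block_mixture, two_block_mixture.atoms[0],
        )
        assert np.allclose(S, 0.0, atol=1e-12)

    @pytest.mark.parametrize("m", [2, 4, 7])
    def test_classical_independent_gives_half_kernel(self, m, two_block_mixture):
        x = two_block_mixture.atoms[0]
        S = difference_covariance(
            weight_profile(classical_coefficients(m)), np.eye(m), 0, 1,
            two_block_mixture, x,
        )
        assert np.allclose(S, 0.5 * sigma_x(two_block_mixture, x), atol=1e-12)

    def test_difference_equals_dampening_of_limiting_correlation(
        self, two_block_mixture
    ):
        """Σ̃ = 2(1 − ρ(s1,s2))·Σ(x) across 100 random designs/correlations."""
        rng = np.random.default_rng(42)
        x = two_block_mixture.atoms[0]
        Sx = sigma_x(two_block_mixture, x)
        for _ in range(100):
            m = int(rng.integers(2, 9))
            alpha = weight_profile(weighted_pairwise_coefficients(rng.random(m) + 0.2))
            R = random_valid_R(m, rng)
            s1, s2 = rng.choice(m, size=2, replace=False)
            S = difference_covariance(alpha, R, s1, s2, two_block_mixture, x)
            rho = limiting_correlation(alpha, R, s1, s2).total
            assert np.allclose(S, 2 * (1 - rho) * Sx, atol=1e-10)

    def test_row_sum_violation_trips_guard(self, two_block_mixture):
        alpha = weight_profile(classical_coefficients(3)).alpha.copy()
        alpha[0, 1] += 0.3  # rows no longer sum to m
        with pytest.raises(AssertionError):
            difference_covariance(
                alpha, np.eye(3), 0, 1, two_block_mixture, two_block_mixture.atoms[0]
            )

    def test_identical_rows_give_correlation_one(self):
        alpha = np.full((3, 3), 1.0)
        assert limiting_correlation(alpha, np.eye(3), 0, 1).total == pytest.approx(1.0)

    def test_monotone_in_inherent_correlation(self):
        alpha = weight_profile(classical_coefficients(4))
        vals = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            R = np.eye(4)
            R[0, 1] = R[1, 0] = rho
            vals.append(limiting_correlation(alpha, R, 0, 1).total)
        assert np.all(np.diff(vals) > 0)


class TestClosedForms:
    def test_table_pair_value(self):
        R = build_generator_R([0.8] * 50 + [0.3] * 50)
        alpha = weight_profile(classical_coefficients(100))
        assert limiting_correlation(alpha, R, 0, 1).total == pytest.approx(
            0.91, abs=1e-12
        )

    def test_total_average_small_case(self):
        assert closed_form_correlation("totalavg", m=3, rho_in=0.0) == pytest.approx(
            8 / 9
        )

    def test_weighted_equal_pair_reduces_to_classical_at_unit_weight(self):
        for m in (2, 5, 10):
            for rho in (0.0, 0.4):
                assert closed_form_correlation(
                    "weighted_equal_pair", m=m, w=1.0, rho_in=rho
                ) == pytest.approx(0.75 + rho / 4, abs=1e-12)

    def test_pair_preserving_printed_value(self):
        val = closed_form_correlation("pair12", m=100, rho_in=0.64)
        assert val == pytest.approx(1 - 0.36 * 99**2 / 100**2, abs=1e-15)
        assert abs(val - 0.64) < 0.01  # ≈ inherent for large m

    def test_closed_forms_match_general_formula(self):
        """Each printed closed form equals the general correlation formula
        applied to the corresponding coefficient builder — the central
        anti-regression oracle."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = int(rng.integers(2, 13))
            rho_in = float(rng.random())
            R = np.eye(m)
            R[0, 1] = R[1, 0] = rho_in

            a = weight_profile(classical_coefficients(m))
            assert limiting_correlation(a, R, 0, 1).total == pytest.approx(
                closed_form_correlation("classical", rho_in=rho_in), abs=1e-10
            )

            a = weight_profile(total_average_coefficients(m))
            assert limiting_correlation(a, R, 0, 1).total == pytest.approx(
                closed_form_correlation("totalavg", m=m, rho_in=rho_in), abs=1e-10
            )

            w = float(rng.random() * 4 + 0.2)
            wvec = np.ones(m)
            wvec[0] = wvec[1] = w
            a = weight_profile(weighted_pairwise_coefficients(wvec))
            assert limiting_correlation(a, R, 0, 1).total == pytest.approx(
                closed_form_correlation("weighted_equal_pair", m=m, w=w, rho_in=rho_in),
                abs=1e-10,
            )

            if m % 2 == 0:
                a = weight_profile(pair_preserving_coefficients(m))
                assert limiting_correlation(a, R, 0, 1).total == pytest.approx(
                    closed_form_correlation("pair12", m=m, rho_in=rho_in), abs=1e-10
                )


def dampened_method_correlation(s1: int, s2: int, m: int) -> float:
    """Independent transcription of the printed method-correlation sums for
    the dampened design with weights w_ℓ = ℓ (1-based s1 < s2)."""
    b1 = (s1**2 + 1) / (s1 + 1) + sum(
        1 / (l + 1) for l in range(s1 + 1, m + 1) if l != s2
    )
    b2 = (s2**2 - s2 + 1) / (s2 + 1) + sum(1 / (l + 1) for l in range(s2 + 1, m + 1))
    total = (
        (s1 - 1) * (s2 - s1) ** 2 / ((s1 + 1) ** 2 * (s2 + 1) ** 2)
        + b1**2
        + sum((l / (l + 1) - 1 / (s2 + 1)) ** 2 for l in range(s1 + 1, s2))
        + b2**2
    )
    return 1 - total / (2 * m**2)


def dampened_model_correlation(s1: int, s2: int, m: int, R: np.ndarray) -> float:
    """Independent transcription of the printed inherent-correlation sums
    for the dampened design with w_ℓ = ℓ (R is 1-based via R[q-1, l-1])."""
    def rho(q, l):
        return R[q - 1, l - 1]

    b1 = (s1**2 + 1) / (s1 + 1) + sum(
        1 / (h + 1) for h in range(s1 + 1, m + 1) if h != s2
    )
    b2 = (s2**2 - s2 + 1) / (s2 + 1) + sum(1 / (h + 1) for h in range(s2 + 1, m + 1))
    g = (s2 - s1) / ((s1 + 1) * (s2 + 1))
    acc = 0.0
    for l in range(1, s1):
        for q in range(1, l):
            acc += -(g**2) * rho(q, l)
    for q in range(1, s1):
        acc += -g * b1 * rho(q, s1)
    for l in range(s1 + 1, s2):
        fl = 1 / (s2 + 1) - l / (l + 1)
        for q in range(1, s1):
            acc += g * fl * rho(q, l)
        acc += b1 * fl * rho(s1, l)
        for q in range(s1 + 1, l):
            acc += (q / (q + 1) - 1 / (s2 + 1)) * fl * rho(q, l)
    for q in range(1, s1):
        acc += g * b2 * rho(q, s2)
    acc += b1 * b2 * rho(s1, s2)
    for q in range(s1 + 1, s2):
        acc += (q / (q + 1) - 1 / (s2 + 1)) * b2 * rho(q, s2)
    return acc / m**2


class TestDampenedTranscriptionOracle:
    @pytest.mark.parametrize("s1, s2", [(1, 2), (2, 7), (5, 20), (10, 25)])
    def test_printed_sums_match_general_formula(self, s1, s2):
        m = 30
        coeffs = dampened_coefficients(np.arange(1, m + 1, dtype=float))
        alpha = weight_profile(coeffs)
        R = build_forward_R([0.8] * (m - 1)).R
        parts = limiting_correlation(alpha, R, s1 - 1, s2 - 1)
        assert parts.method == pytest.approx(
            dampened_method_correlation(s1, s2, m), abs=1e-10
        )
        assert parts.model == pytest.approx(
            dampened_model_correlation(s1, s2, m, R), abs=1e-10
        )


class TestEffectiveSampleSize:
    @pytest.mark.parametrize("m, rho, expected", [
        (5, 0.0, 5.0), (5, 1.0, 1.0), (2, 0.5, 4 / 3),
    ])
    def test_values(self, m, rho, expected):
        assert effective_sample_size(m, rho) == pytest.approx(expected)

    def test_bounds_and_monotonicity(self):
        vals = [effective_sample_size(6, r) for r in np.linspace(0, 1, 11)]
        assert np.all(np.diff(vals) < 0)
        assert all(1 <= v <= 6 for v in vals)
        with pytest.raises(ValueError):
            effective_sample_size(0, 0.5)
        with pytest.raises(ValueError):
            effective_sample_size(3, 1.5)

    def test_averaged_covariance_composition(self, two_block_mixture):
        x = two_block_mixture.atoms[0]
        Sx = sigma_x(two_block_mixture, x)
        # independent graphs: the full 1/m averaging gain
        assert np.allclose(
            averaged_estimator_covariance(4, 0.0, two_block_mixture, x), Sx / 4
        )
        # perfectly correlated graphs: no better than a single graph
        assert np.allclose(
            averaged_estimator_covariance(4, 1.0, two_block_mixture, x), Sx
        )
        # scaling is exactly the reciprocal effective sample size
        for m, rho in [(3, 0.2), (6, 0.7)]:
            expect = Sx / effective_sample_size(m, rho)
            assert np.allclose(
                averaged_estimator_covariance(m, rho, two_block_mixture, x), expect
            )
        with pytest.raises(ValueError):
            averaged_estimator_covariance(1, 0.5, two_block_mixture, x)
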