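"""Feature-extraction tests, checked against independent brute-force oracles.

The oracles here deliberately avoid the vectorized paths in the package:
raw/central moments are computed with explicit double loops, and the Hahn
basis is re-derived from the terminating hypergeometric-sum definition of
the polynomials with exact Pochhammer arithmetic.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rccc_pred.errors import ContractError
from rccc_pred.features import (
    MOMENT_ORDERS,
    FeatureVector,
    SequenceMatrix,
    central_moments,
    encode_sequence,
    extract_features,
    hahn_basis,
    hahn_moments,
    layer1,
    layer2,
    raw_moments,
    sequence_to_matrix,
)

# ---------------------------------------------------------------- oracles


def oracle_raw(beta, a, b):
    n = len(beta)
    return sum(
        (x + 1) ** a * (y + 1) ** b * beta[x][y] for x in range(n) for y in range(n)
    )


def oracle_central(beta, a, b):
    n = len(beta)
    mass = oracle_raw(beta, 0, 0)
    if mass == 0:
        return 0.0
    xbar = oracle_raw(beta, 1, 0) / mass
    ybar = oracle_raw(beta, 0, 1) / mass
    return sum(
        ((x + 1) - xbar) ** a * ((y + 1) - ybar) ** b * beta[x][y]
        for x in range(n)
        for y in range(n)
    )


def _poch(z: Fraction, k: int) -> Fraction:
    out = Fraction(1)
    for i in range(k):
        out *= z + i
    return out


def oracle_hahn_polynomial(q: int, x: int, N: int) -> Fraction:
    """Terminating 3F2 sum for the Hahn polynomial Q_q(x) with alpha=beta=0."""
    Np = N - 1
    total = Fraction(0)
    for j in range(q + 1):
        num = _poch(Fraction(-q), j) * _poch(Fraction(q + 1), j) * _poch(Fraction(-x), j)
        den = _poch(Fraction(1), j) * _poch(Fraction(-Np), j) * math.factorial(j)
        total += Fraction(num, 1) / den
    return total


def oracle_hahn_norm_sq(q: int, N: int) -> Fraction:
    """d_q^2 for alpha=beta=0: (N+q)! (N-1-q)! / ((2q+1) ((N-1)!)^2)."""
    return Fraction(
        math.factorial(N + q) * math.factorial(N - 1 - q),
        (2 * q + 1) * math.factorial(N - 1) ** 2,
    )


def oracle_hahn_basis_value(q: int, x: int, N: int) -> float:
    # weight rho(x) = 1 for alpha = beta = 0
    return float(oracle_hahn_polynomial(q, x, N)) / math.sqrt(oracle_hahn_norm_sq(q, N))


def random_matrix(rng, n):
    return SequenceMatrix(n=n, beta=rng.integers(0, 5, size=(n, n)))


# ---------------------------------------------------------------- encoding


def test_encode_definition():
    assert encode_sequence("ACGT") == [1, 2, 3, 4]


def test_encode_ambiguity_code():
    assert encode_sequence("AANA") == [1, 1, 0, 1]


def test_encode_lowercase():
    assert encode_sequence("acgt") == [1, 2, 3, 4]


def test_encode_empty_rejected():
    with pytest.raises(ContractError):
        encode_sequence("")


# ---------------------------------------------------------------- embedding


def test_matrix_perfect_square():
    m = sequence_to_matrix("ACGT")
    assert m.n == 2
    assert m.beta.tolist() == [[1, 2], [3, 4]]


def test_matrix_padding_count():
    m = sequence_to_matrix("ACGTA")
    assert m.n == 3
    assert int(np.count_nonzero(m.beta == 0)) == 4


def test_matrix_uniform():
    m = sequence_to_matrix("A" * 9)
    assert m.beta.tolist() == [[1, 1, 1]] * 3


# ---------------------------------------------------------------- raw moments


def test_raw_mass():
    m = sequence_to_matrix("ACGT")
    assert raw_moments(m)[MOMENT_ORDERS.index((0, 0))] == 10.0


def test_raw_r11_oracle_value():
    m = sequence_to_matrix("ACGT")
    assert raw_moments(m)[MOMENT_ORDERS.index((1, 1))] == 27.0


def test_raw_zero_matrix():
    m = SequenceMatrix(n=3, beta=np.zeros((3, 3), dtype=np.int64))
    assert raw_moments(m) == tuple([0.0] * 10)


def test_raw_and_central_match_bruteforce_oracle():
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = int(rng.integers(1, 13))
        m = random_matrix(rng, n)
        raw = raw_moments(m)
        central, _ = central_moments(m)
        for i, (a, b) in enumerate(MOMENT_ORDERS):
            expect = oracle_raw(m.beta.tolist(), a, b)
            assert raw[i] == pytest.approx(expect, rel=1e-10, abs=1e-10)
            expect_c = oracle_central(m.beta.tolist(), a, b)
            assert central[i] == pytest.approx(expect_c, rel=1e-10, abs=1e-8)


# ---------------------------------------------------------------- central moments


def test_centroid_and_c20_hand_value():
    m = sequence_to_matrix("ACGT")
    central, (xbar, ybar) = central_moments(m)
    assert xbar == pytest.approx(1.7)
    assert ybar == pytest.approx(1.6)
    assert central[MOMENT_ORDERS.index((2, 0))] == pytest.approx(2.1)


def test_first_central_moments_vanish():
    rng = np.random.default_rng(99)
    for _ in range(50):
        m = random_matrix(rng, int(rng.integers(1, 10)))
        if m.beta.sum() == 0:
            continue
        central, _ = central_moments(m)
        assert central[MOMENT_ORDERS.index((1, 0))] == pytest.approx(0.0, abs=1e-9)
        assert central[MOMENT_ORDERS.index((0, 1))] == pytest.approx(0.0, abs=1e-9)


def test_zero_mass_convention():
    m = SequenceMatrix(n=2, beta=np.zeros((2, 2), dtype=np.int64))
    central, centroid = central_moments(m)
    assert centroid == (0.0, 0.0)
    assert central == tuple([0.0] * 10)


# ---------------------------------------------------------------- Hahn


@pytest.mark.parametrize("N", [2, 3, 5, 8, 10])
def test_hahn_basis_orthonormal(N):
    basis = hahn_basis(N)
    gram = basis.values @ basis.values.T
    q = min(3, N - 1)
    assert np.allclose(gram[: q + 1, : q + 1], np.eye(q + 1), atol=1e-8)


@pytest.mark.parametrize("N", range(2, 11))
def test_hahn_recurrence_matches_hypergeometric_oracle(N):
    basis = hahn_basis(N)
    for q in range(min(3, N - 1) + 1):
        for x in range(N):
            assert basis.values[q, x] == pytest.approx(
                oracle_hahn_basis_value(q, x, N), abs=1e-8
            )


def test_hahn_degree_zero_is_constant():
    for N in (1, 4, 9):
        basis = hahn_basis(N)
        assert np.allclose(basis.values[0], 1 / math.sqrt(N))


def test_hahn_h00_equals_scaled_mass():
    m = sequence_to_matrix("ACGTACGTA")
    h = hahn_moments(m)
    assert h[MOMENT_ORDERS.index((0, 0))] == pytest.approx(m.beta.sum() / m.n)


def test_hahn_zero_matrix():
    m = SequenceMatrix(n=4, beta=np.zeros((4, 4), dtype=np.int64))
    assert hahn_moments(m) == tuple([0.0] * 10)


def test_hahn_small_grid_orders_zeroed():
    # N=2 supports degrees 0..1 only; degrees 2,3 must read as 0
    m = sequence_to_matrix("ACGT")
    h = hahn_moments(m)
    assert h[MOMENT_ORDERS.index((0, 2))] == 0.0
    assert h[MOMENT_ORDERS.index((3, 0))] == 0.0


def test_hahn_invalid_grid():
    with pytest.raises(ContractError):
        hahn_basis(0)


# ---------------------------------------------------------------- layers


def test_layer1_has_30_finite_values():
    pooled = layer1(sequence_to_matrix("ACGTTGCAACGT")).pooled()
    assert len(pooled) == 30
    assert all(math.isfinite(v) for v in pooled)


def test_layer1_zero_matrix():
    m = SequenceMatrix(n=2, beta=np.zeros((2, 2), dtype=np.int64))
    assert layer1(m).pooled() == tuple([0.0] * 30)


def test_layer1_position_sensitivity():
    a = layer1(sequence_to_matrix("ACGT")).pooled()
    b = layer1(sequence_to_matrix("TGCA")).pooled()
    assert a != b


def test_layer2_hand_value():
    fv = layer2([0.0, 1.0])
    assert fv.as_tuple() == pytest.approx((0.5, 0.25, 0.0, 0.0625, 0.0, 1.0))


def test_layer2_constant_vector():
    fv = layer2([3.5] * 12)
    assert fv.as_tuple() == pytest.approx((3.5, 0.0, 0.0, 0.0, 3.5, 3.5))


def test_layer2_empty_rejected():
    with pytest.raises(ContractError):
        layer2([])


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_layer2_sign_properties(values):
    fv = layer2(values)
    assert fv.M2 >= 0
    assert fv.M4 >= 0
    assert fv.min_val <= fv.max_val


# ---------------------------------------------------------------- end to end


def test_extract_features_arity():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    assert len(extract_features(seq).as_tuple()) == 6


def test_extract_features_deterministic():
    seq = "ACGTTGCA" * 10
    assert extract_features(seq).as_tuple() == extract_features(seq).as_tuple()


def test_extract_features_mass_separates_homopolymers():
    a = extract_features("AAAA").as_tuple()
    t = extract_features("TTTT").as_tuple()
    assert a != t
    assert a[0] != t[0]  # M1 reflects total mass


def test_extract_features_translation_sensitivity():
    base = "ACGTTGCAACGTTGCA"
    assert extract_features(base).as_tuple() != extract_features("A" + base).as_tuple()


@settings(max_examples=25)
@given(st.text(alphabet="ACGT", min_size=1, max_size=120))
def test_extract_features_pure(seq):
    first = extract_features(seq).as_tuple()
    second = extract_features(seq).as_tuple()
    assert first == second
    assert all(math.isfinite(v) for v in first)
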