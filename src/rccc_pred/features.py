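"""Two-layer moment-based feature extraction for DNA sequences.

Layer 1 embeds the encoded sequence into the smallest square matrix that
holds it (row-major, zero padded) and computes three families of
position-sensitive moments up to combined order 3: raw moments ``R_ab``,
central moments ``C_ab`` about the mass centroid, and discrete orthogonal
Hahn moments ``H_ab`` built from weighted-normalized Hahn polynomials.

Layer 2 pools the 30 layer-1 values into one 6-value summary:
``[M1, M2, M3, M4, Min, Max]`` where ``M1`` is the mean and ``M2..M4`` are
the central moments of orders 2..4 of the pooled values.

Conventions (fixed, see package docs): nucleotides encode as A=1, C=2, G=3,
T=4, anything else 0; raw/central moments index the grid 1-based; Hahn
polynomials live on the 0-based grid ``x = 0..N-1`` with parameters
``alpha = beta = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, isqrt, lgamma, sqrt

import numpy as np

from .errors import ContractError

#: (a, b) exponent pairs with a + b <= 3, lexicographic — the layer-1 order.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(4) for b in range(4) if a + b <= 3
)

_ENCODING = {"A": 1, "C": 2, "G": 3, "T": 4}


@dataclass(frozen=True)
class SequenceMatrix:
    """Square row-major embedding of an encoded sequence (zero padded)."""

    n: int
    beta: np.ndarray  # shape (n, n), small non-negative ints

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ContractError(f"matrix side must be >= 1, got {self.n}")
        if self.beta.shape != (self.n, self.n):
            raise ContractError(f"beta has shape {self.beta.shape}, expected ({self.n}, {self.n})")


@dataclass(frozen=True)
class MomentSet:
    """The 30 layer-1 values plus the mass centroid."""

    raw: tuple[float, ...]
    central: tuple[float, ...]
    hahn: tuple[float, ...]
    centroid: tuple[float, float]

    def pooled(self) -> tuple[float, ...]:
        """All 30 values in the fixed family order raw, central, Hahn."""
        return self.raw + self.central + self.hahn


@dataclass(frozen=True)
class HahnBasis:
    """Weighted-normalized Hahn polynomial values on the grid 0..N-1.

    ``values[q, x]`` holds the orthonormal polynomial of degree ``q``; rows
    with ``q > N - 1`` (degrees that do not exist on the grid) are zero.
    """

    N: int
    alpha_param: float
    beta_param: float
    values: np.ndarray  # shape (4, N)


@dataclass(frozen=True)
class FeatureVector:
    """The 6-value per-sample summary [M1, M2, M3, M4, Min, Max]."""

    M1: float
    M2: float
    M3: float
    M4: float
    min_val: float
    max_val: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.M1, self.M2, self.M3, self.M4, self.min_val, self.max_val)


def encode_sequence(sequence: str) -> list[int]:
    """Numerically encode a DNA string: A=1, C=2, G=3, T=4, other=0."""
    if not sequence:
        raise ContractError("cannot encode an empty sequence")
    return [_ENCODING.get(c, 0) for c in sequence.upper()]


def sequence_to_matrix(sequence: str) -> SequenceMatrix:
    """Embed a sequence into the smallest square grid that holds it."""
    codes = encode_sequence(sequence)
    length = len(codes)
    n = isqrt(length)
    if n * n < length:
        n += 1
    beta = np.zeros(n * n, dtype=np.int64)
    beta[:length] = codes
    return SequenceMatrix(n=n, beta=beta.reshape(n, n))


def raw_moments(matrix: SequenceMatrix, max_order: int = 3) -> tuple[float, ...]:
    """Raw moments R_ab = sum_x sum_y x^a y^b beta_xy, 1-based x (row), y (col)."""
    n = matrix.n
    idx = np.arange(1, n + 1, dtype=np.float64)
    beta = matrix.beta.astype(np.float64)
    # x^a applies along rows, y^b along columns
    xpow = {a: idx**a for a in range(max_order + 1)}
    return tuple(
        float(xpow[a] @ beta @ xpow[b])
        for a, b in MOMENT_ORDERS
        if a + b <= max_order
    )


def central_moments(
    matrix: SequenceMatrix, max_order: int = 3
) -> tuple[tuple[float, ...], tuple[float, float]]:
    """Central moments about the mass centroid, plus the centroid itself.

    Zero-mass matrices get centroid (0, 0) and all-zero moments by
    convention.
    """
    n = matrix.n
    beta = matrix.beta.astype(np.float64)
    mass = beta.sum()
    if mass <= 0:
        zeros = tuple(0.0 for ab in MOMENT_ORDERS if sum(ab) <= max_order)
        return zeros, (0.0, 0.0)
    idx = np.arange(1, n + 1, dtype=np.float64)
    xbar = float(idx @ beta.sum(axis=1)) / mass
    ybar = float(idx @ beta.sum(axis=0)) / mass
    dx = {a: (idx - xbar) ** a for a in range(max_order + 1)}
    dy = {b: (idx - ybar) ** b for b in range(max_order + 1)}
    central = tuple(
        float(dx[a] @ beta @ dy[b]) for a, b in MOMENT_ORDERS if a + b <= max_order
    )
    return central, (xbar, ybar)


def _hahn_norm_sq(q: int, alpha: float, beta: float, Np: int) -> float:
    """Squared norm d_q^2 of the Hahn polynomial of degree q on 0..Np."""
    # d_q^2 = (q+a+b+1)_{Np+1} (b+1)_q q! (Np-q)! / ((2q+a+b+1)(a+1)_q (Np!)^2)
    def poch_ln(z: float, k: float) -> float:
        return lgamma(z + k) - lgamma(z)

    ln = (
        poch_ln(q + alpha + beta + 1, Np + 1)
        + poch_ln(beta + 1, q)
        + lgamma(q + 1)
        + lgamma(Np - q + 1)
        - np.log(2 * q + alpha + beta + 1)
        - poch_ln(alpha + 1, q)
        - 2 * lgamma(Np + 1)
    )
    return float(np.exp(ln))


def _hahn_weight(x: np.ndarray, alpha: float, beta: float, Np: int) -> np.ndarray:
    """Hahn orthogonality weight rho(x) on the grid 0..Np."""
    ln = np.array(
        [
            lgamma(alpha + xi + 1)
            - lgamma(alpha + 1)
            - lgamma(xi + 1)
            + lgamma(beta + Np - xi + 1)
            - lgamma(beta + 1)
            - lgamma(Np - xi + 1)
            for xi in x
        ]
    )
    return np.exp(ln)


def hahn_basis(N: int, alpha_param: float = 0.0, beta_param: float = 0.0) -> HahnBasis:
    """Build weighted-normalized Hahn polynomials of degree 0..3 on 0..N-1.

    Polynomials are generated by the standard three-term recurrence

        A_q Q_{q+1}(x) = (A_q + C_q - x) Q_q(x) - C_q Q_{q-1}(x)

    and normalized to hhat_q(x) = Q_q(x) * sqrt(rho(x) / d_q^2) so that
    sum_x hhat_p hhat_q = delta_pq for p, q <= min(3, N-1).
    """
    if N < 1:
        raise ContractError(f"grid size must be >= 1, got {N}")
    if alpha_param <= -1 or beta_param <= -1:
        raise ContractError("Hahn parameters must be > -1")
    a, b = float(alpha_param), float(beta_param)
    Np = N - 1  # polynomial support is x = 0..Np
    x = np.arange(N, dtype=np.float64)

    max_q = min(3, Np)
    Q = np.zeros((4, N), dtype=np.float64)
    Q[0] = 1.0
    prev, cur = None, Q[0]
    for q in range(max_q):
        A_q = ((q + a + b + 1) * (q + a + 1) * (Np - q)) / (
            (2 * q + a + b + 1) * (2 * q + a + b + 2)
        )
        if q == 0:
            C_q = 0.0
        else:
            C_q = (q * (q + a + b + Np + 1) * (q + b)) / ((2 * q + a + b) * (2 * q + a + b + 1))
        nxt = ((A_q + C_q - x) * cur - (C_q * prev if prev is not None else 0.0)) / A_q
        Q[q + 1] = nxt
        prev, cur = cur, nxt

    rho = _hahn_weight(x, a, b, Np)
    values = np.zeros((4, N), dtype=np.float64)
    for q in range(max_q + 1):
        values[q] = Q[q] * np.sqrt(rho / _hahn_norm_sq(q, a, b, Np))
    return HahnBasis(N=N, alpha_param=a, beta_param=b, values=values)


def hahn_moments(
    matrix: SequenceMatrix, basis: HahnBasis | None = None, max_order: int = 3
) -> tuple[float, ...]:
    """Hahn moments H_ab = sum_xy hhat_a(x) hhat_b(y) beta[x, y] (0-based grid)."""
    if basis is None:
        basis = hahn_basis(matrix.n)
    if basis.N != matrix.n:
        raise ContractError(f"basis grid size {basis.N} != matrix side {matrix.n}")
    beta = matrix.beta.astype(np.float64)
    H = basis.values @ beta @ basis.values.T  # H[a, b]
    return tuple(float(H[a, b]) for a, b in MOMENT_ORDERS if a + b <= max_order)


def layer1(matrix: SequenceMatrix) -> MomentSet:
    """Compute all 30 layer-1 values: raw, central, Hahn (10 each)."""
    raw = raw_moments(matrix)
    central, centroid = central_moments(matrix)
    hahn = hahn_moments(matrix)
    return MomentSet(raw=raw, central=central, hahn=hahn, centroid=centroid)


def layer2(values) -> FeatureVector:
    """Summarize pooled layer-1 values into [mean, m2, m3, m4, min, max]."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ContractError("layer2 requires a non-empty value list")
    mean = float(v.mean())
    centered = v - mean
    return FeatureVector(
        M1=mean,
        M2=float(np.mean(centered**2)),
        M3=float(np.mean(centered**3)),
        M4=float(np.mean(centered**4)),
        min_val=float(v.min()),
        max_val=float(v.max()),
    )


def extract_features(sequence: str) -> FeatureVector:
    """Full two-layer extraction: sequence -> 6-value feature vector."""
    return layer2(layer1(sequence_to_matrix(sequence)).pooled())
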