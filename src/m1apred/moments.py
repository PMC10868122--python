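"""Raw, central and Hahn moments of square numeric matrices.

Every matrix-valued feature group (sequence matrix, PRIM, RPRIM) is
summarized by the same fixed set of 30 coefficients: the ten moment orders
(j, k) with j + k <= 3 for each of the three families.

Definitions
-----------
For an m x m matrix with entries ``b[c, d]`` (1-based row c, column d):

* raw moments      ``N_jk = sum_c sum_d c**j * d**k * b[c, d]``
* central moments  ``n_ij = sum_c sum_d (c - xbar)**i * (d - ybar)**j * b[c, d]``
  about the mass centroid ``(xbar, ybar)``
* Hahn moments     ``H_ij = sum_p sum_q b[p, q] * h_i(p, N) * h_j(q, N)``
  over 0-based abscissas, where ``h_n`` is the discrete Hahn polynomial
  with shape parameters (u, v).

The Hahn polynomial is evaluated from its hypergeometric-sum form with
rising-factorial Pochhammer symbols:

    h_n(r, N) = (N + v - 1)_n (N - 1)_n *
                sum_{k=0..n} (-1)^k (-n)_k (-r)_k (2N + u + v - n - 1)_k
                             / [ (N + v - 1)_k (N - 1)_k k! ]

The polynomials are used as printed, without orthonormal weighting; the
2-D moment is the standard separable product with one polynomial factor
per axis.  Shape parameters default to u = v = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: The ten (j, k) orders with j + k <= 3, in frozen serialization order.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
)


class DegenerateMatrixError(ValueError):
    """Raised when a matrix has zero total mass and no centroid exists."""


@dataclass(frozen=True)
class MomentSet:
    """The 30 moment coefficients of one matrix plus auxiliary quantities."""

    raw: tuple[float, ...]
    central: tuple[float, ...]
    hahn: tuple[float, ...]
    centroid: tuple[float, float]
    hahn_params: tuple[float, float]

    def values(self) -> np.ndarray:
        """Concatenated coefficients in the frozen order raw+central+hahn."""
        return np.asarray(self.raw + self.central + self.hahn, dtype=float)


def _as_square(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 1:
        raise ValueError(f"expected a nonempty square matrix, got shape {M.shape}")
    return M


def centroid(M) -> tuple[float, float]:
    """Mass centroid (xbar, ybar) over 1-based row/column indices."""
    M = _as_square(M)
    total = M.sum()
    if total == 0:
        raise DegenerateMatrixError("matrix has zero total mass; centroid undefined")
    idx = np.arange(1, M.shape[0] + 1, dtype=float)
    xbar = float((idx @ M.sum(axis=1)) / total)
    ybar = float((M.sum(axis=0) @ idx) / total)
    return xbar, ybar


def raw_moments(M, orders=MOMENT_ORDERS) -> np.ndarray:
    """Raw moments N_jk with the row index raised to j, column to k."""
    M = _as_square(M)
    idx = np.arange(1, M.shape[0] + 1, dtype=float)
    return np.array([(idx**j) @ M @ (idx**k) for j, k in orders])


def central_moments(M, orders=MOMENT_ORDERS) -> np.ndarray:
    """Central moments n_ij about the centroid."""
    M = _as_square(M)
    xbar, ybar = centroid(M)
    idx = np.arange(1, M.shape[0] + 1, dtype=float)
    return np.array([((idx - xbar) ** i) @ M @ ((idx - ybar) ** j) for i, j in orders])


def _pochhammer(x: float, k: int) -> float:
    """Rising factorial (x)_k = x (x+1) ... (x+k-1); (x)_0 = 1."""
    out = 1.0
    for t in range(k):
        out *= x + t
    return out


def hahn_poly(n: int, r: float, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Value of the Hahn polynomial h_n^{u,v}(r, N).

    The hypergeometric sum defines the value for any order ``n >= 0`` (for
    ``n >= N`` the polynomial lies outside its orthogonality range but the
    formula stays valid); raises on a vanishing Pochhammer denominator.
    """
    if n < 0 or N < 1:
        raise ValueError(f"need n >= 0 and N >= 1, got n={n}, N={N}")
    prefactor = _pochhammer(N + v - 1, n) * _pochhammer(N - 1, n)
    total = 0.0
    for k in range(n + 1):
        denom = _pochhammer(N + v - 1, k) * _pochhammer(N - 1, k) * float(_factorial(k))
        if denom == 0:
            raise ZeroDivisionError(f"Pochhammer denominator vanished at k={k} (N={N}, u={u}, v={v})")
        num = (-1.0) ** k * _pochhammer(-n, k) * _pochhammer(-r, k) * _pochhammer(2 * N + u + v - n - 1, k)
        total += num / denom
    return prefactor * total


def _factorial(k: int) -> int:
    out = 1
    for t in range(2, k + 1):
        out *= t
    return out


@lru_cache(maxsize=64)
def _hahn_table(N: int, u: float, v: float, max_order: int = 3) -> np.ndarray:
    """Table P[n, r] of h_n^{u,v}(r, N) for n <= max_order, r in 0..N-1."""
    P = np.empty((max_order + 1, N))
    for n in range(max_order + 1):
        for r in range(N):
            P[n, r] = hahn_poly(n, r, N, u, v)
    return P


def hahn_moments(M, orders=MOMENT_ORDERS, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Hahn moments H_ij via the separable product form over 0-based abscissas."""
    M = _as_square(M)
    N = M.shape[0]
    max_order = max(max(j, k) for j, k in orders)
    P = _hahn_table(N, float(u), float(v), max_order)
    G = P @ M @ P.T  # G[i, j] = sum_pq h_i(p) M[p, q] h_j(q)
    return np.array([G[i, j] for i, j in orders])


def moment_set(M, u: float = 0.0, v: float = 0.0) -> MomentSet:
    """All 30 coefficients of one matrix, in the frozen raw/central/Hahn order."""
    M = _as_square(M)
    return MomentSet(
        raw=tuple(raw_moments(M)),
        central=tuple(central_moments(M)),
        hahn=tuple(hahn_moments(M, u=u, v=v)),
        centroid=centroid(M),
        hahn_params=(float(u), float(v)),
    )
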