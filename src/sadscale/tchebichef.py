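"""Scaled (orthonormal) discrete Tchebichef polynomials and moment inversion.

The discrete Tchebichef polynomials are orthogonal on the integer lattice
``{0, 1, ..., N-1}``; their scaled form used here is orthonormal with unit
weight, ``sum_x t_m(x) t_n(x) = delta_mn``, which keeps the recurrence
numerically stable for the supports that arise from octave histograms
(N up to a few tens of classes).  They are the standard tool in image
analysis for reconstructing a discrete density from its moments, and they
are used here to turn extrapolated raw moments of a species abundance
distribution back into a histogram.

Closed forms for the first two orders and the three-term recurrence::

    t_0(x) = 1 / sqrt(N)
    t_1(x) = (2x + 1 - N) * sqrt(3 / (N (N^2 - 1)))
    t_n(x) = (a1 x + a2) t_{n-1}(x) - a3 t_{n-2}(x)

    a1 = (2/n)        sqrt((4n^2 - 1) / (N^2 - n^2))
    a2 = ((1 - N)/n)  sqrt((4n^2 - 1) / (N^2 - n^2))
    a3 = ((n - 1)/n)  sqrt((2n + 1)/(2n - 3)) sqrt((N^2 - (n-1)^2)/(N^2 - n^2))

Because ``t_n`` is a degree-n polynomial, its moments against a density p
are a linear combination of the power moments of p: ``T_n = sum_k c_{n,k}
mu_k`` where ``t_n(x) = sum_k c_{n,k} x^k``.  For low orders this is
well-conditioned in double precision; recovering a density from *all* N
power moments is exponentially ill-conditioned, so the conversion accepts
an optional ``dps`` (decimal digits) argument that reruns the recurrence
and the contraction in extended precision (mpmath).  With ~60 digits the
full-order round trip histogram -> power moments -> Tchebichef moments ->
histogram is exact to well below 1e-9 for N <= 32.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath as mp
import numpy as np

from .sad import BinnedSAD

__all__ = [
    "TchebichefBasis",
    "build_basis",
    "tcheb_moments_from_distribution",
    "tcheb_moments_from_raw",
    "reconstruct",
    "select_order",
    "binned_power_moments",
]


@dataclass
class TchebichefBasis:
    """Orthonormal discrete Tchebichef basis on ``{0 .. N-1}``.

    Attributes
    ----------
    support_size
        N, the number of lattice points (octave classes).
    max_order
        Highest polynomial order held (``max_order <= N - 1``).
    values
        Array of shape ``(max_order + 1, N)``; ``values[n, x] = t_n(x)``.
    monomial_coeffs
        Lower-triangular array ``c[n, k]`` with ``t_n(x) = sum_k c[n,k] x^k``.
    """

    support_size: int
    max_order: int
    values: np.ndarray
    monomial_coeffs: np.ndarray


def _recurrence_coeffs(n: int, N: int):
    a1 = (2.0 / n) * np.sqrt((4 * n**2 - 1) / (N**2 - n**2))
    a2 = ((1.0 - N) / n) * np.sqrt((4 * n**2 - 1) / (N**2 - n**2))
    a3 = (
        ((n - 1.0) / n)
        * np.sqrt((2 * n + 1) / (2 * n - 3))
        * np.sqrt((N**2 - (n - 1) ** 2) / (N**2 - n**2))
    )
    return a1, a2, a3


def build_basis(support_size: int, max_order: int) -> TchebichefBasis:
    """Build the orthonormal basis up to ``max_order`` on ``{0..N-1}``.

    ``max_order`` must be strictly less than ``support_size``: on N lattice
    points only N linearly independent polynomials exist.
    """
    N = int(support_size)
    if N < 1:
        raise ValueError("support_size must be >= 1")
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if max_order >= N:
        raise ValueError(
            f"max_order ({max_order}) must be < support_size ({N}): "
            "the discrete basis is complete at order N-1"
        )
    x = np.arange(N, dtype=float)
    vals = np.zeros((max_order + 1, N))
    coeffs = np.zeros((max_order + 1, max_order + 1))
    vals[0] = 1.0 / np.sqrt(N)
    coeffs[0, 0] = 1.0 / np.sqrt(N)
    if max_order >= 1:
        s = np.sqrt(3.0 / (N * (N**2 - 1)))
        vals[1] = (2 * x + 1 - N) * s
        coeffs[1, 0] = (1 - N) * s
        coeffs[1, 1] = 2 * s
    for n in range(2, max_order + 1):
        a1, a2, a3 = _recurrence_coeffs(n, N)
        vals[n] = (a1 * x + a2) * vals[n - 1] - a3 * vals[n - 2]
        coeffs[n, 1:] += a1 * coeffs[n - 1, :-1]
        coeffs[n] += a2 * coeffs[n - 1] - a3 * coeffs[n - 2]
    return TchebichefBasis(N, int(max_order), vals, coeffs)


def _mp_coeffs(N: int, max_order: int) -> list[list[mp.mpf]]:
    """Monomial coefficients of the basis computed in mpmath precision."""
    C = [[mp.mpf(0)] * (max_order + 1) for _ in range(max_order + 1)]
    C[0][0] = 1 / mp.sqrt(N)
    if max_order >= 1:
        s = mp.sqrt(mp.mpf(3) / (N * (N**2 - 1)))
        C[1][0] = (1 - N) * s
        C[1][1] = 2 * s
    for n in range(2, max_order + 1):
        a1 = (mp.mpf(2) / n) * mp.sqrt(mp.mpf(4 * n**2 - 1) / (N**2 - n**2))
        a2 = (mp.mpf(1 - N) / n) * mp.sqrt(mp.mpf(4 * n**2 - 1) / (N**2 - n**2))
        a3 = (
            (mp.mpf(n - 1) / n)
            * mp.sqrt(mp.mpf(2 * n + 1) / (2 * n - 3))
            * mp.sqrt(mp.mpf(N**2 - (n - 1) ** 2) / (N**2 - n**2))
        )
        for k in range(max_order + 1):
            v = a2 * C[n - 1][k] - a3 * C[n - 2][k]
            if k > 0:
                v += a1 * C[n - 1][k - 1]
            C[n][k] = v
    return C


def tcheb_moments_from_distribution(p, basis: TchebichefBasis) -> np.ndarray:
    """Tchebichef moments ``T_n = sum_x p(x) t_n(x)`` of a density p.

    This projection route is numerically stable at any order and is the
    preferred way to compute ``T_n`` when the density itself is available.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (basis.support_size,):
        raise ValueError(
            f"density has length {p.size}, basis support is {basis.support_size}"
        )
    return basis.values @ p


def tcheb_moments_from_raw(raw_moments, basis: TchebichefBasis, dps: int | None = None) -> np.ndarray:
    """Convert power moments ``mu_k (k = 0..m)`` to Tchebichef moments.

    Uses the linearity ``T_n = sum_k c_{n,k} mu_k`` with the basis's
    monomial coefficients.  ``raw_moments[0]`` must be 1 (a density).

    Parameters
    ----------
    raw_moments
        Power moments of the class-index density, orders 0..m with
        ``m <= basis.max_order``.  May be floats or mpmath values.
    dps
        If given, redo the conversion with ``dps`` decimal digits.  Required
        for near-full-order conversions (the monomial expansion is severely
        ill-conditioned in double precision once m exceeds ~15).
    """
    m = len(raw_moments) - 1
    if m > basis.max_order:
        raise ValueError("more raw moments than basis orders")
    if m >= basis.support_size:
        raise ValueError("moment order must be below the support size")
    if abs(float(raw_moments[0]) - 1.0) > 1e-9:
        raise ValueError("raw_moments[0] must equal 1 (moments of a density)")
    if dps is None:
        mu = np.asarray([float(v) for v in raw_moments])
        return basis.monomial_coeffs[: m + 1, : m + 1] @ mu
    with mp.workdps(dps):
        C = _mp_coeffs(basis.support_size, m)
        mu = [v if isinstance(v, mp.mpf) else mp.mpf(float(v)) for v in raw_moments]
        T = [mp.fsum(C[n][k] * mu[k] for k in range(m + 1)) for n in range(m + 1)]
        return np.array([float(t) for t in T])


def _mp_values(N: int, max_order: int) -> list[list[mp.mpf]]:
    """Basis values t_n(x) computed in mpmath precision (value recurrence)."""
    vals = [[mp.mpf(0)] * N for _ in range(max_order + 1)]
    r0 = 1 / mp.sqrt(N)
    for x in range(N):
        vals[0][x] = r0
    if max_order >= 1:
        s = mp.sqrt(mp.mpf(3) / (N * (N**2 - 1)))
        for x in range(N):
            vals[1][x] = (2 * x + 1 - N) * s
    for n in range(2, max_order + 1):
        a1 = (mp.mpf(2) / n) * mp.sqrt(mp.mpf(4 * n**2 - 1) / (N**2 - n**2))
        a2 = (mp.mpf(1 - N) / n) * mp.sqrt(mp.mpf(4 * n**2 - 1) / (N**2 - n**2))
        a3 = (
            (mp.mpf(n - 1) / n)
            * mp.sqrt(mp.mpf(2 * n + 1) / (2 * n - 3))
            * mp.sqrt(mp.mpf(N**2 - (n - 1) ** 2) / (N**2 - n**2))
        )
        for x in range(N):
            vals[n][x] = (a1 * x + a2) * vals[n - 1][x] - a3 * vals[n - 2][x]
    return vals


def reconstruct(
    tcheb_moments,
    basis: TchebichefBasis,
    clip_negative: bool = True,
    dps: int | None = None,
) -> np.ndarray:
    """Reconstruct a density on ``{0..N-1}`` from Tchebichef moments.

    ``p_hat(x) = sum_{n<=k} T_n t_n(x)``; with all ``N`` moments the
    reconstruction is exact (the basis is complete).  With ``clip_negative``
    (default) negative entries of a truncated reconstruction are set to zero
    and the density renormalized to sum to 1.  ``dps`` evaluates the basis
    and the contraction in extended precision — needed for full-order
    reconstructions on large supports, where the double-precision value
    recurrence itself carries errors near 1e-9.
    """
    T = np.asarray(tcheb_moments, dtype=float)
    k = T.size - 1
    if k > basis.max_order:
        raise ValueError("more moments than basis orders")
    if dps is None:
        p_hat = basis.values[: k + 1].T @ T
    else:
        with mp.workdps(dps):
            vals = _mp_values(basis.support_size, k)
            p_hat = np.array(
                [
                    float(mp.fsum(mp.mpf(T[n]) * vals[n][x] for n in range(k + 1)))
                    for x in range(basis.support_size)
                ]
            )
    if clip_negative:
        p_hat = np.clip(p_hat, 0.0, None)
        s = p_hat.sum()
        if s <= 0:
            raise ValueError("reconstruction clipped to zero mass")
        p_hat = p_hat / s
    return p_hat


def clipped_mass(tcheb_moments, basis: TchebichefBasis) -> float:
    """Total negative mass removed by clipping a truncated reconstruction.

    Used as an instability indicator: large clipped mass signals that the
    supplied (typically extrapolated) moments are inconsistent with a
    nonnegative density at this order.
    """
    raw = reconstruct(tcheb_moments, basis, clip_negative=False)
    return float(-raw[raw < 0].sum())


def binned_power_moments(b, n_max: int, dps: int | None = None):
    """Power moments ``mu_n = sum_i p_i i**n`` of an octave histogram.

    With ``dps`` the moments are computed in extended precision, which is
    required when they will be inverted at full order (the high-order
    moments carry the density information in digits far beyond double
    precision).
    """
    if isinstance(b, BinnedSAD):
        p = b.proportions
    else:
        p = np.asarray(b, dtype=float)
        p = p / p.sum()
    N = p.size
    if dps is None:
        i = np.arange(N, dtype=float)
        return np.array([np.sum(p * i**n) for n in range(n_max + 1)])
    with mp.workdps(dps):
        pm = [mp.mpf(float(v)) for v in p]
        return [
            mp.fsum(pm[i] * mp.mpf(i) ** n for i in range(N))
            for n in range(n_max + 1)
        ]


def select_order(
    empirical: BinnedSAD,
    raw_moments,
    basis: TchebichefBasis,
    k_max: int,
) -> int:
    """Choose the reconstruction order ``k*`` against an empirical histogram.

    For each ``k in 1..k_max`` the first ``k`` raw moments (plus ``mu_0 = 1``)
    are converted to Tchebichef moments and reconstructed; ``k*`` minimises
    the sum of squared differences between the empirical class counts and
    ``S * p_hat_k``.  Ties break toward the smaller order.
    """
    if k_max >= basis.support_size:
        raise ValueError("k_max must be below the basis support size")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts = empirical.class_counts
    if counts.size != basis.support_size:
        raise ValueError("empirical histogram does not match the basis support")
    S = counts.sum()
    if S <= 0 or empirical.num_classes < 2:
        raise ValueError("degenerate empirical histogram")
    raw = np.asarray([float(v) for v in raw_moments])
    if len(raw) - 1 < k_max:
        raise ValueError("need raw moments up to order k_max")
    best_k, best_sse = None, np.inf
    for k in range(1, k_max + 1):
        T = tcheb_moments_from_raw(raw[: k + 1], basis)
        p_hat = reconstruct(T, basis)
        sse = float(np.sum((counts - S * p_hat) ** 2))
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    return int(best_k)
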