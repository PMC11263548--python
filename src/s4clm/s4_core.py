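"""Structured state-space (S4) primitives.

A single-input single-output discrete state-space system

    x_k = Abar x_{k-1} + Bbar u_k
    y_k = Cbar x_k + Dbar u_k

is equivalently a causal convolution ``y = u * Kbar`` with filter taps
``Kbar_k = Cbar Abar^k Bbar``.  This duality — train as a global
convolution over the whole sequence, generate step by step with the same
parameters — is the architectural core of the chemical language model in
this package.

The continuous-time state matrix is initialized from the HiPPO-LegS
operator, kept in diagonal-plus-low-rank (DPLR) form ``A = V (Λ - p q*) V*``
so the convolution kernel can also be computed through a stable
generating-function (Cauchy-kernel) path.  A naive kernel path via
materialized matrix powers is always available for moderate state sizes and
serves as the in-repo oracle for the structured path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal
from scipy.fft import ifft, next_fast_len

__all__ = [
    "StateSpaceParams",
    "ConvKernel",
    "hippo_legs_matrix",
    "hippo_legs_dplr",
    "init_state_space",
    "init_state_space_bank",
    "discretize",
    "compute_kernel",
    "recurrent_step",
    "convolve_sequence",
]

#: Largest state size for which the naive (matrix-power) kernel path is
#: considered cheap enough to serve as the oracle.
NAIVE_KERNEL_MAX_N = 64


class DiscretizationError(np.linalg.LinAlgError):
    """Bilinear transform failed (singular I - Δ/2·A)."""


@dataclass
class StateSpaceParams:
    """Continuous + discretized parameters of one SISO state-space channel.

    Continuous side: ``A`` (N×N, real, materialized), its DPLR factors
    ``Lambda`` (complex diagonal), ``p``/``q`` (rank-1 correction) and the
    unitary basis ``V`` such that ``A = V (diag(Lambda) - p q*) V*``;
    input/output maps ``B``/``C`` and step size ``delta``.  The DPLR factors
    are absent for hand-built systems, in which case only the naive kernel
    path applies.  Discrete side (populated by :func:`discretize`):
    ``A_bar``, ``B_bar``, ``C_bar``, ``D_bar``.
    """

    N: int
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float
    D: float = 1.0
    Lambda: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    V: np.ndarray | None = None
    A_bar: np.ndarray | None = None
    B_bar: np.ndarray | None = None
    C_bar: np.ndarray | None = None
    D_bar: float | None = None

    @classmethod
    def from_continuous(
        cls, A: np.ndarray, B: np.ndarray, C: np.ndarray, delta: float, D: float = 0.0
    ) -> "StateSpaceParams":
        A = np.atleast_2d(np.asarray(A, dtype=float))
        return cls(N=A.shape[0], A=A, B=np.asarray(B, float).reshape(-1),
                   C=np.asarray(C, float).reshape(-1), delta=float(delta), D=D)

    @classmethod
    def from_discrete(
        cls, A_bar: np.ndarray, B_bar: np.ndarray, C_bar: np.ndarray, D_bar: float = 0.0
    ) -> "StateSpaceParams":
        """Build directly from discrete matrices (mainly for small examples)."""
        A_bar = np.atleast_2d(np.asarray(A_bar, dtype=float))
        obj = cls(N=A_bar.shape[0], A=A_bar, B=np.asarray(B_bar, float).reshape(-1),
                  C=np.asarray(C_bar, float).reshape(-1), delta=1.0, D=D_bar)
        obj.A_bar = A_bar
        obj.B_bar = obj.B.copy()
        obj.C_bar = obj.C.copy()
        obj.D_bar = float(D_bar)
        return obj

    @property
    def discretized(self) -> bool:
        return self.A_bar is not None


@dataclass(frozen=True)
class ConvKernel:
    """Impulse response of a discretized system: ``taps[k] = Cbar Abar^k Bbar``."""

    taps: np.ndarray
    L: int


def hippo_legs_matrix(N: int) -> np.ndarray:
    """The HiPPO-LegS continuous state matrix (lower triangular, N×N).

    ``A[n, k] = -sqrt((2n+1)(2k+1))`` for ``n > k``, ``-(n+1)`` on the
    diagonal, 0 above.  Its eigenvalues are ``-(n+1) < 0``, so the
    continuous system is strictly stable.
    """
    n = np.arange(N)
    A = -np.sqrt(np.outer(2 * n + 1, 2 * n + 1))
    A = np.tril(A, k=-1) + np.diag(-(n + 1).astype(float))
    return A


def hippo_legs_dplr(N: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """DPLR decomposition of the HiPPO-LegS matrix.

    With ``P_n = sqrt(n + 1/2)``, the matrix ``A + P P^T + I/2`` is
    skew-symmetric, hence unitarily diagonalizable with purely imaginary
    spectrum.  Returns ``(Lambda, p, q, V)`` with ``A = V (diag(Lambda)
    - p q*) V*`` and ``Lambda_n = -1/2 + i·θ_n``.
    """
    A = hippo_legs_matrix(N)
    P = np.sqrt(np.arange(N) + 0.5)
    S = A + np.outer(P, P)  # = skew - I/2
    skew = S + 0.5 * np.eye(N)
    # eigendecomposition through the Hermitian matrix i·skew
    theta, V = np.linalg.eigh(1j * skew)
    Lambda = -0.5 - 1j * theta
    p = V.conj().T @ P
    return Lambda, p, p.copy(), V


def init_state_space(
    N: int,
    rng: np.random.Generator | int | None = 0,
    delta_range: tuple[float, float] = (1e-3, 1e-1),
) -> StateSpaceParams:
    """Initialize one channel: HiPPO-LegS DPLR state matrix, random B and C,
    log-uniform Δ in ``delta_range``.  Deterministic given the seed."""
    if N < 1:
        raise ValueError("state size N must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Lambda, p, q, V = hippo_legs_dplr(N)
    A = hippo_legs_matrix(N)
    B = rng.standard_normal(N)
    C = rng.standard_normal(N) / np.sqrt(N)
    lo, hi = delta_range
    delta = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return StateSpaceParams(N=N, A=A, B=B, C=C, delta=delta, D=1.0,
                            Lambda=Lambda, p=p, q=q, V=V)


def init_state_space_bank(
    N: int, model_width: int, rng: np.random.Generator | int | None = 0,
    delta_range: tuple[float, float] = (1e-3, 1e-1),
) -> list[StateSpaceParams]:
    """One independent SISO system per model channel (shared HiPPO spectrum,
    channel-specific B, C and Δ)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [init_state_space(N, rng, delta_range) for _ in range(model_width)]


def discretize(params: StateSpaceParams) -> StateSpaceParams:
    """Bilinear (Tustin) discretization.

    ``Abar = (I - Δ/2·A)^{-1} (I + Δ/2·A)``, ``Bbar = (I - Δ/2·A)^{-1} Δ B``,
    ``Cbar = C``, ``Dbar = D``.  Returns a new parameter object.
    """
    if params.delta <= 0:
        raise ValueError("discretization step delta must be positive")
    N, dt = params.N, params.delta
    lhs = np.eye(N) - dt / 2.0 * params.A
    try:
        A_bar = np.linalg.solve(lhs, np.eye(N) + dt / 2.0 * params.A)
        B_bar = np.linalg.solve(lhs, dt * params.B)
    except np.linalg.LinAlgError as exc:
        raise DiscretizationError(
            f"singular (I - Δ/2·A) with Δ={dt}; the bilinear transform is "
            "undefined at this step size"
        ) from exc
    out = replace(params)
    out.A_bar, out.B_bar = A_bar, B_bar
    out.C_bar, out.D_bar = params.C.copy(), float(params.D)
    return out


def _kernel_naive(params: StateSpaceParams, L: int) -> np.ndarray:
    x = params.B_bar.copy()
    taps = np.empty(L)
    for k in range(L):
        taps[k] = params.C_bar @ x
        x = params.A_bar @ x
    return taps


def _matrix_power(A: np.ndarray, n: int) -> np.ndarray:
    return np.linalg.matrix_power(A, n)


def _kernel_structured(params: StateSpaceParams, L: int) -> np.ndarray:
    """Generating-function kernel evaluation via the Cauchy kernel.

    The truncated generating function ``Khat(z) = Σ_{l<M} K_l z^l`` is
    evaluated at the M-th roots of unity (M odd, so the bilinear pole at
    z = -1 is never hit) and inverted with an inverse FFT.  The resolvent in
    the DPLR basis is expanded with the Woodbury identity, reducing the
    evaluation to four Cauchy dot products against ``1/(ζ - Λ)``.
    """
    if params.Lambda is None:
        raise ValueError("structured kernel path requires DPLR factors")
    M = L if L % 2 == 1 else L + 1
    dt = params.delta
    # truncation correction: Khat uses Ctilde = C (I - Abar^M)
    C_tilde = params.C_bar @ (np.eye(params.N) - _matrix_power(params.A_bar, M))
    c = C_tilde @ params.V                  # row vector in the DPLR basis
    b = params.V.conj().T @ params.B        # column vector in the DPLR basis
    p, q, Lam = params.p, params.q, params.Lambda

    j = np.arange(M)
    z = np.exp(-2j * np.pi * j / M)
    zeta = (2.0 / dt) * (1.0 - z) / (1.0 + z)          # (M,)
    denom = zeta[:, None] - Lam[None, :]               # Cauchy denominators
    cd = (c[None, :] / denom)                          # c · D(ζ)
    k00 = cd @ b
    k01 = cd @ p
    k10 = (q.conj()[None, :] / denom) @ b
    k11 = (q.conj()[None, :] / denom) @ p
    khat = (2.0 / (1.0 + z)) * (k00 - k01 * k10 / (1.0 + k11))
    taps = ifft(khat).real[:L]
    return taps + (np.arange(L) == 0) * 0.0


def compute_kernel(
    params: StateSpaceParams, L: int, method: str = "auto"
) -> ConvKernel:
    """Convolution filter ``Kbar`` of length ``L``.

    ``method``: ``"naive"`` materializes matrix powers (the oracle path,
    mandatory for N ≤ 64), ``"structured"`` uses the Cauchy generating
    function, ``"auto"`` picks naive for small N and structured otherwise.
    """
    if L < 1:
        raise ValueError("kernel length L must be >= 1")
    if not params.discretized:
        raise ValueError("discretize() the parameters before computing kernels")
    if method == "auto":
        method = "naive" if params.N <= NAIVE_KERNEL_MAX_N or params.Lambda is None \
            else "structured"
    if method == "naive":
        taps = _kernel_naive(params, L)
    elif method == "structured":
        taps = _kernel_structured(params, L)
    else:
        raise ValueError(f"unknown kernel method {method!r}")
    return ConvKernel(taps=taps, L=L)


def recurrent_step(
    params: StateSpaceParams, x_prev: np.ndarray, u_k: float
) -> tuple[np.ndarray, float]:
    """One step of the linear recurrence; returns ``(x_k, y_k)``."""
    if not params.discretized:
        raise ValueError("discretize() the parameters before stepping")
    x_prev = np.asarray(x_prev, dtype=float).reshape(-1)
    if x_prev.shape[0] != params.N:
        raise ValueError(f"state has size {x_prev.shape[0]}, expected {params.N}")
    x_k = params.A_bar @ x_prev + params.B_bar * u_k
    y_k = float(params.C_bar @ x_k + params.D_bar * u_k)
    return x_k, y_k


def run_recurrence(params: StateSpaceParams, u: np.ndarray) -> np.ndarray:
    """Unroll the recurrence over a whole input sequence (zero initial state)."""
    x = np.zeros(params.N)
    y = np.empty(len(u))
    for k, u_k in enumerate(u):
        x, y[k] = recurrent_step(params, x, u_k)
    return y


def convolve_sequence(
    u: np.ndarray, kernel: ConvKernel, D_bar: float = 0.0
) -> np.ndarray:
    """Causal convolution ``y_k = Σ_{j<=k} K_{k-j} u_j + Dbar u_k`` (FFT-based)."""
    u = np.asarray(u, dtype=float)
    if len(u) != kernel.L:
        raise ValueError(f"input length {len(u)} != kernel length {kernel.L}")
    y = _signal.fftconvolve(u, kernel.taps)[: kernel.L]
    return y + D_bar * u


def spectral_radius(params: StateSpaceParams) -> float:
    """Spectral radius of the discretized state matrix."""
    if not params.discretized:
        raise ValueError("discretize() first")
    return float(np.max(np.abs(np.linalg.eigvals(params.A_bar))))
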