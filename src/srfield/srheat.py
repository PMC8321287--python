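"""Sub-Riemannian heat semigroup exp(tau * L) on orientation scores.

The sub-Laplacian L = X1^2 + beta^2 * X2^2, with X1 = cos(theta) d/dx +
sin(theta) d/dy and X2 = d/dtheta, generates a hypoelliptic diffusion on
R^2 x P^1 that spreads activity along oriented contours, modelling the
lateral connectivity of V1.  beta > 0 couples the spatial and angular units.

Numerical scheme
----------------
The spatial domain is the unit square sampled at N points per axis
(dx = 1/N), with periodic boundary conditions; the orientation circle [0, pi)
is sampled at K points.  Central differences in space become, after a 2D DFT,
multiplication by i*N*d[r, s, k] with the real symbol

    d[r, s, k] = cos(theta_k) sin(2 pi s / N) + sin(theta_k) sin(2 pi r / N),

where s indexes the x-axis (columns) and r the y-axis (rows).  The heat
equation thus decouples into N^2 independent K-dimensional linear ODEs

    dPsi/dt = [Theta - N^2 diag_k(d[r, s, k]^2)] Psi,

with Theta the periodic tridiagonal second-difference operator in theta
scaled by beta^2 / dtheta^2.  Each ODE is integrated by Crank-Nicolson steps
whose cyclic tridiagonal systems are solved in O(K) by a Sherman-Morrison
variant of the Thomas algorithm.  Since the step matrix is constant, the
m-step propagator can equivalently be precomputed per frequency from the
eigendecomposition of the (symmetric) generator; both paths agree to
round-off and the propagator path is used inside the model iterations.

A dense matrix-exponential oracle on tiny grids provides the independent
reference for testing.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse

from .lifting import orientation_grid

__all__ = [
    "default_beta",
    "diffusion_tensor",
    "spectral_symbol",
    "build_theta_operator",
    "solve_periodic_tridiagonal",
    "HeatFlow",
    "heat_evolve",
    "dense_generator",
    "dense_heat_oracle",
    "dense_heat_kernel",
]

_DENSE_LIMIT = 4200  # largest N*N*K the dense oracle will assemble


def default_beta(N: int, K: int) -> float:
    """Default spatial/angular coherency constant beta = K / (2 sqrt(2) N).

    One spatial unit corresponds to two pixel edges and one orientation unit
    to a single pixel edge, which fixes the relative scaling of the
    derivatives in L.  Always overridable through the model configuration.
    """
    return K / (2.0 * np.sqrt(2.0) * N)


def diffusion_tensor(theta: float, beta: float) -> np.ndarray:
    """The 3x3 diffusion tensor of L in the (d/dx, d/dy, d/dtheta) frame.

    L = D^T l D with D = (d/dx, d/dy, d/dtheta); l has rank 2 with
    eigenvalues {0, beta^2, 1} for every theta -- the degeneracy that makes
    L sub-Riemannian rather than elliptic.
    """
    c, s = np.cos(theta), np.sin(theta)
    return np.array(
        [
            [c * c, c * s, 0.0],
            [c * s, s * s, 0.0],
            [0.0, 0.0, beta ** 2],
        ]
    )


def spectral_symbol(N: int, K: int) -> np.ndarray:
    """Real symbol d of the spatial central-difference operator D.

    Returns an (N, N, K) array indexed [r, s, k]: r is the DFT index of the
    y (row) axis, s of the x (column) axis.  Applying D in the DFT domain is
    multiplication by i * N * d.  |d| <= sqrt(2) everywhere and d = 0 on the
    zero-frequency plane.
    """
    if N < 2 or K < 1:
        raise ValueError(f"need N >= 2 and K >= 1, got N={N}, K={K}")
    sin_f = np.sin(2 * np.pi * np.arange(N) / N)
    thetas = orientation_grid(K)
    return (
        np.cos(thetas)[None, None, :] * sin_f[None, :, None]
        + np.sin(thetas)[None, None, :] * sin_f[:, None, None]
    )


def build_theta_operator(K: int, beta: float) -> np.ndarray:
    """Periodic second-difference operator in theta, scaled by beta^2/dtheta^2.

    The K x K circulant of (1, -2, 1) with corner couplings (1, K) and (K, 1);
    symmetric, rows summing to zero, negative semidefinite, with eigenvalues
    -(2 beta^2 / dtheta^2) (1 - cos(2 pi l / K)).
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    dtheta = np.pi / K
    scale = beta ** 2 / dtheta ** 2
    op = np.zeros((K, K))
    idx = np.arange(K)
    op[idx, idx] = -2.0
    op[idx, (idx + 1) % K] += 1.0
    op[idx, (idx - 1) % K] += 1.0
    return scale * op


def _thomas(diag, lower, upper, rhs):
    """Batched Thomas solve of tridiagonal systems (no pivoting).

    Shapes: diag (..., K); lower, upper (..., K-1); rhs (..., K).  The batch
    dimensions broadcast.  Raises on vanishing pivots.
    """
    K = diag.shape[-1]
    dtype = np.result_type(diag, rhs)
    cp = np.empty(np.broadcast_shapes(diag.shape, rhs.shape)[:-1] + (K - 1,), dtype=dtype)
    dp = np.empty(np.broadcast_shapes(diag.shape, rhs.shape), dtype=dtype)
    denom = diag[..., 0]
    _check_pivot(denom)
    cp[..., 0] = upper[..., 0] / denom
    dp[..., 0] = rhs[..., 0] / denom
    for i in range(1, K):
        denom = diag[..., i] - lower[..., i - 1] * cp[..., i - 1]
        _check_pivot(denom)
        if i < K - 1:
            cp[..., i] = upper[..., i] / denom
        dp[..., i] = (rhs[..., i] - lower[..., i - 1] * dp[..., i - 1]) / denom
    x = dp
    for i in range(K - 2, -1, -1):
        x[..., i] = dp[..., i] - cp[..., i] * x[..., i + 1]
    return x


def _check_pivot(denom):
    if np.min(np.abs(denom)) < 1e-300:
        raise np.linalg.LinAlgError("singular (periodic) tridiagonal system")


def solve_periodic_tridiagonal(diag, lower, upper, corner_lower, corner_upper, rhs):
    """Solve cyclic tridiagonal systems A x = rhs in O(K) per right-hand side.

    A has main diagonal ``diag`` (..., K), sub/super-diagonals ``lower`` /
    ``upper`` (..., K-1), and corner entries ``A[0, K-1] = corner_upper``,
    ``A[K-1, 0] = corner_lower`` (scalars or batched).  All batch dimensions
    broadcast; the rhs may be complex.  Uses the Sherman-Morrison correction
    of two Thomas solves; with both corners zero it reduces to the classic
    Thomas algorithm.  Requires K >= 3 in the cyclic case (for K = 2 the
    corner and off-diagonal positions coincide).
    """
    diag = np.asarray(diag, dtype=float)
    rhs = np.asarray(rhs)
    K = diag.shape[-1]
    lower = np.broadcast_to(np.asarray(lower, dtype=float), diag.shape[:-1] + (K - 1,))
    upper = np.broadcast_to(np.asarray(upper, dtype=float), diag.shape[:-1] + (K - 1,))
    cl = np.asarray(corner_lower, dtype=float)
    cu = np.asarray(corner_upper, dtype=float)

    if np.all(cl == 0) and np.all(cu == 0):
        return _thomas(diag, lower, upper, rhs)
    if K < 3:
        raise ValueError("cyclic solve requires K >= 3; use a dense solve for K = 2")

    gamma = -diag[..., 0]
    _check_pivot(gamma)
    mod_diag = diag.copy()
    mod_diag[..., 0] = diag[..., 0] - gamma
    mod_diag[..., -1] = diag[..., -1] - cl * cu / gamma

    y = _thomas(mod_diag, lower, upper, rhs)
    u = np.zeros(mod_diag.shape, dtype=float)
    u[..., 0] = gamma
    u[..., -1] = cl
    z = _thomas(mod_diag, lower, upper, u)

    # v = e_0 + (cu / gamma) e_{K-1}
    vy = y[..., 0] + (cu / gamma) * y[..., -1]
    vz = z[..., 0] + (cu / gamma) * z[..., -1]
    factor = vy / (1.0 + vz)
    return y - z * factor[..., None]


class HeatFlow:
    """Precomputed application of exp(tau * L) for a fixed grid and schedule.

    ``method="propagator"`` assembles, per spatial frequency, the m-step
    Crank-Nicolson propagator from the eigendecomposition of the symmetric
    per-mode generator; ``method="thomas"`` performs the m Crank-Nicolson
    steps explicitly with the cyclic Thomas solver.  The two agree to
    round-off; the propagator is preferred when the flow is applied many
    times (its cost per application is one FFT pair plus a batched K x K
    matrix product).
    """

    def __init__(self, N: int, K: int, tau: float, dtau: float, beta: float | None = None,
                 method: str = "propagator"):
        if tau < 0:
            raise ValueError(f"tau must be >= 0, got {tau}")
        if tau > 0 and not 0 < dtau <= tau:
            raise ValueError(f"need 0 < dtau <= tau, got dtau={dtau}, tau={tau}")
        if method not in ("propagator", "thomas"):
            raise ValueError(f"unknown method {method!r}")
        if beta is None:
            beta = default_beta(N, K)
        self.N, self.K, self.tau, self.dtau, self.beta = N, K, tau, dtau, beta
        self.method = method
        self.m = 0 if tau == 0 else max(1, int(round(tau / dtau)))
        if tau == 0:
            return

        self._d2 = spectral_symbol(N, K) ** 2
        self._theta_op = build_theta_operator(K, beta)

        if method == "propagator" or K < 3:
            # per-mode generator M = Theta - N^2 diag(d^2), symmetric
            gen = np.broadcast_to(self._theta_op, (N, N, K, K)).copy()
            idx = np.arange(K)
            gen[..., idx, idx] -= N ** 2 * self._d2
            w, V = np.linalg.eigh(gen)
            z = 0.5 * dtau * w
            gain = ((1.0 + z) / (1.0 - z)) ** self.m
            self._propagator = np.einsum("yxkl,yxl,yxml->yxkm", V, gain, V)

    def apply(self, activation: np.ndarray) -> np.ndarray:
        activation = np.asarray(activation, dtype=float)
        if activation.shape != (self.N, self.N, self.K):
            raise ValueError(
                f"activation shape {activation.shape} does not match "
                f"({self.N}, {self.N}, {self.K})"
            )
        if self.tau == 0:
            return activation.copy()
        spectrum = np.fft.fft2(activation, axes=(0, 1))
        if self.method == "propagator" or self.K < 3:
            out = np.einsum("yxkl,yxl->yxk", self._propagator, spectrum)
        else:
            out = self._crank_nicolson_steps(spectrum)
        return np.fft.ifft2(out, axes=(0, 1)).real

    def _crank_nicolson_steps(self, spectrum: np.ndarray) -> np.ndarray:
        N, K, h = self.N, self.K, self.dtau
        scale = self.beta ** 2 / (np.pi / K) ** 2
        diag = 1.0 + h * scale + 0.5 * h * N ** 2 * self._d2
        off = np.full((N, N, K - 1), -0.5 * h * scale)
        corner = -0.5 * h * scale
        v = spectrum
        for _ in range(self.m):
            theta_v = scale * (np.roll(v, 1, axis=-1) + np.roll(v, -1, axis=-1) - 2.0 * v)
            rhs = v + 0.5 * h * (theta_v - N ** 2 * self._d2 * v)
            v = solve_periodic_tridiagonal(diag, off, off, corner, corner, rhs)
        return v


def heat_evolve(activation: np.ndarray, tau: float, dtau: float,
                beta: float | None = None, method: str = "thomas") -> np.ndarray:
    """Evolve an N x N x K activation by the sub-Riemannian heat semigroup.

    Convenience wrapper constructing a :class:`HeatFlow` for a single
    application; ``tau = 0`` is the identity.
    """
    activation = np.asarray(activation, dtype=float)
    N, N2, K = activation.shape
    if N != N2:
        raise ValueError(f"activation must be square in space, got {activation.shape}")
    flow = HeatFlow(N, K, tau, dtau, beta=beta, method=method)
    return flow.apply(activation)


def _spatial_shift_ops(N: int):
    shift = scipy.sparse.diags([np.ones(N - 1)], [1], shape=(N, N), format="csr")
    shift = shift + scipy.sparse.csr_matrix(([1.0], ([N - 1], [0])), shape=(N, N))
    eye = scipy.sparse.identity(N, format="csr")
    # x = column axis (fastest in (i * N + j) flattening), y = row axis
    sx = scipy.sparse.kron(eye, shift, format="csr")
    sy = scipy.sparse.kron(shift, eye, format="csr")
    dx = (N / 2.0) * (sx - sx.T)
    dy = (N / 2.0) * (sy - sy.T)
    return dx, dy


def dense_generator(N: int, K: int, beta: float | None = None) -> np.ndarray:
    """Full (N^2 K) x (N^2 K) semi-discrete sub-Laplacian, for tiny grids.

    Spatial central differences (step 1/N, periodic) combined per slice as
    (cos theta_k Dx + sin theta_k Dy)^2, plus the periodic theta operator.
    Flattened index order is [k, i, j] (slice, row, column).  Refuses grids
    beyond dense feasibility.
    """
    if N * N * K > _DENSE_LIMIT:
        raise ValueError(
            f"dense generator refused: N*N*K = {N * N * K} exceeds {_DENSE_LIMIT}"
        )
    if beta is None:
        beta = default_beta(N, K)
    dx, dy = _spatial_shift_ops(N)
    thetas = orientation_grid(K)
    blocks = []
    for theta in thetas:
        d_op = np.cos(theta) * dx + np.sin(theta) * dy
        blocks.append(d_op @ d_op)
    spatial = scipy.sparse.block_diag(blocks, format="csr")
    theta_part = scipy.sparse.kron(
        scipy.sparse.csr_matrix(build_theta_operator(K, beta)),
        scipy.sparse.identity(N * N, format="csr"),
        format="csr",
    )
    return (spatial + theta_part).toarray()


def dense_heat_kernel(N: int, K: int, tau: float, beta: float | None = None) -> np.ndarray:
    """Matrix exponential exp(tau * generator): the discrete heat kernel
    k_tau(xi, eta) on a tiny grid (symmetric, rows summing to 1)."""
    return scipy.linalg.expm(tau * dense_generator(N, K, beta))


def dense_heat_oracle(activation: np.ndarray, tau: float,
                      beta: float | None = None) -> np.ndarray:
    """Reference evolution by dense matrix exponential (test oracle)."""
    activation = np.asarray(activation, dtype=float)
    N, N2, K = activation.shape
    if N != N2:
        raise ValueError(f"activation must be square in space, got {activation.shape}")
    kernel = dense_heat_kernel(N, K, tau, beta)
    flat = activation.transpose(2, 0, 1).reshape(-1)
    out = kernel @ flat
    return out.reshape(K, N, N).transpose(1, 2, 0)
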