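"""Mean-field Wilson-Cowan and Local Histogram Equalisation dynamics on V1.

Two integro-differential evolutions for the cortical activation
``a(x, y, theta, t)`` are implemented, both driven by the sub-Riemannian heat
semigroup ``exp(tau L)`` as interaction kernel (an isotropic 3D Gaussian is
available as a baseline):

Wilson-Cowan (WC)
    da/dt = -(1 + lambda) a + (1 / 2M) exp(tau L) sigma(a) + lambda a0 + mu,

with a decreasing saturating sigmoid ``sigma`` acting on local *activity*.

Local Histogram Equalisation (LHE)
    da/dt = -(1 + lambda) a
            + (1 / 2M) int k_tau(xi, eta) sigma_hat(a(xi) - a(eta)) deta
            + lambda a0 + mu,

where the odd sigmoid ``sigma_hat`` acts on local *contrast*.  Writing
``sigma_hat`` as a polynomial sum c_j r^j and expanding the contrast
binomially turns the pairwise integral into n + 1 heat-kernel applications
(one per power of a), which is what makes the model computable at image
scale.  The LHE flow is the gradient descent of an explicit energy whose
pairwise term involves the even primitive of ``sigma_hat``; see
:func:`lhe_energy`.

Both flows are discretised by explicit gradient-descent steps of size
``dt``; the scheme converges for dt <= 1 / (1 + lambda).  ``a0`` is the
initial lift (the simple-cell response) and ``mu`` its per-slice 2D Gaussian
local mean.
"""

from __future__ import annotations

import dataclasses
import math
import time
import warnings

import numpy as np
from scipy.special import comb

from . import lifting, srheat

__all__ = [
    "ModelConfig",
    "EvolutionState",
    "EvolutionResult",
    "PolyCoefficients",
    "sigma",
    "sigma_hat",
    "sigma_hat_primitive",
    "local_mean",
    "fit_sigma_hat_poly",
    "interaction_coeffs",
    "gaussian_interaction",
    "build_interaction_operator",
    "wc_step",
    "lhe_step",
    "lhe_energy",
    "evolve",
]


# ---------------------------------------------------------------------------
# nonlinearities


def sigma(r, alpha: float):
    """Decreasing saturating sigmoid -min{1, max(alpha (r - 1/2), -1)}.

    Acts elementwise; values lie in [-1, 1] with sigma(1/2) = 0.  The leading
    minus sign is part of the model definition.
    """
    r = np.asarray(r, dtype=float)
    return -np.clip(alpha * (r - 0.5), -1.0, 1.0)


def sigma_hat(r, alpha: float):
    """Odd contrast sigmoid -sigma(r + 1/2) = min{1, max(alpha r, -1)}."""
    r = np.asarray(r, dtype=float)
    return np.clip(alpha * r, -1.0, 1.0)


def sigma_hat_primitive(r, alpha: float):
    """Even primitive of sigma_hat, normalised to vanish at 0.

    alpha r^2 / 2 in the linear zone |r| <= 1/alpha, |r| - 1/(2 alpha)
    beyond it.
    """
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r <= 1.0 / alpha, 0.5 * alpha * r ** 2, r - 0.5 / alpha)


# ---------------------------------------------------------------------------
# local mean


def local_mean(A0: np.ndarray, sigma_mu: float) -> np.ndarray:
    """Per-slice periodic 2D Gaussian smoothing of the initial lift.

    sigma_mu is the standard deviation in pixels.  The convolution is
    evaluated spectrally with the exact periodic (wrapped) Gaussian symbol,
    so the per-slice sum is preserved exactly and the large-sigma limit is
    the per-slice spatial mean.
    """
    if sigma_mu <= 0:
        raise ValueError(f"sigma_mu must be > 0, got {sigma_mu}")
    A0 = np.asarray(A0, dtype=float)
    n = A0.shape[0]
    f = np.fft.fftfreq(n)  # cycles per pixel
    decay = np.exp(-2.0 * np.pi ** 2 * sigma_mu ** 2 * (f[:, None] ** 2 + f[None, :] ** 2))
    spectrum = np.fft.fft2(A0, axes=(0, 1)) * decay[..., None]
    return np.fft.ifft2(spectrum, axes=(0, 1)).real


# ---------------------------------------------------------------------------
# polynomial contrast nonlinearity


@dataclasses.dataclass(frozen=True)
class PolyCoefficients:
    """Power-basis coefficients c_0..c_n approximating sigma_hat on [-R, R]."""

    coeffs: np.ndarray
    alpha: float
    domain: float
    sup_error: float

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, r):
        return np.polynomial.polynomial.polyval(np.asarray(r, dtype=float), self.coeffs)


def fit_sigma_hat_poly(alpha: float, n: int, R: float, grid_points: int = 2001) -> PolyCoefficients:
    """Least-squares polynomial fit of sigma_hat on a uniform grid over [-R, R].

    Odd symmetry of sigma_hat on the symmetric grid makes the even
    coefficients vanish to round-off.  The achieved sup-norm error on the
    fitting grid is recorded; it decreases as n grows.
    """
    if n < 1:
        raise ValueError(f"poly degree must be >= 1, got {n}")
    if R <= 0:
        raise ValueError(f"fit half-range must be > 0, got {R}")
    r = np.linspace(-R, R, grid_points)
    y = sigma_hat(r, alpha)
    # fit on the mapped domain for conditioning, convert to the power basis in r
    series = np.polynomial.polynomial.Polynomial.fit(r, y, deg=n)
    vander = np.polynomial.polynomial.polyvander(r / R, n)
    cond = np.linalg.cond(vander)
    if cond > 1e8:
        warnings.warn(
            f"ill-conditioned polynomial fit (degree {n}, condition ~{cond:.2e})",
            stacklevel=2,
        )
    coeffs = series.convert().coef
    if len(coeffs) < n + 1:  # trailing zeros trimmed by convert()
        coeffs = np.pad(coeffs, (0, n + 1 - len(coeffs)))
    sup_error = float(np.max(np.abs(np.polynomial.polynomial.polyval(r, coeffs) - y)))
    return PolyCoefficients(coeffs=coeffs, alpha=alpha, domain=R, sup_error=sup_error)


def interaction_coeffs(A: np.ndarray, poly: PolyCoefficients | np.ndarray) -> np.ndarray:
    """Coefficient fields C_0..C_n of the binomial contrast expansion.

    For sigma_hat(r) ~ sum_j c_j r^j one has, for every scalar b,

        sum_j c_j (A(xi) - b)^j = sum_i C_i(xi) b^i,
        C_i(xi) = (-1)^i sum_{j >= i} c_j binom(j, i) A(xi)^{j - i}.

    Returns an array of shape (n + 1,) + A.shape.
    """
    c = poly.coeffs if isinstance(poly, PolyCoefficients) else np.asarray(poly, dtype=float)
    A = np.asarray(A, dtype=float)
    n = len(c) - 1
    powers = np.empty((n + 1,) + A.shape)
    powers[0] = 1.0
    for p in range(1, n + 1):
        powers[p] = powers[p - 1] * A
    out = np.zeros((n + 1,) + A.shape)
    for i in range(n + 1):
        for j in range(i, n + 1):
            out[i] += c[j] * comb(j, i, exact=True) * powers[j - i]
        if i % 2:
            out[i] = -out[i]
    return out


def _poly_primitive(coeffs: np.ndarray) -> np.ndarray:
    """Antiderivative coefficients (constant 0) of a power-basis polynomial."""
    c = np.asarray(coeffs, dtype=float)
    return np.concatenate([[0.0], c / np.arange(1, len(c) + 1)])


# ---------------------------------------------------------------------------
# configuration and state


@dataclasses.dataclass
class ModelConfig:
    """All scalar parameters of a model run.

    Attributes
    ----------
    model:
        ``"wc"`` or ``"lhe"``.
    kernel:
        ``"subriemannian"`` (heat semigroup) or ``"gaussian3d"`` (isotropic
        baseline of the earlier cortical models).
    lam:
        Fidelity weight lambda >= 0 towards the initial lift.
    alpha:
        Sigmoid slope (> 1 in the model; the polynomial fit also accepts
        smaller values).
    M:
        Interaction normaliser; the interaction enters as 1 / (2 M).
    sigma_mu:
        Std (pixels) of the 2D Gaussian computing the local mean mu.
    dt:
        Outer gradient-descent step; dt <= 1 / (1 + lambda) is sufficient
        for convergence and a warning is issued beyond it.
    tau, dtau:
        Inner diffusion time and Crank-Nicolson step of the heat kernel.
    beta:
        Spatial/angular coherency of the sub-Laplacian; ``None`` selects
        K / (2 sqrt(2) N).
    poly_degree:
        Degree n of the contrast-sigmoid polynomial (LHE only; odd degrees
        match the odd symmetry).
    sigma_omega:
        Spatial std (pixels) of the 3D Gaussian baseline kernel; its angular
        std defaults to sigma_omega * K / N slices.
    max_iters, tol:
        Stopping rule: at most ``max_iters`` steps or relative residual
        below ``tol``.
    discrete_as_printed:
        Reproduce the update with unit fidelity weight on a0, lambda on mu
        and no 1/(2M) factor (a published variant of the same scheme)
        instead of the continuous-model form.
    negate_sigma:
        Use the increasing sigmoid -sigma (the convention of earlier
        mean-field models) in the WC interaction.
    """

    model: str = "wc"
    kernel: str = "subriemannian"
    lam: float = 0.01
    alpha: float = 20.0
    M: float = 1.0
    sigma_mu: float = 6.5
    dt: float = 0.1
    tau: float = 5.0
    dtau: float = 0.01
    beta: float | None = None
    poly_degree: int = 7
    sigma_omega: float | None = None
    sigma_theta: float | None = None
    max_iters: int = 500
    tol: float = 1e-6
    discrete_as_printed: bool = False
    negate_sigma: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("wc", "lhe"):
            raise ValueError(f"model must be 'wc' or 'lhe', got {self.model!r}")
        if self.kernel not in ("subriemannian", "gaussian3d"):
            raise ValueError(
                f"kernel must be 'subriemannian' or 'gaussian3d', got {self.kernel!r}"
            )
        if self.lam < 0 or self.M <= 0 or self.dt <= 0:
            raise ValueError("require lam >= 0, M > 0, dt > 0")
        if self.kernel == "gaussian3d" and self.sigma_omega is None:
            raise ValueError("gaussian3d kernel requires sigma_omega")
        if self.dt > 1.0 / (1.0 + self.lam) + 1e-12:
            warnings.warn(
                f"dt = {self.dt} exceeds the sufficient stability bound "
                f"1/(1+lambda) = {1.0 / (1.0 + self.lam):.4g}",
                stacklevel=2,
            )


@dataclasses.dataclass
class EvolutionState:
    """Current iterate of the gradient descent.

    ``A`` is the evolving activation, ``A0`` the initial lift, ``U`` the
    local mean; ``residuals`` collects the per-iteration relative update
    norms and ``energies`` (LHE, when requested) the energy estimates.
    """

    A: np.ndarray
    A0: np.ndarray
    U: np.ndarray
    p: int = 0
    residuals: list = dataclasses.field(default_factory=list)
    energies: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.A.shape == self.A0.shape == self.U.shape):
            raise ValueError("A, A0 and U must share one shape")


@dataclasses.dataclass
class EvolutionResult:
    output: np.ndarray           # projected image-plane field, unclamped
    activation: np.ndarray       # final cortical state
    state: EvolutionState
    diagnostics: list            # per-iteration dicts


# ---------------------------------------------------------------------------
# interaction operators


def gaussian_interaction(A: np.ndarray, sigma_omega: float,
                         sigma_theta: float | None = None) -> np.ndarray:
    """Isotropic 3D periodic Gaussian convolution (baseline kernel).

    Spatial std ``sigma_omega`` in pixels on both axes; angular std
    ``sigma_theta`` in slice units, defaulting to ``sigma_omega * K / N``
    (the same physical width under the default unit coherency).  Evaluated
    spectrally with exact wrapped-Gaussian symbols, so mass is preserved and
    the spatial spread is exactly isotropic.
    """
    A = np.asarray(A, dtype=float)
    n, _, K = A.shape
    if sigma_theta is None:
        sigma_theta = sigma_omega * K / n
    f = np.fft.fftfreq(n)
    fk = np.fft.fftfreq(K)
    decay = (
        np.exp(-2.0 * np.pi ** 2 * sigma_omega ** 2 * (f[:, None] ** 2 + f[None, :] ** 2))[..., None]
        * np.exp(-2.0 * np.pi ** 2 * sigma_theta ** 2 * fk ** 2)[None, None, :]
    )
    return np.fft.ifftn(np.fft.fftn(A) * decay).real


def build_interaction_operator(cfg: ModelConfig, N: int, K: int):
    """Callable applying the configured interaction kernel to an activation."""
    if cfg.kernel == "subriemannian":
        flow = srheat.HeatFlow(N, K, cfg.tau, cfg.dtau, beta=cfg.beta, method="propagator")
        return flow.apply
    sigma_theta = cfg.sigma_theta
    return lambda A: gaussian_interaction(A, cfg.sigma_omega, sigma_theta)


# ---------------------------------------------------------------------------
# gradient-descent steps


def _residual(new: np.ndarray, old: np.ndarray) -> float:
    denom = np.linalg.norm(old)
    return float(np.linalg.norm(new - old) / max(denom, 1e-300))


def _bracket(cfg: ModelConfig, A, A0, U, S):
    if cfg.discrete_as_printed:
        return -(1.0 + cfg.lam) * A + A0 + cfg.lam * U + S
    return -(1.0 + cfg.lam) * A + S / (2.0 * cfg.M) + cfg.lam * A0 + U


def wc_step(state: EvolutionState, cfg: ModelConfig, op=None) -> EvolutionState:
    """One explicit step of the (sub-Riemannian) Wilson-Cowan flow."""
    if cfg.model != "wc":
        raise ValueError("wc_step requires cfg.model == 'wc'")
    if op is None:
        n, _, K = state.A.shape
        op = build_interaction_operator(cfg, n, K)
    sig = sigma(state.A, cfg.alpha)
    if cfg.negate_sigma:
        sig = -sig
    S = op(sig)
    new_A = state.A + cfg.dt * _bracket(cfg, state.A, state.A0, state.U, S)
    state.residuals.append(_residual(new_A, state.A))
    state.A = new_A
    state.p += 1
    return state


def lhe_step(state: EvolutionState, cfg: ModelConfig, op=None,
             poly: PolyCoefficients | None = None) -> EvolutionState:
    """One explicit step of the (sub-Riemannian) LHE flow.

    The pairwise contrast interaction is evaluated through the binomial
    expansion: n + 1 kernel applications to the elementwise powers of the
    activation, recombined with the coefficient fields of
    :func:`interaction_coeffs`.
    """
    if cfg.model != "lhe":
        raise ValueError("lhe_step requires cfg.model == 'lhe'")
    if op is None:
        n, _, K = state.A.shape
        op = build_interaction_operator(cfg, n, K)
    if poly is None:
        poly = default_contrast_poly(cfg, state)
    S = _lhe_interaction(state.A, poly, op)
    new_A = state.A + cfg.dt * _bracket(cfg, state.A, state.A0, state.U, S)
    state.residuals.append(_residual(new_A, state.A))
    state.A = new_A
    state.p += 1
    return state


def _lhe_interaction(A: np.ndarray, poly, op) -> np.ndarray:
    coeff_fields = interaction_coeffs(A, poly)
    S = np.zeros_like(A)
    power = np.ones_like(A)
    for i in range(coeff_fields.shape[0]):
        S += coeff_fields[i] * op(power)
        power = power * A
    return S


def default_contrast_poly(cfg: ModelConfig, state: EvolutionState) -> PolyCoefficients:
    """Fit the contrast sigmoid on an a-priori bound of the contrast range.

    Under dt <= 1/(1+lambda) the explicit scheme keeps iterates within
    B = max(||A0||_inf, (lambda ||A0||_inf + ||U||_inf + 1.2/(2M)) / (1+lambda)),
    so contrasts stay in [-2B, 2B]; the fit domain adds a 20% margin.  This
    is the "rescale contrasts to [-1, 1]" normalisation expressed in the
    activation's own units.
    """
    a0_max = float(np.max(np.abs(state.A0)))
    u_max = float(np.max(np.abs(state.U)))
    bound = max(a0_max, (cfg.lam * a0_max + u_max + 1.2 / (2 * cfg.M)) / (1.0 + cfg.lam))
    R = max(2.4 * bound, 1e-6)
    return fit_sigma_hat_poly(cfg.alpha, cfg.poly_degree, R)


# ---------------------------------------------------------------------------
# energy


def lhe_energy(A: np.ndarray, A0: np.ndarray, U: np.ndarray, cfg: ModelConfig,
               kernel: np.ndarray, primitive=None) -> float:
    """LHE Lyapunov energy with the dense pairwise kernel (small grids).

    E = lambda/2 sum |A - A0|^2 + 1/2 sum |A - U|^2
        - 1/(4M) sum_{xi, eta} k_tau(xi, eta) Sigma(A(xi) - A(eta)),

    where Sigma is the even primitive of sigma_hat
    (:func:`sigma_hat_primitive` by default).  The explicit update is exactly
    gradient descent on this functional: symmetrising the double sum over the
    symmetric kernel turns the -1/(4M) factor into the +1/(2M) interaction of
    the flow.  ``kernel`` is the (N^2 K) x (N^2 K) matrix from
    :func:`srheat.dense_heat_kernel`, flattened in [k, i, j] order.
    """
    if primitive is None:
        primitive = lambda r: sigma_hat_primitive(r, cfg.alpha)
    flat = np.asarray(A, dtype=float).transpose(2, 0, 1).reshape(-1)
    fidelity = 0.5 * cfg.lam * float(np.sum((A - A0) ** 2))
    mean_term = 0.5 * float(np.sum((A - U) ** 2))
    contrast = flat[:, None] - flat[None, :]
    pairwise = float(np.sum(kernel * primitive(contrast)))
    return fidelity + mean_term - pairwise / (4.0 * cfg.M)


def lhe_energy_estimate(state: EvolutionState, cfg: ModelConfig, op,
                        poly: PolyCoefficients) -> float:
    """Kernel-free energy estimate for large grids.

    Replaces Sigma by the primitive of the fitted polynomial and evaluates
    the pairwise term through the same binomial-expansion trick as the flow
    (n + 2 kernel applications), avoiding the dense kernel.
    """
    prim_coeffs = _poly_primitive(poly.coeffs)
    coeff_fields = interaction_coeffs(state.A, prim_coeffs)
    pairwise = 0.0
    power = np.ones_like(state.A)
    for i in range(coeff_fields.shape[0]):
        pairwise += float(np.sum(coeff_fields[i] * op(power)))
        power = power * state.A
    fidelity = 0.5 * cfg.lam * float(np.sum((state.A - state.A0) ** 2))
    mean_term = 0.5 * float(np.sum((state.A - state.U) ** 2))
    return fidelity + mean_term - pairwise / (4.0 * cfg.M)


# ---------------------------------------------------------------------------
# full pipeline


def evolve(image: np.ndarray, cfg: ModelConfig, bank: lifting.CakeWaveletBank,
           log_energy: bool = False, log_every: int = 10,
           callback=None) -> EvolutionResult:
    """Lift an image, run the configured mean-field flow, and project back.

    Iterates until the relative residual drops below ``cfg.tol`` or
    ``cfg.max_iters`` steps are reached; aborts with a diagnostic if the
    residual grows over 100 consecutive iterations.  The returned output
    field is the plain orientation sum, not renormalised (display
    normalisation is a separate, output-time concern).
    """
    image = np.asarray(image, dtype=float)
    A0 = lifting.lift(image, bank)
    U = local_mean(A0, cfg.sigma_mu)
    state = EvolutionState(A=A0.copy(), A0=A0, U=U)
    n, _, K = A0.shape
    op = build_interaction_operator(cfg, n, K)
    poly = default_contrast_poly(cfg, state) if cfg.model == "lhe" else None

    diagnostics = []
    growth_streak = 0
    t0 = time.perf_counter()
    for _ in range(cfg.max_iters):
        if cfg.model == "wc":
            wc_step(state, cfg, op)
        else:
            lhe_step(state, cfg, op, poly)
        res = state.residuals[-1]
        entry = {
            "iteration": state.p,
            "residual": res,
            "walltime": time.perf_counter() - t0,
        }
        if log_energy and cfg.model == "lhe" and (state.p % log_every == 0 or state.p == 1):
            energy = lhe_energy_estimate(state, cfg, op, poly)
            state.energies.append(energy)
            entry["energy"] = energy
        diagnostics.append(entry)
        if callback is not None:
            callback(state)
        if not np.isfinite(res):
            raise RuntimeError(
                f"divergence: non-finite residual at iteration {state.p}"
            )
        if len(state.residuals) >= 2 and res > state.residuals[-2]:
            growth_streak += 1
            if growth_streak >= 100:
                raise RuntimeError(
                    f"divergence: residual grew over 100 consecutive iterations "
                    f"(iteration {state.p}, residual {res:.3e})"
                )
        else:
            growth_streak = 0
        if res < cfg.tol:
            break

    output = lifting.project(state.A)
    return EvolutionResult(output=output, activation=state.A, state=state,
                           diagnostics=diagnostics)


def normalise01(image: np.ndarray) -> np.ndarray:
    """Min-max renormalisation to [0, 1] for display; constant fields map to 0."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi - lo < 1e-300:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)
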