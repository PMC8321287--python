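"""Invertible lifting of 2D images to the position-orientation space R^2 x P^1.

Simple cells in V1 respond selectively to local orientation: an image
``f : Q -> R`` is represented as an *orientation score*
``a0(x, y, theta_k) = <f, psi_{x,y,theta_k}>`` obtained by filtering with a
bank of orientation-selective *cake wavelets*.  Each wavelet is an angular
"cake slice" of the 2D Fourier plane with a B-spline angular profile and an
all-scale (flat) radial profile; each slice is combined with its antipodal
slice, since orientations live on the projective line P^1 = [0, pi).

Because the slices form an exact partition of unity in the frequency domain,
summing the score over orientations recovers the image exactly: the lifting
is invertible by plain summation, which is the discrete counterpart of the
reconstruction integral over theta.

Filtering is carried out in the DFT domain, which implies periodic spatial
boundary conditions (consistent with the FFT-based heat solver); stimuli
should keep their content away from the image borders.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "CakeWaveletBank",
    "build_cake_bank",
    "lift",
    "project",
    "orientation_grid",
    "save_activation",
    "load_activation",
]


def orientation_grid(K: int) -> np.ndarray:
    """Orientation samples theta_k = k * pi / K for k = 1..K."""
    return np.arange(1, K + 1) * np.pi / K


@dataclasses.dataclass(frozen=True)
class CakeWaveletBank:
    """K orientation-selective filters given on the N x N DFT frequency grid.

    ``frequency_responses[k]`` is the (real) transfer function of slice k,
    centred on orientations around ``theta_k = k * pi / K``.  The responses
    sum to 1 at every frequency (the zero frequency is apportioned according
    to ``dc_policy``), which makes ``project(lift(f)) == f`` exact.
    """

    K: int
    N: int
    bw: int
    dc_policy: str
    frequency_responses: np.ndarray  # shape (K, N, N), real

    @property
    def thetas(self) -> np.ndarray:
        return orientation_grid(self.K)

    def partition_defect(self) -> float:
        """max over frequencies of |sum_k response_k - 1|."""
        return float(np.max(np.abs(self.frequency_responses.sum(axis=0) - 1.0)))


def _cardinal_bspline(order: int):
    """Centred cardinal B-spline of the given order (degree), zero outside
    its support [-(order+1)/2, (order+1)/2]."""
    b = BSpline.basis_element(np.arange(order + 2, dtype=float), extrapolate=False)
    half = (order + 1) / 2.0

    def evaluate(x):
        y = b(np.asarray(x, dtype=float) + half)
        return np.nan_to_num(y, nan=0.0)

    return evaluate


def build_cake_bank(N: int, K: int, bw: int = 5, dc_policy: str = "uniform") -> CakeWaveletBank:
    """Construct the all-scale cake-wavelet bank.

    Parameters
    ----------
    N:
        Spatial size (images are N x N).
    K:
        Number of orientations on [0, pi).
    bw:
        Order of the angular B-spline profile ("frequency band").  Higher
        orders give smoother, more overlapping slices; the partition of unity
        is exact for every order by the B-spline refinement property.
    dc_policy:
        How the zero-frequency (DC) component is apportioned; ``"uniform"``
        splits it as 1/K per slice so constant images lift to
        orientation-uniform activations.
    """
    if N < 4:
        raise ValueError(f"N must be >= 4, got {N}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if bw < 1:
        raise ValueError(f"bw must be >= 1, got {bw}")
    if dc_policy != "uniform":
        raise ValueError(f"unknown dc_policy {dc_policy!r}")
    if K > N:
        warnings.warn(
            f"K={K} exceeds N={N}: angular resolution exceeds spatial bandwidth",
            stacklevel=2,
        )

    spline = _cardinal_bspline(bw)
    dtheta = np.pi / K  # angular slice width on the (2K-slice) full circle

    fy = np.fft.fftfreq(N)[:, None]
    fx = np.fft.fftfreq(N)[None, :]
    phi = np.arctan2(fy, fx)

    # periodicised angular profile: wraps needed when the spline support
    # (bw+1 slices) exceeds the circle
    n_wraps = int(np.ceil((bw + 1) / 2.0 * dtheta / (2 * np.pi))) + 1
    wraps = 2 * np.pi * np.arange(-n_wraps, n_wraps + 1)

    def angular_profile(delta):
        d = (delta + np.pi) % (2 * np.pi) - np.pi
        return sum(spline((d + w) / dtheta) for w in wraps)

    thetas = orientation_grid(K)
    responses = np.empty((K, N, N), dtype=float)
    for k, theta in enumerate(thetas):
        # slice k responds to structures *oriented* along theta, whose
        # spectral energy lies along the normal direction theta + pi/2
        centre = theta + np.pi / 2
        responses[k] = angular_profile(phi - centre) + angular_profile(phi - centre - np.pi)

    # enforce exact symmetry under frequency negation: away from the Nyquist
    # lines this is a no-op (antipodal grid points carry antipodal angles),
    # on them it resolves the +/- Nyquist ambiguity so each slice response is
    # Hermitian and the per-slice filter output is exactly real
    flip = (-np.arange(N)) % N
    responses = 0.5 * (responses + responses[:, flip][:, :, flip])
    responses[:, 0, 0] = 1.0 / K  # DC split per policy
    return CakeWaveletBank(K=K, N=N, bw=bw, dc_policy=dc_policy, frequency_responses=responses)


def lift(image: np.ndarray, bank: CakeWaveletBank) -> np.ndarray:
    """Lift a 2D image to an N x N x K orientation score.

    ``A0[..., k]`` is the real part of the inverse DFT of the image spectrum
    multiplied by slice k's transfer function.  The antipodal symmetrisation
    of the slices makes each response Hermitian, so the discarded imaginary
    part is pure round-off.  The operation is linear in the image.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (bank.N, bank.N):
        raise ValueError(
            f"image shape {image.shape} does not match bank size ({bank.N}, {bank.N})"
        )
    spectrum = np.fft.fft2(image)
    out = np.empty((bank.N, bank.N, bank.K), dtype=float)
    for k in range(bank.K):
        out[:, :, k] = np.fft.ifft2(spectrum * bank.frequency_responses[k]).real
    return out


def project(activation: np.ndarray) -> np.ndarray:
    """Sum the orientation score over slices, recovering an image-plane field.

    The bank is normalised so that the slices sum to one, absorbing the
    angular measure; hence the plain sum over k is the discrete
    reconstruction integral and ``project(lift(f)) == f`` to round-off.
    The result is not clamped to [0, 1].
    """
    activation = np.asarray(activation, dtype=float)
    return activation.sum(axis=-1)


def save_activation(path, activation: np.ndarray, bank: CakeWaveletBank | None = None,
                    source_image: np.ndarray | None = None) -> None:
    """Persist an activation stack as HDF5 dataset ``/activation``."""
    import h5py

    activation = np.asarray(activation)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("activation", data=activation)
        ds.attrs["K"] = activation.shape[-1]
        if bank is not None:
            ds.attrs["bw"] = bank.bw
            ds.attrs["dc_policy"] = bank.dc_policy
        if source_image is not None:
            digest = hashlib.sha256(
                np.ascontiguousarray(source_image, dtype=float).tobytes()
            ).hexdigest()
            ds.attrs["source_image_hash"] = digest


def load_activation(path) -> tuple[np.ndarray, dict]:
    """Load an activation stack and its attributes from HDF5."""
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["activation"]
        return ds[()], dict(ds.attrs)
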