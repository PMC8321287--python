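"""Poggendorff-type grey-scale test stimuli.

The classical Poggendorff figure is an oblique transversal interrupted by a
vertical occluding bar: the collinear continuation on the far side of the bar
is perceived as misaligned.  The grating variant replaces the single
transversal by a family of parallel oblique stripes, so that the perceived
bias also depends on the contrast between the bar and the background lines.

All images are generated deterministically on the integer pixel grid with
anti-aliasing off, so the set of grey values is exactly
``{grey_background, grey_bar, grey_line}`` and geometric invariants can be
asserted exactly.

Coordinate convention: x rightward (columns), y downward (rows), origin at
the top-left pixel centre.  The incidence angle ``phi`` is measured between
the oblique lines and the vertical bar; lines ascend to the right, i.e. their
direction vector is ``(sin phi, -cos phi)`` in (x, y-down) coordinates.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "StimulusSpec",
    "make_poggendorff",
    "make_poggendorff_grating",
    "make_stimulus",
    "grating_line_crossings",
]

_VARIANTS = ("classical", "grating")


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a Poggendorff-type stimulus.

    Attributes
    ----------
    size:
        Image side length N in pixels (the image is N x N).
    bar_width:
        Width w of the central vertical occluding bar, in pixels.
    incidence_angle:
        Angle phi in (0, pi/2) between the oblique lines and the vertical
        bar, in radians.
    line_thickness:
        Stroke thickness of the oblique lines in pixels; pixels whose centre
        lies within ``thickness / 2`` of the ideal line are painted.  A value
        of 0 draws no lines.
    grating_spacing:
        Perpendicular distance between consecutive stripes (grating variant).
    grey_background, grey_bar, grey_line:
        Intensities in [0, 1]; must be pairwise distinct.
    variant:
        ``"classical"`` or ``"grating"``.
    misalignment_offset:
        Vertical offset (pixels, downward) of the second, non-collinear
        right-hand segment of the classical figure.  ``None`` selects the
        default ``w / (2 tan phi)``.
    """

    size: int = 200
    bar_width: int = 30
    incidence_angle: float = math.pi / 3
    line_thickness: float = 2.0
    grating_spacing: float = 24.0
    grey_background: float = 1.0
    grey_bar: float = 0.5
    grey_line: float = 0.0
    variant: str = "classical"
    misalignment_offset: float | None = None

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ValueError(f"size must be >= 4, got {self.size}")
        if not 0 <= self.bar_width < self.size:
            raise ValueError(
                f"bar_width must satisfy 0 <= w < N, got w={self.bar_width}, N={self.size}"
            )
        if not 0.0 < self.incidence_angle < math.pi / 2:
            raise ValueError(
                f"incidence_angle must lie in (0, pi/2), got {self.incidence_angle}"
            )
        greys = (self.grey_background, self.grey_bar, self.grey_line)
        if not all(0.0 <= g <= 1.0 for g in greys):
            raise ValueError(f"grey levels must lie in [0, 1], got {greys}")
        if len(set(greys)) != 3:
            raise ValueError(f"grey levels must be pairwise distinct, got {greys}")
        if self.line_thickness < 0:
            raise ValueError("line_thickness must be >= 0")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.variant == "grating" and self.grating_spacing <= self.line_thickness:
            raise ValueError(
                "grating_spacing must exceed line_thickness "
                f"(got spacing={self.grating_spacing}, thickness={self.line_thickness})"
            )

    @property
    def offset(self) -> float:
        """Vertical offset of the misaligned right-hand segment (pixels)."""
        if self.misalignment_offset is not None:
            return self.misalignment_offset
        return self.bar_width * math.tan(math.pi / 2 - self.incidence_angle) / 2

    @property
    def bar_first_column(self) -> int:
        return (self.size - self.bar_width) // 2

    @property
    def bar_columns(self) -> slice:
        c0 = self.bar_first_column
        return slice(c0, c0 + self.bar_width)


def _pixel_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return xx, yy


def _line_distance(xx, yy, x0, y0, phi):
    # perpendicular distance to the infinite line through (x0, y0) with
    # direction (sin phi, -cos phi); the normal is (cos phi, sin phi)
    return np.abs((xx - x0) * math.cos(phi) + (yy - y0) * math.sin(phi))


def make_poggendorff(spec: StimulusSpec) -> np.ndarray:
    """Render the classical Poggendorff stimulus.

    A left oblique segment meets the occluding bar; on the right, both the
    collinear continuation and a vertically offset (misaligned) segment are
    drawn.  The portion of every line inside the bar is absent.
    """
    if spec.variant != "classical":
        raise ValueError("make_poggendorff requires variant='classical'")
    n = spec.size
    img = np.full((n, n), spec.grey_background, dtype=float)
    xx, yy = _pixel_grid(n)
    cx = cy = (n - 1) / 2.0
    phi = spec.incidence_angle
    t = spec.line_thickness

    c0 = spec.bar_first_column
    right_start = c0 + spec.bar_width

    if t > 0:
        half = t / 2.0
        d_main = _line_distance(xx, yy, cx, cy, phi)
        d_shift = _line_distance(xx, yy, cx, cy + spec.offset, phi)
        left = (d_main <= half) & (xx < c0)
        right_collinear = (d_main <= half) & (xx >= right_start)
        right_misaligned = (d_shift <= half) & (xx >= right_start)
        img[left | right_collinear | right_misaligned] = spec.grey_line

    if spec.bar_width > 0:
        img[:, spec.bar_columns] = spec.grey_bar
    return img


def make_poggendorff_grating(spec: StimulusSpec) -> np.ndarray:
    """Render the Poggendorff grating stimulus.

    Parallel oblique stripes (one global line family, anchored so that one
    stripe passes through the image centre) are interrupted by the central
    vertical bar; the true continuations across the bar are collinear by
    construction.
    """
    if spec.variant != "grating":
        raise ValueError("make_poggendorff_grating requires variant='grating'")
    n = spec.size
    img = np.full((n, n), spec.grey_background, dtype=float)
    xx, yy = _pixel_grid(n)
    cx = cy = (n - 1) / 2.0
    phi = spec.incidence_angle
    t = spec.line_thickness
    s = spec.grating_spacing

    if t > 0:
        # signed distance along the stripe normal, folded to the nearest stripe
        proj = (xx - cx) * math.cos(phi) + (yy - cy) * math.sin(phi)
        folded = (proj + s / 2.0) % s - s / 2.0
        img[np.abs(folded) <= t / 2.0] = spec.grey_line

    if spec.bar_width > 0:
        img[:, spec.bar_columns] = spec.grey_bar
    return img


def make_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Dispatch on ``spec.variant``."""
    if spec.variant == "classical":
        return make_poggendorff(spec)
    return make_poggendorff_grating(spec)


def grating_line_crossings(spec: StimulusSpec, row: int) -> np.ndarray:
    """x-coordinates where stripe centre lines of the grating cross ``row``.

    Enumerates the generator's own line family n.(p - c) = j * spacing with
    normal n = (cos phi, sin phi); used to predict stripe counts per row.
    """
    n = spec.size
    cx = cy = (n - 1) / 2.0
    phi = spec.incidence_angle
    s = spec.grating_spacing
    # cos(phi)*(x-cx) + sin(phi)*(row-cy) = j*s
    b = math.sin(phi) * (row - cy)
    jmax = int(math.ceil((n * math.cos(phi) + abs(b)) / s)) + 1
    js = np.arange(-jmax, jmax + 1)
    x = cx + (js * s - b) / math.cos(phi)
    return np.sort(x[(x >= 0) & (x <= n - 1)])
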