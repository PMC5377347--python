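"""Synthetic pure-phase test objects (phantoms).

Two phantom families are provided, mirroring the objects used in
fluence-resolution studies of lensless X-ray imaging:

* a random binary **bitmap** with phase values {0, -1} rad, each bit
  rendered as a ``block_size x block_size`` block of image pixels;
* a procedural **cell** phantom: two adhering smooth cell bodies with
  internal compartments and a scattering of small high-contrast dots,
  phases in ``[max_phase, 0]`` rad.

Both are embedded centrally in a larger grid (default 512x512 object in a
1024x1024 frame) so that the simulated numerical aperture supports
pixel-level detail.  The phase map is the ground truth of every numerical
experiment; the support mask is the region assumed known a priori during
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "Phantom",
    "make_bitmap_phantom",
    "make_cell_phantom",
    "make_support",
]

PhantomKind = Literal["cell", "bitmap"]


@dataclass(frozen=True)
class Phantom:
    """A pure-phase object and its known support.

    Attributes
    ----------
    phase
        Real phase map in radians, shape ``(ny, nx)``.  Zero outside the
        support; in ``[-1, 0]`` (cell) or ``{0, -1}`` (bitmap) inside.
    support
        Boolean mask of the region known to contain the object.
    kind
        ``"cell"`` or ``"bitmap"``.
    block_size
        Rendered size of one bitmap bit in image pixels (bitmap only).
    bit_values
        The two phase levels of a bitmap phantom.
    seed
        Seed the generator was called with (reproducibility record).
    """

    phase: np.ndarray
    support: np.ndarray
    kind: PhantomKind
    seed: int
    block_size: int = 1
    bit_values: tuple[float, float] = (0.0, -1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        support = np.asarray(self.support, dtype=bool)
        if phase.ndim != 2 or phase.shape != support.shape:
            raise ValueError("phase and support must be 2-D arrays of equal shape")
        if np.any(phase[~support] != 0.0):
            raise ValueError("phase must be exactly 0 outside the support")
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "support", support)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def with_support(self, support: np.ndarray) -> "Phantom":
        return replace(self, support=np.asarray(support, dtype=bool))


def _centered_slices(grid_shape: tuple[int, int], obj_shape: tuple[int, int]):
    """Slices placing an object of ``obj_shape`` at the center of the grid."""
    out = []
    for n_grid, n_obj in zip(grid_shape, obj_shape):
        start = (n_grid - n_obj) // 2
        out.append(slice(start, start + n_obj))
    return tuple(out)


def make_bitmap_phantom(
    n_bits_x: int = 51,
    n_bits_y: int | None = None,
    block_size: int = 10,
    grid_size: int = 1024,
    fill_prob: float = 0.5,
    seed: int = 0,
    bit_values: tuple[float, float] = (0.0, -1.0),
) -> Phantom:
    """Generate a random binary bitmap phantom.

    Each of the ``n_bits_y x n_bits_x`` bits is drawn i.i.d.
    Bernoulli(``fill_prob``); a set bit takes phase ``bit_values[1]``
    (default -1 rad), an unset bit ``bit_values[0]`` (default 0).  Bits are
    rendered as ``block_size x block_size`` pixel blocks and the whole
    bitmap is centered in a ``grid_size x grid_size`` frame.  The support
    is the full rectangular bitmap region.

    The default 51x51 bits with 10-px blocks give a 510x510 object inside
    a 1024x1024 grid, i.e. the object occupies (just under) the central
    half of the frame in each dimension.
    """
    if n_bits_y is None:
        n_bits_y = n_bits_x
    if n_bits_x <= 0 or n_bits_y <= 0 or block_size <= 0 or grid_size <= 0:
        raise ValueError("sizes must be positive")
    if not 0.0 <= fill_prob <= 1.0:
        raise ValueError(f"fill_prob must be a probability, got {fill_prob}")
    obj_ny = n_bits_y * block_size
    obj_nx = n_bits_x * block_size
    if obj_nx > grid_size // 2 or obj_ny > grid_size // 2:
        raise ValueError(
            f"bitmap object ({obj_ny}x{obj_nx}) exceeds the central half of the "
            f"{grid_size}x{grid_size} grid; enlarge the grid or shrink the bitmap"
        )

    rng = np.random.default_rng(seed)
    bits = rng.random((n_bits_y, n_bits_x)) < fill_prob
    lo, hi = bit_values
    bitmap = np.where(bits, hi, lo)
    rendered = np.kron(bitmap, np.ones((block_size, block_size)))

    phase = np.zeros((grid_size, grid_size))
    support = np.zeros((grid_size, grid_size), dtype=bool)
    sl = _centered_slices(phase.shape, rendered.shape)
    phase[sl] = rendered
    support[sl] = True
    return Phantom(
        phase=phase,
        support=support,
        kind="bitmap",
        seed=seed,
        block_size=block_size,
        bit_values=(float(lo), float(hi)),
        meta={
            "n_bits_x": n_bits_x,
            "n_bits_y": n_bits_y,
            "fill_prob": fill_prob,
            "grid_size": grid_size,
        },
    )


def make_cell_phantom(
    grid_size: int = 1024,
    max_phase: float = -1.0,
    seed: int = 0,
    n_compartments: tuple[int, int] = (5, 10),
    n_dots: tuple[int, int] = (20, 40),
) -> Phantom:
    """Generate a procedural two-cell phantom.

    Emulates the statistical character of a phase map of two adhering
    biological cells: two overlapping smooth elliptical bodies of moderate
    phase shift, each containing a handful of denser elliptical
    compartments (organelles), plus 20-40 small (2-4 px) dots at nearly
    the maximum phase shift, standing in for fine intracellular structure.
    Phases are continuous in ``[max_phase, 0]`` rad and the object is
    confined to the central ``grid_size/2`` square.

    Parameters
    ----------
    max_phase
        Most negative phase shift, in radians; must lie in ``[-pi, 0]``.
        The default -1 rad is a deliberately exaggerated contrast for a
        biological cell at multi-keV photon energies.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    if not -np.pi <= max_phase <= 0.0:
        raise ValueError(f"max_phase must lie in [-pi, 0], got {max_phase}")

    rng = np.random.default_rng(seed)
    half = grid_size // 2
    # Build the object on the central half-grid, then embed.
    yy, xx = np.mgrid[0:half, 0:half].astype(float)

    def ellipse(cx, cy, ax_, ay_, angle, edge):
        """Smooth (tanh-edged) ellipse indicator in [0, 1]."""
        c, s = np.cos(angle), np.sin(angle)
        xr = (xx - cx) * c + (yy - cy) * s
        yr = -(xx - cx) * s + (yy - cy) * c
        r = np.sqrt((xr / ax_) ** 2 + (yr / ay_) ** 2)
        return 0.5 * (1.0 - np.tanh((r - 1.0) / edge))

    u = np.zeros((half, half))  # phase *depth* in [0, 1]; phase = max_phase * u

    # Two adhering cell bodies, side by side with overlap.
    body_masks = []
    for k, cx_frac in enumerate((0.36, 0.64)):
        cx = half * cx_frac + rng.uniform(-0.02, 0.02) * half
        cy = half * 0.5 + rng.uniform(-0.05, 0.05) * half
        ax_ = half * rng.uniform(0.20, 0.26)
        ay_ = half * rng.uniform(0.26, 0.34)
        angle = rng.uniform(-0.4, 0.4)
        body = ellipse(cx, cy, ax_, ay_, angle, edge=0.06)
        body_masks.append((body, cx, cy, ax_, ay_, angle))
        u = np.maximum(u, 0.35 * body)

    # Internal compartments: denser elliptical inclusions inside each body.
    n_comp = rng.integers(n_compartments[0], n_compartments[1] + 1)
    for _ in range(n_comp):
        body, cx, cy, ax_, ay_, angle = body_masks[rng.integers(len(body_masks))]
        # place inside the body (rejection-free: sample in body frame)
        rho = rng.uniform(0.0, 0.55)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(angle), np.sin(angle)
        dx, dy = rho * ax_ * np.cos(theta), rho * ay_ * np.sin(theta)
        ccx, ccy = cx + dx * c - dy * s, cy + dx * s + dy * c
        comp = ellipse(
            ccx, ccy,
            ax_ * rng.uniform(0.10, 0.25), ay_ * rng.uniform(0.10, 0.25),
            rng.uniform(0, np.pi), edge=0.15,
        )
        u = np.maximum(u, (0.35 + rng.uniform(0.15, 0.4)) * comp * (body > 0.5))

    # Smooth the large-scale structure a little (membranes are not razor sharp).
    u = ndimage.gaussian_filter(u, sigma=1.5)

    # Fine structure: small dots at near-maximal depth, inside the bodies.
    any_body = np.zeros_like(u, dtype=bool)
    for body, *_ in body_masks:
        any_body |= body > 0.5
    nd = rng.integers(n_dots[0], n_dots[1] + 1)
    inside = np.argwhere(any_body)
    if len(inside):
        picks = inside[rng.integers(len(inside), size=nd)]
        dots = np.zeros_like(u)
        for (iy, ix) in picks:
            r = rng.uniform(1.0, 2.0)  # radius 1-2 px -> 2-4 px diameter
            y0, y1 = int(max(iy - 4, 0)), int(min(iy + 5, half))
            x0, x1 = int(max(ix - 4, 0)), int(min(ix + 5, half))
            py, px = np.mgrid[y0:y1, x0:x1]
            d2 = (py - iy) ** 2 + (px - ix) ** 2
            dots[y0:y1, x0:x1] = np.maximum(
                dots[y0:y1, x0:x1], np.exp(-d2 / (2 * (r / 1.7) ** 2))
            )
        u = np.maximum(u, 0.97 * dots * any_body)

    u = np.clip(u, 0.0, 1.0)
    u[u < 1e-3] = 0.0  # cut smoothing tails: keep the object compactly supported
    obj_phase = max_phase * u

    phase = np.zeros((grid_size, grid_size))
    sl = _centered_slices(phase.shape, obj_phase.shape)
    phase[sl] = obj_phase
    return Phantom(
        phase=phase, support=phase != 0.0, kind="cell", seed=seed,
        meta={"grid_size": grid_size, "max_phase": max_phase},
    )


def make_support(phantom: Phantom, dilation_px: int = 5, tight: bool = False) -> np.ndarray:
    """Reconstruction support mask for a phantom.

    For a bitmap the base region is the bounding rectangle of the bitmap
    (or, with ``tight=True``, the exact set-pixel region); for a cell it
    is the nonzero-phase region.  The base is dilated by ``dilation_px``
    (binary dilation, 8-connected), modelling a support known to surround
    the object with a margin.

    Note that far-field (CDI) data do not pin the object's position or
    orientation: any margin around the object, and for a two-level phase
    bitmap even the centrosymmetric bounding rectangle, admits exactly
    degenerate shifted/inverted solutions.  Reconstructions therefore use
    the tight, zero-margin support by default (see
    :func:`reconstruction_support`); the dilated masks exist for
    sensitivity studies.
    """
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    if phantom.kind == "bitmap" and not tight:
        base = np.zeros(phantom.shape, dtype=bool)
        nz = np.argwhere(phantom.support)
        (y0, x0), (y1, x1) = nz.min(axis=0), nz.max(axis=0)
        base[y0 : y1 + 1, x0 : x1 + 1] = True
    else:
        base = phantom.phase != 0.0
    if dilation_px == 0:
        return base
    structure = np.ones((3, 3), dtype=bool)
    return ndimage.binary_dilation(base, structure=structure, iterations=dilation_px)


def reconstruction_support(phantom: Phantom) -> np.ndarray:
    """Default support prior handed to the phase-retrieval algorithm.

    The exact nonzero-phase region ("perfectly known" support, no
    margin).  A margin would leave translated — and, for the bitmap's
    symmetric rectangle, inverted — objects exactly consistent with
    far-field moduli, making the CDI problem non-unique.  Falls back to
    the phantom's stored support for degenerate (all-zero) phantoms.
    """
    tight = phantom.phase != 0.0
    return tight if tight.any() else phantom.support
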