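"""Wave-optical propagation in dimensionless (pixel / Fresnel-number) units.

The exit wave of a pure-phase object under unit plane-wave illumination is
``psi = exp(i * phi)``.  Two detection regimes are modelled:

* **NFH** (near-field inline holography): free-space Fresnel propagation
  over an effective distance parameterized by the per-pixel Fresnel number
  ``Fr = dx^2 / (lambda * z_eff)``.  The propagator multiplies the
  centered spectrum by the quadratic-phase kernel
  ``H(nu) = exp(-i * pi * (nu_x^2 + nu_y^2) / Fr)`` with
  ``nu = n/N in [-1/2, 1/2)`` cycles/pixel.
* **CDI** (far-field coherent diffractive imaging): a centered unitary
  2-D discrete Fourier transform.

Both operators are unitary, so total power ``sum |psi|^2`` is conserved
and photon bookkeeping is convention-free.  All spectra use the centered
(zero frequency at the array center) layout.

A grid of side ``N`` resolves detail down to the single-pixel level only
if the simulated numerical aperture is large enough, which translates to
``Fr >= 1/N`` (see :func:`na_requirement`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.fft as sfft

from .phantoms import Phantom

__all__ = [
    "Regime",
    "ComplexField",
    "OpticsConfig",
    "exit_wave",
    "fresnel_propagate",
    "farfield_propagate",
    "propagate",
    "na_requirement",
    "fresnel_kernel",
]

Regime = Literal["nfh", "cdi"]
Plane = Literal["object", "detector"]


@dataclass(frozen=True)
class ComplexField:
    """A 2-D complex wavefield tagged with its plane and imaging regime."""

    values: np.ndarray
    plane: Plane = "object"
    regime: Regime | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("field must be 2-D")
        if not np.iscomplexobj(v):
            v = v.astype(complex)
        if not np.all(np.isfinite(v)):
            raise ValueError("field contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def power(self) -> float:
        """Total power sum |psi|^2."""
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass(frozen=True)
class OpticsConfig:
    """Simulation geometry: per-pixel Fresnel number and grid size."""

    fresnel_number: float = 1e-3
    nx: int = 1024
    ny: int = 1024

    def __post_init__(self) -> None:
        if self.fresnel_number <= 0:
            raise ValueError("fresnel_number must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid sides must be positive")

    @property
    def na_sufficient(self) -> bool:
        return na_requirement(self.fresnel_number, min(self.nx, self.ny))


def exit_wave(phantom: Phantom, dtype=np.complex128) -> ComplexField:
    """Exit wave of a pure-phase object: ``psi = exp(i * phi)``.

    Perfect unit-amplitude plane-wave illumination is assumed, so the
    modulus is 1 everywhere and the total power equals the pixel count.
    """
    psi = np.exp(1j * phantom.phase).astype(dtype)
    return ComplexField(values=psi, plane="object")


def fresnel_kernel(
    shape: tuple[int, int], fresnel_number: float, *, centered: bool = True,
    dtype=np.complex128,
) -> np.ndarray:
    """Fresnel transfer function ``exp(-i pi (nu_x^2+nu_y^2)/Fr)``.

    ``centered=True`` samples nu on the fftshift-ed grid ``(n - N/2)/N``
    (matching centered spectra); ``centered=False`` returns the same
    kernel in the unshifted FFT layout.
    """
    if fresnel_number <= 0:
        raise ValueError("fresnel_number must be positive")
    ny, nx = shape
    fy = sfft.fftfreq(ny)
    fx = sfft.fftfreq(nx)
    if centered:
        fy = sfft.fftshift(fy)
        fx = sfft.fftshift(fx)
    nu2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-1j * np.pi * nu2 / fresnel_number).astype(dtype)


def _cfft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT (zero frequency at the array center)."""
    return sfft.fftshift(sfft.fft2(sfft.ifftshift(x), norm="ortho"))


def _icfft2(x: np.ndarray) -> np.ndarray:
    return sfft.fftshift(sfft.ifft2(sfft.ifftshift(x), norm="ortho"))


def fresnel_propagate(
    field: ComplexField, fresnel_number: float, inverse: bool = False
) -> ComplexField:
    """Propagate a field by the (unitary) discrete Fresnel propagator.

    The centered spectrum is multiplied by the quadratic-phase kernel and
    transformed back; ``inverse=True`` conjugates the kernel,
    back-propagating to the object plane.
    """
    kern = fresnel_kernel(field.shape, fresnel_number, centered=True,
                          dtype=np.result_type(field.values, np.complex64))
    if inverse:
        kern = np.conj(kern)
    out = _icfft2(_cfft2(field.values) * kern)
    return ComplexField(
        values=out,
        plane="object" if inverse else "detector",
        regime="nfh",
    )


def farfield_propagate(field: ComplexField, inverse: bool = False) -> ComplexField:
    """Centered unitary 2-D DFT (forward) or its inverse: the far-field map."""
    out = _icfft2(field.values) if inverse else _cfft2(field.values)
    return ComplexField(
        values=out,
        plane="object" if inverse else "detector",
        regime="cdi",
    )


def propagate(
    field: ComplexField,
    regime: Regime,
    fresnel_number: float | None = None,
    inverse: bool = False,
) -> ComplexField:
    """Dispatch to the regime's propagator (NFH: Fresnel, CDI: far field)."""
    if regime == "nfh":
        if fresnel_number is None:
            raise ValueError("NFH propagation requires a Fresnel number")
        return fresnel_propagate(field, fresnel_number, inverse=inverse)
    if regime == "cdi":
        return farfield_propagate(field, inverse=inverse)
    raise ValueError(f"unknown regime {regime!r}")


def na_requirement(fresnel_number: float, grid_side: int) -> bool:
    """Whether the simulated NA supports pixel-level resolution.

    Equating the NA resolution limit with the pixel size yields the
    requirement ``Fr >= 1/N`` for a grid of side ``N``.
    """
    if fresnel_number <= 0 or grid_side <= 0:
        raise ValueError("inputs must be positive")
    return fresnel_number >= 1.0 / grid_side
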