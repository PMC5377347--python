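"""Ideal intensities and Poisson photon-count measurements.

The fluence ``mu`` is the mean photon number per pixel in the *object*
plane — the study's sole noise-control parameter.  The measurement recipe
is: (i) propagate the exit wave to the detection plane, (ii) take
intensities and normalize them to unit sum, (iii) multiply by
``mu * N_x * N_y`` and draw per-pixel Poisson counts.  Because the
propagators are unitary, the expected total photon number equals
``mu * N_x * N_y`` in both regimes.

The detector is ideal: full numerical aperture, no beamstop, no point
spread, no read noise — Poisson counting is the only stochastic element.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .optics import ComplexField, Regime, exit_wave, propagate
from .phantoms import Phantom

__all__ = [
    "Measurement",
    "intensity",
    "normalize",
    "apply_poisson",
    "simulate_measurement",
]


@dataclass(frozen=True)
class Measurement:
    """A detector-plane intensity pattern, ideal or Poisson-sampled.

    ``counts`` is a non-negative real array: expected intensity when
    ``noisy`` is False, integer photon counts when True.  The centered
    spectral layout of the propagators is preserved, so CDI patterns have
    the zero-order (brightest) pixel at the array center.
    """

    counts: np.ndarray
    regime: Regime | None = None
    fluence: float | None = None
    noisy: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.noisy and not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("noisy counts must be integers")
        object.__setattr__(self, "counts", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> float:
        return float(self.counts.sum())


def intensity(field: ComplexField) -> Measurement:
    """Squared modulus of a detector-plane field: ``M = |D psi|^2``."""
    return Measurement(
        counts=np.abs(field.values) ** 2, regime=field.regime, noisy=False
    )


def normalize(measurement: Measurement) -> Measurement:
    """Normalize a measurement to unit total: ``M' = M / sum(M)``.

    This makes ``mu`` the mean photons per pixel after the subsequent
    scaling by ``mu * N_x * N_y``.  Idempotent.
    """
    total = measurement.counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero measurement")
    return replace(measurement, counts=measurement.counts / total)


def apply_poisson(
    normalized: Measurement, fluence: float, seed
) -> Measurement:
    """Draw per-pixel Poisson counts with mean ``mu * N_x * N_y * M'``.

    ``normalized`` must sum to 1 (see :func:`normalize`).  ``seed`` may be
    an int, a ``numpy.random.SeedSequence`` or a ``Generator``.
    """
    if fluence <= 0:
        raise ValueError("fluence must be positive")
    total = float(normalized.counts.sum())
    if not np.isclose(total, 1.0, rtol=1e-5):
        raise ValueError("apply_poisson expects a unit-sum (normalized) measurement")
    ny, nx = normalized.shape
    rng = np.random.default_rng(seed)
    # divide by the realized total so the expected grand total is exact
    lam = fluence * nx * ny * (np.asarray(normalized.counts, dtype=float) / total)
    counts = rng.poisson(lam)
    return Measurement(
        counts=counts,
        regime=normalized.regime,
        fluence=float(fluence),
        noisy=True,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def simulate_measurement(
    phantom: Phantom,
    regime: Regime,
    fresnel_number: float | None = None,
    fluence: float | None = None,
    seed=None,
    dtype=np.complex128,
) -> Measurement:
    """Full forward model: phantom -> propagate -> intensity [-> Poisson].

    With ``fluence=None`` the ideal (noiseless) intensity pattern is
    returned, scaled so that its total equals the exit-wave power
    ``N_x * N_y`` (exact for the unitary propagators).  With a fluence,
    the normalized pattern is Poisson-sampled at that object-plane
    photon density.
    """
    psi = exit_wave(phantom, dtype=dtype)
    det = propagate(psi, regime, fresnel_number=fresnel_number)
    m = intensity(det)
    m = replace(m, regime=regime)
    if fluence is None:
        return m
    return apply_poisson(normalize(m), fluence, seed)
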