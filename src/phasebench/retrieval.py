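"""RAAR iterative phase retrieval with support / pure-phase / binary constraints.

The relaxed averaged alternating reflections (RAAR) iteration is

    psi_{n+1} = (beta_n / 2) * (R_S R_M psi_n + psi_n) + (1 - beta_n) * P_M psi_n

with reflectors ``R_C = 2 P_C - I`` about the measurement set (``P_M``,
the magnitude projector through the regime's propagator) and the object
set (``P_S``, support + pure-phase, optionally composed with a binary
phase threshold).  The relaxation follows the cubic-exponential switch

    beta_n = beta_max + (beta_0 - beta_max) * exp(-(n / beta_s)^3),

decreasing from ``beta_0`` toward ``beta_max`` around iteration
``beta_s``.  Defaults: beta_0 = 0.99, beta_max = 0.75, beta_s = 150,
200 iterations.

The object constraint anchors gauge and position: outside the support the
exit wave is the known unit plane wave (1 + 0i); inside, the modulus is
set to 1 (pure phase object) and the phase is kept.  The evaluated output
is the object-plane field after the final *measurement* projection; the
field after the final object projection is also returned (the thresholded
experiments score that one).

Internally the iteration runs in the unshifted FFT layout (measurement,
support and Fresnel kernel are ifftshift-ed once before the loop), which
is exactly equivalent to composing the centered operators but avoids four
array shuffles per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Literal

import numpy as np
import scipy.fft as sfft

from .detector import Measurement
from .optics import ComplexField, Regime, fresnel_kernel, propagate

__all__ = [
    "RAARConfig",
    "ReconstructionResult",
    "beta_schedule",
    "project_magnitude",
    "project_object",
    "project_binary",
    "raar_step",
    "init_guess",
    "raar_run",
]

InitKind = Literal["flat", "random_phase"]


@dataclass(frozen=True)
class RAARConfig:
    """RAAR relaxation schedule, iteration count and constraint set."""

    beta0: float = 0.99
    beta_max: float = 0.75
    beta_switch: float = 150.0
    n_iter: int = 200
    init: InitKind | None = None  # None -> flat for NFH, random_phase for CDI
    phase_range: tuple[float, float] | None = (-1.0, 0.0)
    binary: bool = False
    binary_levels: tuple[float, float] = (0.0, -1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phase_range is not None:
            object.__setattr__(self, "phase_range", tuple(self.phase_range))
        object.__setattr__(self, "binary_levels", tuple(self.binary_levels))
        if not (0.0 < self.beta_max <= self.beta0 <= 1.0):
            raise ValueError(
                f"need 0 < beta_max <= beta0 <= 1, got beta0={self.beta0}, "
                f"beta_max={self.beta_max}"
            )
        if self.beta_switch <= 0:
            raise ValueError("beta_switch must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class ReconstructionResult:
    """Output of :func:`raar_run`."""

    field_after_pm: ComplexField
    field_after_ps: ComplexField
    betas: np.ndarray
    residuals: np.ndarray
    config: RAARConfig
    regime: Regime
    fresnel_number: float | None = None
    init_seed: int | None = None

    @property
    def phase_after_pm(self) -> np.ndarray:
        return np.angle(self.field_after_pm.values)

    @property
    def phase_after_ps(self) -> np.ndarray:
        return np.angle(self.field_after_ps.values)


def beta_schedule(n, config: RAARConfig) -> np.ndarray | float:
    """Relaxation parameter at iteration ``n`` (vectorized over ``n``).

    ``beta_n = beta_max + (beta0 - beta_max) * exp(-(n / beta_s)^3)``:
    monotonically non-increasing from ``beta0`` toward ``beta_max``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("iteration index must be >= 0")
    out = config.beta_max + (config.beta0 - config.beta_max) * np.exp(
        -((n / config.beta_switch) ** 3)
    )
    return float(out) if out.ndim == 0 else out


def _unit_phase(values: np.ndarray) -> np.ndarray:
    """``values / |values|`` with zero-modulus pixels mapped to 1 (phase 0)."""
    mod = np.abs(values)
    out = np.ones_like(values)
    np.divide(values, mod, out=out, where=mod > 0)
    return out


def project_magnitude(
    field: ComplexField,
    measurement: Measurement,
    regime: Regime,
    fresnel_number: float | None = None,
) -> ComplexField:
    """Magnitude projector ``P_M``.

    Propagate to the detector plane, replace the modulus by
    ``sqrt(counts)`` while keeping the phase (zero-modulus detector pixels
    get phase 0), and propagate back.  Idempotent up to floating point.
    The measurement must be on the same (centered) layout as the
    propagated spectra.
    """
    if field.shape != measurement.shape:
        raise ValueError("field and measurement shapes differ")
    det = propagate(field, regime, fresnel_number=fresnel_number)
    amp = np.sqrt(measurement.counts)
    corrected = amp * _unit_phase(det.values)
    back = propagate(
        ComplexField(corrected, plane="detector", regime=regime),
        regime,
        fresnel_number=fresnel_number,
        inverse=True,
    )
    return back


def _clamp_phase(phase: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Project angles onto the unit-circle arc [lo, hi].

    Angles inside the arc are kept; angles outside snap to the nearer
    endpoint, measured by chord distance (correct across the +-pi wrap).
    """
    inside = (phase >= lo) & (phase <= hi)
    d_lo = np.abs(np.exp(1j * phase) - np.exp(1j * lo))
    d_hi = np.abs(np.exp(1j * phase) - np.exp(1j * hi))
    return np.where(inside, phase, np.where(d_lo < d_hi, lo, hi))


def project_object(
    field: ComplexField,
    support: np.ndarray,
    phase_range: tuple[float, float] | None = None,
) -> ComplexField:
    """Support + pure-phase projector ``P_S``.

    Inside the support the modulus is set to 1 and the phase kept; outside
    the field is the known unperturbed illumination, exactly ``1 + 0i``.
    With ``phase_range=(lo, hi)`` the phase is additionally clamped to the
    object's admissible phase-shift window (e.g. ``(-1, 0)`` rad for the
    study's phantoms), which keeps the iterate from wandering into phase
    wraps at very low fluence and resolves the complex-conjugate
    ambiguity of far-field data.
    """
    support = np.asarray(support, dtype=bool)
    if support.shape != field.shape:
        raise ValueError("support shape mismatch")
    if not support.any():
        raise ValueError("support is empty")
    out = np.ones_like(field.values)
    inner = _unit_phase(field.values[support])
    if phase_range is not None:
        lo, hi = phase_range
        if not lo < hi:
            raise ValueError("phase_range must be an increasing pair")
        inner = np.exp(1j * _clamp_phase(np.angle(inner), lo, hi))
    out[support] = inner
    return ComplexField(out, plane="object", regime=field.regime)


def project_binary(
    field: ComplexField,
    support: np.ndarray,
    levels: tuple[float, float] = (0.0, -1.0),
) -> ComplexField:
    """Binary phase-threshold projector for two-level objects.

    Inside the support each pixel's phase is snapped to the nearer of the
    two levels (unit modulus); a tie at the midpoint goes to the nonzero
    level.  Outside the support the field is 1 + 0i.
    """
    l0, l1 = levels
    if l0 == l1:
        raise ValueError("levels must be distinct")
    support = np.asarray(support, dtype=bool)
    phase = np.angle(field.values[support])
    # tie at the midpoint resolves to the level of larger magnitude (l1)
    lo, hi = (l0, l1) if abs(l1) >= abs(l0) else (l1, l0)
    snapped = np.where(np.abs(phase - hi) <= np.abs(phase - lo), hi, lo)
    out = np.ones_like(field.values)
    out[support] = np.exp(1j * snapped)
    return ComplexField(out, plane="object", regime=field.regime)


def _project_s(field: ComplexField, support: np.ndarray, config: RAARConfig) -> ComplexField:
    ps = project_object(field, support, phase_range=config.phase_range)
    if config.binary:
        ps = project_binary(ps, support, config.binary_levels)
    return ps


def raar_step(
    field: ComplexField,
    beta_n: float,
    measurement: Measurement,
    support: np.ndarray,
    regime: Regime,
    fresnel_number: float | None = None,
    config: RAARConfig | None = None,
) -> ComplexField:
    """One RAAR update (reference implementation with centered operators).

    ``psi' = (beta/2) (R_S R_M psi + psi) + (1 - beta) P_M psi``.
    The optimized :func:`raar_run` loop is numerically identical.
    """
    if not 0.0 <= beta_n <= 1.0:
        raise ValueError("beta_n must lie in [0, 1]")
    config = config or RAARConfig()
    pm = project_magnitude(field, measurement, regime, fresnel_number)
    rm = 2.0 * pm.values - field.values
    ps = _project_s(ComplexField(rm, regime=field.regime), support, config)
    rs = 2.0 * ps.values - rm
    out = 0.5 * beta_n * (rs + field.values) + (1.0 - beta_n) * pm.values
    return ComplexField(out, plane="object", regime=field.regime)


def init_guess(
    kind: InitKind, shape: tuple[int, int], seed: int | None = None,
    dtype=np.complex128,
) -> ComplexField:
    """Initial object-plane iterate.

    ``flat``: unit amplitude, zero phase (the holographic default).
    ``random_phase``: unit amplitude, i.i.d. uniform phases on [-pi, pi)
    (the far-field default, breaking the trivial-phase symmetry).
    """
    if kind == "flat":
        values = np.ones(shape, dtype=dtype)
    elif kind == "random_phase":
        rng = np.random.default_rng(seed)
        values = np.exp(1j * rng.uniform(-np.pi, np.pi, size=shape)).astype(dtype)
    else:
        raise ValueError(f"unknown init kind {kind!r}")
    return ComplexField(values, plane="object")


def raar_run(
    measurement: Measurement,
    support: np.ndarray,
    config: RAARConfig | None = None,
    regime: Regime | None = None,
    fresnel_number: float | None = None,
    dtype=np.complex128,
    renormalize_measurement: bool = True,
) -> ReconstructionResult:
    """Run the full RAAR reconstruction on one (possibly noisy) measurement.

    The measured counts are first rescaled to total power ``N_x * N_y``,
    matching the known power of the unit-modulus exit wave, so that the
    magnitude constraint is on the same scale as the object constraint
    (this uses only prior knowledge, not the ground truth).  The iterate
    starts from :func:`init_guess` (``flat`` for NFH, ``random_phase`` for
    CDI unless overridden) and is updated ``n_iter`` times; the returned
    fields are the final iterate after one more measurement projection
    (``field_after_pm``, the evaluated quantity) and after the subsequent
    object projection (``field_after_ps``).

    Raises ``FloatingPointError`` if the iterate becomes non-finite.
    """
    config = config or RAARConfig()
    if regime is None:
        regime = measurement.regime
    if regime is None:
        raise ValueError("regime not set on measurement; pass regime=...")
    if regime == "nfh" and fresnel_number is None:
        raise ValueError("NFH reconstruction requires fresnel_number")
    support = np.asarray(support, dtype=bool)
    if support.shape != measurement.shape:
        raise ValueError("support / measurement shape mismatch")
    if not support.any():
        raise ValueError("support is empty")

    ny, nx = measurement.shape
    total = measurement.counts.sum()
    if total <= 0:
        raise ValueError("measurement has no counts")
    real_dtype = np.zeros(1, dtype=dtype).real.dtype
    counts = measurement.counts
    if renormalize_measurement:
        # optional: rescale to the unit-exit-wave power scale N_x*N_y
        counts = counts * (nx * ny / total)
    amp_u = sfft.ifftshift(np.sqrt(counts).astype(real_dtype))
    sup_u = sfft.ifftshift(support)
    bg_u = np.where(sup_u, 0, 1).astype(dtype)  # known field outside S
    kern_u = None
    if regime == "nfh":
        kern_u = fresnel_kernel((ny, nx), fresnel_number, centered=False, dtype=dtype)

    init_kind = config.init or ("flat" if regime == "nfh" else "random_phase")
    psi0 = init_guess(init_kind, (ny, nx), seed=config.seed, dtype=dtype)
    psi = sfft.ifftshift(psi0.values)

    if config.binary:
        lo, hi = config.binary_levels
        l_lo, l_hi = (lo, hi) if abs(hi) >= abs(lo) else (hi, lo)

    def pm_u(x: np.ndarray) -> np.ndarray:
        g = sfft.fft2(x, norm="ortho")
        if kern_u is not None:
            g *= kern_u
            g = sfft.ifft2(g, norm="ortho", overwrite_x=True)
        g = amp_u * _unit_phase(g)
        if kern_u is not None:
            g = sfft.fft2(g, norm="ortho", overwrite_x=True)
            g *= np.conj(kern_u)
        return sfft.ifft2(g, norm="ortho", overwrite_x=True)

    def ps_u(x: np.ndarray) -> np.ndarray:
        out = bg_u.copy()
        ph = np.angle(x[sup_u])
        if config.phase_range is not None:
            ph = _clamp_phase(ph, *config.phase_range)
        if config.binary:
            ph = np.where(np.abs(ph - l_hi) <= np.abs(ph - l_lo), l_hi, l_lo)
        out[sup_u] = np.exp(1j * ph)
        return out

    betas = np.asarray(beta_schedule(np.arange(config.n_iter), config))
    residuals = np.empty(config.n_iter)
    for n, beta in enumerate(betas):
        pm = pm_u(psi)
        rm = 2.0 * pm - psi
        rs = 2.0 * ps_u(rm) - rm
        new = 0.5 * beta * (rs + psi) + (1.0 - beta) * pm
        residuals[n] = np.linalg.norm(new - psi)
        psi = new
        if (n % 25 == 24 or n == config.n_iter - 1) and not np.all(np.isfinite(psi)):
            raise FloatingPointError(
                f"RAAR iterate became non-finite at iteration {n} "
                f"(regime={regime}, mu={measurement.fluence})"
            )

    final_pm = pm_u(psi)
    final_ps = ps_u(final_pm)
    return ReconstructionResult(
        field_after_pm=ComplexField(
            sfft.fftshift(final_pm), plane="object", regime=regime
        ),
        field_after_ps=ComplexField(
            sfft.fftshift(final_ps), plane="object", regime=regime
        ),
        betas=betas,
        residuals=residuals,
        config=config,
        regime=regime,
        fresnel_number=fresnel_number,
        init_seed=config.seed,
    )
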