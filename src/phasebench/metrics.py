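"""Resolution and error metrics: Fourier ring correlation and phase errors.

The Fourier ring correlation (FRC) of two real images a, b is, per ring r
of constant radial spatial frequency,

    FRC(r) = Re[ sum_r F_a F_b* ] / sqrt( sum_r |F_a|^2 * sum_r |F_b|^2 ),

with F the 2-D DFT.  The resolved frequency ``f_r`` is the first (lowest)
frequency at which the curve drops below the half-bit significance
threshold

    T(n) = (0.2071 + 1.9102 / sqrt(n)) / (1.2071 + 0.9102 / sqrt(n)),

where n is the number of Fourier samples in the ring; if the curve never
drops below the threshold, ``f_r = 0.5`` periods/pixel, the half-period
(single-pixel) resolution limit of the grid.

Reconstruction error is quantified by the squared l2 phase discrepancy
over the support, ``Delta = sum_S (phi_rec - phi_true)^2``.  For binary
{0, -1} phase maps, Delta equals the number of wrong bits and
``Delta / N`` (N = support pixel count) the wrong-bit fraction; a
reconstruction is counted a *success* when Delta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

__all__ = [
    "FRCCurve",
    "ErrorSummary",
    "frc",
    "half_bit_threshold",
    "resolved_frequency",
    "delta_l2",
    "success_fraction",
]


@dataclass(frozen=True)
class FRCCurve:
    """Per-ring FRC values, half-bit thresholds and the resolved frequency."""

    freq: np.ndarray              # ring-center frequencies, periods/pixel
    corr: np.ndarray              # correlation per ring
    threshold: np.ndarray         # half-bit threshold per ring
    ring_pixel_counts: np.ndarray
    empty_rings: np.ndarray       # flags: ring had zero energy in an input

    @property
    def f_r(self) -> float:
        return resolved_frequency(self)


@dataclass(frozen=True)
class ErrorSummary:
    """Squared-l2 phase discrepancy over the support."""

    delta: float          # sum_S (phi_rec - phi_true)^2
    delta_per_n: float    # delta / |S|
    n_support: int
    success: bool         # delta == 0 (exact recovery)
    delta_root: float     # sqrt(delta): the literal l2-norm variant


def _ring_index(shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Ring label per Fourier pixel (nearest-bin radial frequency), centered.

    Ring k has center frequency k/N (N = min grid side); rings with
    centers above 0.5 periods/pixel (grid corners) are labelled -1 and
    excluded.
    """
    ny, nx = shape
    fy = sfft.fftshift(sfft.fftfreq(ny))
    fx = sfft.fftshift(sfft.fftfreq(nx))
    rad = np.hypot(fy[:, None], fx[None, :])
    n = min(ny, nx)
    k = np.rint(rad * n).astype(int)
    n_rings = n // 2  # rings 1 .. N/2 (centers 1/N .. 0.5)
    k[(k < 1) | (k > n_rings)] = -1
    return k, n_rings


def frc(
    phase_a: np.ndarray, phase_b: np.ndarray, ring_width: int = 1
) -> FRCCurve:
    """Fourier ring correlation of two real images (full-grid DFT).

    Rings are one frequency sample wide by default; ``ring_width`` > 1
    merges consecutive rings.  Rings with zero energy in either input get
    correlation 0 and are flagged.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be 2-D arrays of equal shape")
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    fa = sfft.fftshift(sfft.fft2(a))
    fb = sfft.fftshift(sfft.fft2(b))
    k, n_rings = _ring_index(a.shape)
    valid = k >= 0
    kk = k[valid]
    cross = np.bincount(kk, weights=(fa * np.conj(fb)).real[valid], minlength=n_rings + 1)
    pa = np.bincount(kk, weights=(np.abs(fa) ** 2)[valid], minlength=n_rings + 1)
    pb = np.bincount(kk, weights=(np.abs(fb) ** 2)[valid], minlength=n_rings + 1)
    counts = np.bincount(kk, minlength=n_rings + 1)

    if ring_width > 1:
        n_out = int(np.ceil(n_rings / ring_width))
        pad = n_out * ring_width - n_rings

        def merge(x):
            x = np.concatenate([x[1:], np.zeros(pad)])
            return x.reshape(n_out, ring_width).sum(axis=1)

        cross, pa, pb = merge(cross), merge(pa), merge(pb)
        counts = merge(counts.astype(float)).astype(int)
        n_min = min(a.shape)
        freq = (np.arange(n_out) * ring_width + 0.5 * (ring_width + 1)) / n_min
        freq = np.minimum(freq, 0.5)
    else:
        cross, pa, pb, counts = cross[1:], pa[1:], pb[1:], counts[1:]
        freq = np.arange(1, n_rings + 1) / min(a.shape)

    nonempty = counts > 0
    denom = np.sqrt(pa * pb)
    empty = (denom <= 0) | ~nonempty
    corr = np.zeros_like(cross)
    np.divide(cross, denom, out=corr, where=~empty)
    thr = np.ones_like(corr)
    thr[nonempty] = half_bit_threshold(counts[nonempty])
    return FRCCurve(
        freq=freq[nonempty],
        corr=corr[nonempty],
        threshold=thr[nonempty],
        ring_pixel_counts=counts[nonempty],
        empty_rings=empty[nonempty],
    )


def half_bit_threshold(ring_pixel_count) -> np.ndarray | float:
    """Half-bit information threshold for a ring of n Fourier samples.

    ``T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n))``;
    T(1) = 1 exactly and T -> 0.2071/1.2071 ~= 0.17157 for large rings.
    """
    n = np.asarray(ring_pixel_count, dtype=float)
    if np.any(n < 1):
        raise ValueError("ring pixel count must be >= 1")
    root = 1.0 / np.sqrt(n)
    out = (0.2071 + 1.9102 * root) / (1.2071 + 0.9102 * root)
    return float(out) if out.ndim == 0 else out


def resolved_frequency(curve: FRCCurve) -> float:
    """First half-bit crossing of an FRC curve, in periods/pixel.

    The crossing is linearly interpolated between the bracketing rings;
    if the correlation starts below the threshold the first ring frequency
    is returned, and if it never drops below, 0.5 (the single-pixel
    limit).
    """
    if len(curve.freq) == 0:
        raise ValueError("empty FRC curve")
    diff = curve.corr - curve.threshold
    below = np.nonzero(diff < 0)[0]
    if len(below) == 0:
        return 0.5
    i = below[0]
    if i == 0:
        return float(curve.freq[0])
    f0, f1 = curve.freq[i - 1], curve.freq[i]
    d0, d1 = diff[i - 1], diff[i]
    return float(f0 + (f1 - f0) * d0 / (d0 - d1))


def delta_l2(
    phase_rec: np.ndarray, phase_true: np.ndarray, support: np.ndarray
) -> ErrorSummary:
    """Squared-l2 phase error over the support.

    ``Delta = sum_S (phi_rec - phi_true)^2``; for binary {0, -1} maps this
    is the wrong-bit count and ``Delta/N`` the wrong-bit fraction.  The
    literal l2 norm ``sqrt(Delta)`` is reported alongside.
    """
    rec = np.asarray(phase_rec, dtype=float)
    true = np.asarray(phase_true, dtype=float)
    support = np.asarray(support, dtype=bool)
    if rec.shape != true.shape or rec.shape != support.shape:
        raise ValueError("shape mismatch")
    n = int(support.sum())
    if n == 0:
        raise ValueError("support is empty")
    delta = float(np.sum((rec[support] - true[support]) ** 2))
    return ErrorSummary(
        delta=delta,
        delta_per_n=delta / n,
        n_support=n,
        success=delta == 0.0,
        delta_root=float(np.sqrt(delta)),
    )


def success_fraction(deltas) -> float:
    """Fraction of an ensemble with exact recovery (Delta = 0)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty ensemble")
    return float(np.mean(deltas == 0.0))
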