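"""Fluence-sweep experiments and derived dose-resolution quantities.

Each experiment varies the object-plane photon fluence mu over a
logarithmic grid, simulates ``n_realizations`` independent Poisson noise
realizations per grid point, reconstructs each with RAAR, and scores the
reconstruction against the ground-truth phantom (FRC resolved frequency
``f_r`` and per-support-pixel phase error ``Delta/N``).  Derived
quantities summarize the resulting curves:

* saturation fluence — where mean f_r first reaches the pixel-resolution
  limit 0.5 periods/pixel and stays there;
* crossover fluence — where one regime's Delta/N curve drops below the
  other's for good;
* reconstructability curve — fraction of exact (Delta = 0) recoveries of
  a 1:1 binary bitmap vs fluence, with the binary phase constraint;
* decade shift and transition width of reconstructability curves, in
  log10 fluence.

A direct back-propagation benchmark (no iterative retrieval: assign the
measured moduli zero phase and apply the inverse propagator) provides the
no-prior baseline.

Seeding: every (mu index, realization) cell derives its Poisson seed and
its random-phase-init seed from ``numpy.random.SeedSequence([base_seed,
mu_index, realization])``, so sweeps are reproducible from ``base_seed``
alone and cells are independent.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .detector import apply_poisson, normalize, simulate_measurement
from .metrics import delta_l2, frc, resolved_frequency
from .optics import ComplexField, Regime, propagate
from .phantoms import Phantom, reconstruction_support
from .retrieval import RAARConfig, raar_run

__all__ = [
    "log_mu_grid",
    "fluence_sweep",
    "summarize_records",
    "saturation_fluence",
    "crossover_fluence",
    "reconstructability_curve",
    "fluence_at_level",
    "decade_shift",
    "transition_width",
    "backprop_benchmark",
]

RECORD_COLUMNS = [
    "regime", "fluence", "mu_index", "realization", "noise_seed", "init_seed",
    "f_r", "delta", "delta_per_n", "delta_ps", "delta_per_n_ps", "success", "ok",
]


def log_mu_grid(lo: float, hi: float, points_per_decade: int = 8) -> np.ndarray:
    """Logarithmic fluence grid from ``lo`` to ``hi`` (inclusive)."""
    if lo <= 0 or hi <= lo:
        raise ValueError("need 0 < lo < hi")
    n = int(np.ceil(np.log10(hi / lo) * points_per_decade)) + 1
    return np.geomspace(lo, hi, n)


def _cell_seeds(base_seed: int, mu_index: int, realization: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([int(base_seed), int(mu_index), int(realization)])
    s = ss.generate_state(2)
    return int(s[0] % 2**31), int(s[1] % 2**31)


def fluence_sweep(
    phantom: Phantom,
    regime: Regime,
    mu_grid,
    n_realizations: int = 30,
    raar_config: RAARConfig | None = None,
    fresnel_number: float = 1e-3,
    base_seed: int = 0,
    dtype=np.complex128,
    compute_frc: bool = True,
    recon_support: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct ``n_realizations`` noisy measurements at each fluence.

    Returns ``(records, summary)``: one record per (mu, realization) with
    f_r, Delta/N (scored on the post-measurement-projection phase),
    Delta/N after the object/binary projection, and the exact-recovery
    flag; and the per-fluence aggregate (mean/std f_r and Delta/N,
    success fraction).  Individual failed runs (non-finite iterates) are
    recorded with ``ok=False`` rather than aborting the sweep.

    The support prior given to RAAR is the tight nonzero region by
    default (``recon_support``, see
    :func:`~phasebench.phantoms.reconstruction_support`); error metrics
    are always normalized over the phantom's stored support (for a
    bitmap, the full rectangle, so Delta/N is the wrong-bit fraction of
    the whole bitmap).
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid <= 0) or np.any(np.diff(mu_grid) <= 0):
        raise ValueError("mu_grid must be positive and strictly ascending")
    raar_config = raar_config or RAARConfig()

    ideal = normalize(simulate_measurement(
        phantom, regime, fresnel_number=fresnel_number, dtype=dtype
    ))
    support = phantom.support
    if recon_support is None:
        recon_support = reconstruction_support(phantom)
    rows = []
    for i, mu in enumerate(mu_grid):
        for r in range(n_realizations):
            noise_seed, init_seed = _cell_seeds(base_seed, i, r)
            noisy = apply_poisson(ideal, mu, noise_seed)
            row = dict(
                regime=regime, fluence=mu, mu_index=i, realization=r,
                noise_seed=noise_seed, init_seed=init_seed,
                f_r=np.nan, delta=np.nan, delta_per_n=np.nan,
                delta_ps=np.nan, delta_per_n_ps=np.nan,
                success=False, ok=True,
            )
            try:
                res = raar_run(
                    noisy, recon_support,
                    config=replace(raar_config, seed=init_seed),
                    regime=regime, fresnel_number=fresnel_number, dtype=dtype,
                )
            except FloatingPointError:
                row["ok"] = False
                rows.append(row)
                continue
            if compute_frc:
                row["f_r"] = resolved_frequency(
                    frc(res.phase_after_pm, phantom.phase)
                )
            err = delta_l2(res.phase_after_pm, phantom.phase, support)
            err_ps = delta_l2(res.phase_after_ps, phantom.phase, support)
            row.update(
                delta=err.delta, delta_per_n=err.delta_per_n,
                delta_ps=err_ps.delta, delta_per_n_ps=err_ps.delta_per_n,
                success=err_ps.success if raar_config.binary else err.success,
            )
            rows.append(row)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, summarize_records(records)


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-fluence aggregates of a sweep's records."""
    ok = records[records["ok"]]
    grouped = ok.groupby("fluence")
    summary = pd.DataFrame({
        "f_r_mean": grouped["f_r"].mean(),
        "f_r_std": grouped["f_r"].std(ddof=0),
        "delta_per_n_mean": grouped["delta_per_n"].mean(),
        "delta_per_n_std": grouped["delta_per_n"].std(ddof=0),
        "delta_per_n_ps_mean": grouped["delta_per_n_ps"].mean(),
        "success_fraction": grouped["success"].mean(),
        "n_ok": grouped.size(),
    }).reset_index()
    n_total = records.groupby("fluence").size().reset_index(name="n_total")
    summary = summary.merge(n_total, on="fluence", how="right")
    summary["incomplete"] = summary["n_ok"].fillna(0) < summary["n_total"]
    return summary.sort_values("fluence").reset_index(drop=True)


def saturation_fluence(
    summary: pd.DataFrame, f_target: float = 0.5, tol: float = 0.01
) -> float | None:
    """Smallest grid fluence whose mean f_r reaches (and keeps) the target.

    Returns the smallest mu with ``mean f_r >= f_target - tol`` at that mu
    and every larger grid mu, or ``None`` if resolution never saturates.
    """
    s = summary.sort_values("fluence")
    good = (s["f_r_mean"] >= f_target - tol).to_numpy()
    mu = s["fluence"].to_numpy()
    # first index from which all subsequent points are saturated
    for i in range(len(good)):
        if good[i:].all():
            return float(mu[i])
    return None


def crossover_fluence(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    metric: str = "delta_per_n_mean",
) -> float | None:
    """Fluence where curve a drops below curve b and stays below.

    Both summaries must share the fluence grid.  The crossing is
    log-linearly interpolated between the bracketing grid points; if
    curve a is below from the first point, that point is returned, and
    ``None`` if a never stays below b.
    """
    mu_a = summary_a.sort_values("fluence")["fluence"].to_numpy()
    mu_b = summary_b.sort_values("fluence")["fluence"].to_numpy()
    if len(mu_a) != len(mu_b) or not np.allclose(mu_a, mu_b):
        raise ValueError("summaries must share a common fluence grid")
    va = summary_a.sort_values("fluence")[metric].to_numpy()
    vb = summary_b.sort_values("fluence")[metric].to_numpy()
    below = va < vb
    idx = None
    for i in range(len(below)):
        if below[i:].all():
            idx = i
            break
    if idx is None:
        return None
    if idx == 0:
        return float(mu_a[0])
    # interpolate the zero of (va - vb) in log10(mu)
    d0, d1 = va[idx - 1] - vb[idx - 1], va[idx] - vb[idx]
    l0, l1 = np.log10(mu_a[idx - 1]), np.log10(mu_a[idx])
    if d0 == d1:
        return float(mu_a[idx])
    t = d0 / (d0 - d1)
    return float(10 ** (l0 + t * (l1 - l0)))


def reconstructability_curve(
    phantom: Phantom,
    regime: Regime,
    mu_grid,
    n_repeats: int = 100,
    raar_config: RAARConfig | None = None,
    fresnel_number: float = 4e-3,
    base_seed: int = 0,
    dtype=np.complex128,
) -> pd.DataFrame:
    """Exact-recovery probability of a binary bitmap vs fluence.

    Runs RAAR with the binary phase constraint active and scores success
    as ``Delta = 0`` on the thresholded (post-object-projection) phase.
    Intended for the 1:1 bitmap (one bit per image pixel), the hardest
    discrete recovery problem.  Returns columns ``fluence``,
    ``success_fraction``, ``n``.
    """
    config = raar_config or RAARConfig(binary=True)
    if not config.binary:
        config = replace(config, binary=True)
    records, summary = fluence_sweep(
        phantom, regime, mu_grid, n_realizations=n_repeats,
        raar_config=config, fresnel_number=fresnel_number,
        base_seed=base_seed, dtype=dtype, compute_frc=False,
    )
    out = summary[["fluence", "success_fraction", "n_ok"]].rename(
        columns={"n_ok": "n"}
    )
    return out


def fluence_at_level(curve: pd.DataFrame, level: float) -> float | None:
    """Log-interpolated fluence at which a success curve first reaches ``level``.

    ``curve`` has columns ``fluence`` (ascending) and ``success_fraction``.
    Returns ``None`` when the curve never reaches the level; the first
    grid fluence when it starts at or above it.
    """
    c = curve.sort_values("fluence")
    mu = c["fluence"].to_numpy()
    s = c["success_fraction"].to_numpy()
    reach = np.nonzero(s >= level)[0]
    if len(reach) == 0:
        return None
    i = reach[0]
    if i == 0:
        return float(mu[0])
    s0, s1 = s[i - 1], s[i]
    l0, l1 = np.log10(mu[i - 1]), np.log10(mu[i])
    t = (level - s0) / (s1 - s0) if s1 != s0 else 1.0
    return float(10 ** (l0 + t * (l1 - l0)))


def decade_shift(
    curve_a: pd.DataFrame, curve_b: pd.DataFrame, level: float = 0.5
) -> float | None:
    """Horizontal offset (decades of fluence) between two success curves.

    ``log10 mu_b(level) - log10 mu_a(level)``; positive when curve b needs
    more photons.  ``None`` if either curve never reaches the level.
    """
    ma = fluence_at_level(curve_a, level)
    mb = fluence_at_level(curve_b, level)
    if ma is None or mb is None:
        return None
    return float(np.log10(mb) - np.log10(ma))


def transition_width(
    curve: pd.DataFrame, low: float = 0.05, high: float = 0.95
) -> float | None:
    """Width (decades) of the reconstructability transition.

    ``log10 mu(high) - log10 mu(low)`` with log-interpolated crossings;
    ``None`` if the curve does not span both levels.
    """
    ml = fluence_at_level(curve, low)
    mh = fluence_at_level(curve, high)
    if ml is None or mh is None:
        return None
    return float(np.log10(mh) - np.log10(ml))


def backprop_benchmark(
    phantom: Phantom,
    regime: Regime,
    mu_grid,
    n_realizations: int = 30,
    fresnel_number: float = 1e-3,
    base_seed: int = 0,
    dtype=np.complex128,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct back-propagation baseline: no phase retrieval.

    Each noisy measurement is assigned zero detector phase (the only
    information-free choice — measurements carry no phase), the modulus
    ``sqrt(counts)`` is back-propagated with the regime's inverse
    propagator, and the resulting object-plane phase is scored by FRC
    against the phantom.  Returns ``(records, summary)`` like
    :func:`fluence_sweep`.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid <= 0) or np.any(np.diff(mu_grid) <= 0):
        raise ValueError("mu_grid must be positive and strictly ascending")
    ideal = normalize(simulate_measurement(
        phantom, regime, fresnel_number=fresnel_number, dtype=dtype
    ))
    support = phantom.support
    rows = []
    for i, mu in enumerate(mu_grid):
        for r in range(n_realizations):
            noise_seed, _ = _cell_seeds(base_seed, i, r)
            noisy = apply_poisson(ideal, mu, noise_seed)
            det = ComplexField(
                np.sqrt(noisy.counts).astype(dtype), plane="detector",
                regime=regime,
            )
            obj = propagate(det, regime, fresnel_number=fresnel_number,
                            inverse=True)
            phase = np.angle(obj.values)
            err = delta_l2(phase, phantom.phase, support)
            rows.append(dict(
                regime=regime, fluence=mu, mu_index=i, realization=r,
                noise_seed=noise_seed, init_seed=-1,
                f_r=resolved_frequency(frc(phase, phantom.phase)),
                delta=err.delta, delta_per_n=err.delta_per_n,
                delta_ps=np.nan, delta_per_n_ps=np.nan,
                success=err.success, ok=True,
            ))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, summarize_records(records)
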