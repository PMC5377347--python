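import numpy as np
import pytest

from phasebench import (
    ComplexField,
    Measurement,
    RAARConfig,
    beta_schedule,
    delta_l2,
    exit_wave,
    frc,
    init_guess,
    intensity,
    project_binary,
    project_magnitude,
    project_object,
    raar_run,
    raar_step,
    reconstruction_support,
    resolved_frequency,
    simulate_measurement,
)
from phasebench.optics import propagate


@pytest.fixture(scope="module")
def noiseless_setup(small_bitmap):
    """Noiseless NFH measurement of the small bitmap (consistent data)."""
    fr = 4e-3
    m = simulate_measurement(small_bitmap, "nfh", fresnel_number=fr)
    return small_bitmap, m, fr


class TestBetaSchedule:
    def test_endpoints_and_switch_value(self):
        cfg = RAARConfig()
        assert beta_schedule(0, cfg) == pytest.approx(0.99)
        assert beta_schedule(10 * 150, cfg) == pytest.approx(0.75, abs=1e-6)
        # at n = beta_switch the relaxation is 1/e of the way down
        expected = 0.75 + 0.24 * np.exp(-1.0)
        assert beta_schedule(150, cfg) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.83830, abs=1e-5)

    def test_monotone_nonincreasing(self):
        cfg = RAARConfig()
        betas = beta_schedule(np.arange(500), cfg)
        assert np.all(np.diff(betas) <= 1e-15)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RAARConfig(beta0=0.5, beta_max=0.9)
        with pytest.raises(ValueError):
            RAARConfig(n_iter=0)
        with pytest.raises(ValueError):
            beta_schedule(-1, RAARConfig())


class TestProjectors:
    def test_magnitude_projector_fixed_point_and_idempotence(self, noiseless_setup):
        ph, m, fr = noiseless_setup
        psi = exit_wave(ph)
        out = project_magnitude(psi, m, "nfh", fr)
        assert np.abs(out.values - psi.values).max() < 1e-9
        # idempotence on a random field
        rng = np.random.default_rng(0)
        f = ComplexField(rng.normal(size=m.shape) + 1j * rng.normal(size=m.shape))
        once = project_magnitude(f, m, "nfh", fr)
        twice = project_magnitude(once, m, "nfh", fr)
        rel = np.linalg.norm(twice.values - once.values) / np.linalg.norm(once.values)
        assert rel < 1e-8

    def test_magnitude_projector_rejects_shape_mismatch(self, noiseless_setup):
        _, m, fr = noiseless_setup
        with pytest.raises(ValueError):
            project_magnitude(ComplexField(np.ones((8, 8), complex)), m, "nfh", fr)

    def test_object_projector(self, rng):
        support = np.zeros((16, 16), dtype=bool)
        support[4:12, 4:12] = True
        v = 0.5 * np.exp(-0.3j) * np.ones((16, 16), complex)
        out = project_object(ComplexField(v), support)
        assert np.allclose(np.abs(out.values[support]), 1.0)
        assert np.allclose(np.angle(out.values[support]), -0.3)
        assert np.allclose(out.values[~support], 1.0 + 0j)
        # fixed point: already-feasible field unchanged
        again = project_object(out, support)
        assert np.allclose(again.values, out.values, atol=1e-15)

    def test_object_projector_phase_clamp(self):
        support = np.ones((4, 4), dtype=bool)
        v = np.exp(1j * np.array([[0.4, -0.5, -1.4, 3.0]] * 4))
        out = project_object(ComplexField(v), support, phase_range=(-1.0, 0.0))
        ph = np.angle(out.values)[0]
        assert ph[0] == pytest.approx(0.0, abs=1e-12)   # positive -> upper edge
        assert ph[1] == pytest.approx(-0.5)             # inside range kept
        assert ph[2] == pytest.approx(-1.0)             # below -> lower edge
        # +3 rad is nearer (chord) to the -1 endpoint than to 0
        assert ph[3] == pytest.approx(-1.0)

    def test_object_projector_rejects_empty_support(self):
        with pytest.raises(ValueError):
            project_object(ComplexField(np.ones((4, 4), complex)),
                           np.zeros((4, 4), dtype=bool))

    def test_binary_projector_snapping_and_tie(self):
        support = np.ones((1, 4), dtype=bool)
        v = np.exp(1j * np.array([[-0.9, -0.2, -0.5, 0.3]]))
        out = project_binary(ComplexField(v), support, levels=(0.0, -1.0))
        ph = np.angle(out.values)[0]
        assert ph[0] == pytest.approx(-1.0)
        assert ph[1] == pytest.approx(0.0, abs=1e-12)
        assert ph[2] == pytest.approx(-1.0)  # tie at midpoint -> nonzero level
        assert ph[3] == pytest.approx(0.0, abs=1e-12)
        again = project_binary(out, support, levels=(0.0, -1.0))
        assert np.allclose(again.values, out.values, atol=1e-15)

    def test_projector_idempotence_on_random_fields(self, rng):
        support = np.zeros((32, 32), dtype=bool)
        support[8:24, 8:24] = True
        f = ComplexField(rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)))
        for proj in (
            lambda x: project_object(x, support),
            lambda x: project_object(x, support, phase_range=(-1, 0)),
            lambda x: project_binary(x, support),
        ):
            once = proj(f)
            twice = proj(once)
            assert np.linalg.norm(twice.values - once.values) < 1e-8


class TestRAARStep:
    def test_beta_zero_reduces_to_magnitude_projection(self, noiseless_setup, rng):
        ph, m, fr = noiseless_setup
        f = ComplexField(np.exp(1j * rng.normal(scale=0.2, size=m.shape)))
        cfg = RAARConfig(phase_range=None)
        stepped = raar_step(f, 0.0, m, ph.support, "nfh", fr, config=cfg)
        pm = project_magnitude(f, m, "nfh", fr)
        assert np.allclose(stepped.values, pm.values, atol=1e-12)

    def test_beta_one_is_averaged_alternating_reflections(self, noiseless_setup, rng):
        ph, m, fr = noiseless_setup
        f = ComplexField(np.exp(1j * rng.normal(scale=0.2, size=m.shape)))
        cfg = RAARConfig(phase_range=None)
        stepped = raar_step(f, 1.0, m, ph.support, "nfh", fr, config=cfg)
        pm = project_magnitude(f, m, "nfh", fr)
        rm = 2 * pm.values - f.values
        ps = project_object(ComplexField(rm), ph.support)
        rs = 2 * ps.values - rm
        assert np.allclose(stepped.values, 0.5 * (rs + f.values), atol=1e-12)

    def test_consistent_field_is_fixed_point(self, noiseless_setup):
        ph, m, fr = noiseless_setup
        psi = exit_wave(ph)
        for beta in (0.3, 0.99):
            out = raar_step(psi, beta, m, ph.support, "nfh", fr)
            assert np.linalg.norm(out.values - psi.values) < 1e-8


class TestInitGuess:
    def test_flat(self):
        f = init_guess("flat", (32, 32))
        assert np.allclose(f.values, 1.0 + 0j)
        assert f.power() == pytest.approx(1024)

    def test_random_phase_statistics_and_determinism(self):
        f1 = init_guess("random_phase", (64, 64), seed=3)
        f2 = init_guess("random_phase", (64, 64), seed=3)
        assert np.array_equal(f1.values, f2.values)
        assert np.allclose(np.abs(f1.values), 1.0)
        # circular mean of uniform phases is near zero
        assert np.abs(f1.values.mean()) <= 3 / 64

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            init_guess("bogus", (8, 8))


class TestRAARRun:
    def test_noiseless_nfh_reconstructs_to_pixel_resolution(self, noiseless_setup):
        ph, m, fr = noiseless_setup
        res = raar_run(m, reconstruction_support(ph), RAARConfig(), "nfh", fr)
        curve = frc(res.phase_after_pm, ph.phase)
        assert resolved_frequency(curve) == pytest.approx(0.5)
        err = delta_l2(res.phase_after_pm, ph.phase, ph.support)
        assert err.delta_per_n < 1e-4

    def test_noiseless_cdi_reconstructs(self, small_bitmap):
        m = simulate_measurement(small_bitmap, "cdi")
        res = raar_run(m, reconstruction_support(small_bitmap),
                       RAARConfig(seed=0), "cdi")
        assert resolved_frequency(frc(res.phase_after_pm, small_bitmap.phase)) \
            == pytest.approx(0.5)

    def test_noisy_run_contract(self, small_bitmap):
        m = simulate_measurement(small_bitmap, "nfh", fresnel_number=4e-3,
                                 fluence=200, seed=1)
        res = raar_run(m, reconstruction_support(small_bitmap),
                       RAARConfig(), "nfh", 4e-3)
        assert len(res.betas) == len(res.residuals) == 200
        assert np.all(np.isfinite(res.field_after_pm.values))
        assert np.all(np.isfinite(res.residuals))

    def test_determinism(self, small_bitmap):
        m = simulate_measurement(small_bitmap, "cdi", fluence=500, seed=2)
        sup = reconstruction_support(small_bitmap)
        r1 = raar_run(m, sup, RAARConfig(seed=5), "cdi")
        r2 = raar_run(m, sup, RAARConfig(seed=5), "cdi")
        assert np.array_equal(r1.field_after_pm.values, r2.field_after_pm.values)

    def test_loop_matches_reference_step_composition(self, tiny_bitmap_1to1):
        """The optimized unshifted-layout loop must agree with explicitly
        composing the centered-operator raar_step."""
        ph = tiny_bitmap_1to1
        fr = 1.0 / 16
        m = simulate_measurement(ph, "nfh", fresnel_number=fr, fluence=300, seed=4)
        sup = reconstruction_support(ph)
        cfg = RAARConfig(n_iter=12)
        res = raar_run(m, sup, cfg, "nfh", fr)
        # reference: centered operators on the power-rescaled measurement
        scaled = Measurement(m.counts * (64 * 64 / m.counts.sum()), regime="nfh")
        f = init_guess("flat", (64, 64))
        for n in range(cfg.n_iter):
            f = raar_step(f, beta_schedule(n, cfg), scaled, sup, "nfh", fr,
                          config=cfg)
        ref_pm = project_magnitude(f, scaled, "nfh", fr)
        assert np.allclose(res.field_after_pm.values, ref_pm.values, atol=1e-9)

    def test_residual_stability_after_beta_switch(self, noiseless_setup):
        """With consistent (noiseless) data the update norm is
        non-increasing for the vast majority of late iterations."""
        ph, m, fr = noiseless_setup
        res = raar_run(m, reconstruction_support(ph),
                       RAARConfig(n_iter=250), "nfh", fr)
        tail = res.residuals[150:]
        frac_nonincreasing = np.mean(np.diff(tail) <= 1e-12)
        assert frac_nonincreasing >= 0.9

    def test_binary_constraint_exact_recovery_at_high_fluence(self, tiny_bitmap_1to1):
        ph = tiny_bitmap_1to1
        sup = reconstruction_support(ph)
        cfg = RAARConfig(binary=True)
        successes = {"nfh": 0, "cdi": 0}
        n_seeds = 5
        for regime in ("nfh", "cdi"):
            for s in range(n_seeds):
                m = simulate_measurement(ph, regime, fresnel_number=1 / 16,
                                         fluence=2e4, seed=100 + s)
                res = raar_run(m, sup, RAARConfig(binary=True, seed=s),
                               regime, 1 / 16)
                err = delta_l2(res.phase_after_ps, ph.phase, ph.support)
                successes[regime] += err.delta == 0.0
        assert successes["nfh"] == n_seeds
        assert successes["cdi"] == n_seeds

    def test_rejects_bad_inputs(self, small_bitmap):
        m = simulate_measurement(small_bitmap, "nfh", fresnel_number=4e-3)
        with pytest.raises(ValueError):
            raar_run(m, np.zeros_like(small_bitmap.support), RAARConfig(),
                     "nfh", 4e-3)
        with pytest.raises(ValueError):
            raar_run(m, small_bitmap.support, RAARConfig(), "nfh", None)
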