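"""VMD: closed-form recoveries, update-equation oracle, invariants."""

import numpy as np
import pytest

from vmdp300.vmd import (
    ModeSet,
    VMDConfig,
    VMDConvergenceWarning,
    center_freq_update,
    convergence_check,
    dual_update,
    mode_update,
    vmd_decompose,
    vmd_decompose_matrix,
)


def interior(x, frac=0.8):
    n = len(x)
    cut = int(n * (1 - frac) / 2)
    return x[cut:n - cut]


def corr(a, b):
    return np.corrcoef(a, b)[0, 1]


# ---------------------------------------------------------------------------
# decomposition on constructed signals
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_pure_tone_recovered(self):
        t = np.arange(512)
        x = np.sin(2 * np.pi * 0.1 * t)
        ms = vmd_decompose(x, VMDConfig(n_modes=1))
        assert ms.converged
        assert abs(ms.center_freqs[0] - 0.1) < 0.005
        assert corr(interior(ms.modes[0]), interior(x)) > 0.99

    def test_zero_signal_gives_zero_modes(self):
        ms = vmd_decompose(np.zeros(256), VMDConfig(n_modes=3))
        assert np.abs(ms.modes).max() < 1e-9
        assert np.abs(ms.residual).max() < 1e-12

    def test_two_separated_tones(self):
        t = np.arange(1024)
        lo = np.sin(2 * np.pi * 0.05 * t)
        hi = np.sin(2 * np.pi * 0.25 * t)
        ms = vmd_decompose(lo + hi, VMDConfig(n_modes=2))
        # desc_freq ordering: mode 0 is the high tone
        assert abs(ms.center_freqs[0] - 0.25) < 0.01
        assert abs(ms.center_freqs[1] - 0.05) < 0.01
        assert corr(interior(ms.modes[0]), interior(hi)) > 0.95
        assert corr(interior(ms.modes[1]), interior(lo)) > 0.95

    def test_near_reconstruction_on_bandlimited_input(self, rng):
        t = np.arange(512)
        x = sum(
            a * np.sin(2 * np.pi * f * t + p)
            for a, f, p in zip(
                (1.0, 0.7, 0.4), (0.04, 0.12, 0.3), rng.uniform(0, 6.28, 3)
            )
        )
        ms = vmd_decompose(x, VMDConfig(n_modes=3))
        rel = np.linalg.norm(ms.residual) / np.linalg.norm(x)
        assert rel < 0.1

    def test_monotone_separation_with_frequency_gap(self):
        t = np.arange(1024)
        lo = np.sin(2 * np.pi * 0.05 * t)
        corrs = []
        for f_hi in (0.10, 0.20, 0.30):
            hi = np.sin(2 * np.pi * f_hi * t)
            ms = vmd_decompose(lo + hi, VMDConfig(n_modes=2))
            corrs.append(
                min(
                    corr(interior(ms.modes[0]), interior(hi)),
                    corr(interior(ms.modes[1]), interior(lo)),
                )
            )
        assert corrs == sorted(corrs)

    def test_determinism(self, rng):
        x = rng.standard_normal(300)
        cfg = VMDConfig(omega_init="random", seed=3)
        a = vmd_decompose(x, cfg)
        b = vmd_decompose(x, cfg)
        assert np.array_equal(a.modes, b.modes)
        assert np.array_equal(a.center_freqs, b.center_freqs)

    def test_center_freqs_in_range(self, rng):
        x = rng.standard_normal(400)
        ms = vmd_decompose(x)
        assert ((ms.center_freqs >= 0) & (ms.center_freqs <= 0.5)).all()
        assert np.all(np.diff(ms.center_freqs) <= 0)  # desc_freq ordering

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="non-finite"):
            vmd_decompose(np.array([1.0, np.nan, 3.0, 4.0]), VMDConfig(n_modes=1))
        with pytest.raises(ValueError, match="too short"):
            vmd_decompose(np.ones(6), VMDConfig(n_modes=5))

    def test_nonconvergence_warns_not_silent(self, rng):
        x = rng.standard_normal(256)
        with pytest.warns(VMDConvergenceWarning):
            ms = vmd_decompose(x, VMDConfig(max_iter=1, tol=1e-9))
        assert not ms.converged

    def test_config_validation(self):
        for bad in (
            dict(alpha=0),
            dict(tau=-1),
            dict(tol=0),
            dict(n_modes=0),
            dict(max_iter=0),
            dict(omega_init="nope"),
        ):
            with pytest.raises(ValueError):
                VMDConfig(**bad)


# ---------------------------------------------------------------------------
# the individual ADMM updates against literal re-evaluation
# ---------------------------------------------------------------------------

class TestUpdates:
    def _random_state(self, rng, n_modes=3, n_bins=65):
        u = rng.standard_normal((n_modes, n_bins)) + 1j * rng.standard_normal(
            (n_modes, n_bins)
        )
        lam = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
        x = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
        freqs = np.linspace(0, 0.5, n_bins)
        omegas = rng.uniform(0, 0.5, n_modes)
        return x, u, lam, omegas, freqs

    def test_mode_update_matches_literal_formula(self, rng):
        x, u, lam, omegas, freqs = self._random_state(rng)
        alpha = 1000.0
        for m in range(3):
            got = mode_update(x, u, lam, omegas, alpha, m, freqs)
            # independent element-by-element transcription
            expected = np.empty_like(got)
            for k in range(len(freqs)):
                s = 0.0 + 0.0j
                for i in range(3):
                    if i != m:
                        s += u[i, k]
                num = x[k] - s + lam[k] / 2
                expected[k] = num / (1 + 2 * alpha * (freqs[k] - omegas[m]) ** 2)
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_mode_update_huge_alpha_kills_offgrid_mode(self, rng):
        x, u, lam, omegas, freqs = self._random_state(rng)
        omegas[0] = 0.7  # off the grid entirely
        got = mode_update(x, u, lam, omegas, 1e18, 0, freqs)
        assert np.abs(got).max() < 1e-9

    def test_mode_update_single_mode_zero_dual(self, rng):
        n_bins = 65
        x = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
        u = np.zeros((1, n_bins), dtype=complex)
        freqs = np.linspace(0, 0.5, n_bins)
        got = mode_update(x, u, np.zeros(n_bins, complex), np.array([0.2]), 50.0, 0, freqs)
        np.testing.assert_allclose(got, x / (1 + 2 * 50.0 * (freqs - 0.2) ** 2))

    def test_center_freq_delta_spectrum(self):
        freqs = np.linspace(0, 0.5, 33)
        spec = np.zeros(33, dtype=complex)
        spec[10] = 3.0 - 4.0j
        assert center_freq_update(spec, freqs) == freqs[10]

    def test_center_freq_symmetric_split(self):
        freqs = np.linspace(0, 0.5, 33)
        spec = np.zeros(33, dtype=complex)
        spec[8] = 2.0
        spec[24] = 2.0j
        assert np.isclose(center_freq_update(spec, freqs), (freqs[8] + freqs[24]) / 2)

    def test_center_freq_matches_weighted_mean(self, rng):
        freqs = np.linspace(0, 0.5, 101)
        spec = rng.standard_normal(101) + 1j * rng.standard_normal(101)
        got = center_freq_update(spec, freqs)
        p = np.abs(spec) ** 2
        assert np.isclose(got, (freqs * p).sum() / p.sum(), rtol=1e-12)

    def test_center_freq_zero_spectrum_raises(self):
        with pytest.raises(ValueError):
            center_freq_update(np.zeros(16, complex), np.linspace(0, 0.5, 16))

    def test_dual_update_zero_step_and_exact_reconstruction(self, rng):
        x, u, lam, _, _ = self._random_state(rng)
        np.testing.assert_array_equal(dual_update(lam, x, u, 0.0), lam)
        u_exact = u.copy()
        u_exact[0] = x - u[1:].sum(axis=0)
        np.testing.assert_allclose(dual_update(lam, x, u_exact, 0.5), lam, rtol=1e-12)

    def test_dual_update_literal(self, rng):
        x, u, lam, _, _ = self._random_state(rng)
        got = dual_update(lam, x, u, 0.01)
        np.testing.assert_allclose(got, lam + 0.01 * (x - u.sum(axis=0)), rtol=1e-12)

    def test_convergence_identical_and_constructed_perturbation(self, rng):
        u = rng.standard_normal((2, 40)) + 1j * rng.standard_normal((2, 40))
        assert convergence_check(u, u.copy(), 1e-12)
        tol = 0.005
        # perturb one mode by relative L2-squared change of exactly 2*tol
        norm0 = np.sqrt((np.abs(u[0]) ** 2).sum())
        bump = np.zeros_like(u)
        bump[0, 0] = np.sqrt(2 * tol) * norm0
        assert not convergence_check(u, u + bump, tol)

    def test_default_tolerance_from_config(self):
        assert VMDConfig().tol == 0.005
        assert VMDConfig().alpha == 1000.0
        assert VMDConfig().tau == 0.01
        assert VMDConfig().n_modes == 5


# ---------------------------------------------------------------------------
# full-loop equivalence with a naive literal transcription
# ---------------------------------------------------------------------------

def naive_vmd_trajectory(x, config, n_iters):
    """Literal, loop-by-loop transcription of the three spectral updates.

    Written independently of the implementation: plain Python loops over
    modes and frequency bins, fixed iteration count, no early exit.
    Returns the (u_hat, omega) trajectory after each iteration.
    """
    half = len(x) // 2
    xe = np.concatenate([x[:half][::-1], x, x[len(x) - half:][::-1]])
    T = len(xe)
    x_hat = np.fft.rfft(xe)
    freqs = np.fft.rfftfreq(T)
    M = config.n_modes
    omegas = np.array([0.5 * (m + 1) / M for m in range(M)])
    u = np.zeros((M, len(freqs)), dtype=complex)
    lam = np.zeros(len(freqs), dtype=complex)
    traj = []
    for _ in range(n_iters):
        for m in range(M):
            others = np.zeros(len(freqs), dtype=complex)
            for i in range(M):
                if i != m:
                    others = others + u[i]
            u[m] = (x_hat - others + lam / 2) / (
                1 + 2 * config.alpha * (freqs - omegas[m]) ** 2
            )
            power = np.abs(u[m]) ** 2
            if power.sum() > 0:
                omegas[m] = (freqs * power).sum() / power.sum()
        lam = lam + config.tau * (x_hat - u.sum(axis=0))
        traj.append((u.copy(), omegas.copy()))
    return traj


def test_loop_matches_naive_transcription_per_iteration(rng):
    """ADMM trajectory equals the naive oracle on a 3-tone signal, 1e-8/iter."""
    t = np.arange(1024)
    x = (
        np.sin(2 * np.pi * 0.03 * t)
        + 0.8 * np.sin(2 * np.pi * 0.15 * t)
        + 0.6 * np.sin(2 * np.pi * 0.35 * t)
    )
    config = VMDConfig(n_modes=3, max_iter=30, tol=1e-30, mode_order="input")
    traj = naive_vmd_trajectory(x, config, n_iters=30)

    # replay the implementation's loop state iteration by iteration
    from vmdp300.vmd import _init_omegas, _mirror_extend

    xe, _ = _mirror_extend(x)
    x_hat = np.fft.rfft(xe)
    freqs = np.fft.rfftfreq(len(xe))
    omegas = _init_omegas(config)
    u = np.zeros((3, len(freqs)), dtype=complex)
    lam = np.zeros(len(freqs), dtype=complex)
    for it in range(30):
        for m in range(3):
            u[m] = mode_update(x_hat, u, lam, omegas, config.alpha, m, freqs)
            omegas[m] = center_freq_update(u[m], freqs)
        lam = dual_update(lam, x_hat, u, config.tau)
        u_ref, om_ref = traj[it]
        np.testing.assert_allclose(u, u_ref, atol=1e-8)
        np.testing.assert_allclose(omegas, om_ref, atol=1e-8)


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

class TestBatch:
    def test_matches_single_signal_path(self, rng):
        X = rng.standard_normal((6, 250))
        cfg = VMDConfig()
        modes, omegas, iters, conv = vmd_decompose_matrix(X, cfg, chunk_rows=4)
        for i in range(6):
            single = vmd_decompose(X[i], cfg)
            np.testing.assert_allclose(modes[i], single.modes, atol=1e-10)
            np.testing.assert_allclose(omegas[i], single.center_freqs, atol=1e-12)
            assert iters[i] == single.n_iters
            assert conv[i] == single.converged

    def test_shapes_and_validation(self, rng):
        X = rng.standard_normal((3, 100))
        modes, omegas, iters, conv = vmd_decompose_matrix(X, VMDConfig(n_modes=2))
        assert modes.shape == (3, 2, 100)
        assert omegas.shape == (3, 2)
        with pytest.raises(ValueError):
            vmd_decompose_matrix(X[0], VMDConfig())
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            vmd_decompose_matrix(X, VMDConfig())
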