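"""Multiple-tau correlator, virial stress and Green–Kubo integration."""

import numpy as np
import pytest

from nanostargel import ForceFieldParams, MultipleTauCorrelator, green_kubo, stress_tensor
from nanostargel.io import make_fixture


class TestMultipleTauCorrelator:
    def test_constant_input_gives_c_squared_at_all_lags(self):
        corr = MultipleTauCorrelator(p=8, m=2)
        for _ in range(200):
            corr.push(3.0)
        assert np.allclose(corr.values()[:, 0], 9.0)

    def test_alternating_input_at_level_zero(self):
        corr = MultipleTauCorrelator(p=8, m=2)
        for k in range(400):
            corr.push((-1.0) ** k)
        lags = corr.lags().astype(int)
        vals = corr.values()[:, 0]
        for lag in range(8):  # level 0 holds the raw alternating signal
            k = np.flatnonzero(lags == lag)[0]
            assert vals[k] == pytest.approx((-1.0) ** lag)

    def test_lag_zero_equals_second_moment(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        corr = MultipleTauCorrelator(p=16, m=2)
        for v in x:
            corr.push(v)
        vals = corr.values()[:, 0]
        lags = corr.lags()
        assert vals[np.flatnonzero(lags == 0)[0]] == pytest.approx(
            np.mean(x * x), rel=1e-10
        )

    def test_matches_bruteforce_autocorrelation_of_correlated_noise(self):
        """Agreement with the direct estimator at overlapping lags (AR(1) input)."""
        rng = np.random.default_rng(2)
        n = 20000
        phi = 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for k in range(1, n):
            x[k] = phi * x[k - 1] + rng.standard_normal()
        corr = MultipleTauCorrelator(p=16, m=2)
        for v in x:
            corr.push(v)
        lags = corr.lags().astype(int)
        vals = corr.values()[:, 0]
        for lag in (0, 1, 4, 8, 15, 16, 24, 30):
            direct = np.mean(x[: n - lag] * x[lag:])
            k = np.flatnonzero(lags == lag)[0]
            # small bias from block averaging at coarse levels is allowed
            assert vals[k] == pytest.approx(direct, rel=0.1, abs=0.1)

    def test_multichannel_shapes(self):
        corr = MultipleTauCorrelator(p=8, m=2, n_channels=3)
        for k in range(100):
            corr.push([1.0, 2.0, 3.0])
        vals = corr.values()
        assert vals.shape[1] == 3
        assert np.allclose(vals[0], [1.0, 4.0, 9.0])


class TestStressTensor:
    def test_no_interactions_zero_stress(self):
        st = make_fixture("gas", N=4, box_L=40.0, seed=3, min_core_distance=8.0)
        assert np.allclose(stress_tensor(st, ForceFieldParams()), 0.0)

    def test_axis_aligned_dimer_has_zero_offdiagonal_stress(self):
        """A pair bonded along x contributes r_x F_x only: P_xy = P_xz = P_yz = 0."""
        st = make_fixture("dimer")
        assert np.allclose(stress_tensor(st, ForceFieldParams()), 0.0, atol=1e-12)

    def test_matches_bruteforce_virial(self):
        """Off-diagonal stress equals an independent O(N^2) pair-sum."""
        from nanostargel.potentials import morse_force, wca_force
        from nanostargel.geometry import PATCH

        st = make_fixture("gas", N=6, box_L=9.0, seed=9, min_core_distance=2.0)
        ff = ForceFieldParams()
        got = stress_tensor(st, ff)
        pos = st.bead_positions()
        types = np.tile(st.template.bead_types, 6)
        mol = np.repeat(np.arange(6), 10)
        w = np.zeros((3, 3))
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if mol[i] == mol[j]:
                    continue
                pi, pj = types[i] == PATCH, types[j] == PATCH
                if pi != pj:
                    continue
                d = pos[i] - pos[j]
                d -= st.box_L * np.round(d / st.box_L)
                r = np.linalg.norm(d)
                if pi and pj:
                    fmag = float(morse_force(r, ff))
                elif r < ff.r_cut_wca:
                    fmag = float(wca_force(r, ff))
                else:
                    continue
                F = fmag * d / r
                w += np.outer(d, F)
        expected = np.array([w[0, 1], w[0, 2], w[1, 2]]) / st.box_L**3
        assert np.allclose(got, expected, atol=1e-10)


class TestGreenKubo:
    def test_synthetic_exponential_integrates_to_g0_tau(self):
        """G(t) = G0 exp(-t/tau) must integrate to eta = G0 * tau."""
        G0, tau = 2.5, 8.0
        dt = 0.05
        V, T = 10.0, 1.0
        lags = np.arange(0, 20 * tau / dt)  # in sampling-interval units
        C = (G0 * T / V) * np.exp(-lags * dt / tau)  # per channel
        res = green_kubo((lags, np.tile(C[:, None], 3)), V=V, T=T, dt_sample=dt)
        assert res.eta == pytest.approx(G0 * tau, rel=1e-3)

    def test_noisy_exponential_recovers_g0_tau(self):
        """Streaming AR(1) stress with known relaxation integrates to ~G0*tau."""
        G0, tau = 2.5, 8.0
        dt = 0.05
        corr = MultipleTauCorrelator(p=16, m=2, n_channels=3)
        n = 60000
        phi = np.exp(-dt / tau)
        rng = np.random.default_rng(4)
        x = np.empty((n, 3))
        x[0] = rng.standard_normal(3)
        eps = rng.standard_normal((n, 3)) * np.sqrt(1 - phi * phi)
        for k in range(1, n):
            x[k] = phi * x[k - 1] + eps[k]
        V, T = 10.0, 1.0
        scale = np.sqrt(G0 * T / V)  # each channel variance G0*T/V -> G(0)=G0
        for v in x * scale:
            corr.push(v)
        res = green_kubo(corr, V=V, T=T, dt_sample=dt)
        assert res.eta == pytest.approx(G0 * tau, rel=0.6)

    def test_component_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((5000, 3))
        a = MultipleTauCorrelator(p=16, m=2, n_channels=3)
        b = MultipleTauCorrelator(p=16, m=2, n_channels=3)
        for v in x:
            a.push(v)
            b.push(v[[2, 0, 1]])
        ra = green_kubo(a, V=1.0, T=1.0, dt_sample=1.0)
        rb = green_kubo(b, V=1.0, T=1.0, dt_sample=1.0)
        assert ra.eta == pytest.approx(rb.eta, rel=1e-12)

    def test_undecayed_g_flags_lower_bound(self):
        corr = MultipleTauCorrelator(p=8, m=2)
        for _ in range(100):
            corr.push(1.0)  # constant, never decays
        res = green_kubo(corr, V=1.0, T=1.0, dt_sample=1.0)
        assert res.lower_bound


class TestOverlapConcentration:
    def test_dense_gel_shows_viscoelastic_signatures(self):
        """At the overlap volume fraction (rho = 0.06) the bonded network is
        viscoelastic: the centre MSD is subdiffusive and the shear modulus
        G(t) holds a plateau over a decade of lag.  (The terminal recovery
        of free diffusion lies beyond desk-scale run lengths.)"""
        import nanostargel as ng
        from nanostargel.dynamics import (
            DynamicsParams, box_for_volume_fraction, random_gas_state, run,
        )
        from nanostargel.network_analysis import msd

        N = 90
        L = box_for_volume_fraction(N, 0.06)
        st = random_gas_state(N, L, 0.0, 1.0, seed=61, min_core_distance=2.0)
        ff = ForceFieldParams()
        dyn = DynamicsParams(dt=1e-4)
        run(st, ff, dyn, 1000000, record_every=0, chunk_size=50000)  # assemble
        res = run(st, ff, dyn, 600000, record_every=200, frame_every=5000,
                  chunk_size=5000)
        unw = res.frames_centers + res.frames_images * L
        lags, m = msd(unw, res.frame_times)
        sel = (lags >= 1.0) & (lags <= 5.0)
        slope = np.polyfit(np.log(lags[sel]), np.log(m[sel]), 1)[0]
        assert slope < 0.8  # subdiffusive caging by the bond network

        corr = MultipleTauCorrelator(p=16, m=2, n_channels=3)
        for s in res.stress:
            corr.push(s)
        res_gk = green_kubo(corr, V=L**3, T=1.0, dt_sample=0.02)
        G1, G5 = np.interp([1.0, 5.0], res_gk.lags, res_gk.G_of_t)
        assert G1 > 0
        assert G5 > 0.4 * G1  # plateau over ~a decade of lag
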