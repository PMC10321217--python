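"""Brownian dynamics engine: diffusion, rigidity, determinism, equilibrium."""

import numpy as np
import pytest
from scipy import stats

import nanostargel as ng
from nanostargel.dynamics import (
    DynamicsParams,
    box_for_volume_fraction,
    random_gas_state,
    run,
    step,
    volume_fraction,
)
from nanostargel.io import make_fixture

FF = ng.ForceFieldParams()
IDEAL = ng.ForceFieldParams(eps_m=0.0)


class TestVolumeFraction:
    def test_reference_study_points(self):
        assert volume_fraction(175, 40.0) == pytest.approx(0.0100, abs=2.5e-5)
        assert volume_fraction(1050, 40.0) == pytest.approx(0.06, abs=2e-4)

    def test_empty_box(self):
        assert volume_fraction(0, 40.0) == 0.0

    def test_box_solver_round_trip(self):
        L = box_for_volume_fraction(175, 0.01)
        assert volume_fraction(175, L) == pytest.approx(0.01, rel=1e-12)

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            volume_fraction(10, 0.0)


class TestRigidBodyContract:
    def test_intra_star_distances_constant_over_a_run(self):
        st = make_fixture("gas", N=6, box_L=12.0, seed=5, min_core_distance=2.0)
        ref = None
        dyn = DynamicsParams(dt=2e-4)
        for _ in range(5):
            run(st, FF, dyn, 2000, record_every=0)
            pos = st.bead_positions().reshape(6, 10, 3)
            d = np.linalg.norm(pos - pos[:, :1, :], axis=2)
            if ref is None:
                ref = d
            assert np.allclose(d, ref, atol=1e-9)

    def test_quaternions_stay_normalised(self):
        st = make_fixture("gas", N=6, box_L=12.0, seed=5, min_core_distance=2.0)
        run(st, FF, DynamicsParams(dt=2e-4), 5000, record_every=0)
        assert np.allclose(np.linalg.norm(st.quats, axis=1), 1.0, atol=1e-9)

    def test_positions_stay_wrapped(self):
        st = make_fixture("gas", N=6, box_L=8.0, seed=6, min_core_distance=2.0)
        run(st, IDEAL, DynamicsParams(dt=2e-4), 20000, record_every=0)
        assert np.all(st.centers >= 0)
        assert np.all(st.centers < st.box_L)


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self):
        a = make_fixture("gas", N=5, box_L=10.0, seed=7, min_core_distance=2.0)
        b = make_fixture("gas", N=5, box_L=10.0, seed=7, min_core_distance=2.0)
        dyn = DynamicsParams(dt=1e-4)
        ra = run(a, FF, dyn, 3000, record_every=500)
        rb = run(b, FF, dyn, 3000, record_every=500)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.quats, b.quats)
        assert np.array_equal(ra.energy, rb.energy)

    def test_step_advances_time(self):
        st = make_fixture("dimer")
        dyn = DynamicsParams(dt=1e-4)
        step(st, FF, dyn)
        assert st.step_count == 1
        assert st.time == pytest.approx(1e-4)


class TestFreeDiffusion:
    def test_msd_matches_6_dt_t(self):
        """Free-star MSD = 6 D_t t within sampling error."""
        N = 60
        st = random_gas_state(N, 60.0, 0.0, 1.0, seed=8, min_core_distance=1.0)
        dyn = DynamicsParams(dt=2e-4)
        res = run(st, IDEAL, dyn, 25000, record_every=0, frame_every=1000,
                  chunk_size=1000)
        unw = res.frames_centers + res.frames_images * st.box_L
        t = res.frame_times - res.frame_times[0]
        disp = unw - unw[0]
        msd = np.einsum("fnk,fnk->f", disp, disp) / N
        slope = np.polyfit(t, msd, 1)[0]
        assert slope == pytest.approx(6 * dyn.D_t, rel=0.15)

    def test_orientation_acf_matches_rotational_diffusion(self):
        """Arm-axis autocorrelation <e(0)*e(t)> = exp(-2 D_r t)."""
        N = 80
        st = random_gas_state(N, 80.0, 0.0, 1.0, seed=9, min_core_distance=1.0)
        dyn = DynamicsParams(dt=2e-4)
        axes = [
            np.einsum("nab,b->na", np.array([ng.geometry.quat_to_matrix(q) for q in st.quats]),
                      st.template.arm_axes[0])
        ]
        times = [0.0]
        for _ in range(25):
            run(st, IDEAL, dyn, 2500, record_every=0)  # 0.5 tau_Br
            axes.append(
                np.einsum("nab,b->na",
                          np.array([ng.geometry.quat_to_matrix(q) for q in st.quats]),
                          st.template.arm_axes[0])
            )
            times.append(st.time)
        axes = np.array(axes)
        acf = np.einsum("fnk,nk->fn", axes, axes[0]).mean(axis=1)
        t = np.array(times)
        expected = np.exp(-2 * dyn.D_r * t)
        assert np.allclose(acf, expected, atol=0.12)

    def test_ideal_gas_occupancy_is_uniform(self):
        """At eps_m = 0 the centre-of-mass distribution covers the box
        uniformly (detailed-balance sanity; samples are correlated on the
        box-crossing time, so the check uses coarse moments, not a naive
        chi-square)."""
        st = random_gas_state(40, 12.0, 0.0, 1.0, seed=10, min_core_distance=1.0)
        dyn = DynamicsParams(dt=2e-4)
        coords = []
        for _ in range(30):
            run(st, IDEAL, dyn, 2500, record_every=0)
            coords.append(st.centers.copy())
        x = np.concatenate(coords).ravel()  # pool all axes and stars
        assert x.mean() == pytest.approx(6.0, abs=0.5)
        assert x.std() == pytest.approx(12.0 / np.sqrt(12.0), abs=0.4)
        hist, _ = np.histogram(x, bins=4, range=(0, 12))
        assert np.all(np.abs(hist / hist.mean() - 1.0) < 0.35)

    def test_no_attraction_means_no_bonds(self):
        st = make_fixture("gas", N=20, box_L=26.0, seed=11)
        res = run(st, IDEAL, DynamicsParams(dt=2e-4), 20000, record_every=2000)
        assert np.all(res.n_contacts == 0)


class TestBondEquilibrium:
    def test_bond_persists_longer_cold_than_hot(self):
        """A bonded pair at T = 0.8 outlives the same pair at T = 1.4."""
        dyn = DynamicsParams(dt=1e-4)

        def bonded_fraction(T, seed):
            st = make_fixture("dimer", box_L=9.0, T=T, seed=seed)
            res = run(st, FF, dyn, 400000, record_every=200)  # 40 tau_Br
            return (res.n_contacts > 0).mean()

        assert bonded_fraction(0.8, 1) > bonded_fraction(1.4, 2) + 0.3

    def test_bd_matches_metropolis_monte_carlo(self):
        """Two-star bonded fraction from BD equals a Metropolis MC oracle of
        the same Hamiltonian, within sampling error (oracle equivalence)."""
        from nanostargel import _kernels
        from nanostargel.geometry import build_template

        T, L = 1.25, 9.0
        tpl = build_template(0.0)
        types = np.tile(tpl.bead_types, 2).astype(np.int64)
        mol = np.repeat(np.arange(2), 10).astype(np.int64)
        rcut2 = FF.r_cut_patch**2

        def beads(c, q):
            out = np.empty((20, 3))
            _kernels.build_beads(c, q, tpl.bead_positions, out)
            return out

        def energy(c, q):
            return _kernels.forces_bruteforce(
                beads(c, q), types, mol, L, FF.eps_rep, FF.sigma, FF.eps_m,
                FF.a_m, FF.r0_m, FF.r_cut_patch, FF.morse_shift,
            )[1]

        def is_bonded(c, q):
            p = beads(c, q)[[7, 8, 9, 17, 18, 19]]
            for x in range(3):
                for y in range(3, 6):
                    d = p[x] - p[y + 0]
                    d -= L * np.round(d / L)
                    if d @ d < rcut2:
                        return 1
            return 0

        rng = np.random.default_rng(33)
        centers = np.array([[L / 2 - 2.55, L / 2, L / 2], [L / 2 + 2.55, L / 2, L / 2]])
        quats = np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 1.0]])
        E = energy(centers, quats)
        bonded = 0
        nsamp = 0
        for s in range(40000):
            for i in range(2):
                c2, q2 = centers.copy(), quats.copy()
                if rng.random() < 0.5:
                    c2[i] = (c2[i] + (rng.random(3) - 0.5) * 0.4) % L
                else:
                    w = (rng.random(3) - 0.5) * 0.5
                    ang = np.linalg.norm(w)
                    if ang > 0:
                        ax = w / ang
                        dq = np.array([np.cos(ang / 2), *(np.sin(ang / 2) * ax)])
                        qw, qx, qy, qz = quats[i]
                        q2[i] = [
                            dq[0] * qw - dq[1] * qx - dq[2] * qy - dq[3] * qz,
                            dq[0] * qx + dq[1] * qw + dq[2] * qz - dq[3] * qy,
                            dq[0] * qy - dq[1] * qz + dq[2] * qw + dq[3] * qx,
                            dq[0] * qz + dq[1] * qy - dq[2] * qx + dq[3] * qw,
                        ]
                        q2[i] = np.asarray(q2[i]) / np.linalg.norm(q2[i])
                E2 = energy(c2, q2)
                if rng.random() < np.exp(min(0.0, -(E2 - E) / T)):
                    centers, quats, E = c2, q2, E2
            if s % 5 == 0:
                bonded += is_bonded(centers, quats)
                nsamp += 1
        mc = bonded / nsamp

        st = make_fixture("dimer", box_L=L, T=T, seed=44)
        res = run(st, FF, DynamicsParams(dt=1e-4), 3000000, record_every=200,
                  chunk_size=50000)
        bd = (res.n_contacts > 0).mean()
        assert bd == pytest.approx(mc, abs=0.06)

    def test_quench_with_attraction_forms_bonds(self):
        """Turning on the patch attraction at T = 0.9 grows theta from zero."""
        from nanostargel.dynamics import box_for_volume_fraction

        N = 12
        st = random_gas_state(N, box_for_volume_fraction(N, 0.02), 0.0, 0.9, seed=13)
        res = run(st, FF, DynamicsParams(dt=1e-4), 1500000, record_every=10000,
                  chunk_size=50000)
        assert res.n_contacts[0] == 0
        assert res.n_contacts[-5:].mean() > 2
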