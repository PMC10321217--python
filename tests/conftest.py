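"""Shared fixtures, including the scaled-down gel simulations.

The simulation fixtures are session-scoped and lazily built: melting
ladders, steady-state gel trajectories at T = 1.0 and dimer bond-kinetics
scans are each computed once and shared by every test that needs them.
Problem sizes are deliberately small (N = 18–40 stars, runs of a few
hundred Brownian times) so the whole suite stays desk-scale; the science
they support is statistical, not exact.
"""

import numpy as np
import pytest

import nanostargel as ng
from nanostargel.dynamics import (
    DynamicsParams,
    box_for_volume_fraction,
    random_gas_state,
    run,
)
from nanostargel.geometry import build_template
from nanostargel.network_analysis import contacts_from_state

FF = ng.ForceFieldParams()
DT = 1e-4
STEPS_PER_TAU = int(round(1.0 / DT))


def _ladder(d_p: float, seed: int):
    """Anneal a small gel at T=0.9, then step the temperature up, recording
    the steady-ish bonded fraction at each rung (graph-filtered theta)."""
    N = 24
    L = box_for_volume_fraction(N, 0.01)
    dyn = DynamicsParams(dt=DT)
    st = random_gas_state(N, L, d_p, 0.90, seed=seed)
    run(st, FF, dyn, 500 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
    temps = [0.90, 1.00, 1.10, 1.20, 1.30]
    theta_mean, theta_err = [], []
    for k, T in enumerate(temps):
        st.T = T
        if k > 0:  # re-equilibrate after the temperature step
            run(st, FF, dyn, 250 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
        ths = []
        for _ in range(12):
            run(st, FF, dyn, 10 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
            ths.append(contacts_from_state(st, FF).theta())
        theta_mean.append(float(np.mean(ths)))
        theta_err.append(float(np.std(ths) / np.sqrt(len(ths))))
    return dict(
        temperatures=np.array(temps),
        theta_mean=np.array(theta_mean),
        theta_err=np.array(theta_err),
        state=st,
        N=N,
        box_L=L,
    )


@pytest.fixture(scope="session")
def melt_planar():
    return _ladder(0.0, seed=101)


@pytest.fixture(scope="session")
def melt_nonplanar():
    return _ladder(0.6, seed=102)


def _gel(d_p: float, seed: int):
    """Steady-state gel trajectory at T = 1.0, rho = 0.01 (N = 40).

    Assembled at T = 0.95, then observed at T = 1.0: frames every 2 tau_Br
    over 300 tau_Br, virial stress every 0.02 tau_Br over the same window.
    """
    N = 40
    L = box_for_volume_fraction(N, 0.01)
    dyn = DynamicsParams(dt=DT)
    st = random_gas_state(N, L, d_p, 0.95, seed=seed)
    run(st, FF, dyn, 300 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
    st.T = 1.0
    run(st, FF, dyn, 50 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
    res = run(
        st,
        FF,
        dyn,
        300 * STEPS_PER_TAU,
        record_every=STEPS_PER_TAU // 50,
        frame_every=2 * STEPS_PER_TAU,
        chunk_size=20000,
    )
    graphs = []
    for k in range(len(res.frame_times)):
        snap = st.copy()
        snap.centers = res.frames_centers[k].copy()
        snap.quats = res.frames_quats[k].copy()
        graphs.append(contacts_from_state(snap, FF))
    return dict(
        state=st, result=res, graphs=graphs, N=N, box_L=L,
        dt_sample=DT * (STEPS_PER_TAU // 50),
    )


@pytest.fixture(scope="session")
def gel_planar():
    return _gel(0.0, seed=201)


@pytest.fixture(scope="session")
def gel_nonplanar():
    return _gel(0.6, seed=202)


def _cold_msd(gel, seed_shift: int):
    """Quench a steady-state T=1.0 gel to T=0.8 and record the centre MSD."""
    st = gel["state"].copy()
    st.T = 0.8
    dyn = DynamicsParams(dt=DT)
    run(st, FF, dyn, 30 * STEPS_PER_TAU, record_every=0, chunk_size=50000)
    res = run(
        st, FF, dyn, 120 * STEPS_PER_TAU,
        record_every=0, frame_every=STEPS_PER_TAU // 2, chunk_size=20000,
    )
    unw = res.frames_centers + res.frames_images * st.box_L
    return unw, res.frame_times


@pytest.fixture(scope="session")
def cold_msd_planar(gel_planar):
    return _cold_msd(gel_planar, 0)


@pytest.fixture(scope="session")
def cold_msd_nonplanar(gel_nonplanar):
    return _cold_msd(gel_nonplanar, 1)


@pytest.fixture(scope="session")
def dimer_kinetics():
    """Bond on/off series of an isolated bonded pair across temperatures.

    The contact-count autocorrelation of a single bond decays on the bond
    lifetime, the same activation scale that controls the network relaxation
    time; a dimer makes the Arrhenius scan affordable.
    """
    from nanostargel.io import make_fixture

    dyn = DynamicsParams(dt=DT)
    temps = [1.1, 1.2, 1.3, 1.4]
    out = {}
    for k, T in enumerate(temps):
        st = make_fixture("dimer", box_L=9.0, T=T, seed=301 + k)
        res = run(
            st, FF, dyn, 1200 * STEPS_PER_TAU,
            record_every=STEPS_PER_TAU // 20, chunk_size=50000,
        )
        out[T] = dict(n_contacts=res.n_contacts, dt_sample=DT * (STEPS_PER_TAU // 20))
    return out
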