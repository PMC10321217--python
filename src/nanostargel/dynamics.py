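"""Overdamped rigid-body Brownian dynamics of N nanostars in a periodic box.

Reduced units throughout: lengths in the bead diameter σ, energies in ε,
temperature in ε/k_B and time in the Brownian time τ_Br = σ²/D (the time a
single bead needs to diffuse its own diameter; D = 1 in these units).  A
star made of 7 finite-size beads gets the bead-count-scaled translational
mobility D_t = D/7 and a rotational diffusion constant D_r = 3 D_t / σ_h²
with hydrodynamic radius σ_h = 2.5σ (the gyration scale of the star); any
other consistent choice only rescales time.

The integrator is Euler–Maruyama on the star centres and orientations
(no inertia): centres advance by (D_t/k_BT) F dt plus Gaussian noise of
variance 2 D_t dt per axis, orientations by the rotation vector
(D_r/k_BT) τ dt plus angular noise of variance 2 D_r dt per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import (
    BEADS_PER_STAR,
    NanostarTemplate,
    build_template,
    quat_to_matrix,
    random_quaternion,
)
from .potentials import ForceFieldParams

__all__ = [
    "SimulationState",
    "DynamicsParams",
    "RunResult",
    "volume_fraction",
    "random_gas_state",
    "step",
    "run",
]

N_FINITE_BEADS = 7  # core + 6 arm beads carry excluded volume; patches are points


def volume_fraction(N: int, box_L: float) -> float:
    """Volume fraction ρ = N · 7 · (π/6) σ³ / L³ of N ten-site stars.

    Only the 7 finite-size beads per star count; patch sites are volumeless.
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    if box_L <= 0:
        raise ValueError("box_L must be positive")
    return N * N_FINITE_BEADS * (math.pi / 6.0) / box_L**3


def box_for_volume_fraction(N: int, rho: float) -> float:
    """Cubic box edge that gives volume fraction ``rho`` for N stars."""
    return (N * N_FINITE_BEADS * (math.pi / 6.0) / rho) ** (1.0 / 3.0)


@dataclass
class DynamicsParams:
    """Integrator and mobility parameters (reduced units)."""

    dt: float = 1e-4            #: timestep, τ_Br
    D_t: float = 1.0 / 7.0      #: star translational diffusion, σ²/τ_Br
    D_r: float = 3.0 * (1.0 / 7.0) / 2.5**2  #: star rotational diffusion, 1/τ_Br
    skin: float = 0.5           #: Verlet-list skin, σ
    displacement_cap: float = 0.1  #: max per-step move before dt halving, σ
    max_halvings: int = 4

    def __post_init__(self):
        if self.dt <= 0 or self.D_t <= 0 or self.D_r <= 0:
            raise ValueError("dt, D_t and D_r must be positive")


@dataclass
class SimulationState:
    """Positions and orientations of N rigid nanostars in a cubic box."""

    centers: np.ndarray         #: (N, 3) wrapped into [0, L)
    quats: np.ndarray           #: (N, 4) unit quaternions (w, x, y, z)
    box_L: float
    T: float                    #: temperature, ε/k_B
    template: NanostarTemplate
    seed: int
    time: float = 0.0           #: τ_Br
    step_count: int = 0
    images: np.ndarray = None   #: (N, 3) periodic image flags
    rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        self.centers = np.ascontiguousarray(self.centers, dtype=np.float64)
        self.quats = np.ascontiguousarray(self.quats, dtype=np.float64)
        if self.images is None:
            self.images = np.zeros_like(self.centers, dtype=np.int64)
        self.images = np.ascontiguousarray(self.images, dtype=np.int64)
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)
        self.centers %= self.box_L

    @property
    def n_stars(self) -> int:
        return self.centers.shape[0]

    def rotation_matrices(self) -> np.ndarray:
        return np.array([quat_to_matrix(q) for q in self.quats])

    def bead_positions(self) -> np.ndarray:
        """World-frame positions of all 10N sites (centres wrapped, beads may
        protrude through the box faces; pair distances use minimum image)."""
        out = np.empty((self.n_stars * BEADS_PER_STAR, 3))
        _kernels.build_beads(
            self.centers, self.quats, self.template.bead_positions, out
        )
        return out

    def unwrapped_centers(self) -> np.ndarray:
        return self.centers + self.images * self.box_L

    def patch_positions(self) -> np.ndarray:
        """(N, 3 arms, 3) world positions of the patch sites."""
        pos = self.bead_positions().reshape(self.n_stars, BEADS_PER_STAR, 3)
        return pos[:, self.template.patch_bead_index, :]

    def copy(self) -> "SimulationState":
        new = SimulationState(
            centers=self.centers.copy(),
            quats=self.quats.copy(),
            box_L=self.box_L,
            T=self.T,
            template=self.template,
            seed=self.seed,
            time=self.time,
            step_count=self.step_count,
            images=self.images.copy(),
        )
        new.rng = np.random.default_rng()
        new.rng.bit_generator.state = self.rng.bit_generator.state
        return new


def random_gas_state(
    N: int,
    box_L: float,
    d_p: float,
    T: float,
    seed: int,
    min_core_distance: float = 2.0,
) -> SimulationState:
    """Random non-overlapping configuration of N stars (an ε_m = 0 gas).

    Star centres are rejection-sampled so no two cores are closer than
    ``min_core_distance``; orientations are uniform. Deterministic in seed.
    """
    rng = np.random.default_rng(seed)
    template = build_template(d_p)
    centers = np.empty((N, 3))
    placed = 0
    attempts = 0
    while placed < N:
        attempts += 1
        if attempts > 100000 * max(N, 1):
            raise RuntimeError("could not place stars: box too dense for rejection sampling")
        c = rng.random(3) * box_L
        d = centers[:placed] - c
        d -= box_L * np.round(d / box_L)
        if placed and (np.einsum("ij,ij->i", d, d).min() < min_core_distance**2):
            continue
        centers[placed] = c
        placed += 1
    quats = np.array([random_quaternion(rng) for _ in range(N)])
    return SimulationState(
        centers=centers, quats=quats, box_L=box_L, T=T, template=template, seed=seed
    )


@dataclass
class RunResult:
    """Observable time series and (optionally) frames from one BD run."""

    times: np.ndarray           #: sample times, τ_Br
    energy: np.ndarray          #: total pair energy per sample, ε
    stress: np.ndarray          #: (n_samples, 3) off-diagonal P_xy, P_xz, P_yz, ε/σ³
    n_contacts: np.ndarray      #: raw patch-pair contact count per sample
    frame_times: np.ndarray = None
    frames_centers: np.ndarray = None   #: (F, N, 3) wrapped
    frames_quats: np.ndarray = None     #: (F, N, 4)
    frames_images: np.ndarray = None    #: (F, N, 3)
    n_rejected: int = 0
    n_rebuilds: int = 0


def _chunk_kernel_args(state: SimulationState, ff: ForceFieldParams, dyn: DynamicsParams):
    return dict(
        tpl=np.ascontiguousarray(state.template.bead_positions),
        tpl_types=np.ascontiguousarray(state.template.bead_types),
        box_L=float(state.box_L),
        T=float(state.T),
        dt=float(dyn.dt),
        D_t=float(dyn.D_t),
        D_r=float(dyn.D_r),
        eps_rep=float(ff.eps_rep),
        sigma=float(ff.sigma),
        eps_m=float(ff.eps_m),
        a_m=float(ff.a_m),
        r0_m=float(ff.r0_m),
        rcut_patch=float(ff.r_cut_patch),
        morse_shift=float(ff.morse_shift),
        skin=float(dyn.skin),
        disp_cap=float(dyn.displacement_cap),
        max_halvings=int(dyn.max_halvings),
    )


def step(state: SimulationState, ff: ForceFieldParams, dyn: DynamicsParams) -> SimulationState:
    """Advance one BD step in place (returns the same state object)."""
    run(state, ff, dyn, n_steps=1, record_every=0)
    return state


def run(
    state: SimulationState,
    ff: ForceFieldParams,
    dyn: DynamicsParams,
    n_steps: int,
    record_every: int = 100,
    frame_every: int | None = None,
    observers: list | None = None,
    chunk_size: int = 10000,
) -> RunResult:
    """Run ``n_steps`` of Brownian dynamics, streaming observables.

    Energy, off-diagonal virial stress and the raw patch contact count are
    sampled every ``record_every`` steps (0 disables sampling); full frames
    (centres, quaternions, image flags) are stored every ``frame_every``
    steps, at which point each callable in ``observers`` is invoked with the
    live state.  Bit-reproducible for a fixed seed and step count.

    Raises
    ------
    FloatingPointError
        If forces become non-finite (the state at the failing step is kept
        for diagnosis).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    args = _chunk_kernel_args(state, ff, dyn)
    n = state.n_stars
    n_samp_max = (n_steps // record_every + 2) if record_every else 1
    samp_step = np.empty(n_samp_max, dtype=np.int64)
    samp_E = np.empty(n_samp_max)
    samp_P = np.empty((n_samp_max, 3))
    samp_Nc = np.empty(n_samp_max, dtype=np.int64)
    all_step, all_E, all_P, all_Nc = [], [], [], []
    frames_c, frames_q, frames_i, frame_t = [], [], [], []
    n_rejected = 0
    n_rebuilds = 0
    V = state.box_L**3

    if frame_every:
        chunk_size = min(chunk_size, frame_every)
        if frame_every % chunk_size:
            raise ValueError("frame_every must be a multiple of the chunk size")

    done = 0
    step0 = state.step_count
    while done < n_steps:
        todo = min(chunk_size, n_steps - done)
        noise = state.rng.standard_normal((todo, n, 6))
        ns, nrej, nreb, nan_step = _kernels.bd_chunk(
            state.centers, state.quats, state.images,
            noise=noise,
            sample_every=record_every if record_every else 0,
            step0=state.step_count,
            samp_step=samp_step, samp_E=samp_E, samp_P=samp_P, samp_Nc=samp_Nc,
            **args,
        )
        if nan_step >= 0:
            raise FloatingPointError(
                f"non-finite forces (or pair-list overflow) at step "
                f"{state.step_count + nan_step}; state retained for diagnosis"
            )
        n_rejected += nrej
        n_rebuilds += nreb
        if ns:
            all_step.append(samp_step[:ns].copy())
            all_E.append(samp_E[:ns].copy())
            all_P.append(samp_P[:ns].copy())
            all_Nc.append(samp_Nc[:ns].copy())
        done += todo
        state.step_count += todo
        state.time += todo * dyn.dt
        if frame_every and (state.step_count - step0) % frame_every == 0:
            frames_c.append(state.centers.copy())
            frames_q.append(state.quats.copy())
            frames_i.append(state.images.copy())
            frame_t.append(state.time)
            if observers:
                for obs in observers:
                    obs(state)

    if all_step:
        steps_arr = np.concatenate(all_step)
        times = (steps_arr - step0) * dyn.dt + (state.time - n_steps * dyn.dt)
        energy = np.concatenate(all_E)
        stress = np.concatenate(all_P) / V
        ncont = np.concatenate(all_Nc)
    else:
        times = np.empty(0)
        energy = np.empty(0)
        stress = np.empty((0, 3))
        ncont = np.empty(0, dtype=np.int64)

    return RunResult(
        times=times,
        energy=energy,
        stress=stress,
        n_contacts=ncont,
        frame_times=np.array(frame_t) if frame_t else None,
        frames_centers=np.array(frames_c) if frames_c else None,
        frames_quats=np.array(frames_q) if frames_q else None,
        frames_images=np.array(frames_i) if frames_i else None,
        n_rejected=n_rejected,
        n_rebuilds=n_rebuilds,
    )
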