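"""Pair interactions: WCA excluded volume and patch–patch Morse attraction.

Beads of different nanostars repel through a purely repulsive truncated and
shifted Lennard-Jones (WCA) potential of diameter σ, so stars cannot
interpenetrate.  The sticky-end hybridisation between two stars is modelled
by a short-ranged Morse well between patch sites,

    U_M(r) = ε_m [(1 − exp(−a_m (r − r0_m)))² − 1],

truncated (and by default shifted to zero) at ``r_cut = r0_m + 0.2 σ`` so
that patches attract each other within a radius of 0.2σ.  Patch sites are
massless interaction points: they feel the Morse well only, never the WCA.

Default Morse parameters (ε_m = 14ε, a_m = 12/σ, r0_m = 0.45σ) are a
calibration of the free well parameters against the bulk behaviour the model
must reproduce: with them a percolating gel melts near T_m ≈ 1 ε/k_B at
volume fraction ρ = 0.01, the effective well depth ε_m(1 − e^{−0.2 a_m})² ≈
11.6ε sets the Arrhenius activation energy of network reconfiguration, and
the well (width 1/a_m ≈ 0.08σ) is wide enough for the Brownian integrator to
resolve at its default timestep.  Together with the patch offset of 2.325σ
the bonded core–core distance is ≈ 5σ, the first peak of the gel's g(r).
A deliberate trade-off of the wide well is that triple-patch clusters are
not strictly excluded energetically; the contact-graph analysis enforces the
single-bond-per-patch accounting (nearest partner wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import _kernels
from .geometry import PATCH

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import SimulationState

__all__ = [
    "ForceFieldParams",
    "wca_energy",
    "wca_force",
    "morse_energy",
    "morse_force",
    "compute_forces",
    "ForcesResult",
    "PATCH_ATTRACTION_RADIUS",
]

#: Range of the patch–patch attraction beyond the Morse minimum, in σ.
PATCH_ATTRACTION_RADIUS = 0.2

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: Bead pairs closer than this indicate an integration instability.
OVERLAP_WARN_DISTANCE = 0.5


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the pair interactions, in reduced units (σ = ε = 1)."""

    sigma: float = 1.0
    eps_rep: float = 1.0     #: WCA strength
    eps_m: float = 14.0      #: Morse well depth
    a_m: float = 12.0        #: Morse inverse width, 1/σ
    r0_m: float = 0.45       #: Morse minimum position, σ
    shift: bool = True       #: shift Morse energy to zero at the cutoff

    def __post_init__(self):
        if self.eps_m < 0:
            raise ValueError("eps_m must be non-negative")
        if self.eps_rep <= 0 or self.sigma <= 0 or self.a_m <= 0:
            raise ValueError("sigma, eps_rep and a_m must be positive")

    @property
    def r_cut_patch(self) -> float:
        """Patch–patch cutoff: r0_m + 0.2σ (attraction radius of 0.2σ)."""
        return self.r0_m + PATCH_ATTRACTION_RADIUS * self.sigma

    @property
    def r_cut_wca(self) -> float:
        return WCA_CUTOFF * self.sigma

    @property
    def morse_shift(self) -> float:
        """Energy subtracted from the Morse well so U(r_cut) = 0 (if shifted)."""
        if not self.shift:
            return 0.0
        x = 1.0 - np.exp(-self.a_m * (self.r_cut_patch - self.r0_m))
        return self.eps_m * (x * x - 1.0)


def wca_energy(r, params: ForceFieldParams = ForceFieldParams()):
    """Purely repulsive WCA energy at centre distance ``r`` (> 0).

    4 ε_rep [(σ/r)¹² − (σ/r)⁶] + ε_rep for r < 2^{1/6} σ, zero beyond.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("wca_energy requires r > 0")
    sr6 = (params.sigma / r) ** 6
    e = 4.0 * params.eps_rep * (sr6 * sr6 - sr6) + params.eps_rep
    return np.where(r < params.r_cut_wca, e, 0.0)


def wca_force(r, params: ForceFieldParams = ForceFieldParams()):
    """Magnitude of the WCA pair force −dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("wca_force requires r > 0")
    sr6 = (params.sigma / r) ** 6
    f = 24.0 * params.eps_rep * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r < params.r_cut_wca, f, 0.0)


def morse_energy(r, params: ForceFieldParams = ForceFieldParams()):
    """Morse patch–patch energy at distance ``r`` (≥ 0), truncated/shifted."""
    r = np.asarray(r, dtype=float)
    x = 1.0 - np.exp(-params.a_m * (r - params.r0_m))
    e = params.eps_m * (x * x - 1.0) - params.morse_shift
    return np.where(r < params.r_cut_patch, e, 0.0)


def morse_force(r, params: ForceFieldParams = ForceFieldParams()):
    """Morse pair force −dU/dr (negative = attractive, r > r0_m)."""
    r = np.asarray(r, dtype=float)
    ex = np.exp(-params.a_m * (r - params.r0_m))
    f = -2.0 * params.eps_m * params.a_m * (1.0 - ex) * ex
    return np.where(r < params.r_cut_patch, f, 0.0)


@dataclass
class ForcesResult:
    """Per-bead forces plus the scalar energy and virial of one configuration."""

    forces: np.ndarray          #: (10N, 3) force on every bead, ε/σ
    energy: float               #: total pair energy, ε
    virial: np.ndarray          #: (3, 3) Σ_pairs r_ij ⊗ F_ij, ε
    n_overlaps: int = 0         #: bead pairs closer than 0.5σ (instability flag)
    star_forces: np.ndarray = field(default=None)   #: (N, 3) net rigid-body forces
    star_torques: np.ndarray = field(default=None)  #: (N, 3) net rigid-body torques


def compute_forces(state: "SimulationState", params: ForceFieldParams) -> ForcesResult:
    """Forces, energy and virial of the full configuration.

    Patch–patch pairs interact through the Morse well; CORE/ARM bead pairs of
    different stars through the WCA repulsion; patch–bead cross pairs and all
    intramolecular pairs are excluded (the star is rigid).  Distances use the
    minimum-image convention in the cubic periodic box.
    """
    pos = state.bead_positions()
    tpl = state.template
    n = state.n_stars
    bead_types = np.tile(tpl.bead_types, n)
    mol = np.repeat(np.arange(n), tpl.bead_positions.shape[0])
    forces, energy, virial, n_overlap = _kernels.forces_bruteforce(
        pos,
        bead_types.astype(np.int64),
        mol.astype(np.int64),
        state.box_L,
        params.eps_rep,
        params.sigma,
        params.eps_m,
        params.a_m,
        params.r0_m,
        params.r_cut_patch,
        params.morse_shift,
    )
    if n_overlap:
        import logging

        logging.getLogger(__name__).warning(
            "%d bead pair(s) closer than %.2fσ: integration may be unstable",
            n_overlap,
            OVERLAP_WARN_DISTANCE,
        )
    # net force and torque per rigid body
    nb = tpl.bead_positions.shape[0]
    fb = forces.reshape(n, nb, 3)
    star_forces = fb.sum(axis=1)
    offsets = np.einsum("nij,bj->nbi", state.rotation_matrices(), tpl.bead_positions)
    star_torques = np.cross(offsets, fb).sum(axis=1)
    return ForcesResult(
        forces=forces,
        energy=float(energy),
        virial=virial,
        n_overlaps=int(n_overlap),
        star_forces=star_forces,
        star_torques=star_torques,
    )
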