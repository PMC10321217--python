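"""Rigid nanostar geometry.

A trivalent DNA nanostar is coarse-grained as a rigid body of ten sites:
one core bead, two beads per arm (at 1σ and 2σ from the core along the arm
axis) and one attractive patch site near the tip of each arm.  The shape of
the star is controlled by a single dimensionless number, the planarity
``d_p``: the distance from the core to the plane through the tips of the
three *normalised* arm vectors.  ``d_p = 0`` is a flat Y with 120° between
arms; as ``d_p → 1`` the three arms collapse onto a single axis.

All lengths are in units of the bead diameter σ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "NanostarTemplate",
    "build_template",
    "compute_dp",
    "dp_symmetric_limit",
    "compute_alpha",
    "alpha_from_dp",
    "bending_angle",
    "bending_angle_axes",
    "quat_to_matrix",
    "random_quaternion",
    "world_arm_axes",
    "CORE",
    "ARM",
    "PATCH",
    "N_ARMS",
    "BEADS_PER_STAR",
    "PATCH_OFFSET",
]

# Bead type codes shared by the whole package.
CORE, ARM, PATCH = 0, 1, 2
BEAD_TYPE_NAMES = {CORE: "CORE", ARM: "ARM", PATCH: "PATCH"}
BEAD_TYPE_CODES = {v: k for k, v in BEAD_TYPE_NAMES.items()}

N_ARMS = 3  # valence f
ARM_BEAD_OFFSETS = (1.0, 2.0)  # arm bead centres along the arm axis, in σ
BEADS_PER_STAR = 1 + N_ARMS * (len(ARM_BEAD_OFFSETS) + 1)  # = 10

#: Distance of the patch interaction site from the core, along the arm axis.
#: The patch sits near the surface of the outermost arm bead, recessed by
#: half the patch-bond length so that two hybridised stars have their cores
#: ~5σ apart (the first-neighbour distance of the gel network).
PATCH_OFFSET = 2.325

_DEGENERATE_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent nanostar geometry."""


@dataclass(frozen=True)
class NanostarTemplate:
    """Body-frame description of one rigid nanostar.

    Attributes
    ----------
    d_p:
        Target planarity of the template, in [0, 1).
    arm_axes:
        (3, 3) array of unit vectors ê_1, ê_2, ê_3 from the core along the
        three arms, in the body frame.
    bead_positions:
        (10, 3) body-frame positions: core, then the two beads of each arm,
        then the three patch sites.
    bead_types:
        (10,) integer array of CORE/ARM/PATCH codes.
    patch_offset:
        Distance of each patch site from the core, in σ.
    """

    d_p: float
    arm_axes: np.ndarray
    bead_positions: np.ndarray
    bead_types: np.ndarray
    patch_offset: float = PATCH_OFFSET
    f: int = N_ARMS
    sigma: float = 1.0
    patch_bead_index: np.ndarray = field(init=False)

    def __post_init__(self):
        idx = np.flatnonzero(self.bead_types == PATCH)
        object.__setattr__(self, "patch_bead_index", idx)


def build_template(d_p: float, patch_offset: float = PATCH_OFFSET) -> NanostarTemplate:
    """Build the symmetric rigid template for a given planarity.

    The three arm axes make a polar angle ψ = arccos(d_p) with the symmetry
    axis (+z) and sit 120° apart in azimuth, which is the tetrahedron-with-
    equilateral-base geometry: ``compute_dp`` on the result returns ``d_p``.

    Raises
    ------
    GeometryError
        If ``d_p`` is outside [0, 1); d_p = 1 would make the arms colinear
        and the tip plane undefined.
    """
    if not 0.0 <= d_p < 1.0:
        raise GeometryError(
            f"d_p={d_p!r} outside [0, 1): d_p -> 1 collapses the three arms "
            "onto one axis and the tip plane becomes degenerate"
        )
    psi = np.arccos(d_p)
    az = 2.0 * np.pi * np.arange(N_ARMS) / N_ARMS
    axes = np.column_stack(
        [np.sin(psi) * np.cos(az), np.sin(psi) * np.sin(az), np.full(N_ARMS, np.cos(psi))]
    )
    beads = np.zeros((BEADS_PER_STAR, 3))
    types = np.zeros(BEADS_PER_STAR, dtype=np.int64)
    k = 1
    for arm in range(N_ARMS):
        for off in ARM_BEAD_OFFSETS:
            beads[k] = off * axes[arm]
            types[k] = ARM
            k += 1
    for arm in range(N_ARMS):
        beads[k] = patch_offset * axes[arm]
        types[k] = PATCH
        k += 1
    return NanostarTemplate(
        d_p=float(d_p),
        arm_axes=axes,
        bead_positions=beads,
        bead_types=types,
        patch_offset=float(patch_offset),
    )


def compute_dp(arm_axes: np.ndarray, tol: float = _DEGENERATE_TOL) -> float:
    """Planarity of three arm unit vectors.

    Returns the unsigned distance from the origin (the core) to the unique
    plane through the tips of the three normalised arm vectors.

    Raises
    ------
    GeometryError
        If the three tips are (close to) colinear so that no unique plane
        exists.  For the symmetric colinear limit use
        :func:`dp_symmetric_limit`.
    """
    p = np.asarray(arm_axes, dtype=float)
    if p.shape != (3, 3):
        raise GeometryError(f"expected three 3-vectors, got shape {p.shape}")
    norms = np.linalg.norm(p, axis=1)
    if np.any(norms < tol):
        raise GeometryError("zero-length arm vector")
    p = p / norms[:, None]
    normal = np.cross(p[1] - p[0], p[2] - p[0])
    nn = np.linalg.norm(normal)
    if nn < tol:
        raise GeometryError(
            "arm-vector tips are colinear/coincident within tolerance; "
            "no unique plane (symmetric limit: d_p = cos psi)"
        )
    return float(abs(np.dot(normal, p[0])) / nn)


def dp_symmetric_limit(psi: float) -> float:
    """d_p of a symmetric template with polar angle ``psi`` (radians): cos ψ."""
    return float(np.cos(psi))


def compute_alpha(e_i: np.ndarray, e_j: np.ndarray) -> float:
    """Angle α_ij = arccos(ê_i·ê_j) between two arm axes, in degrees."""
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    ni, nj = np.linalg.norm(e_i), np.linalg.norm(e_j)
    if abs(ni - 1.0) > 1e-8 or abs(nj - 1.0) > 1e-8:
        warnings.warn("compute_alpha: non-unit input vectors were normalised", stacklevel=2)
    c = np.dot(e_i / ni, e_j / nj)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def alpha_from_dp(d_p: float) -> float:
    """Inter-arm angle (degrees) of the symmetric template: arccos((3 d_p² − 1)/2).

    Decreasing in d_p, with α(0) = 120° and α → 0° as d_p → 1.
    """
    return float(np.degrees(np.arccos(np.clip((3.0 * d_p**2 - 1.0) / 2.0, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# quaternions and placed stars
# ---------------------------------------------------------------------------

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit quaternion (Shoemake)."""
    u1, u2, u3 = rng.random(3)
    return np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )[[3, 0, 1, 2]]  # (w, x, y, z) with w = sqrt(u1) cos(2 pi u3)


def world_arm_axes(template: NanostarTemplate, quat: np.ndarray) -> np.ndarray:
    """Arm unit vectors of a placed star in the world frame, shape (3, 3)."""
    return template.arm_axes @ quat_to_matrix(quat).T


def bending_angle_axes(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Bending angle ϕ (degrees) between two hybridised arm axes.

    ϕ is the angle between the arm axis of the first star and the *reversed*
    arm axis of the second, so that two arms joined perfectly end-to-end give
    ϕ = 0 and any kink at the junction gives ϕ > 0.
    """
    return compute_alpha(np.asarray(axis_a, float), -np.asarray(axis_b, float))


def bending_angle(
    template: NanostarTemplate,
    center_a: np.ndarray,
    quat_a: np.ndarray,
    arm_a: int,
    center_b: np.ndarray,
    quat_b: np.ndarray,
    arm_b: int,
    box_L: float,
    r_bond: float,
) -> float:
    """Bending angle ϕ between two patch-bonded arms of two placed stars.

    Raises
    ------
    GeometryError
        If the named patches are farther apart than ``r_bond`` (the arms are
        not bonded).
    """
    Ra = quat_to_matrix(quat_a)
    Rb = quat_to_matrix(quat_b)
    pa = np.asarray(center_a, float) + Ra @ (template.patch_offset * template.arm_axes[arm_a])
    pb = np.asarray(center_b, float) + Rb @ (template.patch_offset * template.arm_axes[arm_b])
    d = pa - pb
    d -= box_L * np.round(d / box_L)
    if np.linalg.norm(d) >= r_bond:
        raise GeometryError(
            f"arms ({arm_a}, {arm_b}) are not patch-bonded: patch distance "
            f"{np.linalg.norm(d):.3f}σ >= r_bond={r_bond:.3f}σ"
        )
    return bending_angle_axes(Ra @ template.arm_axes[arm_a], Rb @ template.arm_axes[arm_b])
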