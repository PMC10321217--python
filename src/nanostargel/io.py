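"""Configuration, trajectory and fixture I/O.

Trajectories are written either as extended XYZ (a ``Properties=...`` header
carrying species, molecule id and image flags) or as a LAMMPS-dump dialect
(``id mol type x y z ix iy iz``), both plain text.  Coordinates are stored
wrapped together with image flags, so unwrapping is unambiguous.  All
quantities are in reduced units (σ, ε, τ_Br); the mapping to physical units
(σ = 2.5 nm ≈ 8 bp) is provided as a documented helper and never applied
internally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import numpy as np
import yaml

from .geometry import (
    BEAD_TYPE_CODES,
    BEAD_TYPE_NAMES,
    BEADS_PER_STAR,
    N_ARMS,
    PATCH_OFFSET,
    build_template,
)
from .dynamics import SimulationState, random_gas_state, volume_fraction

__all__ = [
    "RunConfig",
    "TrajectoryFrame",
    "frame_from_state",
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "make_fixture",
    "sigma_to_nm",
]

SIGMA_NM = 2.5  #: one bead diameter in nanometres (≈ 8 bp of dsDNA)


def sigma_to_nm(length_sigma: float) -> float:
    """Convert a reduced length to nanometres (documentation helper only)."""
    return length_sigma * SIGMA_NM


MODES = ("quench", "melt_sweep", "viscosity", "metadyn_demo")


@dataclass
class RunConfig:
    """One simulation run, fully determined by these fields plus the seed."""

    N: int = 175
    d_p: float = 0.0
    box_L: float = 40.0
    T: float = 1.0
    eps_m: float = 14.0
    dt: float = 1e-4
    n_steps: int = 100000
    record_every: int = 100
    seed: int = 1
    mode: str = "quench"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("N", "box_L", "T", "dt", "n_steps", "record_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.d_p < 1.0:
            raise ValueError("d_p must lie in [0, 1)")
        if self.eps_m < 0:
            raise ValueError("eps_m must be non-negative")

    @property
    def volume_fraction(self) -> float:
        return volume_fraction(self.N, self.box_L)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, echoed into output headers."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class TrajectoryFrame:
    """One stored frame: wrapped per-bead coordinates plus image flags."""

    step: int
    time: float
    box_L: float
    mol_id: np.ndarray      #: (10N,)
    bead_type: np.ndarray   #: (10N,) CORE/ARM/PATCH codes
    positions: np.ndarray   #: (10N, 3) wrapped
    images: np.ndarray      #: (10N, 3) integer image flags

    @property
    def n_stars(self) -> int:
        return len(self.positions) // BEADS_PER_STAR

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box_L


def frame_from_state(state: SimulationState, step: int | None = None) -> TrajectoryFrame:
    """Snapshot a live simulation state into a storable frame.

    Beads are wrapped into the box individually; their image flags combine
    the star's image flag with any extra wrap of the bead offset.
    """
    n = state.n_stars
    raw = state.bead_positions()  # centres wrapped, beads may protrude
    star_images = np.repeat(state.images, BEADS_PER_STAR, axis=0)
    extra = np.floor(raw / state.box_L).astype(np.int64)
    pos = raw - extra * state.box_L
    return TrajectoryFrame(
        step=state.step_count if step is None else step,
        time=state.time,
        box_L=state.box_L,
        mol_id=np.repeat(np.arange(n), BEADS_PER_STAR),
        bead_type=np.tile(state.template.bead_types, n),
        positions=pos,
        images=star_images + extra,
    )


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, frames, mode: str = "w") -> None:
    """Write frames as extended XYZ (species, mol id, position, image flags)."""
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    with open(path, mode) as fh:
        for fr in frames:
            fh.write(f"{len(fr.positions)}\n")
            fh.write(
                f'Lattice="{fr.box_L} 0 0 0 {fr.box_L} 0 0 0 {fr.box_L}" '
                "Properties=species:S:1:mol:I:1:pos:R:3:image:I:3 "
                f"step={fr.step} time={fr.time:.8g}\n"
            )
            for t, m, p, im in zip(fr.bead_type, fr.mol_id, fr.positions, fr.images):
                fh.write(
                    f"{BEAD_TYPE_NAMES[int(t)]} {int(m)} "
                    f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {im[0]} {im[1]} {im[2]}\n"
                )


def read_xyz(path) -> list[TrajectoryFrame]:
    """Read frames written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected an atom count") from exc
        header = lines[i + 1]
        box_L = None
        step = 0
        time = 0.0
        for token in header.replace('"', " ").split():
            if token.startswith("step="):
                step = int(token[5:])
            elif token.startswith("time="):
                time = float(token[5:])
        if "Lattice=" in header:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box_L = float(lat[0])
        if box_L is None:
            raise ValueError(f"line {i + 2}: missing Lattice in extended-XYZ header")
        body = lines[i + 2 : i + 2 + nat]
        if len(body) < nat:
            raise ValueError(f"line {i + 1}: frame truncated ({len(body)}/{nat} atoms)")
        types = np.empty(nat, dtype=np.int64)
        mols = np.empty(nat, dtype=np.int64)
        pos = np.empty((nat, 3))
        img = np.empty((nat, 3), dtype=np.int64)
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(f"line {i + 3 + k}: expected 8 columns, got {len(parts)}")
            types[k] = BEAD_TYPE_CODES[parts[0]]
            mols[k] = int(parts[1])
            pos[k] = [float(x) for x in parts[2:5]]
            img[k] = [int(x) for x in parts[5:8]]
        frames.append(
            TrajectoryFrame(
                step=step, time=time, box_L=box_L,
                mol_id=mols, bead_type=types, positions=pos, images=img,
            )
        )
        i += 2 + nat
    return frames


# ---------------------------------------------------------------------------
# LAMMPS dump dialect
# ---------------------------------------------------------------------------

def write_lammps_dump(path, frames, mode: str = "w") -> None:
    """Write frames as LAMMPS dump text: ``id mol type x y z ix iy iz``."""
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    with open(path, mode) as fh:
        for fr in frames:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{fr.step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(fr.positions)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {fr.box_L:.8f}\n")
            fh.write("ITEM: ATOMS id mol type x y z ix iy iz\n")
            for k, (t, m, p, im) in enumerate(
                zip(fr.bead_type, fr.mol_id, fr.positions, fr.images)
            ):
                fh.write(
                    f"{k + 1} {int(m) + 1} {int(t) + 1} "
                    f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {im[0]} {im[1]} {im[2]}\n"
                )


def read_lammps_dump(path) -> list[TrajectoryFrame]:
    """Read frames written by :func:`write_lammps_dump`."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ValueError(f"line {i + 1}: expected 'ITEM: TIMESTEP'")
        step = int(lines[i + 1])
        nat = int(lines[i + 3])
        lo, hi = (float(x) for x in lines[i + 5].split()[:2])
        box_L = hi - lo
        cols = lines[i + 8].split()[2:]
        idx = {c: k for k, c in enumerate(cols)}
        body = lines[i + 9 : i + 9 + nat]
        if len(body) < nat:
            raise ValueError(f"line {i + 4}: frame truncated")
        types = np.empty(nat, dtype=np.int64)
        mols = np.empty(nat, dtype=np.int64)
        pos = np.empty((nat, 3))
        img = np.zeros((nat, 3), dtype=np.int64)
        for line in body:
            parts = line.split()
            k = int(parts[idx["id"]]) - 1
            mols[k] = int(parts[idx["mol"]]) - 1
            types[k] = int(parts[idx["type"]]) - 1
            pos[k] = [float(parts[idx[c]]) for c in ("x", "y", "z")]
            if "ix" in idx:
                img[k] = [int(parts[idx[c]]) for c in ("ix", "iy", "iz")]
        frames.append(
            TrajectoryFrame(
                step=step, time=float("nan"), box_L=box_L,
                mol_id=mols, bead_type=types, positions=pos, images=img,
            )
        )
        i += 9 + nat
    return frames


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, ff=None, seed: int = 1, **params) -> SimulationState:
    """Deterministic test configurations.

    ``dimer``: two planar stars bonded arm-to-arm at the Morse minimum
    (core–core distance 2·patch_offset + r0_m = 5σ).
    ``six_ring``: a closed planar ring of six stars with consecutive arms
    bonded at the Morse minimum and bending angle ϕ = 0 everywhere.
    ``gas``: N random non-overlapping stars (keyword ``N``, ``box_L``,
    ``d_p``), seeded; no patch pair within the bond range.
    """
    from .potentials import ForceFieldParams

    ff = ff or ForceFieldParams()
    bond = 2.0 * PATCH_OFFSET + ff.r0_m  # core-core distance of a bonded pair

    if name == "dimer":
        box_L = params.get("box_L", 20.0)
        template = build_template(0.0)
        c = box_L / 2.0
        centers = np.array([[c - bond / 2, c, c], [c + bond / 2, c, c]])
        # star 0 arm 0 points +x; star 1 rotated by pi about z so arm 0 points -x
        quats = np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 1.0]])
        return SimulationState(
            centers=centers, quats=quats, box_L=box_L,
            T=params.get("T", 1.0), template=template, seed=seed,
        )

    if name == "six_ring":
        box_L = params.get("box_L", 30.0)
        template = build_template(0.0)
        R = bond  # circumradius of a regular hexagon equals its side
        c = box_L / 2.0
        centers = np.empty((6, 3))
        quats = np.empty((6, 4))
        for k in range(6):
            th = 2.0 * np.pi * k / 6.0
            centers[k] = [c + R * np.cos(th), c + R * np.sin(th), c]
            nxt = np.array(
                [np.cos(2 * np.pi * (k + 1) / 6) - np.cos(th),
                 np.sin(2 * np.pi * (k + 1) / 6) - np.sin(th)]
            )
            ang = np.arctan2(nxt[1], nxt[0])  # rotate arm 0 (azimuth 0) onto it
            quats[k] = [np.cos(ang / 2.0), 0.0, 0.0, np.sin(ang / 2.0)]
        return SimulationState(
            centers=centers, quats=quats, box_L=box_L,
            T=params.get("T", 1.0), template=template, seed=seed,
        )

    if name == "gas":
        N = params.get("N", 20)
        box_L = params.get("box_L", 25.0)
        state = random_gas_state(
            N=N, box_L=box_L, d_p=params.get("d_p", 0.0),
            T=params.get("T", 1.0), seed=seed,
            min_core_distance=params.get("min_core_distance", 5.3),
        )
        return state

    raise ValueError(f"unknown fixture {name!r}; choose dimer, six_ring or gas")
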