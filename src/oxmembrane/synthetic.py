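"""Synthetic bilayer fixtures with known ground truth.

These generators produce structures and trajectories whose membrane
properties are known by construction — flat and sinusoidally undulated
bilayers, and lipids undergoing 2-D Brownian motion — so every analyzer in
:mod:`oxmembrane.membrane_props` can be validated without running molecular
dynamics.  Lipids are reduced to the beads the analyzers rely on: a ``PO4``
head bead defining the leaflet surface and one tail bead; dynamics are plain
Gaussian steps (no inertia, no interactions), which is exactly the diffusive
regime the MSD-based analysis assumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _gro
from .membrane_builder import (
    BoxSpec,
    MembraneComposition,
    allocate_counts,
)
from .lipid_topology import GRO_RESNAMES
from .membrane_props import Frame, Trajectory

__all__ = [
    "FixtureSpec",
    "make_flat_bilayer",
    "make_undulated_bilayer",
    "make_brownian_trajectory",
    "write_fixture",
]

TAIL_OFFSET = 0.9  # tail bead this far inside the head-group plane, nm


@dataclass
class FixtureSpec:
    """Ground-truth parameters of a synthetic bilayer fixture.

    ``n_per_leaflet`` lipids per leaflet at area per lipid ``apl`` (nm^2),
    head-group planes separated by ``d`` (nm), optional sinusoidal surface
    undulation of amplitude ``amplitude`` and wavelength ``wavelength`` (nm)
    along x, Gaussian head z-noise ``head_sigma`` (nm), and per-species
    lateral diffusion coefficients ``diffusion`` (nm^2/ns) sampled every
    ``dt`` ps for ``n_frames`` frames.
    """

    n_per_leaflet: int = 128
    apl: float = 0.64
    d: float = 4.0
    amplitude: float = 0.0
    wavelength: float = 10.0
    head_sigma: float = 0.0
    diffusion: dict[str, float] = field(default_factory=lambda: {"DSPC": 1.0})
    composition: dict[str, float] = field(default_factory=lambda: {"DSPC": 1.0})
    n_frames: int = 100
    dt: float = 100.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.apl, self.d, self.wavelength, self.dt) <= 0:
            raise ValueError("all fixture scales must be positive")
        if self.amplitude < 0 or self.head_sigma < 0:
            raise ValueError("amplitude and noise must be non-negative")
        if self.amplitude >= self.d / 2:
            raise ValueError("undulation amplitude must stay below d/2 "
                             "(leaflets must not interpenetrate)")

    @property
    def box(self) -> BoxSpec:
        xy = math.sqrt(self.n_per_leaflet * self.apl)
        return BoxSpec(xy, xy, self.d + 2 * TAIL_OFFSET + 4.0)


def _species_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    comp = MembraneComposition(dict(spec.composition))
    counts = allocate_counts(comp, spec.n_per_leaflet)
    order = [n for n in sorted(counts) for _ in range(counts[n])]
    rng.shuffle(order)
    return order


def _build_frame(spec: FixtureSpec, rng: np.random.Generator):
    """Common lattice layout; returns arrays plus the lipid (x, y) lattice."""
    box = spec.box
    n = spec.n_per_leaflet
    m = math.ceil(math.sqrt(n))
    k = math.ceil(n / m)
    sx, sy = box.x / m, box.y / k

    atomnames, resids, resnames = [], [], []
    xy = np.empty((2 * n, 2))
    leaflet_sign = np.empty(2 * n)
    resid = 0
    for sign in (+1.0, -1.0):
        order = _species_sequence(spec, rng)
        for site, name in enumerate(order):
            resid += 1
            xy[resid - 1] = ((site % m + 0.5) * sx, (site // m + 0.5) * sy)
            leaflet_sign[resid - 1] = sign
            gname = GRO_RESNAMES.get(name, name[:5])
            for bead in ("PO4", "C1A"):
                atomnames.append(bead)
                resids.append(resid)
                resnames.append(gname)
    return (np.asarray(atomnames, dtype=str), np.asarray(resids, dtype=np.int64),
            np.asarray(resnames, dtype=str), xy, leaflet_sign, box)


def _positions(spec: FixtureSpec, xy, leaflet_sign, box, rng) -> np.ndarray:
    """Bead coordinates for the (possibly undulated) bilayer layout."""
    z_mid = box.z / 2.0
    n_lipids = len(xy)
    surf = spec.amplitude * np.sin(2 * np.pi * xy[:, 0] / spec.wavelength)
    noise = rng.normal(0.0, spec.head_sigma, n_lipids) if spec.head_sigma else 0.0
    head_z = z_mid + leaflet_sign * spec.d / 2 + surf + noise
    tail_z = z_mid + leaflet_sign * (spec.d / 2 - TAIL_OFFSET) + surf
    pos = np.empty((2 * n_lipids, 3))
    pos[0::2, 0] = pos[1::2, 0] = xy[:, 0]
    pos[0::2, 1] = pos[1::2, 1] = xy[:, 1]
    pos[0::2, 2] = head_z
    pos[1::2, 2] = tail_z
    return pos


def _truth(spec: FixtureSpec, leaflet_sign) -> dict:
    return {
        "apl": spec.apl,
        "width": spec.d,
        "curvature": 4.0 * spec.amplitude / spec.wavelength,
        "diffusion": dict(spec.diffusion),
        "box": list(spec.box.as_tuple()),
        "leaflets": {str(i + 1): ("upper" if s > 0 else "lower")
                     for i, s in enumerate(leaflet_sign)},
    }


def make_flat_bilayer(spec: FixtureSpec) -> tuple[Frame, dict]:
    """Flat bilayer: heads at +-d/2 (+ optional noise) around the box middle.

    Ground truth: area per lipid = ``apl`` exactly, width = ``d``,
    curvature = 0.
    """
    flat = FixtureSpec(**{**asdict(spec), "amplitude": 0.0})
    return make_undulated_bilayer(flat)


def make_undulated_bilayer(spec: FixtureSpec) -> tuple[Frame, dict]:
    """Bilayer with both leaflet surfaces displaced by A*sin(2*pi*x/L).

    The common-mode undulation leaves the width unchanged; the true mean
    |gradient| of each surface is 4A/L (the average of |cos|).
    """
    rng = np.random.default_rng(spec.seed)
    atomnames, resids, resnames, xy, leaflet_sign, box = _build_frame(spec, rng)
    pos = _positions(spec, xy, leaflet_sign, box, rng)
    frame = Frame(positions=pos, box=box, time=0.0,
                  atomnames=atomnames, resids=resids, resnames=resnames)
    return frame, _truth(spec, leaflet_sign)


def make_brownian_trajectory(spec: FixtureSpec) -> tuple[Trajectory, dict]:
    """Trajectory of lipids taking independent 2-D Gaussian steps.

    Each lipid's in-plane displacement per frame is drawn with variance
    2*D*dt per axis (dt converted to ns), wrapped into the periodic box; z is
    frozen.  Seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    atomnames, resids, resnames, xy, leaflet_sign, box = _build_frame(spec, rng)
    pos0 = _positions(spec, xy, leaflet_sign, box, rng)
    n_lipids = len(xy)
    sigma_per_species = {
        s: math.sqrt(2.0 * d * spec.dt / 1000.0) for s, d in spec.diffusion.items()
    }
    lipid_resname = resnames[0::2]
    rev = {GRO_RESNAMES.get(s, s[:5]): s for s in spec.diffusion}
    missing = {rn for rn in lipid_resname if rn not in rev}
    if missing:
        raise ValueError(f"no diffusion coefficient for species {sorted(missing)}")
    sigma = np.array([sigma_per_species[rev[rn]] for rn in lipid_resname])

    frames = []
    offsets = np.zeros((n_lipids, 2))
    for t in range(spec.n_frames):
        pos = pos0.copy()
        shift = np.repeat(offsets, 2, axis=0)
        pos[:, 0] = (pos[:, 0] + shift[:, 0]) % box.x
        pos[:, 1] = (pos[:, 1] + shift[:, 1]) % box.y
        frames.append(Frame(positions=pos, box=box, time=t * spec.dt,
                            atomnames=atomnames, resids=resids, resnames=resnames))
        offsets = offsets + rng.normal(0.0, 1.0, (n_lipids, 2)) * sigma[:, None]
    truth = _truth(spec, leaflet_sign)
    truth["n_frames"] = spec.n_frames
    truth["dt_ps"] = spec.dt
    return Trajectory(frames), truth


def write_fixture(obj, truth: dict, gro_path, truth_path=None) -> None:
    """Write a fixture Frame/Trajectory as GRO plus its ground-truth JSON."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    gro_frames = [
        _gro.GroFrame(resids=f.resids, resnames=f.resnames, atomnames=f.atomnames,
                      positions=f.positions, box=f.box.as_tuple(), time=f.time)
        for f in frames
    ]
    _gro.write_frames(gro_frames, path=gro_path, title="oxmembrane fixture (synthetic)")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
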