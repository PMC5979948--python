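"""Insane-style bilayer construction: place lipids of a given composition on
per-leaflet lattices, solvate with coarse-grained water, and write GRO files.

The builder is deliberately geometric: straight lipids perpendicular to the
membrane plane, heads outward, on a square lattice whose in-plane box is
derived from the requested initial area per lipid (``box_x = box_y =
sqrt(n_per_leaflet * apl0)``), so the measured area per lipid of a fresh
build equals ``apl0`` exactly.  Energy minimization and equilibration (see
:mod:`oxmembrane.sim_pipeline`) are expected to relax the start geometry.
Species are shuffled in-plane with a seeded RNG for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _gro
from .lipid_topology import (
    GRO_RESNAMES,
    GRO_RESNAMES_REVERSE,
    LipidTopology,
    build_topology,
    parse_abbreviation,
)

__all__ = [
    "MembraneComposition",
    "BoxSpec",
    "MembraneSystem",
    "allocate_counts",
    "build_bilayer",
    "write_gro",
    "read_gro",
]

WATER_RESNAME = "W"
BEAD_DZ = 0.30          # vertical stacking between bonded beads at build time, nm
MIDPLANE_GAP = 0.16     # half-gap between the two leaflets' terminal beads, nm
PEROXIDE_DX = 0.22      # in-plane offset of a peroxide bead from its host, nm
SOLVENT_PAD = 3.0       # water slab thickness per side, nm
DEFAULT_APL0 = 0.64     # nm^2
DEFAULT_WATER_PER_LIPID = 10


@dataclass(frozen=True)
class BoxSpec:
    """Rectangular periodic box, nm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) <= 0:
            raise ValueError("box dimensions must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class MembraneComposition:
    """Mole fractions per lipid name; must sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        for name in self.fractions:
            parse_abbreviation(name)  # raises LipidError if unresolvable

    def items(self):
        return self.fractions.items()

    def key(self) -> str:
        """Canonical label, e.g. ``'DSPC=0.80,DOPC=0.20'``."""
        return ",".join(f"{n}={f:.4g}" for n, f in sorted(self.fractions.items()))


@dataclass
class MembraneSystem:
    """Placed bead coordinates with per-lipid bookkeeping.

    ``resids`` number lipids first (1..n_lipids) then water beads; ``leaflets``
    maps each lipid resid to "upper"/"lower"; ``species`` maps each lipid
    resid to its full lipid name (GRO files store the 5-char alias).
    """

    atomnames: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    positions: np.ndarray
    box: BoxSpec
    leaflets: dict[int, str] = field(default_factory=dict)
    species: dict[int, str] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def lipid_resids(self) -> np.ndarray:
        mask = self.resnames != WATER_RESNAME
        return np.unique(self.resids[mask])


def allocate_counts(composition: MembraneComposition, n_per_leaflet: int) -> dict[str, int]:
    """Integer lipid counts per leaflet by largest-remainder rounding.

    Ties in the fractional remainders are broken by lipid-name order, so the
    allocation is deterministic.
    """
    if n_per_leaflet < 1:
        raise ValueError("n_per_leaflet must be >= 1")
    names = sorted(composition.fractions)
    ideal = {n: composition.fractions[n] * n_per_leaflet for n in names}
    counts = {n: math.floor(ideal[n]) for n in names}
    short = n_per_leaflet - sum(counts.values())
    by_remainder = sorted(names, key=lambda n: (-(ideal[n] - counts[n]), n))
    for n in by_remainder[:short]:
        counts[n] += 1
    return counts


def _bead_levels(topology: LipidTopology) -> np.ndarray:
    """Stack height (integer level, 0 = bilayer midplane side) per bead."""
    n_tail = max(
        sum(1 for b in topology.beads if b.name.endswith(suffix) and b.martini_type in ("C1", "C3"))
        for suffix in "AB"
    )
    levels = np.zeros(len(topology.beads))
    for i, b in enumerate(topology.beads):
        if b.name in ("NC3", "NH3"):
            levels[i] = n_tail + 2
        elif b.name == "PO4":
            levels[i] = n_tail + 1
        elif b.name.startswith("GL"):
            levels[i] = n_tail
        else:
            j = int(b.name[1:-1])  # position within the tail, 1-based
            levels[i] = n_tail - j
    return levels


def build_bilayer(
    composition: MembraneComposition,
    n_per_leaflet: int,
    apl0: float = DEFAULT_APL0,
    water_per_lipid: int = DEFAULT_WATER_PER_LIPID,
    seed: int = 0,
) -> MembraneSystem:
    """Construct a solvated bilayer with ``n_per_leaflet`` lipids per leaflet.

    The in-plane box is ``sqrt(n_per_leaflet * apl0)`` square; lipids sit on a
    ceil(sqrt(n))-column lattice (spacing ~sqrt(apl0)), tails pointing toward
    the midplane.  Water beads fill slabs of ``SOLVENT_PAD`` nm on both sides.
    Identical seeds give bit-identical coordinates.
    """
    counts = allocate_counts(composition, n_per_leaflet)
    topologies = {name: build_topology(parse_abbreviation(name)) for name in counts}
    levels = {name: _bead_levels(t) for name, t in topologies.items()}

    box_xy = math.sqrt(n_per_leaflet * apl0)
    max_half = max(MIDPLANE_GAP + BEAD_DZ * lv.max() for lv in levels.values())
    box_z = 2.0 * (max_half + SOLVENT_PAD)
    box = BoxSpec(box_xy, box_xy, box_z)
    z_mid = box_z / 2.0

    rng = np.random.default_rng(seed)
    m = math.ceil(math.sqrt(n_per_leaflet))
    k = math.ceil(n_per_leaflet / m)
    sx, sy = box_xy / m, box_xy / k

    atomnames: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    positions: list[np.ndarray] = []
    leaflets: dict[int, str] = {}
    species: dict[int, str] = {}
    resid = 0

    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        order = [n for n in sorted(counts) for _ in range(counts[n])]
        rng.shuffle(order)
        for site, name in enumerate(order):
            resid += 1
            topo, lv = topologies[name], levels[name]
            gx = (site % m + 0.5) * sx
            gy = (site // m + 0.5) * sy
            leaflets[resid] = leaflet
            species[resid] = name
            gname = GRO_RESNAMES.get(name, name[:5])
            for i, bead in enumerate(topo.beads):
                z = z_mid + sign * (MIDPLANE_GAP + BEAD_DZ * lv[i])
                x, y = gx, gy
                # lateral spread: tail B shifted in x, peroxides in y, so no
                # two beads come closer than PEROXIDE_DX at construction
                if bead.name.endswith("B") or bead.name == "GL2":
                    x = gx + 0.25
                if bead.martini_type == "P2":
                    y += PEROXIDE_DX
                atomnames.append(bead.name)
                resids.append(resid)
                resnames.append(gname)
                positions.append(np.array([x % box_xy, y % box_xy, z]))

    # water slabs above and below the bilayer
    n_water = water_per_lipid * 2 * n_per_leaflet
    per_slab = n_water // 2
    nw = max(1, math.floor(box_xy / 0.5))
    layer = nw * nw
    for slab_sign in (+1.0, -1.0):
        n_slab = per_slab + (n_water % 2 if slab_sign > 0 else 0)
        z0 = z_mid + slab_sign * (max_half + 0.4)
        for w in range(n_slab):
            resid += 1
            zi = w // layer
            rem = w % layer
            x = (rem % nw + 0.5) * (box_xy / nw)
            y = (rem // nw + 0.5) * (box_xy / nw)
            z = z0 + slab_sign * zi * 0.45
            if not (0.2 < z < box_z - 0.2):
                raise ValueError("solvent slab overflow: box z too small")
            atomnames.append("W")
            resids.append(resid)
            resnames.append(WATER_RESNAME)
            positions.append(np.array([x, y, z]))

    return MembraneSystem(
        atomnames=np.asarray(atomnames, dtype=str),
        resids=np.asarray(resids, dtype=np.int64),
        resnames=np.asarray(resnames, dtype=str),
        positions=np.vstack(positions),
        box=box,
        leaflets=leaflets,
        species=species,
    )


def write_gro(system: MembraneSystem, path=None, title: str = "oxmembrane bilayer") -> str:
    """Serialize a built system as (single-frame) GRO text."""
    frame = _gro.GroFrame(
        resids=system.resids,
        resnames=system.resnames,
        atomnames=system.atomnames,
        positions=system.positions,
        box=system.box.as_tuple(),
    )
    return _gro.write_frames([frame], path=path, title=title)


def read_gro(text: str) -> MembraneSystem:
    """Parse GRO text back into a :class:`MembraneSystem`.

    Leaflet labels are not stored in GRO and are left empty; species names are
    recovered from the 5-char residue aliases where known.
    """
    frame = _gro.parse_frames(text)[0]
    species = {}
    for resid, resname in zip(frame.resids, frame.resnames):
        if resname != WATER_RESNAME:
            species[int(resid)] = GRO_RESNAMES_REVERSE.get(resname, resname)
    return MembraneSystem(
        atomnames=frame.atomnames,
        resids=frame.resids,
        resnames=frame.resnames,
        positions=frame.positions,
        box=BoxSpec(*frame.box),
        leaflets={},
        species=species,
    )
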