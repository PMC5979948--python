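"""Membrane property analysis of coarse-grained bilayer trajectories.

Four observables characterize a bilayer here:

* **area per lipid** — in-plane box area divided by the lipid count of one
  leaflet (nm^2);
* **width** — distance between the mean z of the head-group (phosphate)
  beads of the two leaflets (nm);
* **curvature statistic** — the head groups of each leaflet are binned onto a
  periodic (x, y) grid to form a surface z(x, y); the statistic is the mean
  absolute value of the numerical gradient of that surface, averaged over the
  two leaflets (dimensionless).  Flat membranes score 0; a sinusoidal surface
  of amplitude A and wavelength L scores 4A/L;
* **lateral diffusion** — per-species D from the slope of the origin-based
  mean square displacement (D = slope/4 in 2-D), composition-weighted across
  species (nm^2/ns).

Head groups are identified by the phosphate (``PO4``) bead, present in both
PC and PE lipids.  Leaflets are assigned from phosphate z relative to the
median phosphate z of the frame, which is robust for non-porated bilayers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _gro
from .membrane_builder import BoxSpec, WATER_RESNAME, MembraneComposition
from .lipid_topology import GRO_RESNAMES_REVERSE

__all__ = [
    "Frame",
    "Trajectory",
    "LeafletAssignment",
    "PropertyReport",
    "assign_leaflets",
    "area_per_lipid",
    "membrane_width",
    "curvature_statistic",
    "msd",
    "lipid_diffusion",
    "analyze",
    "load_trajectory",
]

HEAD_BEAD = "PO4"


@dataclass
class Frame:
    """Bead positions of one time point plus per-bead lipid bookkeeping."""

    positions: np.ndarray   # (n, 3) nm
    box: BoxSpec
    time: float = 0.0       # ps
    atomnames: np.ndarray = None
    resids: np.ndarray = None
    resnames: np.ndarray = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead positions")

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.resnames != WATER_RESNAME

    @property
    def head_mask(self) -> np.ndarray:
        return self.atomnames == HEAD_BEAD

    def species_of(self, resid: int) -> str:
        name = self.resnames[self.resids == resid][0]
        return GRO_RESNAMES_REVERSE.get(name, name)

    @classmethod
    def from_gro_frame(cls, g: _gro.GroFrame) -> "Frame":
        return cls(positions=g.positions, box=BoxSpec(*g.box), time=g.time,
                   atomnames=g.atomnames, resids=g.resids, resnames=g.resnames)


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing times."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


LeafletAssignment = dict  # lipid resid -> "upper" | "lower"


def load_trajectory(source) -> Trajectory:
    """Read a (possibly multi-frame) GRO file or text into a Trajectory."""
    text = source
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError):
        pass
    return Trajectory([Frame.from_gro_frame(g) for g in _gro.parse_frames(text)])


def _head_z_per_lipid(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    mask = frame.head_mask & frame.lipid_mask
    if not mask.any():
        raise ValueError(f"no {HEAD_BEAD} head beads in frame")
    return frame.resids[mask], frame.positions[mask, 2]


def assign_leaflets(frame: Frame) -> LeafletAssignment:
    """Split lipids into leaflets by phosphate z against the median.

    Deterministic and translation invariant; valid while the bilayer is
    intact (the analyzers here do not model porated or micellized states).
    """
    resids, z = _head_z_per_lipid(frame)
    median = np.median(z)
    return {int(r): ("upper" if zz > median else "lower") for r, zz in zip(resids, z)}


def _leaflet_counts(leaflets: LeafletAssignment) -> tuple[int, int]:
    upper = sum(1 for v in leaflets.values() if v == "upper")
    lower = len(leaflets) - upper
    if upper == 0 or lower == 0:
        raise ValueError("empty leaflet")
    return upper, lower


def area_per_lipid(frame: Frame, leaflets: LeafletAssignment) -> float:
    """In-plane box area over per-leaflet lipid count (nm^2).

    With unequal leaflet populations the two per-leaflet values are averaged.
    """
    upper, lower = _leaflet_counts(leaflets)
    area = frame.box.x * frame.box.y
    return 0.5 * (area / upper + area / lower)


def membrane_width(frame: Frame, leaflets: LeafletAssignment) -> float:
    """Difference between mean head-group z of the two leaflets (nm)."""
    resids, z = _head_z_per_lipid(frame)
    sel = np.array([leaflets[int(r)] == "upper" for r in resids])
    return abs(float(z[sel].mean() - z[~sel].mean()))


def _fill_empty_cells(grid: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Fill empty bins by iterative periodic neighbour averaging."""
    filled = counts > 0
    while not filled.all():
        neigh_sum = np.zeros_like(grid)
        neigh_n = np.zeros_like(grid)
        for axis in (0, 1):
            for shift in (1, -1):
                neigh_sum += np.where(np.roll(filled, shift, axis), np.roll(grid, shift, axis), 0.0)
                neigh_n += np.roll(filled, shift, axis)
        newly = (~filled) & (neigh_n > 0)
        grid[newly] = neigh_sum[newly] / neigh_n[newly]
        if not newly.any():  # isolated region; cannot happen on periodic grid
            raise RuntimeError("periodic fill failed to converge")
        filled |= newly
    return grid


def _leaflet_gradient_mean(x, y, z, box: BoxSpec, grid_spacing: float) -> float:
    nx = max(2, int(round(box.x / grid_spacing)))
    ny = max(2, int(round(box.y / grid_spacing)))
    hx, hy = box.x / nx, box.y / ny
    ix = np.floor((x % box.x) / hx).astype(int) % nx
    iy = np.floor((y % box.y) / hy).astype(int) % ny
    zsum = np.zeros((nx, ny))
    counts = np.zeros((nx, ny))
    np.add.at(zsum, (ix, iy), z)
    np.add.at(counts, (ix, iy), 1)
    surface = np.where(counts > 0, zsum / np.maximum(counts, 1), 0.0)
    surface = _fill_empty_cells(surface, counts)
    # periodic central differences
    gx = (np.roll(surface, -1, 0) - np.roll(surface, 1, 0)) / (2 * hx)
    gy = (np.roll(surface, -1, 1) - np.roll(surface, 1, 1)) / (2 * hy)
    return float(np.mean(np.hypot(gx, gy)))


def curvature_statistic(
    frame: Frame, leaflets: LeafletAssignment, grid_spacing: float = 1.0
) -> float:
    """Mean |gradient| of the interpolated head-group surfaces.

    Each leaflet's phosphate beads are binned on a periodic (x, y) grid
    (empty cells filled by periodic neighbour interpolation), the surface
    gradient is taken by central differences, and the gradient-vector
    magnitudes are averaged; the final value averages the two leaflets.
    """
    mask = frame.head_mask & frame.lipid_mask
    resids = frame.resids[mask]
    pos = frame.positions[mask]
    values = []
    for leaflet in ("upper", "lower"):
        sel = np.array([leaflets[int(r)] == leaflet for r in resids])
        if not sel.any():
            raise ValueError(f"empty {leaflet} leaflet")
        values.append(
            _leaflet_gradient_mean(pos[sel, 0], pos[sel, 1], pos[sel, 2],
                                   frame.box, grid_spacing)
        )
    return float(np.mean(values))


def _lipid_centers(traj: Trajectory, resids: np.ndarray) -> np.ndarray:
    """(n_frames, n_lipids, 3) centers of geometry; assumes constant atom order."""
    f0 = traj[0]
    index_of = {int(r): j for j, r in enumerate(resids)}
    rows_all = np.array([index_of.get(int(r), -1) for r in f0.resids])
    sel = rows_all >= 0
    rows = rows_all[sel]
    counts = np.bincount(rows, minlength=len(resids)).astype(float)
    centers = np.empty((len(traj), len(resids), 3))
    for t, frame in enumerate(traj.frames):
        pos = frame.positions[sel]
        for d in range(3):
            centers[t, :, d] = (
                np.bincount(rows, weights=pos[:, d], minlength=len(resids)) / counts
            )
    return centers


def _unwrap(centers: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Minimum-image unwrapping of consecutive-frame displacements."""
    out = centers.copy()
    for t in range(1, len(centers)):
        delta = centers[t] - centers[t - 1]
        L = boxes[t]
        delta -= np.round(delta / L) * L
        if np.any(np.abs(delta) >= L / 2):
            raise ValueError("per-frame displacement exceeds half the box")
        out[t] = out[t - 1] + delta
    return out


def msd(traj: Trajectory, lipid_resids=None, lateral: bool = True):
    """Origin-based mean square displacement of lipid centers of geometry.

    Displacements are measured from the first frame (not sliding-window
    averaged), after minimum-image unwrapping across periodic boundaries.
    Lateral (x, y) by default; ``lateral=False`` uses all three dimensions.

    Returns ``(lag_times_ps, msd_nm2)`` with lag 0 first.
    """
    f0 = traj[0]
    if lipid_resids is None:
        lipid_resids = np.unique(f0.resids[f0.lipid_mask])
    lipid_resids = np.asarray(lipid_resids)
    boxes = np.array([[f.box.x, f.box.y, f.box.z] for f in traj.frames])
    centers = _unwrap(_lipid_centers(traj, lipid_resids), boxes)
    disp = centers - centers[0]
    if lateral:
        disp = disp[:, :, :2]
    lags = traj.times - traj.times[0]
    return lags, (disp**2).sum(axis=2).mean(axis=1)


def fit_diffusion(lags_ps: np.ndarray, msd_nm2: np.ndarray,
                  fit_window: tuple[float, float] = (0.1, 0.5)) -> float:
    """Least-squares D (nm^2/ns) from an MSD curve; D = slope/4 in 2-D.

    The fit uses lags between 10% and 50% of the trajectory span by default,
    avoiding the short-lag regime and the noisy origin-based tail.
    """
    span = lags_ps[-1]
    lo, hi = fit_window[0] * span, fit_window[1] * span
    sel = (lags_ps >= lo) & (lags_ps <= hi)
    if sel.sum() < 2:
        sel = lags_ps > 0
    slope_per_ps = np.polyfit(lags_ps[sel], msd_nm2[sel], 1)[0]
    return float(max(slope_per_ps, 0.0) * 1000.0 / 4.0)


def lipid_diffusion(
    traj: Trajectory,
    composition: MembraneComposition | dict | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
    lateral: bool = True,
) -> float:
    """Composition-weighted lateral diffusion coefficient (nm^2/ns).

    D is computed per lipid species from its MSD slope, then averaged with
    the species' mole fractions as weights.  With no composition given the
    observed count fractions are used (identical for a faithful build).
    """
    per = per_species_diffusion(traj, fit_window=fit_window, lateral=lateral)
    if composition is None:
        f0 = traj[0]
        resids = np.unique(f0.resids[f0.lipid_mask])
        species = [f0.species_of(int(r)) for r in resids]
        fracs = {s: species.count(s) / len(species) for s in set(species)}
    elif isinstance(composition, MembraneComposition):
        fracs = composition.fractions
    else:
        fracs = dict(composition)
    missing = set(fracs) - set(per)
    if any(fracs[s] > 0 for s in missing):
        raise ValueError(f"species {missing} not present in trajectory")
    return float(sum(frac * per[s] for s, frac in fracs.items() if frac > 0))


def per_species_diffusion(traj: Trajectory, fit_window=(0.1, 0.5), lateral=True) -> dict:
    f0 = traj[0]
    resids = np.unique(f0.resids[f0.lipid_mask])
    by_species: dict[str, list[int]] = {}
    for r in resids:
        by_species.setdefault(f0.species_of(int(r)), []).append(int(r))
    out = {}
    for species, ids in by_species.items():
        lags, curve = msd(traj, np.asarray(ids), lateral=lateral)
        out[species] = fit_diffusion(lags, curve, fit_window)
    return out


@dataclass
class PropertyReport:
    """The four membrane properties for one composition/trajectory."""

    area_per_lipid: float   # nm^2
    width: float            # nm
    curvature: float        # dimensionless
    diffusion: float        # nm^2/ns
    composition: dict = field(default_factory=dict)
    frames_used: int = 0

    def __post_init__(self) -> None:
        if self.area_per_lipid <= 0 or self.width <= 0:
            raise ValueError("area per lipid and width must be positive")
        if self.curvature < 0 or self.diffusion < 0:
            raise ValueError("curvature and diffusion must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def analyze(
    traj: Trajectory,
    composition: MembraneComposition | dict | None = None,
    grid_spacing: float = 1.0,
    static_fraction: float = 0.5,
    fit_window: tuple[float, float] = (0.1, 0.5),
    lateral: bool = True,
) -> PropertyReport:
    """Frame-averaged bundle of the four properties.

    Static properties (area, width, curvature) are averaged over the last
    ``static_fraction`` of frames (equilibration discard); diffusion uses the
    full trajectory.
    """
    start = int(len(traj) * (1.0 - static_fraction))
    frames = traj.frames[start:] or traj.frames
    apls, widths, curvatures = [], [], []
    for frame in frames:
        leaflets = assign_leaflets(frame)
        apls.append(area_per_lipid(frame, leaflets))
        widths.append(membrane_width(frame, leaflets))
        curvatures.append(curvature_statistic(frame, leaflets, grid_spacing))
    if len(traj) > 1:
        diffusion = lipid_diffusion(traj, composition, fit_window, lateral)
    else:
        diffusion = 0.0
    comp_dict = (composition.fractions if isinstance(composition, MembraneComposition)
                 else dict(composition or {}))
    return PropertyReport(
        area_per_lipid=float(np.mean(apls)),
        width=float(np.mean(widths)),
        curvature=float(np.mean(curvatures)),
        diffusion=diffusion,
        composition=comp_dict,
        frames_used=len(frames),
    )
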