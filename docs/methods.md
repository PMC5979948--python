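# Methods

## Scope and model

`oxmembrane` implements the desk-scale half of a coarse-grained MD study of
ferroptosis-relevant membranes: everything up to and after the engine run.
It writes MARTINI-dialect topologies and coordinates and staged GROMACS
run parameters, and analyzes trajectories; it does not integrate equations
of motion. Microsecond production runs belong to an external engine, and
the analyzers are therefore validated on synthetic trajectories with known
ground truth rather than on MD output.

## Lipid topologies

Beads follow the original MARTINI lipid mapping with a 5-bead 18-carbon
tail: Q0/Qd head (PC/PE, +1e), Qa phosphate (−1e), two Na glycerols, C1/C3
tail beads. Every generated lipid is net-neutral by construction.

Choices the mapping leaves open, fixed here deterministically:

- **22-carbon (docosahexaenoyl) tails** are 6 beads, extrapolating the
  ~3.7 carbons/bead ratio of the 5-bead 18-carbon tail. With 6 double
  bonds, every bead is C3.
- **Double-bond placement**: C3 beads are centred in the chain with a
  ceil-centred rule (`start = (n − k + 1)//2`): an 18:1 tail has bead 3 of
  5 as C3, an 18:2 tail beads 3 and 4. Cis-unsaturation sits mid-chain in
  oleoyl/linoleoyl; any fixed rule would do, but it must be deterministic.
- **Peroxide attachment**: each hydroperoxide adds one P2 bead bonded at
  0.33 nm to a C3 bead, hosts filled from the glycerol-proximal end until
  the per-tail peroxide count is exhausted. No angle term ever references
  a P2 bead, so it rotates freely about its host.
- **Force constants**: 1250 kJ·mol⁻¹·nm⁻² for all bonds, including the
  peroxide bond; angles 180°/25 kJ·mol⁻¹ for saturated triples and
  120°/45 kJ·mol⁻¹ for triples centred on a C3 bead. These are the
  standard original-MARTINI lipid values; only the two bond lengths and
  the absence of the peroxide angle are model-specific constants.

The ITP writer/reader is a closed pair: `read_itp(write_itp(t)) == t` is a
property-tested identity, and numeric fields are formatted so they
round-trip exactly.

## Bilayer construction

The builder is a simplified, seeded re-implementation of the insane
lattice-template approach. Lipids stand straight, tails toward the
midplane, on an `⌈√N⌉`-column square lattice per leaflet; the in-plane box
is `√(N·apl0)`, which makes the measured area per lipid of a fresh build
equal `apl0` exactly (the lattice spacing, `box/⌈√N⌉`, equals `√apl0` only
when `N` is a perfect square — the box contract is the one kept exact).
Defaults: `apl0 = 0.64 nm²`, 10 water beads per lipid in 3-nm slabs, both
leaflet populations equal. Species are shuffled over lattice sites with
`numpy.random.default_rng(seed)`; the same seed reproduces coordinates
bit-for-bit, different seeds permute species without touching counts, box
or z-profile. Integer counts per leaflet come from largest-remainder
rounding with ties broken by lipid name. Construction guarantees a minimum
inter-bead distance of 0.2 nm (peroxide beads are offset in y, tail B in
x); energy minimization is expected to relax the artificial start.

GRO files store residue names in a 5-character field, so the two
7-character species names use fixed aliases (`ox1DHPE→OX1DH`,
`ox2DHPE→OX2DH`, `oxDLPE→OXDLP`, `oxSLPE→OXSLP`); readers map them back.
Multi-frame trajectories are concatenated GRO frames with `t=` stamps in
the title line — plain text, valid for any GRO reader frame by frame.

## Scans and staged run inputs

A scan replaces a start lipid by an end lipid in `increment` steps
(default 0.2 → six compositions from 100:0 to 0:100), ten replicates per
composition. The bundled experiment file defines eleven scans in three
experiments (SFA:PUFA 4, PC:PE 3, lipid:ox-lipid 4). Each run gets five
run-parameter files: steepest-descent minimization, position-restrained
NVT, position-restrained NpT, free NpT, and production (default 10 µs at a
20-fs step, i.e. 5×10⁸ steps). Thermostat/barostat settings are the
standard MARTINI recommendations (310 K v-rescale, 1 bar semi-isotropic
Parrinello–Rahman, reaction-field electrostatics at 1.1 nm); only the
stage sequence and production length are protocol constants, the rest are
documented defaults. Replicate seeds are `(master·1000003 + index) mod
2³¹` — deterministic, distinct, and intended to vary both the builder's
lateral shuffle and the engine's velocity generation.

## Property analyzers

- **Head groups** are the phosphate (`PO4`) beads: present in both PC and
  PE, and the conventional reference plane. Leaflets are assigned by
  phosphate z against the median phosphate z — deterministic, translation
  invariant, and correct while the bilayer is intact (porated or
  micellized states are out of scope).
- **Area per lipid** is `box_x·box_y / N_leaflet`; with unequal leaflets
  the two per-leaflet values are averaged.
- **Width** is the difference of mean phosphate z between leaflets.
- **Curvature** bins each leaflet's phosphate beads onto a periodic grid
  (default spacing 1.0 nm; empty cells filled by iterative periodic
  neighbour averaging), takes periodic central-difference gradients, and
  averages the gradient magnitudes over cells and then over the two
  leaflets. On a sinusoid of amplitude A and wavelength L the true mean
  |gradient| is 4A/L; the central-difference estimate carries a
  `sin(kh)/(kh)` factor (k = 2π/L, h = grid spacing), about −1.6% at
  h = L/20, which is why fine-grid checks use h ≤ 0.5 nm.
- **MSD** is origin-based (displacement from the first frame, not
  sliding-window averaged), lateral (x, y) by default with a 3-D flag,
  computed on lipid centres of geometry after minimum-image unwrapping of
  consecutive-frame displacements (each per-frame displacement must stay
  below half the box; asserted).
- **Diffusion** fits the MSD by least squares over lags between 10% and
  50% of the trajectory span — late origin-based lags are dominated by
  statistical noise — and applies `D = slope/4`; the membrane value is the
  composition-weighted mean of per-species coefficients.
- `analyze()` averages the static properties over the last 50% of frames
  (equilibration discard) and uses the full trajectory for diffusion.

## Synthetic fixtures

The generators encode exactly the statistical structure the analyzers
assume: flat or sinusoidally undulated head-group surfaces (common-mode,
so undulation leaves the width unchanged), optional Gaussian head-height
noise, and uncorrelated 2-D Gaussian steps with per-axis variance 2·D·dt
for dynamics. They deliberately omit inertia, inter-lipid interactions,
protrusion/undulation dynamics, and area/volume coupling — so passing
tests certify the estimators (binning, unwrapping, fitting, weighting),
not the physics of real bilayers. Each fixture records its ground truth
(apl, width, 4A/L, D, leaflet labels) in a JSON sidecar.

Problem sizes used in tests and in the acceptance script — 500 lipids ×
1000 frames for diffusion recovery (empirically within ~6% of truth across
seeds, bound claimed: 10%), 6400 lipids/leaflet at 0.25 nm² for the
curvature sinusoid (beads on grid-cell centres, error ~1.3% at h=0.5 nm) —
were chosen so each estimator's sampling error sits well inside its stated
tolerance while the whole suite stays interactive on one CPU.

## Known limitations

- The curvature statistic is a surface-roughness proxy (mean |∇h|), not a
  differential-geometric mean curvature; it depends mildly on grid
  spacing (refinement-stability is tested at <2% under halving).
- Leaflet assignment by median phosphate z fails for vesicles, pores and
  micelles; those regimes are explicitly out of scope.
- Origin-based MSD is noisier than sliding-window MSD at long lags; it is
  kept because it matches the definition the analysis standardizes on,
  and the fit window compensates.
- The builder makes symmetric bilayers solvated in plain water only: no
  asymmetric leaflets, ions, or curved initial geometries.
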