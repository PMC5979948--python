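"""Analyzer correctness on synthetic ground-truth fixtures.

Each analyzer is checked against closed forms (area/width arithmetic, the
4A/L sinusoid curvature), against sampling-error bounds derived from the
generator parameters, against an independent brute-force MSD oracle, and for
the invariances (translation, in-plane rotation) the definitions imply.
"""

import copy
import math

import numpy as np
import pytest

from oxmembrane.membrane_builder import BoxSpec, MembraneComposition, build_bilayer
from oxmembrane.membrane_props import (
    Frame,
    Trajectory,
    analyze,
    area_per_lipid,
    assign_leaflets,
    curvature_statistic,
    fit_diffusion,
    lipid_diffusion,
    membrane_width,
    msd,
    per_species_diffusion,
)
from oxmembrane.synthetic import (
    FixtureSpec,
    make_brownian_trajectory,
    make_flat_bilayer,
    make_undulated_bilayer,
)


def two_layer_frame(n_side=10, box=10.0, z_sep=4.0):
    """Minimal bilayer: one PO4 bead per lipid on two flat planes."""
    n = n_side * n_side
    xy = np.stack(np.meshgrid(
        (np.arange(n_side) + 0.5) * box / n_side,
        (np.arange(n_side) + 0.5) * box / n_side,
    ), axis=-1).reshape(-1, 2)
    pos = np.zeros((2 * n, 3))
    pos[:n, :2] = pos[n:, :2] = xy
    pos[:n, 2] = 5.0 + z_sep / 2
    pos[n:, 2] = 5.0 - z_sep / 2
    return Frame(
        positions=pos,
        box=BoxSpec(box, box, 10.0 + z_sep),
        atomnames=np.array(["PO4"] * 2 * n),
        resids=np.arange(1, 2 * n + 1),
        resnames=np.array(["DSPC"] * 2 * n),
    )


def shifted(frame, dx=0.0, dy=0.0, dz=0.0):
    out = copy.deepcopy(frame)
    out.positions = out.positions + np.array([dx, dy, dz])
    return out


class TestLeaflets:
    def test_flat_layers_split_perfectly(self):
        frame = two_layer_frame()
        lf = assign_leaflets(frame)
        n = len(lf) // 2
        assert all(lf[r] == "upper" for r in range(1, n + 1))
        assert all(lf[r] == "lower" for r in range(n + 1, 2 * n + 1))

    def test_translation_invariance(self):
        frame = two_layer_frame()
        assert assign_leaflets(frame) == assign_leaflets(shifted(frame, 1.2, -0.7, 3.3))

    def test_undulated_matches_generator_labels(self):
        spec = FixtureSpec(n_per_leaflet=100, apl=0.64, d=4.0,
                           amplitude=1.0, wavelength=4.0, seed=2)
        frame, truth = make_undulated_bilayer(spec)
        lf = assign_leaflets(frame)
        assert {str(k): v for k, v in lf.items()} == truth["leaflets"]


class TestAreaPerLipid:
    def test_printed_formula(self):
        frame = two_layer_frame(n_side=10, box=10.0)  # 100 lipids/leaflet
        lf = assign_leaflets(frame)
        assert area_per_lipid(frame, lf) == pytest.approx(10.0 * 10.0 / 100)

    def test_scales_with_box_area(self):
        frame = two_layer_frame()
        lf = assign_leaflets(frame)
        base = area_per_lipid(frame, lf)
        frame.box = BoxSpec(frame.box.x * 2, frame.box.y * 2, frame.box.z)
        assert area_per_lipid(frame, lf) == pytest.approx(4 * base)

    def test_builder_contract(self):
        system = build_bilayer(MembraneComposition({"DSPC": 1.0}), 25,
                               apl0=0.64, seed=0)
        frame = Frame(positions=system.positions, box=system.box,
                      atomnames=system.atomnames, resids=system.resids,
                      resnames=system.resnames)
        lf = assign_leaflets(frame)
        assert area_per_lipid(frame, lf) == pytest.approx(0.64)

    def test_unequal_leaflets_mean_of_per_leaflet_values(self):
        frame = two_layer_frame(n_side=2)  # 4 + 4 lipids
        lf = assign_leaflets(frame)
        lf[1] = "lower"  # force 3 vs 5
        area = frame.box.x * frame.box.y
        assert area_per_lipid(frame, lf) == pytest.approx(0.5 * (area / 3 + area / 5))


class TestWidth:
    def test_exact_separation(self):
        frame = two_layer_frame(z_sep=4.0)
        assert membrane_width(frame, assign_leaflets(frame)) == pytest.approx(4.0)

    def test_translation_invariance(self):
        frame = two_layer_frame(z_sep=3.0)
        lf = assign_leaflets(frame)
        assert membrane_width(shifted(frame, dz=2.5), lf) == pytest.approx(
            membrane_width(frame, lf))

    def test_noisy_heads_within_sampling_bound(self):
        sigma, n = 0.3, 400
        spec = FixtureSpec(n_per_leaflet=n, d=4.0, head_sigma=sigma, seed=4)
        frame, truth = make_flat_bilayer(spec)
        lf = assign_leaflets(frame)
        bound = 3 * sigma * math.sqrt(2 / n)
        assert membrane_width(frame, lf) == pytest.approx(truth["width"], abs=bound)

    def test_common_mode_undulation_leaves_width_unchanged(self):
        base = FixtureSpec(n_per_leaflet=400, d=4.0, seed=0)
        wavy = FixtureSpec(n_per_leaflet=400, d=4.0, amplitude=0.8,
                           wavelength=8.0, seed=0)
        f0, _ = make_flat_bilayer(base)
        f1, _ = make_undulated_bilayer(wavy)
        w0 = membrane_width(f0, assign_leaflets(f0))
        w1 = membrane_width(f1, assign_leaflets(f1))
        assert w1 == pytest.approx(w0, abs=1e-9)


class TestCurvature:
    def test_flat_is_zero(self):
        frame = two_layer_frame()
        assert curvature_statistic(frame, assign_leaflets(frame), 1.0) == 0.0

    def test_sinusoid_converges_to_4A_over_L(self):
        spec = FixtureSpec(n_per_leaflet=6400, apl=0.25, amplitude=0.5,
                           wavelength=10.0, seed=0)
        frame, truth = make_undulated_bilayer(spec)
        lf = assign_leaflets(frame)
        value = curvature_statistic(frame, lf, grid_spacing=0.5)
        assert truth["curvature"] == pytest.approx(4 * 0.5 / 10.0)
        assert value == pytest.approx(truth["curvature"], rel=0.05)

    def test_grid_refinement_stability(self):
        spec = FixtureSpec(n_per_leaflet=6400, apl=0.25, amplitude=0.5,
                           wavelength=10.0, seed=0)
        frame, _ = make_undulated_bilayer(spec)
        lf = assign_leaflets(frame)
        coarse = curvature_statistic(frame, lf, grid_spacing=0.5)
        fine = curvature_statistic(frame, lf, grid_spacing=0.25)
        assert abs(fine - coarse) / coarse < 0.02

    def test_vertical_shift_invariance(self):
        spec = FixtureSpec(n_per_leaflet=400, amplitude=0.5, wavelength=8.0, seed=1)
        frame, _ = make_undulated_bilayer(spec)
        lf = assign_leaflets(frame)
        a = curvature_statistic(frame, lf, 1.0)
        b = curvature_statistic(shifted(frame, dz=1.7), lf, 1.0)
        assert b == pytest.approx(a, abs=1e-12)

    def test_square_box_quarter_rotation_invariance(self):
        # beads on cell centers of the analysis grid, so the rotated lattice
        # rebins without edge ambiguity
        spec = FixtureSpec(n_per_leaflet=1024, apl=0.25, amplitude=0.5,
                           wavelength=8.0, seed=1)
        frame, _ = make_undulated_bilayer(spec)
        lf = assign_leaflets(frame)
        rotated = copy.deepcopy(frame)
        x = rotated.positions[:, 0].copy()
        rotated.positions[:, 0] = rotated.positions[:, 1]
        rotated.positions[:, 1] = frame.box.x - x  # 90 deg about box center
        a = curvature_statistic(frame, lf, 0.5)
        b = curvature_statistic(rotated, lf, 0.5)
        assert b == pytest.approx(a, rel=1e-9)
        # area and width are also unchanged by the rotation
        assert area_per_lipid(rotated, lf) == area_per_lipid(frame, lf)
        assert membrane_width(rotated, lf) == membrane_width(frame, lf)


def brute_force_msd(traj, resids, lateral=True):
    """Independent double-loop MSD oracle with per-step minimum-image unwrap."""
    paths = {}
    for r in resids:
        f0 = traj[0]
        idx = np.flatnonzero(f0.resids == r)
        prev = f0.positions[idx].mean(axis=0)
        path = [prev.copy()]
        for frame in traj.frames[1:]:
            cur = frame.positions[idx].mean(axis=0)
            delta = cur - prev
            for d, L in enumerate((frame.box.x, frame.box.y, frame.box.z)):
                while delta[d] > L / 2:
                    delta[d] -= L
                while delta[d] < -L / 2:
                    delta[d] += L
            path.append(path[-1] + delta)
            prev = cur
        paths[r] = np.array(path)
    ndim = 2 if lateral else 3
    out = np.zeros(len(traj))
    for k in range(len(traj)):
        acc = 0.0
        for r in resids:
            disp = paths[r][k][:ndim] - paths[r][0][:ndim]
            acc += float((disp**2).sum())
        out[k] = acc / len(resids)
    return out


class TestMsd:
    def test_stationary_is_zero(self):
        spec = FixtureSpec(n_per_leaflet=8, diffusion={"DSPC": 0.0},
                           n_frames=10, seed=0)
        traj, _ = make_brownian_trajectory(spec)
        _, curve = msd(traj)
        assert np.all(curve == 0.0)

    def test_uniform_drift_closed_form(self):
        frame = two_layer_frame(n_side=2)
        frames = []
        for k in range(8):
            f = shifted(frame, dx=0.1 * k)
            f.positions[:, 0] %= f.box.x  # wrap: unwrapping must undo this
            f.time = 100.0 * k
            frames.append(f)
        lags, curve = msd(Trajectory(frames))
        assert curve == pytest.approx([(0.1 * k) ** 2 for k in range(8)])
        assert lags == pytest.approx([100.0 * k for k in range(8)])

    def test_matches_brute_force_oracle(self):
        spec = FixtureSpec(n_per_leaflet=5, apl=2.0, diffusion={"DSPC": 2.0},
                           n_frames=20, dt=50.0, seed=9)
        traj, _ = make_brownian_trajectory(spec)
        resids = np.arange(1, 11)
        _, fast = msd(traj, resids)
        slow = brute_force_msd(traj, resids)
        assert fast == pytest.approx(slow, abs=1e-10)


class TestDiffusion:
    def test_recovers_known_coefficient(self):
        spec = FixtureSpec(n_per_leaflet=250, diffusion={"DSPC": 1.0},
                           n_frames=1000, dt=100.0, seed=3)
        traj, truth = make_brownian_trajectory(spec)  # 500 lipids
        d = lipid_diffusion(traj)
        assert d == pytest.approx(truth["diffusion"]["DSPC"], rel=0.10)

    def test_weighted_average_rule(self):
        spec = FixtureSpec(
            n_per_leaflet=100,
            composition={"DSPC": 0.5, "DOPC": 0.5},
            diffusion={"DSPC": 1.0, "DOPC": 3.0},
            n_frames=200, dt=100.0, seed=5,
        )
        traj, _ = make_brownian_trajectory(spec)
        per = per_species_diffusion(traj)
        comp = MembraneComposition({"DSPC": 0.5, "DOPC": 0.5})
        # the final value is exactly the composition-weighted species mean
        assert lipid_diffusion(traj, comp) == pytest.approx(
            0.5 * per["DSPC"] + 0.5 * per["DOPC"])
        assert lipid_diffusion(traj, comp) == pytest.approx(2.0, rel=0.2)

    def test_single_species_equals_its_own_coefficient(self):
        spec = FixtureSpec(n_per_leaflet=50, diffusion={"DOPE": 1.5},
                           composition={"DOPE": 1.0}, n_frames=300, seed=8)
        traj, _ = make_brownian_trajectory(spec)
        per = per_species_diffusion(traj)
        assert lipid_diffusion(traj) == pytest.approx(per["DOPE"])

    def test_fit_diffusion_on_exact_line(self):
        lags = np.linspace(0, 1000, 101)  # ps
        curve = 4 * 2.0 * lags / 1000.0   # D = 2 nm^2/ns in 2-D
        assert fit_diffusion(lags, curve) == pytest.approx(2.0)


class TestAnalyze:
    def test_report_bundles_all_four_properties(self):
        spec = FixtureSpec(n_per_leaflet=64, d=4.0, diffusion={"DSPC": 1.0},
                           n_frames=60, dt=100.0, seed=6)
        traj, truth = make_brownian_trajectory(spec)
        report = analyze(traj, grid_spacing=1.0)
        assert report.area_per_lipid == pytest.approx(truth["apl"])
        assert report.width == pytest.approx(truth["width"])
        assert report.curvature == pytest.approx(0.0, abs=1e-12)
        assert report.diffusion > 0
        assert report.frames_used == 30  # last half

    def test_directionality_of_tail_splay_scan(self):
        """Increasing tail splay raises area per lipid and thins the membrane.

        A 6-point synthetic scan emulating the replacement of a packed lipid
        by a splayed, ferroptosis-relevant one: area per lipid rises
        monotonically while width falls monotonically.
        """
        apls, widths = [], []
        for i in range(6):
            spec = FixtureSpec(n_per_leaflet=100,
                               apl=0.60 + 0.04 * i,
                               d=4.4 - 0.15 * i,
                               seed=10 + i)
            frame, _ = make_flat_bilayer(spec)
            lf = assign_leaflets(frame)
            apls.append(area_per_lipid(frame, lf))
            widths.append(membrane_width(frame, lf))
        assert all(b > a for a, b in zip(apls, apls[1:]))
        assert all(b < a for a, b in zip(widths, widths[1:]))
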