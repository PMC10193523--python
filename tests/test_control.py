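"""Instantaneous CR concentration and the concentration-restraint force."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from cmumd import (
    CmuController,
    ControlLeg,
    RegionSpec,
    asymmetric_pair,
    bell_localizer,
    cannibalistic_pair,
    control_force,
    cr_concentration,
    face_leg,
    spherical_control,
    spherical_controller,
    symmetric_pair,
)
from cmumd.control import ControlRecord
from cmumd.engine import SOLUTE, SOLVENT, ParticleState
from cmumd.errors import ConsistencyError, GeometryError, ParameterError


def state_with(positions, species, box):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    return ParticleState(
        positions, np.zeros((n, 3)), np.asarray(species, dtype=int), np.asarray(box)
    )


BOX = np.array([4.0, 4.0, 12.0])


def region():
    # CR [4, 6] (volume 4*4*2 = 32), FR centred at 8
    return RegionSpec(cr_lo=4.0, cr_hi=6.0, fr_center=8.0, fr_width=0.5)


class TestCrConcentration:
    def test_no_particles_gives_zero(self):
        st = state_with(np.zeros((0, 3)), [], BOX)
        assert cr_concentration(st, region(), "solute", w=0.01) == 0.0

    def test_hard_count_at_midpoint(self):
        # 10 particles at the CR midpoint in a CR of volume 1*1*2 = 2
        box = np.array([1.0, 1.0, 12.0])
        pos = np.tile([0.5, 0.5, 5.0], (10, 1))
        st = state_with(pos, [SOLUTE] * 10, box)
        r = region()
        c = cr_concentration(st, r, "solute", w=r.cr_width / 1e4)
        assert c == pytest.approx(10.0 / 2.0, abs=1e-3)

    def test_uniform_fill_matches_density(self):
        """Counting statistics: CR estimate within 3 SE of the fill density."""
        rho = 0.5
        r = region()
        v_cr = r.cr_volume(BOX)
        n = int(rho * np.prod(BOX))
        est, hard = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 1, (n, 3)) * BOX
            st = state_with(pos, [SOLUTE] * n, BOX)
            est.append(cr_concentration(st, r, "solute", w=0.1))
            inside = (pos[:, 2] >= r.cr_lo) & (pos[:, 2] <= r.cr_hi)
            hard.append(inside.sum() / v_cr)
        se = np.std(est, ddof=1) / 10
        assert abs(np.mean(est) - rho) < 3 * se + 1e-9
        # the smooth estimator is unbiased against the hard count: the two
        # averages agree to 1% (plus the counting-noise allowance of this
        # sample size); per-configuration deviation is edge noise
        diff = np.array(est) - np.array(hard)
        se_diff = diff.std(ddof=1) / 10
        assert abs(diff.mean()) < 0.01 * np.mean(hard) + 3 * se_diff
        rel = np.abs(diff) / np.maximum(hard, 1e-9)
        assert rel.max() < 0.25

    def test_solvent_not_counted(self):
        pos = np.tile([0.5, 0.5, 5.0], (6, 1))
        st = state_with(pos, [SOLVENT] * 6, BOX)
        assert cr_concentration(st, region(), "solute", w=0.05) == 0.0

    def test_empty_species_label_rejected(self, rng):
        st = state_with(np.zeros((1, 3)), [SOLUTE], BOX)
        with pytest.raises(ParameterError):
            cr_concentration(st, region(), "", w=0.05)


def one_leg_controller(k=2.0, c0=0.5):
    leg = ControlLeg(region=region(), c0=c0, k=k, name="cr")
    return CmuController(variant="symmetric", legs=[leg])


class TestControlForce:
    def test_zero_at_target(self):
        ctrl = one_leg_controller()
        pos = np.array([[1.0, 1.0, 8.0], [2.0, 2.0, 5.0]])
        st = state_with(pos, [SOLUTE, SOLUTE], BOX)
        f = control_force(st, ctrl, np.array([ctrl.legs[0].c0]))
        assert np.all(f == 0.0)

    def test_magnitude_and_direction_at_fr_peak(self):
        # excess c - c0 = +0.5 with k = 2: |F| = 2 * 0.5 * G(z_F), pointing
        # away from the CR (the CR is below the FR here, so along +z)
        ctrl = one_leg_controller(k=2.0, c0=0.5)
        st = state_with([[1.0, 1.0, 8.0]], [SOLUTE], BOX)
        f = control_force(st, ctrl, np.array([1.0]))
        g_peak = bell_localizer(8.0, 8.0, 0.5)
        assert f[0, 2] == pytest.approx(2.0 * 0.5 * g_peak)
        assert f[0, 0] == f[0, 1] == 0.0

    def test_deficit_drives_toward_cr(self):
        ctrl = one_leg_controller(k=2.0, c0=0.5)
        st = state_with([[1.0, 1.0, 8.0]], [SOLUTE], BOX)
        f = control_force(st, ctrl, np.array([0.1]))
        assert f[0, 2] < 0.0  # CR lies below the FR

    def test_linear_in_k(self, rng):
        pos = np.column_stack(
            [rng.uniform(0, 4, 40), rng.uniform(0, 4, 40), rng.uniform(0, 12, 40)]
        )
        st = state_with(pos, [SOLUTE] * 40, BOX)
        f1 = control_force(st, one_leg_controller(k=3.0), np.array([0.8]))
        f2 = control_force(st, one_leg_controller(k=6.0), np.array([0.8]))
        np.testing.assert_allclose(f2, 2.0 * f1)

    def test_uncontrolled_species_feel_nothing(self):
        ctrl = one_leg_controller()
        st = state_with([[1.0, 1.0, 8.0]], [SOLVENT], BOX)
        f = control_force(st, ctrl, np.array([1.0]))
        assert np.all(f == 0.0)

    def test_locality_of_bell(self, rng):
        """The sech^2 localizer decays exponentially: the force carried by
        particles far from z_F is a negligible share of the total."""
        w_f = 3.0 / 6.0
        box = np.array([4.0, 4.0, 40.0])
        r = RegionSpec(cr_lo=4.0, cr_hi=6.0, fr_center=20.0, fr_width=w_f)
        leg = ControlLeg(region=r, c0=0.5, k=5.0)
        ctrl = CmuController(variant="symmetric", legs=[leg])
        z = rng.uniform(0, 40, 4000)
        pos = np.column_stack([rng.uniform(0, 4, 4000), rng.uniform(0, 4, 4000), z])
        st = state_with(pos, [SOLUTE] * 4000, box)
        f = np.abs(control_force(st, ctrl, np.array([1.0]))[:, 2])
        assert f[np.abs(z - r.fr_center) > 5 * w_f].sum() < 0.02 * f.sum()
        assert f[np.abs(z - r.fr_center) > 16 * w_f].sum() < 1e-6 * f.sum()

    def test_mismatched_bookkeeping_rejected(self):
        ctrl = one_leg_controller()
        st = state_with([[1.0, 1.0, 8.0]], [SOLUTE], BOX)
        with pytest.raises(ConsistencyError):
            control_force(st, ctrl, np.array([0.5, 0.6]))


class TestSymmetricPair:
    def test_mirrored_regions(self):
        ctrl = symmetric_pair(18.0, 2.0, 1.0, 3.0, 6.0, 0.8, c0=0.2, k=10.0)
        left, right = ctrl.legs[0].region, ctrl.legs[1].region
        assert left.cr_hi - 18.0 == pytest.approx(-(right.cr_lo - 18.0))
        assert left.cr_lo - 18.0 == pytest.approx(-(right.cr_hi - 18.0))
        assert left.fr_center - 18.0 == pytest.approx(-(right.fr_center - 18.0))

    def test_mirror_symmetric_configuration_gives_antisymmetric_force(self):
        box = np.array([4.0, 4.0, 36.0])
        ctrl = symmetric_pair(18.0, 2.0, 1.0, 3.0, 6.0, 0.8, c0=0.2, k=10.0)
        z = np.array([12.0, 24.0, 11.5, 24.5])  # mirror pairs through 18
        pos = np.column_stack([np.full(4, 2.0), np.full(4, 2.0), z])
        st = state_with(pos, [SOLUTE] * 4, box)
        c = ctrl.concentrations(st)
        assert c[0] == pytest.approx(c[1])
        f = control_force(st, ctrl, c)
        assert f[0, 2] == pytest.approx(-f[1, 2])
        assert f[:, 2].sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_sided_rejected(self):
        with pytest.raises(GeometryError):
            symmetric_pair(18.0, -3.0, 1.0, 3.0, 6.0, 0.8, c0=0.2, k=10.0)

    def test_overlapping_force_regions_rejected(self):
        with pytest.raises(GeometryError):
            symmetric_pair(18.0, 0.0, 0.1, 0.5, 0.7, 0.8, c0=0.2, k=10.0)


class TestAsymmetricPair:
    def in_out(self, c_in, c_out):
        inlet = face_leg(13.5, -1, 0.5, 4.0, 8.0, 0.8, c0=c_in, k=10.0)
        outlet = face_leg(16.5, +1, 0.5, 4.0, 8.0, 0.8, c0=c_out, k=10.0)
        return inlet, outlet

    def test_independent_targets(self):
        ctrl = asymmetric_pair(*self.in_out(1.0, 0.25))
        assert [leg.c0 for leg in ctrl.legs] == [1.0, 0.25]
        assert [leg.name for leg in ctrl.legs] == ["inlet", "outlet"]

    def test_equal_targets_warn_only(self):
        with pytest.warns(UserWarning, match="zero driving force"):
            asymmetric_pair(*self.in_out(0.5, 0.5))

    def test_backward_gradient_rejected(self):
        with pytest.raises(ParameterError):
            asymmetric_pair(*self.in_out(0.25, 1.0))


class TestCannibalisticPair:
    def build(self, c0_s=0.2, c0_u=0.1):
        return cannibalistic_pair(c0_s, c0_u, 15.5, 20.5, 1.5, 3.0, 6.0, 0.8, k=10.0)

    def test_targets_ordered_or_error(self):
        with pytest.raises(ParameterError):
            self.build(c0_s=0.1, c0_u=0.2)

    def test_equal_targets_degenerate_to_symmetric(self):
        with pytest.warns(UserWarning, match="symmetric"):
            ctrl = self.build(c0_s=0.15, c0_u=0.15)
        assert ctrl.legs[0].c0 == ctrl.legs[1].c0

    def test_faces_shift_regions_independently(self):
        ctrl = self.build()
        before = [leg.region.cr_lo for leg in ctrl.legs]
        ctrl.reanchor(15.0, 20.5)  # only the S face moved
        after_s, after_u = (leg.region for leg in ctrl.legs)
        assert after_s.cr_lo == pytest.approx(before[0] - 0.5)
        assert after_u.cr_lo == pytest.approx(before[1])

    def test_anchored_both_faces(self):
        ctrl = self.build()
        assert all(leg.region.anchored for leg in ctrl.legs)


class TestSphericalControl:
    BOXS = np.array([14.0, 14.0, 14.0])

    def ctrl(self, c0=0.1, k=5.0):
        return spherical_controller(
            (7, 7, 7), 3.0, 5.0, 5.8, 0.5, c0=c0, k=k, box=self.BOXS
        )

    def test_uniform_gas_shell_matches_bulk(self):
        """Counting oracle: shell concentration of a uniform fill."""
        rho = 0.3
        n = int(rho * 14.0**3)
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 14.0, (n, 3))
            st = state_with(pos, [SOLUTE] * n, self.BOXS)
            vals.append(
                cr_concentration(st, self.ctrl().legs[0].region, "solute", w=0.05)
            )
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - rho) < 3 * se + 1e-9

    def test_restraint_identity(self):
        ctrl = self.ctrl(c0=0.25)
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 14.0, (50, 3))
        st = state_with(pos, [SOLUTE] * 50, self.BOXS)
        f = control_force(st, ctrl, np.array([0.25]))
        assert np.all(f == 0.0)

    def test_particle_at_center_feels_no_force(self):
        ctrl = self.ctrl()
        st = state_with([[7.0, 7.0, 7.0]], [SOLUTE], self.BOXS)
        f = spherical_control(st, ctrl)
        assert np.all(f[0] == 0.0)

    def test_excess_pushes_outward(self):
        ctrl = self.ctrl(c0=0.1, k=5.0)
        # particle in the FR shell, displaced along +x from the center
        st = state_with([[7.0 + 5.8, 7.0, 7.0]], [SOLUTE], self.BOXS)
        f = control_force(st, ctrl, np.array([0.4]))
        assert f[0, 0] > 0.0 and f[0, 1] == f[0, 2] == 0.0

    def test_center_outside_box_rejected(self):
        with pytest.raises(GeometryError):
            spherical_controller(
                (20, 7, 7), 3.0, 5.0, 5.8, 0.5, c0=0.1, k=5.0, box=self.BOXS
            )


class TestControlRecord:
    def test_monotone_steps_enforced(self):
        rec = ControlRecord(["cr"], [0.5])
        rec.append(0, [0.5])
        rec.append(10, [0.4])
        with pytest.raises(ConsistencyError):
            rec.append(10, [0.3])

    def test_negative_concentration_rejected(self):
        rec = ControlRecord(["cr"], [0.5])
        with pytest.raises(ConsistencyError):
            rec.append(0, [-0.1])

    def test_roundtrip_csv(self, tmp_path):
        rec = ControlRecord(["left", "right"], [0.2, 0.2])
        for i in range(5):
            rec.append(i * 50, [0.2 + 0.01 * i, 0.2 - 0.01 * i], 1.0, (16.0, 20.0))
        path = tmp_path / "control.csv"
        rec.to_csv(path)
        df = ControlRecord.read_csv(path)
        assert list(df["step"]) == [0, 50, 100, 150, 200]
        assert df["c_left"].iloc[-1] == pytest.approx(0.24)
        assert df["c0_right"].iloc[0] == pytest.approx(0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
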