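"""Per-residue metrics: closed-form toys, built-model checks, invariances."""

import numpy as np
import pytest

from myotail import trajectory as tm
from myotail.ensemble import Ensemble
from myotail.geometry import backbone_from_dihedrals

from conftest import ca_ensemble, random_rigid_transform


def straight_chain(n, spacing=1.5, offset=(0.0, 0.0, 0.0)):
    pts = np.stack([np.zeros(n), np.zeros(n), spacing * np.arange(n)], axis=1)
    return pts + np.asarray(offset)


def ideal_helix_ca(n, rise=1.5, rotation_deg=100.0, radius=2.3):
    """Closed-form straight α-helix Cα trace (independent of the builder)."""
    ang = np.deg2rad(rotation_deg) * np.arange(n)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * np.arange(n)], axis=1)


class TestDcom:
    def test_parallel_lines_give_exact_distance(self, parallel_lines_ensemble):
        prof = tm.dcom_profile(parallel_lines_ensemble)
        assert np.allclose(prof.mean, 10.0)
        assert np.allclose(prof.sd, 0.0)

    def test_built_model_matches_antipodal_geometry(self, wt_model):
        """Away from termini D_com ≈ 2 × major radius."""
        ens = Ensemble.from_model(wt_model)
        prof = tm.dcom_profile(ens)
        interior = slice(10, -10)
        assert np.all(np.abs(prof.mean[interior] - 2 * wt_model.params.major_radius) < 1.0)

    def test_single_frame_sd_zero(self, parallel_lines_ensemble):
        assert np.all(tm.dcom_profile(parallel_lines_ensemble).sd == 0.0)

    def test_terminal_residues_undefined(self, parallel_lines_ensemble):
        prof = tm.dcom_profile(parallel_lines_ensemble)
        n = 30
        assert prof.res_ids[0] == 4 and prof.res_ids[-1] == n - 3


class TestHeptadLength:
    def test_straight_line_exact(self):
        ens = ca_ensemble({"A": straight_chain(30)[None]})
        prof = tm.heptad_length_profile(ens)["A"]
        assert np.allclose(prof.mean, 10.5)

    @pytest.mark.parametrize("mode", ["windowed-positions", "windowed-distances"])
    def test_ideal_helix_close_to_axial_rise(self, mode):
        """On a straight helix both window conventions give ≈ 7 × rise."""
        ens = ca_ensemble({"A": ideal_helix_ca(40)[None]})
        prof = tm.heptad_length_profile(ens, mode=mode)["A"]
        # windowed positions cancel the minor helix almost exactly;
        # windowed distances keep the Cα chord offsets
        tol = 0.05 if mode == "windowed-positions" else 0.6
        assert np.all(np.abs(prof.mean - 10.5) < tol)

    def test_scaling_homogeneity(self):
        coords = ideal_helix_ca(40)
        base = tm.heptad_length_profile(ca_ensemble({"A": coords[None]}))["A"]
        doubled = tm.heptad_length_profile(ca_ensemble({"A": (2 * coords)[None]}))["A"]
        assert np.allclose(doubled.mean, 2 * base.mean)


class TestInterHeptadAngle:
    def test_collinear_gives_180(self):
        ens = ca_ensemble({"A": straight_chain(30)[None]})
        prof = tm.inter_heptad_angle_profile(ens)["A"]
        assert np.allclose(prof.mean, 180.0)

    def test_30_degree_bend_gives_150(self):
        """A 30° direction change at the vertex yields a 150° interior angle."""
        n = 15
        before = straight_chain(8)  # indices 0..7, vertex at index 7
        direction = np.array([np.sin(np.deg2rad(30.0)), 0.0, np.cos(np.deg2rad(30.0))])
        after = before[-1] + 1.5 * np.outer(np.arange(1, 8), direction)
        chain = np.vstack([before, after])
        ens = ca_ensemble({"A": chain[None]})
        prof = tm.inter_heptad_angle_profile(ens)["A"]
        vertex = prof.value_at(8)[0]  # residue ids are 1-based
        assert vertex == pytest.approx(150.0, abs=1e-6)

    def test_ideal_helix_constant_below_180(self):
        ens = ca_ensemble({"A": ideal_helix_ca(40)[None]})
        prof = tm.inter_heptad_angle_profile(ens)["A"]
        assert np.all(prof.mean < 180.0)
        assert prof.mean.std() < 1e-6  # identical at all interior residues


class TestHelicity:
    @staticmethod
    def _backbone_ensemble(phi_psi):
        bb = backbone_from_dihedrals(phi_psi)
        n = len(phi_psi)
        names, rids, xyz = [], [], []
        for i in range(n):
            for atom in ("N", "CA", "C", "O"):
                names.append(atom)
                rids.append(i + 1)
                xyz.append(bb[atom][i])
        k = len(names)
        return Ensemble(
            np.asarray(xyz)[None], np.array(names), np.array(rids),
            np.array(["A"] * k), np.array(["ALA"] * k),
            np.array([a[0] for a in names]), np.array([1.0]),
        )

    def test_canonical_helix_fully_helical(self):
        ens = self._backbone_ensemble([(-57.0, -47.0)] * 10)
        assert tm.helicity(ens)["overall"] == pytest.approx(1.0)

    def test_extended_chain_zero(self):
        ens = self._backbone_ensemble([(-120.0, 120.0)] * 10)
        assert tm.helicity(ens)["overall"] == 0.0

    def test_half_helical_half_extended(self):
        """Interior residues split 50:50 between helix and strand dihedrals."""
        # 12 residues: φ/ψ defined for the 10 interior ones; make 5 helical
        phi_psi = [(-57.0, -47.0)] * 7 + [(-120.0, 120.0)] * 7
        ens = self._backbone_ensemble(phi_psi)
        frac = tm.helicity(ens)["overall"]
        # 12 interior residues with complete (φ,ψ); the boundary residue mixes
        assert 0.4 <= frac <= 0.6


class TestEndToEnd:
    def test_straight_model_length(self, canonical_model):
        ens = Ensemble.from_model(canonical_model)
        mean, sd = tm.end_to_end(ens)
        expected = canonical_model.axis_length() / 10.0
        assert mean == pytest.approx(expected, rel=1e-3)
        assert sd == 0.0

    def test_right_angle_bend_shortens_by_sqrt2(self):
        n = 41  # bend exactly at the midpoint
        a = straight_chain(n)
        bent = a.copy()
        mid = n // 2
        # rotate the distal half by 90° about x through the midpoint
        rot = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        bent[mid:] = (bent[mid:] - bent[mid]) @ rot.T + bent[mid]
        ens = ca_ensemble({"A": bent[None], "B": (bent + [3, 0, 0])[None]})
        straight = ca_ensemble({"A": a[None], "B": (a + [3, 0, 0])[None]})
        l_straight = tm.end_to_end(straight)[0]
        l_bent = tm.end_to_end(ens)[0]
        assert l_bent == pytest.approx(l_straight / np.sqrt(2), rel=1e-6)


class TestRigidInvariance:
    def test_profiles_invariant_under_rigid_motion(self, wt_model):
        ens = Ensemble.from_model(wt_model)
        rng = np.random.default_rng(5)
        R, t = random_rigid_transform(rng)
        moved = Ensemble(
            ens.coords @ R.T + t, ens.atom_name, ens.res_id, ens.chain_id,
            ens.res_name, ens.element, ens.times_ns,
        )
        for fn in (tm.dcom_profile,):
            assert np.allclose(fn(ens).mean, fn(moved).mean, atol=1e-8)
        for fn in (tm.heptad_length_profile, tm.inter_heptad_angle_profile):
            assert np.allclose(fn(ens)["A"].mean, fn(moved)["A"].mean, atol=1e-8)
        assert tm.end_to_end(ens)[0] == pytest.approx(tm.end_to_end(moved)[0], abs=1e-9)
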