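"""Crick-builder geometry: distances, rise, twist, symmetry, smoothing."""

import numpy as np
import pytest

from myotail.builder import BuildError, build_coiled_coil
from myotail.motifs import make_motif_schedule
from myotail.params import CrickParams
from myotail.register import NumberedSequence, assign_heptad_register

CANONICAL_TWIST = -(360.0 * (2.0 / 7.0 - 1.0 / 3.617))  # deg/residue, left-handed


def fitted_supercoil_twist(ca: np.ndarray) -> np.ndarray:
    """Helix-fit oracle: per-residue supercoil twist from window centroids.

    The 7-residue moving centroid of a coiled-coil Cα trace lies close to
    the helix axis; the increment of its azimuth about the supercoil (z)
    axis measures the local supercoil twist, independent of the builder's
    internal phase bookkeeping.
    """
    centroids = np.array([ca[i - 3 : i + 4].mean(axis=0) for i in range(3, len(ca) - 3)])
    azimuth = np.unwrap(np.arctan2(centroids[:, 1], centroids[:, 0]))
    return np.rad2deg(np.diff(azimuth))


def heptad_smoothed(x: np.ndarray) -> np.ndarray:
    """One-heptad rolling mean: cancels the off-axis wobble of the window
    centroid (exactly zero only when seven residues span whole minor turns)."""
    return np.convolve(x, np.ones(7) / 7, mode="valid")


def fitted_residues_per_turn(ca: np.ndarray) -> float:
    """Refit the intrinsic helix rotation rate from the Cα trace alone."""
    centroids = np.array([ca[i - 3 : i + 4].mean(axis=0) for i in range(3, len(ca) - 3)])
    minor = ca[3 : len(ca) - 3] - centroids
    tangent = np.gradient(centroids, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    minor -= np.sum(minor * tangent, axis=1, keepdims=True) * tangent
    angles = []
    for i in range(len(minor) - 1):
        cross = np.cross(minor[i], minor[i + 1])
        angles.append(
            np.degrees(np.arctan2(np.dot(cross, tangent[i]), np.dot(minor[i], minor[i + 1])))
        )
    return 360.0 / float(np.mean(angles))


class TestCanonicalGeometry:
    def test_consecutive_ca_distances(self, canonical_model):
        """Virtual Cα–Cα bonds of a canonical dimer stay within 3.80 ± 0.05 Å."""
        for chain in "AB":
            d = np.linalg.norm(np.diff(canonical_model.ca(chain), axis=0), axis=1)
            assert np.all(np.abs(d - 3.80) < 0.05)

    def test_mean_axial_rise(self, canonical_model):
        rise = np.diff(canonical_model.ca("A")[:, 2]).mean()
        assert rise == pytest.approx(1.495, abs=0.01)

    def test_supercoil_twist_left_handed(self, canonical_model):
        """Fitted local twist ≈ 360·(2/7 − 1/3.617) °/res, left-handed."""
        twist = fitted_supercoil_twist(canonical_model.ca("A"))
        interior = twist[5:-5]
        assert np.all(interior < 0)  # left-handed
        assert interior.mean() == pytest.approx(CANONICAL_TWIST, rel=0.02)

    def test_twist_uniform_away_from_termini(self, canonical_model):
        twist = heptad_smoothed(fitted_supercoil_twist(canonical_model.ca("A"))[5:-5])
        assert twist.std() < 0.05 * abs(twist.mean())

    def test_roundtrip_recovers_crick_parameters(self, canonical_model):
        """Refit of rise and residues-per-turn agrees with inputs within 1%."""
        ca = canonical_model.ca("A")
        rise = np.diff(ca[:, 2]).mean()
        assert rise == pytest.approx(1.495, rel=0.01)
        assert fitted_residues_per_turn(ca) == pytest.approx(3.617, rel=0.01)

    def test_chain_symmetry(self, canonical_model):
        """Chain B maps onto chain A under a 180° rotation about the axis."""
        rot = np.diag([-1.0, -1.0, 1.0])
        ca_a = canonical_model.ca("A")
        ca_b = canonical_model.ca("B") @ rot.T
        rmsd = np.sqrt(np.mean(np.sum((ca_b - ca_a) ** 2, axis=1)))
        assert rmsd < 0.1


class TestSkipMotifGeometry:
    def test_skip_motif_locally_unwinds(self, wt_model):
        """|twist| inside the 29-residue motif is < 25% of the canonical rate."""
        seq = wt_model.sequences["A"]
        twist = fitted_supercoil_twist(wt_model.ca("A"))
        # twist[k] corresponds to the step at physical index k+3
        (skip_motif,) = wt_model.schedule.noncanonical
        lo = seq.numbering.index(skip_motif.start_residue)
        hi = lo + skip_motif.length
        inner = twist[lo + 5 - 3 : hi - 5 - 3]  # clear of the blend zones
        assert np.all(np.abs(heptad_smoothed(inner)) < 0.25 * abs(CANONICAL_TWIST))
        assert abs(inner.mean()) < 0.25 * abs(CANONICAL_TWIST)

    def test_wt_model_metrics(self, wt_model):
        assert wt_model.n_residues() == 164
        d = np.linalg.norm(np.diff(wt_model.ca("A"), axis=0), axis=1)
        assert np.all(np.abs(d - 3.80) < 0.10)

    def test_deletion_model_builds(self, wt_sequence, wt_assignment):
        from myotail.register import mutate_sequence

        mut = mutate_sequence(wt_sequence, "K1617del")
        schedule = make_motif_schedule(wt_assignment, deletions=[1617])
        model = build_coiled_coil(mut, mut, schedule, CrickParams(), wt_assignment)
        assert model.n_residues() == 163
        assert model.sequences["A"].gaps == (1617,)


class TestValidation:
    def test_schedule_length_mismatch(self, wt_sequence, wt_assignment, wt_schedule):
        short = NumberedSequence(wt_sequence.seq[:-1], wt_sequence.numbering[:-1])
        with pytest.raises(BuildError, match="schedule"):
            build_coiled_coil(short, short, wt_schedule)

    def test_chain_length_mismatch(self, wt_sequence, wt_schedule):
        short = NumberedSequence(wt_sequence.seq[:-1], wt_sequence.numbering[:-1])
        with pytest.raises(BuildError, match="differ"):
            build_coiled_coil(wt_sequence, short, wt_schedule)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CrickParams(residues_per_turn=2.9)
        with pytest.raises(ValueError):
            CrickParams(strand_phase=370.0)
        with pytest.raises(ValueError):
            CrickParams(major_radius=-1.0)


def test_backbone_dihedrals_are_helical(canonical_model):
    """Completed N/C/O atoms give α-helical φ/ψ throughout."""
    from myotail.ensemble import Ensemble
    from myotail.trajectory import helicity

    ens = Ensemble.from_model(canonical_model)
    assert helicity(ens)["overall"] == pytest.approx(1.0)


def test_minor_helix_radius_seen_from_axis(canonical_model):
    """Cα sit at the minor radius from the fitted local helix axis."""
    ca = canonical_model.ca("A")
    centroids = np.array([ca[i - 3 : i + 4].mean(axis=0) for i in range(3, len(ca) - 3)])
    r = np.linalg.norm(ca[3:-3] - centroids, axis=1)
    # window centroid slightly under-reaches the axis; generous band
    assert np.all(np.abs(r - 2.26) < 0.3)
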