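"""Shared fixtures: built models and hand-constructed toy ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from myotail.builder import build_coiled_coil
from myotail.ensemble import Ensemble
from myotail.motifs import make_motif_schedule
from myotail.params import CrickParams
from myotail.register import NumberedSequence, assign_heptad_register
from myotail.sequences import REGISTER_ANCHORS, SKIP_RESIDUE, wild_type_sequence


@pytest.fixture(scope="session")
def wt_sequence():
    return wild_type_sequence()


@pytest.fixture(scope="session")
def wt_assignment(wt_sequence):
    return assign_heptad_register(
        wt_sequence.numbering, REGISTER_ANCHORS, (SKIP_RESIDUE,)
    )


@pytest.fixture(scope="session")
def wt_schedule(wt_assignment):
    return make_motif_schedule(wt_assignment)


@pytest.fixture(scope="session")
def wt_model(wt_sequence, wt_assignment, wt_schedule):
    return build_coiled_coil(
        wt_sequence, wt_sequence, wt_schedule, CrickParams(), wt_assignment
    )


@pytest.fixture(scope="session")
def canonical_model():
    """Skip-free 164-residue canonical dimer."""
    seq = NumberedSequence.from_string("L" * 164, start=1)
    assignment = assign_heptad_register(seq.numbering, {1: "a"})
    schedule = make_motif_schedule(assignment)
    return build_coiled_coil(seq, seq, schedule, CrickParams(), assignment)


def ca_ensemble(chain_coords: "dict[str, np.ndarray]", times=None) -> Ensemble:
    """Cα-only toy ensemble from {chain: (n_frames, n_res, 3)} arrays."""
    frames = None
    names, rids, chains, rnames, elements = [], [], [], [], []
    blocks = []
    for chain, coords in chain_coords.items():
        coords = np.asarray(coords, dtype=float)
        n_res = coords.shape[1]
        names += ["CA"] * n_res
        rids += list(range(1, n_res + 1))
        chains += [chain] * n_res
        rnames += ["GLY"] * n_res
        elements += ["C"] * n_res
        blocks.append(coords)
    frames = np.concatenate(blocks, axis=1)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float) + 1.0
    return Ensemble(
        frames, np.array(names), np.array(rids), np.array(chains),
        np.array(rnames), np.array(elements), np.asarray(times, dtype=float),
    )


@pytest.fixture
def parallel_lines_ensemble():
    """Two straight Cα chains 10 Å apart, 1.5 Å spacing, one frame."""
    n = 30
    a = np.stack([np.zeros(n), np.zeros(n), 1.5 * np.arange(n)], axis=1)
    b = a + np.array([10.0, 0.0, 0.0])
    return ca_ensemble({"A": a[None], "B": b[None]})


def random_rigid_transform(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-50, 50, 3)
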