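"""Geometric salt-bridge detection over ensembles.

A basic (Lys/Arg) and an acidic (Asp/Glu) residue form a salt bridge in a
frame when their side-chain charge centers lie within the distance cutoff
(default 4 Å).  Charge centers: Lys NZ; Arg midpoint of NH1/NH2 (closer to
the formal charge locus than CZ — configurable); Asp midpoint of OD1/OD2;
Glu midpoint of OE1/OE2.  Occupancy is the fraction of frames bridged; a
pair is reported only if bridged in at least one frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from myotail.ensemble import Ensemble

#: Atoms averaged to obtain the side-chain charge center, per residue type.
CHARGE_CENTER_ATOMS: "dict[str, tuple[str, ...]]" = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC = ("LYS", "ARG")
ACIDIC = ("ASP", "GLU")


@dataclass(frozen=True)
class SaltBridge:
    """One donor–acceptor pair with its bridged-frame fraction."""

    donor_chain: str
    donor_resid: int
    donor_resname: str
    acceptor_chain: str
    acceptor_resid: int
    acceptor_resname: str
    occupancy: float
    intra_helical: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def _charge_centers(ensemble: Ensemble, resnames: tuple[str, ...]):
    """(keys, centers) for charged residues with complete charge-center atoms.

    ``keys`` is a list of (chain, resid, resname); ``centers`` has shape
    (n_frames, len(keys), 3).
    """
    keys = []
    centers = []
    charged = np.isin(ensemble.res_name, resnames)
    for chain in ensemble.chains:
        sel = charged & (ensemble.chain_id == chain)
        for rid in np.unique(ensemble.res_id[sel]):
            rmask = sel & (ensemble.res_id == rid)
            resname = str(ensemble.res_name[rmask][0])
            wanted = CHARGE_CENTER_ATOMS[resname]
            amask = rmask & np.isin(ensemble.atom_name, wanted)
            if amask.sum() != len(wanted):
                warnings.warn(
                    f"{chain}/{resname}{rid}: charge-center atoms missing, residue excluded"
                )
                continue
            keys.append((chain, int(rid), resname))
            centers.append(ensemble.coords[:, amask].mean(axis=1))
    if not keys:
        return [], np.empty((ensemble.n_frames, 0, 3))
    return keys, np.stack(centers, axis=1)


def salt_bridge_occupancy(
    ensemble: Ensemble, cutoff: float = 4.0
) -> tuple["list[SaltBridge]", tuple[float, float]]:
    """Salt-bridge occupancies and the per-frame bridge count (mean ± SD).

    Returns every basic–acidic pair bridged in at least one frame, sorted by
    descending occupancy, plus the mean ± SD over frames of the total number
    of bridged pairs (intra- and inter-helical combined).
    """
    basic_keys, basic_xyz = _charge_centers(ensemble, BASIC)
    acid_keys, acid_xyz = _charge_centers(ensemble, ACIDIC)
    n_frames = ensemble.n_frames
    if not basic_keys or not acid_keys:
        return [], (0.0, 0.0)

    # (n_frames, n_basic, n_acid) pairwise center distances.
    diff = basic_xyz[:, :, None, :] - acid_xyz[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    bridged = dist < cutoff

    per_frame_counts = bridged.sum(axis=(1, 2)).astype(float)
    bridges = []
    occ = bridged.mean(axis=0)
    for bi, (bc, br, bn) in enumerate(basic_keys):
        for ai, (ac, ar, an) in enumerate(acid_keys):
            if occ[bi, ai] > 0:
                bridges.append(
                    SaltBridge(bc, br, bn, ac, ar, an, float(occ[bi, ai]), bc == ac)
                )
    bridges.sort(key=lambda b: (-b.occupancy, b.donor_chain, b.donor_resid, b.acceptor_resid))
    return bridges, (float(per_frame_counts.mean()), float(per_frame_counts.std()))


def bridges_to_frame(bridges: "list[SaltBridge]") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor": f"{b.donor_chain}/{b.donor_resname}{b.donor_resid}",
                "acceptor": f"{b.acceptor_chain}/{b.acceptor_resname}{b.acceptor_resid}",
                "occupancy": b.occupancy,
                "intra_helical": b.intra_helical,
            }
            for b in bridges
        ]
    )
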