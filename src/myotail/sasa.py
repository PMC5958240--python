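"""Relative solvent accessibility (RSA) of residue side chains over ensembles.

Accessible surface areas are computed with the Shrake–Rupley algorithm
(:func:`biotite.structure.sasa`) using a NACCESS/Chothia-style element radii
table and a 1.4 Å probe.  The "side chain" of a residue is every heavy atom
except backbone N, C and O — i.e. Cα is counted as part of the side chain,
which makes glycine well-defined.

RSA normalizes each residue's side-chain area by a per-residue-type maximum
computed *with the same engine* from an extended Gly-X-Gly tripeptide,
assembled at run time from ideal extended backbone geometry plus CCD
side-chain templates.  The reference is restricted to the atom subset
actually present in the query (so backbone-only models are normalized
self-consistently against a backbone-only reference); by construction the
central residue of the reference tripeptide has RSA exactly 1.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from myotail.ensemble import Ensemble
from myotail.geometry import extended_backbone, kabsch
from myotail.trajectory import ResidueProfile

#: NACCESS-style van der Waals radii by element (Å).
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "H": 0.0}
DEFAULT_RADIUS = 1.80

BACKBONE_NON_SIDECHAIN = ("N", "C", "O")
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


def _radii_for(elements: np.ndarray) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        el = str(el).upper()
        if el not in VDW_RADII:
            warnings.warn(f"unknown element {el!r}: using default radius {DEFAULT_RADIUS} Å")
        out[i] = VDW_RADII.get(el, DEFAULT_RADIUS)
    return out


def _atom_array(coords, atom_name, res_id, chain_id, res_name, element) -> struc.AtomArray:
    arr = struc.AtomArray(len(atom_name))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.set_annotation("atom_name", np.asarray(atom_name, dtype="U6"))
    arr.set_annotation("res_id", np.asarray(res_id, dtype=int))
    arr.set_annotation("chain_id", np.asarray(chain_id, dtype="U4"))
    arr.set_annotation("res_name", np.asarray(res_name, dtype="U5"))
    arr.set_annotation("element", np.asarray(element, dtype="U2"))
    arr.set_annotation("hetero", np.zeros(len(atom_name), dtype=bool))
    return arr


def atom_sasa(
    array: struc.AtomArray,
    probe: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom Shrake–Rupley SASA (Å²) with the package radii table."""
    radii = _radii_for(array.element)
    keep = radii > 0  # hydrogens, if present, neither occlude nor report
    sub = array[keep]
    areas = struc.sasa(
        sub, probe_radius=probe, point_number=n_sphere_points, vdw_radii=radii[keep]
    )
    out = np.zeros(array.array_length())
    out[keep] = np.nan_to_num(areas)
    return out


def build_gxg_tripeptide(res_name: str) -> struc.AtomArray:
    """Extended Gly-X-Gly tripeptide with X's CCD side chain grafted on.

    The backbone is built from ideal internal coordinates in the extended
    conformation; side-chain heavy atoms of the central residue are taken
    from the CCD ideal-geometry template, rigidly fitted on (N, CA, C).
    """
    bb = extended_backbone(3)
    names, rids, rnames, elements, coords = [], [], [], [], []
    residues = ("GLY", res_name, "GLY")
    for i, rn in enumerate(residues):
        for atom in ("N", "CA", "C", "O"):
            names.append(atom)
            rids.append(i + 1)
            rnames.append(rn)
            elements.append(atom[0])
            coords.append(bb[atom][i])
    if res_name != "GLY":
        tpl = struc_info.residue(res_name)
        tpl = tpl[(tpl.element != "H") & (tpl.atom_name != "OXT")]
        ref = {n: tpl.coord[tpl.atom_name == n][0] for n in ("N", "CA", "C")}
        tgt = np.stack([bb["N"][1], bb["CA"][1], bb["C"][1]])
        R, t, _ = kabsch(np.stack([ref["N"], ref["CA"], ref["C"]]), tgt)
        for atom, el, xyz in zip(tpl.atom_name, tpl.element, tpl.coord):
            if atom in ("N", "CA", "C", "O"):
                continue
            names.append(str(atom))
            rids.append(2)
            rnames.append(res_name)
            elements.append(str(el))
            coords.append(np.asarray(xyz, dtype=float) @ R.T + t)
    return _atom_array(coords, names, rids, ["A"] * len(names), rnames, elements)


@lru_cache(maxsize=None)
def reference_sidechain_sasa(
    res_name: str,
    atom_subset: "frozenset[str] | None" = None,
    probe: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
) -> float:
    """Maximum side-chain SASA (Å²) of X in extended Gly-X-Gly.

    ``atom_subset`` restricts both the numerator atoms and the reference to
    the atom names present in the query structure (backbone-only inputs are
    normalized against a backbone-only tripeptide).
    """
    tri = build_gxg_tripeptide(res_name)
    if atom_subset is not None:
        keep = (tri.res_id != 2) | np.isin(tri.atom_name, sorted(atom_subset))
        tri = tri[keep]
    areas = atom_sasa(tri, probe, n_sphere_points)
    side = (tri.res_id == 2) & ~np.isin(tri.atom_name, BACKBONE_NON_SIDECHAIN)
    total = float(areas[side].sum())
    if total <= 0:
        raise ValueError(f"degenerate reference SASA for {res_name}")
    return total


def rsa_profile(
    ensemble: Ensemble,
    probe: float = PROBE_RADIUS,
    n_sphere_points: int = N_SPHERE_POINTS,
    subsample_ns: float = 0.01,
) -> "dict[str, ResidueProfile]":
    """Per-chain side-chain RSA (mean ± SD over sampled frames).

    Frames are subsampled at approximately ``subsample_ns`` spacing (default
    10 ps equivalent; every frame when frames are farther apart).  Values are
    dimensionless, mostly in [0, 1]; distorted conformers may slightly
    exceed 1.
    """
    times = ensemble.times_ns
    if len(times) > 1:
        dt = float(np.median(np.diff(times)))
        stride = max(1, int(round(subsample_ns / dt))) if dt > 0 else 1
    else:
        stride = 1
    frame_idx = np.arange(ensemble.n_frames)[::stride]

    sidechain = ~np.isin(ensemble.atom_name, BACKBONE_NON_SIDECHAIN)
    per_frame: dict[tuple[str, int], list[float]] = {}
    refs: dict[tuple[str, int], float] = {}
    for fi in frame_idx:
        arr = _atom_array(
            ensemble.coords[fi], ensemble.atom_name, ensemble.res_id,
            ensemble.chain_id, ensemble.res_name, ensemble.element,
        )
        areas = atom_sasa(arr, probe, n_sphere_points)
        for chain in ensemble.chains:
            cmask = ensemble.chain_id == chain
            for rid in np.unique(ensemble.res_id[cmask]):
                rmask = cmask & (ensemble.res_id == rid) & sidechain
                if not rmask.any():
                    continue
                key = (chain, int(rid))
                if key not in refs:
                    res_name = str(ensemble.res_name[rmask][0])
                    subset = frozenset(str(a) for a in ensemble.atom_name[rmask])
                    refs[key] = reference_sidechain_sasa(
                        res_name, subset, probe, n_sphere_points
                    )
                per_frame.setdefault(key, []).append(float(areas[rmask].sum()) / refs[key])

    out: dict[str, ResidueProfile] = {}
    for chain in ensemble.chains:
        rids = sorted(r for c, r in per_frame if c == chain)
        vals = [np.asarray(per_frame[(chain, r)]) for r in rids]
        out[chain] = ResidueProfile(
            np.array(rids),
            np.array([v.mean() for v in vals]),
            np.array([v.std() for v in vals]),
            metric="rsa", units="fraction", chain=chain,
            metadata={"probe": probe, "n_sphere_points": n_sphere_points,
                      "frames_sampled": len(frame_idx)},
        )
    return out
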