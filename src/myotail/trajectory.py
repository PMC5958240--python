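"""Per-residue geometry metrics over conformational ensembles.

All profiles are reported against wild-type residue numbering (a deletion
leaves a gap; moving windows run over *physical* sequence neighbours and
windows that straddle a gap are flagged, not dropped).  Every metric is a
mean ± SD over frames and is invariant under rigid-body transformation of
each frame.

Metrics
-------
``dcom_profile``
    Windowed inter-helix distance: per residue, the distance between the
    centroids of the seven Cα (i−3 … i+3) of chain A and of chain B.
``heptad_length_profile``
    Distance between a residue and its i+7 partner, window-averaged.
``inter_heptad_angle_profile``
    Interior angle at residue i between the segments to Cα(i−7) and
    Cα(i+7); straight geometry gives 180°, bends reduce it.
``helicity``
    Fraction of (residue, frame) pairs whose backbone (φ, ψ) fall in the
    α-helical windows.
``end_to_end``
    Distance between the midpoints of the two chains' first and last Cα,
    in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from myotail.ensemble import Ensemble

#: Default backbone-dihedral windows (degrees) classifying a residue as α-helical.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)


@dataclass
class ResidueProfile:
    """Per-residue metric: mean ± SD over frames, indexed by WT numbering."""

    res_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    metric: str
    units: str
    chain: str | None = None
    flagged: tuple[int, ...] = ()  # residues whose window crossed a numbering gap
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.res_ids) == len(self.mean) == len(self.sd)):
            raise ValueError("res_ids/mean/sd must be aligned")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"resid": self.res_ids, "mean": self.mean, "sd": self.sd}
        )
        df.insert(0, "metric", self.metric)
        if self.chain is not None:
            df.insert(1, "chain", self.chain)
        df["flagged"] = np.isin(self.res_ids, self.flagged)
        return df

    def value_at(self, resid: int) -> tuple[float, float]:
        i = int(np.flatnonzero(self.res_ids == resid)[0])
        return float(self.mean[i]), float(self.sd[i])


def _window_flags(res_ids: np.ndarray, centers: np.ndarray, half: int, ahead: int = 0) -> tuple[int, ...]:
    """Residues whose physical window spans a gap in WT numbering."""
    flagged = []
    for ci in centers:
        lo, hi = ci - half, ci + half + ahead
        span = res_ids[hi] - res_ids[lo]
        if span != hi - lo:
            flagged.append(int(res_ids[ci]))
    return tuple(flagged)


def dcom_profile(ensemble: Ensemble, window: int = 7) -> ResidueProfile:
    """Windowed centroid distance between the two chains (D_com), Å.

    For each residue present (by WT id) in both chains with ``window // 2``
    physical neighbours on either side, the per-frame distance between the
    chain-A and chain-B window centroids is averaged over frames.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    chains = ensemble.chains
    if len(chains) != 2:
        raise ValueError(f"D_com requires exactly two chains, found {chains}")
    ca = {c: ensemble.ca_coords(c) for c in chains}
    rid = {c: ensemble.residues(c) for c in chains}
    common = np.intersect1d(rid[chains[0]], rid[chains[1]])

    ids, means, sds = [], [], []
    flagged: list[int] = []
    for r in common:
        ok = True
        cents = []
        for c in chains:
            j = int(np.flatnonzero(rid[c] == r)[0])
            if j < half or j >= len(rid[c]) - half:
                ok = False
                break
            cents.append(ca[c][:, j - half : j + half + 1].mean(axis=1))
            if rid[c][j + half] - rid[c][j - half] != window - 1:
                ok = None  # window crosses a numbering gap
        if ok is False:
            continue
        d = np.linalg.norm(cents[0] - cents[1], axis=1)
        ids.append(int(r))
        means.append(d.mean())
        sds.append(d.std())
        if ok is None:
            flagged.append(int(r))
    return ResidueProfile(
        np.array(ids), np.array(means), np.array(sds),
        metric="dcom", units="angstrom", flagged=tuple(flagged),
        metadata={"window": window},
    )


def heptad_length_profile(
    ensemble: Ensemble, mode: str = "windowed-positions"
) -> "dict[str, ResidueProfile]":
    """Per-chain heptad length: Cα(i) to Cα(i+7) distance, window-averaged, Å.

    ``mode="windowed-positions"`` (default) takes the distance between the
    averaged Cα position of window {i−3 … i+3} and that of {i+4 … i+10};
    ``mode="windowed-distances"`` averages the seven individual i→i+7
    distances instead.
    """
    if mode not in ("windowed-positions", "windowed-distances"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for chain in ensemble.chains:
        ca = ensemble.ca_coords(chain)
        rid = ensemble.residues(chain)
        n = ca.shape[1]
        centers = np.arange(3, n - 10)
        if len(centers) == 0:
            raise ValueError(f"chain {chain}: too short for heptad windows")
        if mode == "windowed-positions":
            w1 = np.stack([ca[:, i - 3 : i + 4].mean(axis=1) for i in centers], axis=1)
            w2 = np.stack([ca[:, i + 4 : i + 11].mean(axis=1) for i in centers], axis=1)
            d = np.linalg.norm(w1 - w2, axis=2)
        else:
            d = np.stack(
                [
                    np.linalg.norm(ca[:, i - 3 : i + 4] - ca[:, i + 4 : i + 11], axis=2).mean(axis=1)
                    for i in centers
                ],
                axis=1,
            )
        out[chain] = ResidueProfile(
            rid[centers], d.mean(axis=0), d.std(axis=0),
            metric="heptad_length", units="angstrom", chain=chain,
            flagged=_window_flags(rid, centers, half=3, ahead=7),
            metadata={"mode": mode},
        )
    return out


def inter_heptad_angle_profile(ensemble: Ensemble) -> "dict[str, ResidueProfile]":
    """Per-chain interior angle at Cα(i) between segments to Cα(i∓7), degrees."""
    out = {}
    for chain in ensemble.chains:
        ca = ensemble.ca_coords(chain)
        rid = ensemble.residues(chain)
        n = ca.shape[1]
        centers = np.arange(7, n - 7)
        if len(centers) == 0:
            raise ValueError(f"chain {chain}: too short for inter-heptad angles")
        v1 = ca[:, centers - 7] - ca[:, centers]
        v2 = ca[:, centers + 7] - ca[:, centers]
        n1 = np.linalg.norm(v1, axis=2)
        n2 = np.linalg.norm(v2, axis=2)
        if np.any(n1 == 0) or np.any(n2 == 0):
            raise ValueError("zero-length heptad vector")
        cos = np.clip(np.sum(v1 * v2, axis=2) / (n1 * n2), -1.0, 1.0)
        ang = np.degrees(np.arccos(cos))
        out[chain] = ResidueProfile(
            rid[centers], ang.mean(axis=0), ang.std(axis=0),
            metric="inter_heptad_angle", units="degrees", chain=chain,
            flagged=_window_flags(rid, centers, half=7),
        )
    return out


def helicity(
    ensemble: Ensemble,
    phi_window: tuple[float, float] = PHI_WINDOW,
    psi_window: tuple[float, float] = PSI_WINDOW,
) -> "dict[str, float]":
    """α-helical fraction per chain and overall from backbone dihedrals.

    A (residue, frame) pair counts as helical when both φ and ψ (degrees)
    fall inside the given windows; residues lacking a dihedral (chain
    termini) are excluded from the denominator.  Returns fractions in [0, 1]
    keyed by chain id plus ``"overall"``.
    """
    stack = ensemble.to_atom_array_stack()
    result: dict[str, float] = {}
    helical_total = 0
    defined_total = 0
    for chain in ensemble.chains:
        sub = stack[..., stack.chain_id == chain]
        phi, psi, _ = struc.dihedral_backbone(sub)
        phi = np.degrees(phi)
        psi = np.degrees(psi)
        defined = ~np.isnan(phi) & ~np.isnan(psi)
        hel = (
            defined
            & (phi >= phi_window[0]) & (phi <= phi_window[1])
            & (psi >= psi_window[0]) & (psi <= psi_window[1])
        )
        n_def = int(defined.sum())
        if n_def == 0:
            raise ValueError(f"chain {chain}: no complete backbone dihedrals")
        result[chain] = float(hel.sum() / n_def)
        helical_total += int(hel.sum())
        defined_total += n_def
    result["overall"] = helical_total / defined_total
    return result


def end_to_end(ensemble: Ensemble) -> tuple[float, float]:
    """Mean ± SD end-to-end distance over frames, in nm.

    Per frame: distance between the midpoint of the two chains' first Cα
    and the midpoint of their last Cα (first/last by WT numbering).
    """
    chains = ensemble.chains
    if len(chains) != 2:
        raise ValueError("end-to-end distance requires exactly two chains")
    starts = []
    ends = []
    for c in chains:
        ca = ensemble.ca_coords(c)
        starts.append(ca[:, 0])
        ends.append(ca[:, -1])
    head = 0.5 * (starts[0] + starts[1])
    tail = 0.5 * (ends[0] + ends[1])
    d = np.linalg.norm(head - tail, axis=1) / 10.0  # Å → nm
    return float(d.mean()), float(d.std())


def end_to_end_series(ensemble: Ensemble) -> np.ndarray:
    """Per-frame end-to-end distances (nm)."""
    chains = ensemble.chains
    a0 = {c: ensemble.ca_coords(c) for c in chains}
    head = 0.5 * (a0[chains[0]][:, 0] + a0[chains[1]][:, 0])
    tail = 0.5 * (a0[chains[0]][:, -1] + a0[chains[1]][:, -1])
    return np.linalg.norm(head - tail, axis=1) / 10.0
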