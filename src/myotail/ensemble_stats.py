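"""Ensemble-level statistics: equilibration discard, RMSD, RMSF, clustering.

Superpositions use the mass-unweighted Kabsch optimal rotation on Cα atoms.
Clustering follows the deterministic leader (representative) algorithm: in
time order, a frame joins the first existing cluster whose founding frame
is within the RMSD cutoff, otherwise it founds a new cluster.  A
gromos-style average-linkage scheme can be swapped in behind the same
result type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from myotail.ensemble import Ensemble
from myotail.geometry import superpose


class EmptyEnsembleError(ValueError):
    """Raised when an operation would leave or receive zero frames."""


@dataclass
class ClusterResult:
    """Leader-clustering outcome over an ensemble.

    ``labels`` assigns every frame a 0-based cluster id in founding order;
    ``populations`` are percentages of frames summing to 100;
    ``representatives`` are the founding frame indices.
    """

    labels: np.ndarray
    populations: np.ndarray
    representatives: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def to_frame(self, times_ns: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self.labels)), "cluster": self.labels})
        if times_ns is not None:
            df.insert(1, "time_ns", times_ns)
        return df


def discard_equilibration(ensemble: Ensemble, t_cut_ns: float = 10.0) -> Ensemble:
    """Drop all frames with time < ``t_cut_ns`` (equilibration transient)."""
    if t_cut_ns < 0:
        raise ValueError("t_cut_ns must be >= 0")
    keep = ensemble.times_ns >= t_cut_ns
    if not keep.any():
        raise EmptyEnsembleError(
            f"t_cut={t_cut_ns} ns removes all {ensemble.n_frames} frames "
            f"(last frame at {ensemble.times_ns[-1]} ns)"
        )
    out = ensemble.frame_subset(keep)
    out.metadata["equilibration_cut_ns"] = t_cut_ns
    return out


def _ca_frames(ensemble: Ensemble) -> np.ndarray:
    mask = ensemble.ca_mask()
    if not mask.any():
        raise ValueError("no Cα atoms in ensemble")
    return ensemble.coords[:, mask]


def rmsd_vs_initial(ensemble: Ensemble) -> np.ndarray:
    """Optimal-superposition Cα RMSD of every frame vs the first frame, Å."""
    ca = _ca_frames(ensemble)
    ref = ca[0]
    out = np.empty(len(ca))
    for i, frame in enumerate(ca):
        _, out[i] = superpose(frame, ref)
    return out


def rmsf(
    ensemble: Ensemble,
    max_iter: int = 100,
    tol: float = 1e-4,
    superpose_frames: bool = True,
) -> pd.DataFrame:
    """Per-residue Cα root-mean-square fluctuation about the mean structure, Å.

    Frames are iteratively superposed onto their running mean until the mean
    structure changes by less than ``tol`` Å (RMS), then
    ``RMSF_i = sqrt(mean_frames |r_i − <r_i>|²)``.  Returns a tidy frame
    (chain, resid, rmsf).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    mask = ensemble.ca_mask()
    ca = ensemble.coords[:, mask].copy()
    if superpose_frames:
        mean = ca[0].copy()
        for _ in range(max_iter):
            for i in range(len(ca)):
                ca[i], _ = superpose(ca[i], mean)
            new_mean = ca.mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
            mean = new_mean
            if shift < tol:
                break
        else:
            raise RuntimeError(f"RMSF superposition did not converge in {max_iter} iterations")
    mean = ca.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    return pd.DataFrame(
        {
            "chain": ensemble.chain_id[mask],
            "resid": ensemble.res_id[mask],
            "rmsf": fluct,
        }
    )


def cluster_structures(ensemble: Ensemble, cutoff: float = 8.0) -> ClusterResult:
    """Leader clustering of frames on pairwise Cα RMSD with the given cutoff (Å)."""
    ca = _ca_frames(ensemble)
    reps: list[int] = []
    labels = np.empty(len(ca), dtype=int)
    for i, frame in enumerate(ca):
        for k, r in enumerate(reps):
            _, d = superpose(frame, ca[r])
            if d < cutoff:
                labels[i] = k
                break
        else:
            reps.append(i)
            labels[i] = len(reps) - 1
    counts = np.bincount(labels, minlength=len(reps))
    populations = 100.0 * counts / len(ca)
    return ClusterResult(labels, populations, np.array(reps), cutoff)
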