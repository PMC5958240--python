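"""Conformational-ensemble container and its on-disk formats.

An :class:`Ensemble` is an ordered stack of coordinate frames over one fixed
atom table (name, wild-type residue id, chain, residue name, element) with
strictly increasing time stamps.  The canonical interchange format is the
multi-model PDB (``MODEL``/``ENDMDL``); a plain-CSV Cα-trace dialect
(``frame, chain, resid, x, y, z``) is accepted for lightweight toy inputs.
Parsing and writing of PDB records is delegated to :mod:`biotite`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from myotail.builder import CoiledCoilModel
from myotail.register import NumberedSequence

_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class EnsembleFormatError(ValueError):
    """Raised for malformed or inconsistent ensemble files."""


@dataclass
class Ensemble:
    """Coordinate frames over a fixed atom table.

    Attributes
    ----------
    coords:
        (n_frames, n_atoms, 3) array, Å.
    atom_name, res_id, chain_id, res_name, element:
        Per-atom annotation arrays of length n_atoms; ``res_id`` uses
        wild-type numbering (a deletion leaves a gap, never renumbered).
    times_ns:
        Strictly increasing frame times in ns.
    """

    coords: np.ndarray
    atom_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    res_name: np.ndarray
    element: np.ndarray
    times_ns: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for name in ("atom_name", "res_id", "chain_id", "res_name", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length {n_atoms}")
            setattr(self, name, arr)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.times_ns.shape != (self.n_frames,):
            raise ValueError("times_ns must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(str(c))
        return tuple(seen)

    def frame_subset(self, index) -> "Ensemble":
        """New ensemble restricted to the given frame indices/mask."""
        idx = np.arange(self.n_frames)[index]
        return Ensemble(
            self.coords[idx], self.atom_name, self.res_id, self.chain_id,
            self.res_name, self.element, self.times_ns[idx], dict(self.metadata),
        )

    def atom_subset(self, mask: np.ndarray) -> "Ensemble":
        """New ensemble restricted to atoms where ``mask`` is True."""
        return Ensemble(
            self.coords[:, mask], self.atom_name[mask], self.res_id[mask],
            self.chain_id[mask], self.res_name[mask], self.element[mask],
            self.times_ns, dict(self.metadata),
        )

    def ca_mask(self, chain: str | None = None) -> np.ndarray:
        m = self.atom_name == "CA"
        if chain is not None:
            m &= self.chain_id == chain
        return m

    def residues(self, chain: str) -> np.ndarray:
        """Wild-type residue ids with a Cα in the given chain, ascending."""
        return np.unique(self.res_id[self.ca_mask(chain)])

    def ca_coords(self, chain: str) -> np.ndarray:
        """Cα coordinates (n_frames, n_res, 3) ordered by residue id."""
        m = self.ca_mask(chain)
        order = np.argsort(self.res_id[m], kind="stable")
        return self.coords[:, m][:, order]

    def atom_coords(self, chain: str, res_id: int, atom_name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of a single named atom."""
        m = (self.chain_id == chain) & (self.res_id == res_id) & (self.atom_name == atom_name)
        hits = np.flatnonzero(m)
        if len(hits) != 1:
            raise KeyError(f"atom {chain}/{res_id}/{atom_name}: {len(hits)} matches")
        return self.coords[:, hits[0]]

    @classmethod
    def from_model(
        cls, model: CoiledCoilModel, times_ns: np.ndarray | None = None
    ) -> "Ensemble":
        """Single-frame ensemble from a built coiled-coil model."""
        names, rids, chains, rnames, elements, xyz = [], [], [], [], [], []
        for chain in model.chains:
            seq: NumberedSequence = model.sequences[chain]
            atoms = model.coords[chain]
            for i, rid in enumerate(seq.numbering):
                for atom, arr in atoms.items():
                    names.append(atom)
                    rids.append(rid)
                    chains.append(chain)
                    rnames.append(_1TO3.get(seq.seq[i], "UNK"))
                    elements.append(atom[0])
                    xyz.append(arr[i])
        coords = np.asarray(xyz)[None, :, :]
        t = np.array([0.0]) if times_ns is None else np.asarray(times_ns, dtype=float)
        return cls(
            coords, np.array(names), np.array(rids), np.array(chains),
            np.array(rnames), np.array(elements), t,
            {"source": "builder", **model.metadata},
        )

    def to_atom_array_stack(self) -> struc.AtomArrayStack:
        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = self.coords.astype(np.float32)
        stack.set_annotation("atom_name", self.atom_name.astype("U6"))
        stack.set_annotation("res_id", self.res_id.astype(int))
        stack.set_annotation("chain_id", self.chain_id.astype("U4"))
        stack.set_annotation("res_name", self.res_name.astype("U5"))
        stack.set_annotation("element", self.element.astype("U2"))
        stack.set_annotation("hetero", np.zeros(self.n_atoms, dtype=bool))
        return stack


def _prescan_pdb(lines: "list[str]") -> None:
    """Cheap structural sanity check producing line-numbered errors."""
    model_open_line = None
    counts: list[tuple[int, int]] = []  # (model index, atom count)
    current = 0
    model_index = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if model_open_line is not None:
                raise EnsembleFormatError(
                    f"line {lineno}: MODEL opened before previous MODEL "
                    f"(line {model_open_line}) was closed"
                )
            model_open_line = lineno
            model_index += 1
            current = 0
        elif rec == "ENDMDL":
            if model_open_line is None:
                raise EnsembleFormatError(f"line {lineno}: ENDMDL without MODEL")
            counts.append((model_index, current))
            model_open_line = None
        elif rec == "ATOM":
            current += 1
    if model_open_line is not None:
        raise EnsembleFormatError(
            f"truncated MODEL block: MODEL at line {model_open_line} has no ENDMDL"
        )
    if counts:
        ref = counts[0][1]
        for idx, c in counts[1:]:
            if c != ref:
                raise EnsembleFormatError(
                    f"MODEL {idx} has {c} ATOM records, expected {ref} (as in MODEL 1)"
                )


def read_ensemble(path: str | Path, time_per_frame_ns: float = 1.0) -> Ensemble:
    """Read a multi-model PDB or CSV Cα-trace ensemble.

    Frame times are taken as ``(frame_index + 1) * time_per_frame_ns`` unless
    the file encodes them (CSV dialect with a ``time_ns`` column).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv_trace(path, time_per_frame_ns)
    pdb = PDBFile.read(str(path))
    _prescan_pdb(pdb.lines)
    structure = pdb.get_structure(model=None)
    if isinstance(structure, struc.AtomArray):
        structure = struc.stack([structure])
    n_frames = structure.stack_depth()
    return Ensemble(
        np.asarray(structure.coord, dtype=float),
        np.asarray(structure.atom_name),
        np.asarray(structure.res_id),
        np.asarray(structure.chain_id),
        np.asarray(structure.res_name),
        np.asarray(structure.element),
        (np.arange(n_frames) + 1) * time_per_frame_ns,
        {"source": str(path)},
    )


def _read_csv_trace(path: Path, time_per_frame_ns: float) -> Ensemble:
    df = pd.read_csv(path)
    required = {"frame", "chain", "resid", "x", "y", "z"}
    if not required <= set(df.columns):
        raise EnsembleFormatError(f"CSV trace needs columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values(["chain", "resid"])
    key = list(zip(first["chain"], first["resid"]))
    coords = np.empty((len(frames), len(key), 3))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values(["chain", "resid"])
        if list(zip(sub["chain"], sub["resid"])) != key:
            raise EnsembleFormatError(f"frame {f}: atom table differs from frame {frames[0]}")
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    if "time_ns" in df.columns:
        times = df.groupby("frame")["time_ns"].first().loc[frames].to_numpy()
    else:
        times = (np.arange(len(frames)) + 1) * time_per_frame_ns
    n = len(key)
    return Ensemble(
        coords,
        np.full(n, "CA"),
        np.array([r for _, r in key], dtype=int),
        np.array([str(c) for c, _ in key]),
        np.full(n, "GLY"),
        np.full(n, "C"),
        times,
        {"source": str(path)},
    )


def write_ensemble(ensemble: Ensemble, path: str | Path, remarks: "list[str] | None" = None) -> None:
    """Write a multi-model PDB (chains as-is, occupancy 1.00, B 0.00)."""
    pdb = PDBFile()
    pdb.set_structure(ensemble.to_atom_array_stack())
    if remarks:
        pdb.lines = [f"REMARK 250 {r}"[:80] for r in remarks] + pdb.lines
    pdb.write(str(path))


def write_model_pdb(model: CoiledCoilModel, path: str | Path) -> None:
    """Write a built model as a one-MODEL PDB with schedule/params REMARKs."""
    remarks = [
        f"CRICK PARAMS residues_per_turn={model.params.residues_per_turn} "
        f"rise={model.params.rise_per_residue} strand_phase={model.params.strand_phase}",
        f"CRICK PARAMS major_radius={model.params.major_radius} "
        f"minor_radius={model.params.minor_radius} b={model.params.smoothing_b}",
        "MOTIF SCHEDULE mode=" + model.schedule.mode,
    ] + [
        f"MOTIF start={m.start_residue} length={m.length} turns={m.helical_turns:g}"
        for m in model.schedule.motifs
    ]
    write_ensemble(Ensemble.from_model(model), path, remarks=remarks)
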