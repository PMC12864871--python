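"""Structural descriptors for protein/ssDNA coordinate trajectories.

Radius of gyration, per-atom / per-residue RMSF (with optional Kabsch
superposition), and the per-nucleotide surface-distance profile
Delta_s = |r_P - c| - Rg(protein): the distance of each DNA phosphorus
from the protein center minus the protein's radius of gyration, i.e. an
approximate height above an effective protein sphere.  Values may be
negative when a phosphorus sits inside the effective sphere.

Readers cover multi-model PDB (MODEL/ENDMDL) and XYZ trajectories; a
small helper ingests externally computed per-frame energy tables for
mean +/- SD summaries (no force-field evaluation happens here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

_DNA_RESIDUES = {
    "DA", "DC", "DG", "DT", "DU",
    "DA3", "DC3", "DG3", "DT3", "DA5", "DC5", "DG5", "DT5",
    "A", "C", "G", "T", "U",
}

#: standard atomic masses for the elements common in biomolecules
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "ZN": 65.38, "CA": 40.078, "K": 39.098, "CL": 35.45,
}


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    residue_name: str
    residue_index: int
    chain: str  # "protein" | "dna" (or a verbatim chain letter)


@dataclass
class Trajectory:
    """Ordered frames with a consistent atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3), in Angstrom.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise DataError("atom roster does not match coordinate array")
        if self.coords.shape[0] < 1:
            raise DataError("trajectory needs at least one frame")
        if not np.isfinite(self.coords).all():
            raise DataError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(
        self,
        chain: Optional[str] = None,
        atom_name: Optional[str] = None,
        residue_name: Optional[str] = None,
    ) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        idx = []
        for i, atom in enumerate(self.atoms):
            if chain is not None and atom.chain != chain:
                continue
            if atom_name is not None and atom.atom_name != atom_name:
                continue
            if residue_name is not None and atom.residue_name != residue_name:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)


def _chain_kind(residue_name: str) -> str:
    return "dna" if residue_name.upper() in _DNA_RESIDUES else "protein"


def read_pdb(path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    Models are delimited by MODEL/ENDMDL; a file without MODEL records
    is a single-frame trajectory.  Chains are classified as protein or
    dna from the residue name.
    """
    atoms: list[AtomRecord] = []
    frames: list[list] = []
    current: list = []
    first_model_done = False
    with open(path) as handle:
        for line in handle:
            record = line[:6].strip()
            if record == "MODEL":
                current = []
            elif record in ("ATOM", "HETATM"):
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                current.append((x, y, z))
                if not first_model_done:
                    name = line[12:16].strip()
                    res_name = line[17:20].strip()
                    res_index = int(line[22:26])
                    atoms.append(
                        AtomRecord(name, res_name, res_index, _chain_kind(res_name))
                    )
            elif record == "ENDMDL":
                frames.append(current)
                first_model_done = True
                current = []
    if current:
        frames.append(current)
    if not frames:
        raise DataError(f"no coordinates found in {path}")
    n_atoms = len(frames[0])
    for k, frame in enumerate(frames):
        if len(frame) != n_atoms:
            raise DataError(f"model {k + 1} has {len(frame)} atoms, expected {n_atoms}")
    return Trajectory(atoms, np.asarray(frames, dtype=float))


def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    with open(path, "w") as handle:
        for f in range(traj.n_frames):
            handle.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(traj.atoms):
                x, y, z = traj.coords[f, i]
                chain_id = "A" if atom.chain == "protein" else "B"
                # fixed columns: serial 7-11, name 13-16, resName 18-20,
                # chain 22, resSeq 23-26, x/y/z 31-54
                handle.write(
                    f"ATOM  {i + 1:5d} {atom.atom_name:<4s}{atom.residue_name:>4s} "
                    f"{chain_id}{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")


def read_xyz(path) -> Trajectory:
    """Read a concatenated-frames XYZ trajectory.

    Atom 'names' in XYZ carry no residue information; every atom gets
    residue_index equal to its ordinal and chain "protein".
    """
    frames = []
    atoms: list[AtomRecord] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        frame = []
        for j, ln in enumerate(block):
            parts = ln.split()
            frame.append((float(parts[1]), float(parts[2]), float(parts[3])))
            if first:
                atoms.append(AtomRecord(parts[0], parts[0], j + 1, "protein"))
        frames.append(frame)
        first = False
        i += 2 + n
    if not frames:
        raise DataError(f"no frames found in {path}")
    return Trajectory(atoms, np.asarray(frames, dtype=float))


def radius_of_gyration(
    coords: np.ndarray, weights: Optional[np.ndarray] = None
) -> float:
    """sqrt(sum w_i |r_i - rbar|^2 / sum w_i) with rbar the weighted centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise DataError("radius_of_gyration needs a non-empty (n, 3) coordinate set")
    w = np.ones(coords.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    centroid = (w[:, None] * coords).sum(axis=0) / wsum
    sq = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / wsum))


def mass_weights(traj: Trajectory, indices: np.ndarray) -> np.ndarray:
    """Standard atomic masses inferred from the leading element letter."""
    out = []
    for i in indices:
        name = traj.atoms[i].atom_name
        element = name[:2].upper() if name[:2].upper() in ATOMIC_MASSES else name[0].upper()
        out.append(ATOMIC_MASSES.get(element, 12.011))
    return np.asarray(out)


def delta_s(
    frame_coords: np.ndarray,
    protein_idx: np.ndarray,
    phosphorus_idx: np.ndarray,
    center: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-phosphorus |r_P - c| - Rg(protein) for one frame.

    ``center`` defaults to the unweighted centroid of the protein
    selection; pass the coordinate of a reference atom (e.g. a specific
    C-alpha) to anchor the measure there instead.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    protein = frame_coords[protein_idx]
    if protein.shape[0] == 0:
        raise DataError("empty protein selection")
    rg = radius_of_gyration(protein)
    c = protein.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    p_coords = frame_coords[phosphorus_idx]
    return np.linalg.norm(p_coords - c, axis=1) - rg


def trajectory_distance_profile(
    traj: Trajectory,
    protein_chain: str = "protein",
    dna_chain: str = "dna",
    phosphorus_name: str = "P",
    center_atom: Optional[int] = None,
) -> pd.DataFrame:
    """Mean and SD of Delta_s across frames, one row per nucleotide.

    Nucleotides are identified by the residue index of their phosphorus
    atom; a nucleotide without a phosphorus (the 5'-terminal one) is
    simply absent from the profile, with a warning.
    """
    protein_idx = traj.select(chain=protein_chain)
    p_idx = traj.select(chain=dna_chain, atom_name=phosphorus_name)
    dna_residues = sorted({a.residue_index for a in traj.atoms if a.chain == dna_chain})
    covered = {traj.atoms[i].residue_index for i in p_idx}
    missing = [r for r in dna_residues if r not in covered]
    if missing:
        warnings.warn(f"nucleotides without a phosphorus atom omitted: {missing}")
    values = np.empty((traj.n_frames, len(p_idx)))
    for f in range(traj.n_frames):
        center = traj.coords[f, center_atom] if center_atom is not None else None
        values[f] = delta_s(traj.coords[f], protein_idx, p_idx, center=center)
    return pd.DataFrame(
        {
            "nucleotide": [traj.atoms[i].residue_index for i in p_idx],
            "mean_delta_s": values.mean(axis=0),
            "sd_delta_s": values.std(axis=0),  # population SD across frames
        }
    )


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix aligning centered ``mobile`` onto ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def superpose_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly fit every frame onto the reference structure."""
    ref_centered = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        frame = coords[f]
        centered = frame - frame.mean(axis=0)
        rot = kabsch_rotation(centered, ref_centered)
        out[f] = centered @ rot.T + reference.mean(axis=0)
    return out


def rmsf(
    traj: Trajectory,
    superpose: bool = True,
    grouping: str = "atom",
    selection: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Root mean square fluctuation per atom or per residue.

    With ``superpose`` (default), every frame is least-squares fit onto
    the mean structure (one iteration: fit, re-average, measure) before
    fluctuations are computed.  ``grouping="residue"`` averages the
    member-atom RMSF within each (chain, residue) pair.
    """
    if traj.n_frames < 2:
        raise DataError("RMSF needs at least 2 frames")
    idx = np.arange(len(traj.atoms)) if selection is None else np.asarray(selection)
    coords = traj.coords[:, idx, :]
    if superpose:
        mean0 = coords.mean(axis=0)
        spread = ((mean0 - mean0.mean(axis=0)) ** 2).sum()
        if spread <= 1e-12:
            warnings.warn("degenerate structure; superposition skipped")
        else:
            coords = superpose_frames(coords, mean0)
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    rows = pd.DataFrame(
        {
            "chain": [traj.atoms[i].chain for i in idx],
            "residue_index": [traj.atoms[i].residue_index for i in idx],
            "atom_name": [traj.atoms[i].atom_name for i in idx],
            "rmsf": per_atom,
        }
    )
    if grouping == "atom":
        return rows
    if grouping == "residue":
        grouped = (
            rows.groupby(["chain", "residue_index"], sort=True)["rmsf"]
            .mean()
            .reset_index()
        )
        return grouped
    raise ValueError(f"unknown grouping {grouping!r}")


def energy_summary(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean +/- SD of externally computed per-frame energy columns."""
    cols = list(columns) if columns is not None else [
        c for c in table.columns if np.issubdtype(table[c].dtype, np.number)
    ]
    rows = [
        {"component": c, "mean": float(table[c].mean()), "sd": float(table[c].std(ddof=0))}
        for c in cols
    ]
    return pd.DataFrame(rows)
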