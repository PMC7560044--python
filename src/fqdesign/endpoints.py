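"""Post-model endpoint arithmetic and structural post-analysis.

Covers everything downstream of the QSAR fit: converting log f_b back to a
percent binding rate, relative-change screening tables against the parent
compound, reaction Gibbs-energy changes from total electronic energies,
vibrational-frequency stability checks, residue-contact classification with
mean contact distances, and RMSD/RMSF summaries of coordinate trajectories.

Docking scores, DFT energies, vibrational frequencies and endpoint
predictions from external models (pLOEC, logKow, log t1/2) are consumed as
given in input tables; they are never computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "HARTREE_TO_KCAL",
    "RESIDUE_CLASS",
    "log_fb_to_fb",
    "fb_to_log_fb",
    "relative_change",
    "screen_lower_binding",
    "delta_g",
    "stability_check",
    "classify_contacts",
    "mean_contact_distance",
    "Trajectory",
    "rmsd_series",
    "rmsf_per_residue",
    "read_pdb_trajectory",
]

#: 1 hartree in kcal/mol (CODATA-derived).
HARTREE_TO_KCAL = 627.5095

#: Hydrophobic / hydrophilic classification of the 20 standard residues.
#: Leu, Val, Phe, Met, Ala, Tyr and Pro are hydrophobic; Gln, Arg and Lys
#: hydrophilic; the remainder follow the sign of the Kyte-Doolittle scale
#: (positive -> hydrophobic).
RESIDUE_CLASS: dict[str, str] = {
    "ALA": "hydrophobic", "VAL": "hydrophobic", "LEU": "hydrophobic",
    "ILE": "hydrophobic", "MET": "hydrophobic", "PHE": "hydrophobic",
    "TYR": "hydrophobic", "TRP": "hydrophilic", "PRO": "hydrophobic",
    "GLY": "hydrophilic", "CYS": "hydrophobic", "SER": "hydrophilic",
    "THR": "hydrophilic", "ASN": "hydrophilic", "GLN": "hydrophilic",
    "ASP": "hydrophilic", "GLU": "hydrophilic", "LYS": "hydrophilic",
    "ARG": "hydrophilic", "HIS": "hydrophilic",
}


def log_fb_to_fb(log_fb: float) -> float:
    """Percent of drug bound to plasma protein from its base-10 logarithm."""
    return float(10.0 ** np.asarray(log_fb, dtype=float))


def fb_to_log_fb(fb: float) -> float:
    if np.any(np.asarray(fb) <= 0):
        raise ValueError("binding percentage must be positive")
    return float(np.log10(fb))


def relative_change(value: float, parent_value: float) -> float:
    """Signed percent change of an endpoint versus the parent compound."""
    if parent_value == 0:
        raise ValueError("relative change undefined for a zero parent value")
    return (value - parent_value) / parent_value * 100.0


def screen_lower_binding(table: pd.DataFrame, parent_logfb: float,
                         id_col: str = "id", logfb_col: str = "logfb") -> list[str]:
    """Ids with log f_b strictly below the parent, most-reduced first."""
    below = table[table[logfb_col] < parent_logfb]
    return below.sort_values(logfb_col)[id_col].tolist()


def delta_g(g_react: float, g_prod: float) -> float:
    """Reaction Gibbs-energy change (kcal/mol) from total energies in hartree."""
    return (float(g_prod) - float(g_react)) * HARTREE_TO_KCAL


@dataclass
class FrequencySet:
    compound_id: str
    frequencies: list[float]  # cm^-1 (may hold just the minimum frequency)


def stability_check(fs: FrequencySet) -> bool:
    """A structure is a true minimum (stable) iff its lowest frequency is > 0."""
    if not fs.frequencies:
        raise ValueError(f"no frequencies for {fs.compound_id!r}")
    return min(fs.frequencies) > 0


def classify_contacts(residues: list[tuple[str, int]]) -> dict[str, int]:
    """Count hydrophobic and hydrophilic contact residues with multiplicities.

    ``residues`` pairs a 3-letter code with its multiplicity (number of
    residues of that type in contact).
    """
    counts = {"hydrophobic": 0, "hydrophilic": 0}
    for code, n in residues:
        cls = RESIDUE_CLASS.get(code.upper())
        if cls is None:
            raise ValueError(f"unknown residue code {code!r}")
        counts[cls] += int(n)
    return counts


def mean_contact_distance(distances: list[float], decimals: int = 1) -> float:
    """Arithmetic mean contact distance, reported at 0.1-Angstrom precision."""
    if len(distances) == 0:
        raise ValueError("no distances given")
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(round(d.mean(), decimals))


# ----------------------------------------------------------------------
# trajectory summaries


@dataclass
class Trajectory:
    """Coordinate frames with an atom -> residue mapping.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``residue_ids``
    assigns each atom to a residue label (e.g. "GLN149").
    """

    coords: np.ndarray
    residue_ids: list[str]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.residue_ids):
            raise ValueError("atom count must match the residue mapping")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of one frame onto the reference."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsd_series(traj: Trajectory, superpose: bool = True) -> np.ndarray:
    """Per-frame all-atom RMSD from the initial conformation (frame 0)."""
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        x = traj.coords[t]
        if superpose:
            x = _superpose(x, ref)
        out[t] = np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1)))
    return out


def rmsf_per_residue(traj: Trajectory) -> pd.Series:
    """Root-mean-square fluctuation about the mean position, averaged per residue."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    mean = traj.coords.mean(axis=0)
    per_atom = np.sqrt(
        np.mean(np.sum((traj.coords - mean) ** 2, axis=2), axis=0)
    )
    s = pd.Series(per_atom).groupby(pd.Index(traj.residue_ids)).mean()
    s.index.name = "residue"
    s.name = "rmsf"
    return s


def read_pdb_trajectory(path) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL blocks of ATOM records).

    Only ATOM/HETATM coordinates and residue labels are used; every model
    must contain the same atoms. A file without MODEL records is treated as a
    single frame.
    """
    frames: list[list[tuple[float, float, float]]] = []
    residues: list[str] = []
    current: list[tuple[float, float, float]] | None = None
    first = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    first = False
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
                current.append((x, y, z))
                if first:
                    residues.append(line[17:20].strip() + line[22:26].strip())
    if current:  # trailing frame without ENDMDL, or MODEL-less file
        frames.append(current)
    if not frames:
        raise ValueError(f"no coordinates found in {path}")
    n = len(frames[0])
    if any(len(f) != n for f in frames):
        raise ValueError("atom count differs between models")
    if len(residues) > n:
        warnings.warn("residue labels truncated to the first model's atom count")
        residues = residues[:n]
    return Trajectory(coords=np.array(frames, dtype=float), residue_ids=residues)
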