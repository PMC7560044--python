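"""Small-molecule preparation and core-based alignment.

Molecules are parsed from SMILES or SDF, embedded into a single low-energy
3-D conformer, assigned Gasteiger partial charges, Crippen atom-additive
hydrophobicity contributions and H-bond donor/acceptor flags, and rigidly
aligned onto a template by least-squares superposition of a shared
substructure core (the 4-oxo-pyridine-3-carboxylic-acid pharmacophore common
to the quinolone antibacterials).

All coordinates are in Angstroms; atom indices are 0-based and include
explicit hydrogens after preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = [
    "Molecule",
    "AlignmentSpec",
    "AlignedSet",
    "QUINOLONE_CORE_SMARTS",
    "parse_molecule",
    "prepare_molecule",
    "align_to_template",
    "read_smiles_file",
    "write_sdf",
]

#: Bicyclic-core pharmacophore shared by the quinolone/naphthyridone/cinnoline
#: antibacterials: ring N1, position 2 (C or N), the 3-carboxylic acid and the
#: 4-oxo group, closed through the two fused ring-junction carbons.
QUINOLONE_CORE_SMARTS = "[#7;R]1[#6,#7][#6](-[#6](=O)-[OX2H1])[#6](=O)[#6;R][#6;R]1"

# RDKit-style feature definitions for H-bond donors/acceptors (fixed
# substructure rules; applied to the molecule with explicit hydrogens).
_HBD_SMARTS = Chem.MolFromSmarts(
    "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]"
)
_HBA_SMARTS = Chem.MolFromSmarts(
    "[$([O,S;H0;v2]),$([O,S;-]),$([N;v3;!$(N-*=[O,N,P,S])]),"
    "n&H0&+0,$([o;+0;!$([o]:n);!$([o]:c:n)])]"
)


class MoleculeError(ValueError):
    """Raised for unparsable records, failed embeddings or bad alignments."""


@dataclass
class Molecule:
    """A small molecule with per-atom physicochemical weights.

    ``coords``/``charges``/``hydrophobicity``/``is_hbd``/``is_hba`` are
    populated by :func:`prepare_molecule`; before preparation only the
    connectivity (the RDKit mol) is guaranteed.
    """

    id: str
    mol: Chem.Mol
    coords: np.ndarray | None = None          # (n_atoms, 3) Angstrom
    charges: np.ndarray | None = None         # (n_atoms,) elementary charge
    hydrophobicity: np.ndarray | None = None  # (n_atoms,) Crippen logP terms
    is_hbd: np.ndarray | None = None          # (n_atoms,) bool
    is_hba: np.ndarray | None = None          # (n_atoms,) bool
    energy: float | None = None               # minimized FF energy, kcal/mol

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def heavy_atom_mask(self) -> np.ndarray:
        return np.array([a.GetAtomicNum() > 1 for a in self.mol.GetAtoms()])

    @property
    def formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol)

    @property
    def prepared(self) -> bool:
        return self.coords is not None

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            mol=Chem.Mol(self.mol),
            coords=None if self.coords is None else self.coords.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            hydrophobicity=(
                None if self.hydrophobicity is None else self.hydrophobicity.copy()
            ),
            is_hbd=None if self.is_hbd is None else self.is_hbd.copy(),
            is_hba=None if self.is_hba is None else self.is_hba.copy(),
            energy=self.energy,
        )


@dataclass
class AlignmentSpec:
    """Core substructure used as the common alignment framework."""

    template_id: str
    core_smarts: str = QUINOLONE_CORE_SMARTS
    max_core_rmsd: float = 1.0  # Angstrom

    def core_query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.core_smarts)
        if q is None:
            raise MoleculeError(f"invalid core SMARTS: {self.core_smarts!r}")
        return q


@dataclass
class AlignedSet:
    """A template plus members rigidly superposed onto it."""

    template: Molecule
    members: list[Molecule]
    core_rmsd: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def parse_molecule(record: str, id: str) -> Molecule:
    """Parse one SMILES string or SDF record into a connectivity-only Molecule."""
    if "M  END" in record or "$$$$" in record or record.count("\n") > 3:
        mol = Chem.MolFromMolBlock(record, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(record.strip())
    if mol is None:
        raise MoleculeError(f"unparsable molecule record for id {id!r}")
    return Molecule(id=id, mol=mol)


def _assign_weights(m: Molecule) -> None:
    """Populate charges, hydrophobicity contributions and HBD/HBA flags."""
    mol = m.mol
    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )
    # Gasteiger can produce NaN on exotic atoms; treat those as neutral.
    charges = np.nan_to_num(charges, nan=0.0)
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    hyd = np.array([c[0] for c in contribs])
    hbd = np.zeros(mol.GetNumAtoms(), dtype=bool)
    hba = np.zeros(mol.GetNumAtoms(), dtype=bool)
    for (i,) in mol.GetSubstructMatches(_HBD_SMARTS):
        hbd[i] = True
    for (i,) in mol.GetSubstructMatches(_HBA_SMARTS):
        hba[i] = True
    m.charges = charges
    m.hydrophobicity = hyd
    m.is_hbd = hbd
    m.is_hba = hba


def prepare_molecule(
    m: Molecule, seed: int = 2020, n_embed_attempts: int = 10
) -> Molecule:
    """Embed and minimize a single low-energy conformer; assign atom weights.

    Distance-geometry embedding (ETKDGv3) generates ``n_embed_attempts``
    trial conformers from the given seed; each is minimized with MMFF94 and
    the lowest-energy one is kept. The result is deterministic for a fixed
    seed: identical inputs give bit-identical coordinates.
    """
    out = m.copy()
    mol = Chem.AddHs(out.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=max(1, n_embed_attempts), params=params)
    if len(cids) == 0:
        # fall back once to random coordinates before giving up
        params.useRandomCoords = True
        cids = AllChem.EmbedMultipleConfs(
            mol, numConfs=max(1, n_embed_attempts), params=params
        )
    if len(cids) == 0:
        raise MoleculeError(f"3-D embedding failed for {m.id!r}")
    # minimize on a copy: MMFF setup re-perceives aromaticity in place, which
    # would break later aromatic substructure matches on the kept molecule
    ffmol = Chem.Mol(mol)
    results = AllChem.MMFFOptimizeMoleculeConfs(ffmol, maxIters=10_000)
    energies = [e if conv == 0 else np.inf for conv, e in results]
    if not np.isfinite(min(energies)):
        energies = [e for _, e in results]
    best = int(np.argmin(energies))
    keep = ffmol.GetConformer(cids[best])
    coords = np.array(keep.GetPositions(), dtype=float)
    new = Chem.Mol(mol)
    new.RemoveAllConformers()
    conf = Chem.Conformer(new.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    new.AddConformer(conf, assignId=True)
    out.mol = new
    out.coords = coords
    out.energy = float(min(energies))
    if not np.all(np.isfinite(coords)):
        raise MoleculeError(f"non-finite coordinates after embedding {m.id!r}")
    _assign_weights(out)
    return out


def _core_match(m: Molecule, core: Chem.Mol) -> tuple[int, ...]:
    matches = m.mol.GetSubstructMatches(core, uniquify=True)
    if len(matches) != 1:
        raise MoleculeError(
            f"core pattern must match {m.id!r} exactly once; "
            f"found {len(matches)} matches: {matches}"
        )
    return matches[0]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||P @ R.T + t - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def align_to_template(
    m: Molecule, spec: AlignmentSpec, template: Molecule
) -> tuple[Molecule, float]:
    """Rigidly superpose ``m`` onto ``template`` over the matched core atoms.

    Returns the transformed copy and the residual core RMSD in Angstrom.
    """
    if not (m.prepared and template.prepared):
        raise MoleculeError("both molecules must be prepared before alignment")
    core = spec.core_query()
    mi = _core_match(m, core)
    ti = _core_match(template, core)
    P = m.coords[list(mi)]
    Q = template.coords[list(ti)]
    R, t = _kabsch(P, Q)
    out = m.copy()
    out.coords = m.coords @ R.T + t
    conf = out.mol.GetConformer()
    for i, xyz in enumerate(out.coords):
        conf.SetAtomPosition(i, xyz.tolist())
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    if rmsd > spec.max_core_rmsd:
        raise MoleculeError(
            f"core RMSD {rmsd:.3f} A for {m.id!r} exceeds tolerance "
            f"{spec.max_core_rmsd:.3f} A"
        )
    return out, rmsd


def align_set(
    molecules: list[Molecule], template: Molecule, spec: AlignmentSpec | None = None
) -> AlignedSet:
    """Align every molecule (template included if present) onto the template."""
    spec = spec or AlignmentSpec(template_id=template.id)
    members: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for m in molecules:
        aligned, rmsd = align_to_template(m, spec, template)
        members.append(aligned)
        rmsds[m.id] = rmsd
    return AlignedSet(template=template, members=members, core_rmsd=rmsds)


def read_smiles_file(path) -> list[Molecule]:
    """Read a ``SMILES<TAB>id`` file (one record per line, # comments)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smi, _, mid = line.partition("\t")
            out.append(parse_molecule(smi, mid.strip() or smi))
    return out


def write_sdf(molecules: list[Molecule], path) -> None:
    """Write prepared/aligned structures to SDF, preserving ids."""
    with Chem.SDWriter(str(path)) as w:
        for m in molecules:
            mol = Chem.Mol(m.mol)
            mol.SetProp("_Name", m.id)
            w.write(mol)
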