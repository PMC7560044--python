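"""Synthetic aligned molecule sets and bundled fixtures.

``make_toy_set`` builds a set of toy "molecules" (jittered copies of a shared
atom scaffold with randomized per-atom charges, hydrophobicities and donor/
acceptor flags) whose activity is an exact or noisy linear function of the
similarity-index descriptors actually computed by the field engine. Because
the planted coefficients act on the real descriptor columns, latent-factor
fitting, cross-validation and contour stages are all testable end-to-end
with known ground truth and no real chemistry.

``load_fixture`` serves the checksum-verified data tables and structure sets
bundled with the package (binding-rate and endpoint tables, reaction
energies, vibrational frequencies, docking scores, contact residues and
distances, plus the quinolone / derivative SMILES fixtures).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import AlignedSet, Molecule, read_smiles_file
from .fields import (
    DescriptorMatrix,
    GridSpec,
    ProbeSpec,
    build_grid,
    compute_descriptor_matrix,
)

__all__ = ["SyntheticSet", "make_toy_set", "load_fixture", "FIXTURE_CHECKSUMS"]

FIXTURE_CHECKSUMS: dict[str, str] = {
    "quinolones.smi": "f3a767cf6dc62154b010242346cda1c6ec2c57311a1bf93ffab2884c234ed72c",
    "table1": "fb3c925a6016ccdbacc458b14aefa10a174d00a7f044fe7d1b31d1931933ac01",
    "table2": "8068ea01951d6fe0b50a08e5982e08ee0c7dd7e27971bea74e74000d9b03bcfd",
    "table3": "f352b6d44fc4ef09d5aa86c4ca4a2defb61bfb3a7bef3f7185d3bb7fe96f060e",
    "table4": "827121176162a992eb98a91666c64ef0e5817ca108dd7aad4c2dd9c9de6ee9ae",
    "table5": "47de6f06801cd61447c11920a6845d6d878e63f5f13e72cff16a4d46c7621b58",
    "table6": "2c0b8d349e4cc5f7f56daf39d1c97a69992db73680d151ce7fa530f1fdb4d550",
    "table7": "44fc3e8d417cce54073ed94d3c5bfe61ee52a7f6d662dc5df6062c31af2bfbd4",
    "table8": "11521bccb4db53fd0aad0eb8d2e71faf866bd29b08bed157f0aaf2f5b56d9f63",
    "tro_derivatives.smi": "dc839a3fd018cfe3eed8fa333f0e1c8e91d2f3cf69a8abc7dac43ffb942e3797",
}


def _fixture_path(name: str):
    fname = name if "." in name else f"{name}.csv"
    if name not in FIXTURE_CHECKSUMS:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_CHECKSUMS)}"
        )
    ref = resources.files("fqdesign") / "data" / fname
    digest = hashlib.sha256(ref.read_bytes()).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise ValueError(f"fixture {name!r} failed its checksum (got {digest})")
    return ref


def load_fixture(name: str):
    """Load a bundled fixture by name after verifying its checksum.

    Table names (``table1`` .. ``table8``) return a DataFrame; the structure
    sets (``quinolones.smi``, ``tro_derivatives.smi``) return a list of
    connectivity-only :class:`~fqdesign.chem.Molecule`.
    """
    ref = _fixture_path(name)
    if name.endswith(".smi"):
        with resources.as_file(ref) as p:
            return read_smiles_file(p)
    return pd.read_csv(str(ref))


# ----------------------------------------------------------------------
# toy aligned sets with a planted linear structure-activity relationship


@dataclass
class SyntheticSet:
    """A toy aligned set with planted descriptor coefficients."""

    aligned: AlignedSet
    descriptors: DescriptorMatrix
    grid: GridSpec
    beta: np.ndarray          # planted coefficients over kept, scaled columns
    y: np.ndarray             # activities X beta (+ noise)
    noise_sd: float
    seed: int

    @property
    def X(self) -> np.ndarray:
        return self.descriptors.assemble(scaled=True)


def _toy_molecule(
    idx: int,
    scaffold: np.ndarray,
    charges: np.ndarray,
    hyd: np.ndarray,
    hbd: np.ndarray,
    hba: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
) -> Molecule:
    """Atom cloud around shared scaffold points with the given atom weights."""
    n = scaffold.shape[0]
    coords = scaffold + rng.normal(0.0, jitter, size=(n, 3))
    mol = Chem.RWMol()
    for _ in range(n):
        mol.AddAtom(Chem.Atom(6))
    conf = Chem.Conformer(n)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    m = mol.GetMol()
    m.AddConformer(conf)
    return Molecule(
        id=f"toy-{idx}",
        mol=m,
        coords=coords,
        charges=charges,
        hydrophobicity=hyd,
        is_hbd=hbd,
        is_hba=hba,
    )


def make_toy_set(
    n_mol: int = 40,
    n_atoms: int = 8,
    spacing: float = 2.0,
    margin: float = 4.0,
    beta: np.ndarray | None = None,
    n_factors: int = 4,
    signal_sd: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    jitter: float = 0.02,
    probe: ProbeSpec = ProbeSpec(),
    filter_sd: float = 1e-4,
) -> SyntheticSet:
    """Generate an aligned toy set whose activity is linear in its descriptors.

    Atom positions are jittered copies of a shared scaffold (alignment is
    trivial by construction). The descriptor matrix is computed by the real
    field engine; activities are ``y = X beta + eps`` with ``eps ~ N(0,
    noise_sd^2)``. When ``beta`` is omitted, the planted coefficient vector
    is drawn inside the span of the ``n_factors`` leading principal axes of
    the centered descriptor matrix and normalized so the noiseless
    activities have standard deviation ``signal_sd``. A coefficient
    component orthogonal to the row space is invisible to any regression on
    a finite molecule set, and one spread over the trailing axes is washed
    out by leave-one-out resampling; restricting the draw to a
    low-dimensional, well-supported subspace is what guarantees the planted
    relationship is recoverable (``noise_sd`` is then in activity units).
    """
    if n_mol < 4:
        raise ValueError("need at least 4 molecules")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    scaffold = rng.uniform(-3.0, 3.0, size=(n_atoms, 3))
    # molecules vary along a few shared latent property axes (a congeneric
    # series): charges, hydrophobicities AND coordinated geometric
    # displacements are all driven by the same latents, so the descriptor
    # matrix carries genuine low-rank structure across molecules
    k = max(1, min(n_factors, n_mol - 2))
    mix_q = rng.normal(size=(n_atoms, k))
    mix_h = rng.normal(size=(n_atoms, k))
    mix_xyz = rng.normal(size=(n_atoms, 3, k)) * 0.3  # Angstrom per latent unit
    latents = rng.normal(size=(n_mol, k))
    hbd = rng.random(n_atoms) < 0.3  # scaffold-level flags, shared by the set
    hba = rng.random(n_atoms) < 0.3
    members = []
    for i in range(n_mol):
        charges = mix_q @ latents[i]
        charges -= charges.mean()  # neutral molecule: charges sum to 0
        members.append(
            _toy_molecule(
                i, scaffold + mix_xyz @ latents[i],
                charges, mix_h @ latents[i], hbd, hba, rng, jitter
            )
        )
    aset = AlignedSet(
        template=members[0],
        members=members,
        core_rmsd={m.id: 0.0 for m in members},
    )
    grid = build_grid(aset, spacing=spacing, margin=margin)
    desc = compute_descriptor_matrix(aset, grid, probe=probe, filter_sd=filter_sd)
    X = desc.assemble(scaled=True)
    if beta is None:
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        b = Vt[:k].T @ rng.normal(size=k)
        b *= signal_sd / (Xc @ b).std()
    else:
        b = np.asarray(beta, dtype=float)
        if b.size != X.shape[1]:
            raise ValueError(
                f"beta has {b.size} entries but the kept descriptor matrix "
                f"has {X.shape[1]} columns"
            )
    y = X @ b + rng.normal(0.0, noise_sd, size=n_mol) if noise_sd > 0 else X @ b
    return SyntheticSet(
        aligned=aset, descriptors=desc, grid=grid, beta=b, y=np.asarray(y),
        noise_sd=float(noise_sd), seed=int(seed),
    )
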