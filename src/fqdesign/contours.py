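"""Contour (STDEV x COEFF) analysis and substituent-based derivative design.

The product of each kept descriptor column's standard deviation and its PLS
coefficient gives the familiar STDEV*COEFF map: grid points in the top
percentile band mark regions where more of a field property raises the
response (favored for increasing it), the bottom band where it lowers it.
Site summaries tally contour points near labelled substitution sites of the
aligned template, and the derivative enumerator attaches substituent
fragments at those sites to generate the candidate library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chem import Molecule, MoleculeError
from .fields import FIELD_KINDS, DescriptorMatrix
from .pls import PLSModel

__all__ = [
    "ContourMap",
    "SubstitutionScheme",
    "DerivativeSpec",
    "stdev_coeff_map",
    "threshold_contours",
    "summarize_sites",
    "enumerate_derivatives",
    "cross_product_derivatives",
    "TROVAFLOXACIN_SCAFFOLD",
    "SUBSTITUENT_FRAGMENTS",
    "DERIVATIVE_REGISTRY",
]

# Trovafloxacin with labelled attachment points: [*:1] is substitution site 1
# (the exocyclic amine position on the azabicyclohexane ring, -NH2 in the
# parent) and [*:5] is site 5 (the aromatic CH of the naphthyridone ring,
# -H in the parent).
TROVAFLOXACIN_SCAFFOLD = (
    "OC(=O)c1cn(-c2ccc(F)cc2F)c2nc(N3CC4C([*:1])C4C3)c(F)c([*:5])c2c1=O"
)

#: Attachment fragments, written with a site-0 placeholder that is relabelled
#: to the target site at enumeration time.
SUBSTITUENT_FRAGMENTS: dict[str, str] = {
    "H": "[H][*:0]",
    "NH2": "N[*:0]",
    "NO2": "O=[N+]([O-])[*:0]",
    "CH3": "C[*:0]",
    "C2H3": "C=C[*:0]",
    "C2H5": "CC[*:0]",
    "C3H7": "CCC[*:0]",
    "SH": "S[*:0]",
    "OCH3": "CO[*:0]",
    "SiH3": "[SiH3][*:0]",
    "PH2": "[PH2][*:0]",
}

#: The 16-derivative registry: name -> {site: substituent}. Sites not listed
#: keep the parent group (site 1: NH2, site 5: H).
DERIVATIVE_REGISTRY: list[tuple[str, dict[int, str]]] = [
    ("Derivative-1", {1: "NO2"}),
    ("Derivative-2", {1: "C2H5"}),
    ("Derivative-3", {1: "C3H7"}),
    ("Derivative-4", {5: "SiH3"}),
    ("Derivative-5", {5: "PH2"}),
    ("Derivative-6", {1: "NO2", 5: "SiH3"}),
    ("Derivative-7", {1: "OCH3", 5: "SiH3"}),
    ("Derivative-8", {1: "OCH3", 5: "PH2"}),
    ("Derivative-9", {1: "SH", 5: "PH2"}),
    ("Derivative-10", {1: "C2H5", 5: "PH2"}),
    ("Derivative-11", {1: "C3H7", 5: "PH2"}),
    ("Derivative-12", {1: "H"}),
    ("Derivative-13", {1: "CH3"}),
    ("Derivative-14", {1: "C2H3"}),
    ("Derivative-15", {1: "OCH3"}),
    ("Derivative-16", {1: "SH"}),
]


@dataclass
class ContourMap:
    """STDEV*COEFF values per field per grid point, with percentile masks."""

    values: dict[str, np.ndarray]        # field -> (n_points,) map; masked cols = 0
    kept: dict[str, np.ndarray]          # field -> kept-column mask
    grid_points: np.ndarray              # (n_points, 3)
    fav_pct: float = 80.0
    disfav_pct: float = 20.0
    favored: dict[str, np.ndarray] = field(default_factory=dict)
    disfavored: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.values:
            fav = self.favored.get(k)
            dis = self.disfavored.get(k)
            for j in np.flatnonzero(self.kept[k]):
                cls = "neutral"
                if fav is not None and fav[j]:
                    cls = "favored"
                elif dis is not None and dis[j]:
                    cls = "disfavored"
                x, y, z = self.grid_points[j]
                rows.append(
                    {"x": x, "y": y, "z": z, "field": k,
                     "value": float(self.values[k][j]), "class": cls}
                )
        return pd.DataFrame(rows)


def stdev_coeff_map(model: PLSModel, X: DescriptorMatrix) -> ContourMap:
    """Per-gridpoint sd(column) x coefficient for each field's kept columns."""
    n_kept = sum(int(X.kept[k].sum()) for k in FIELD_KINDS)
    if model.coef.size != n_kept:
        raise ValueError(
            f"model has {model.coef.size} coefficients but the descriptor "
            f"matrix has {n_kept} kept columns"
        )
    sds = X.column_sds(scaled=True)
    fields_per_col = X.column_fields()
    values: dict[str, np.ndarray] = {}
    offset = 0
    for k in FIELD_KINDS:
        nk = int(X.kept[k].sum())
        v = np.zeros(X.grid.n_points)
        sel = slice(offset, offset + nk)
        assert all(fields_per_col[sel] == k)
        v[X.kept[k]] = sds[sel] * model.coef[sel]
        values[k] = v
        offset += nk
    return ContourMap(values=values, kept=dict(X.kept), grid_points=X.grid.points())


def threshold_contours(
    cmap: ContourMap, fav_pct: float = 80.0, disfav_pct: float = 20.0
) -> ContourMap:
    """Mark favored/disfavored points by linear-interpolation percentiles.

    Percentiles are taken over kept columns only. Strict-inequality guards
    keep the two masks disjoint and leave both empty when every value ties.
    """
    if fav_pct <= disfav_pct:
        raise ValueError("favored percentile must exceed disfavored percentile")
    cmap.fav_pct = float(fav_pct)
    cmap.disfav_pct = float(disfav_pct)
    for k, v in cmap.values.items():
        keep = cmap.kept[k]
        fav = np.zeros_like(keep)
        dis = np.zeros_like(keep)
        if keep.any():
            vals = v[keep]
            hi = np.percentile(vals, fav_pct)
            lo = np.percentile(vals, disfav_pct)
            fav[keep] = (vals >= hi) & (vals > lo)
            dis[keep] = (vals <= lo) & (vals < hi)
        cmap.favored[k] = fav
        cmap.disfavored[k] = dis
    return cmap


def summarize_sites(
    cmap: ContourMap, site_coords: dict[str, np.ndarray], radius: float = 3.0
) -> pd.DataFrame:
    """Majority favored/disfavored/neutral flag per site and field.

    For each labelled site, contour points within ``radius`` Angstrom vote;
    a site with no kept grid point in range is flagged neutral with a warning.
    """
    if not cmap.favored:
        raise ValueError("run threshold_contours before summarizing sites")
    rows = []
    for site, xyz in site_coords.items():
        xyz = np.asarray(xyz, dtype=float)
        d2 = np.sum((cmap.grid_points - xyz) ** 2, axis=1)
        for k in cmap.values:
            near = (d2 <= radius**2) & cmap.kept[k]
            if not near.any():
                warnings.warn(
                    f"no kept grid points within {radius} A of site {site!r} "
                    f"for field {k}; flagging neutral"
                )
                flag = "neutral"
            else:
                nf = int(cmap.favored[k][near].sum())
                nd = int(cmap.disfavored[k][near].sum())
                flag = "favored" if nf > nd else "disfavored" if nd > nf else "neutral"
            rows.append({"site": site, "field": k, "flag": flag})
    return pd.DataFrame(rows)


@dataclass
class SubstitutionScheme:
    """Labelled-site scaffold plus the substituent vocabulary."""

    scaffold_smiles: str = TROVAFLOXACIN_SCAFFOLD
    fragments: dict[str, str] = field(default_factory=lambda: dict(SUBSTITUENT_FRAGMENTS))
    parent_groups: dict[int, str] = field(default_factory=lambda: {1: "NH2", 5: "H"})

    def sites(self) -> list[int]:
        return sorted(self.parent_groups)


@dataclass
class DerivativeSpec:
    name: str
    substitutions: dict[int, str]
    molecule: Molecule


def _attach(scheme: SubstitutionScheme, site_map: dict[int, str]) -> Chem.Mol:
    mol = Chem.MolFromSmiles(scheme.scaffold_smiles)
    if mol is None:
        raise MoleculeError("invalid scaffold SMILES")
    full = {**scheme.parent_groups, **site_map}
    frags = []
    for site, group in full.items():
        smi = scheme.fragments.get(group)
        if smi is None:
            raise MoleculeError(f"unknown substituent group {group!r}")
        frag = Chem.MolFromSmiles(smi.replace("*:0", f"*:{site}"))
        if frag is None:
            raise MoleculeError(f"invalid fragment SMILES for {group!r}")
        frags.append(frag)
    combined = frags[0]
    for f in frags[1:]:
        combined = Chem.CombineMols(combined, f)
    from rdkit import rdBase

    with rdBase.BlockLogs():  # hydrogen-fragment zips log benign warnings
        out = Chem.molzip(mol, combined)
        out = Chem.RemoveHs(out)
        Chem.SanitizeMol(out)
    return out


def enumerate_derivatives(
    scheme: SubstitutionScheme,
    registry: list[tuple[str, dict[int, str]]] | None = None,
) -> tuple[list[DerivativeSpec], list[tuple[str, str]]]:
    """Build one structure per registry row; invalid rows are reported, not fatal.

    Returns (derivatives, errors) where errors is a list of (name, message).
    """
    registry = DERIVATIVE_REGISTRY if registry is None else registry
    out: list[DerivativeSpec] = []
    errors: list[tuple[str, str]] = []
    for name, site_map in registry:
        try:
            mol = _attach(scheme, site_map)
        except (MoleculeError, Chem.rdchem.AtomValenceException, ValueError) as exc:
            errors.append((name, str(exc)))
            continue
        out.append(
            DerivativeSpec(
                name=name,
                substitutions=dict(site_map),
                molecule=Molecule(id=name, mol=mol),
            )
        )
    return out, errors


def cross_product_derivatives(
    scheme: SubstitutionScheme, site_groups: dict[int, list[str]]
) -> list[DerivativeSpec]:
    """Generic enumerator: full cross-product of the per-site group lists."""
    import itertools

    sites = sorted(site_groups)
    specs = []
    for combo in itertools.product(*(site_groups[s] for s in sites)):
        site_map = dict(zip(sites, combo))
        name = "-".join(f"{s}-{g}" for s, g in site_map.items())
        mol = _attach(scheme, site_map)
        specs.append(
            DerivativeSpec(name=name, substitutions=site_map,
                           molecule=Molecule(id=name, mol=mol))
        )
    return specs


def derivative_formula(spec: DerivativeSpec) -> str:
    return rdMolDescriptors.CalcMolFormula(spec.molecule.mol)
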