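"""Molecular data model and rigid common-substructure alignment.

A congeneric series is modelled as pre-aligned (or alignable) rigid 3D
molecules: each atom carries Cartesian coordinates (Angstrom), a partial
charge (e), a van der Waals radius, and unit-scale weights for the five
similarity-field properties (steric, electrostatic, hydrophobic, H-bond
donor, H-bond acceptor).  Alignment overlays the atoms of a shared core
substructure onto a template via least-squares rigid superposition
(Kabsch); conformer generation and energy minimisation are out of scope —
structures are accepted as provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "AlignmentResult",
    "BONDI_RADII",
    "COMSIA_PROPERTIES",
    "default_comsia_weights",
    "read_structures",
    "kabsch_superpose",
    "align_series",
]

COMSIA_PROPERTIES = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

#: Bondi van der Waals radii (Angstrom); fallback 1.70 for unlisted elements.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

_HALOGENS = {"F", "Cl", "Br", "I"}
_CARBON_RADIUS = BONDI_RADII["C"]


def default_comsia_weights(
    element: str,
    partial_charge: float = 0.0,
    vdw_radius: float | None = None,
    has_h: bool = False,
) -> dict[str, float]:
    """Rule-based similarity-field weights for one atom.

    steric: atom volume proxy (vdw radius cubed, normalised so carbon = 1);
    electrostatic: the partial charge; hydrophobic: +1 for carbon and
    halogens, 0 for polar atoms; donor: +1 for N/O bearing a hydrogen;
    acceptor: +1 for N/O (lone-pair carriers).
    """
    if vdw_radius is None:
        vdw_radius = BONDI_RADII.get(element, 1.70)
    return {
        "steric": (vdw_radius / _CARBON_RADIUS) ** 3,
        "electrostatic": partial_charge,
        "hydrophobic": 1.0 if (element == "C" or element in _HALOGENS) else 0.0,
        "donor": 1.0 if (element in ("N", "O") and has_h) else 0.0,
        "acceptor": 1.0 if element in ("N", "O") else 0.0,
    }


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) Angstrom
    partial_charge: float = 0.0
    vdw_radius: float | None = None
    comsia_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coords must be a 3-vector")
        if self.vdw_radius is None:
            self.vdw_radius = BONDI_RADII.get(self.element, 1.70)
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not self.comsia_weights:
            self.comsia_weights = default_comsia_weights(
                self.element, self.partial_charge, self.vdw_radius
            )
        missing = set(COMSIA_PROPERTIES) - set(self.comsia_weights)
        if missing:
            raise ValueError(f"comsia_weights missing properties {sorted(missing)}")


@dataclass
class Molecule:
    name: str
    atoms: list[Atom]
    core_atom_indices: list[int] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]) if self.atoms else np.zeros((0, 3))

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def weights(self, prop: str) -> np.ndarray:
        return np.array([a.comsia_weights[prop] for a in self.atoms])

    def core_coords(self) -> np.ndarray:
        if not self.core_atom_indices:
            raise ValueError(f"molecule {self.name!r}: no core atoms defined")
        n = len(self.atoms)
        if any(i < 0 or i >= n for i in self.core_atom_indices):
            raise ValueError(f"molecule {self.name!r}: core atom index out of bounds")
        return self.coords[self.core_atom_indices]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates mapped through x -> R x + t."""
        new_atoms = [
            replace(a, coords=rotation @ a.coords + translation) for a in self.atoms
        ]
        return Molecule(self.name, new_atoms, list(self.core_atom_indices))


@dataclass(frozen=True)
class AlignmentResult:
    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)
    core_rmsd: float


def read_structures(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF (V2000) or MOL2 file via RDKit.

    Partial charges are taken from MOL2 charge columns or from an SDF
    ``PARTIAL_CHARGES`` property (whitespace-separated, one value per
    atom); when absent, zeros are assigned with a warning.  Van der Waals
    radii come from the built-in element table.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("sdf", "mol2"):
        raise ValueError(f"unsupported structure format {fmt!r}")

    if path.stat().st_size == 0:
        warnings.warn(f"{path}: no molecules read (empty file)")
        return []

    molecules: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        rdmols = list(supplier)
    else:
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        rdmols = [mol] if mol is not None else []
        if mol is None and path.stat().st_size > 0:
            raise ValueError(f"{path}: unparseable MOL2 record")

    for idx, rdmol in enumerate(rdmols):
        if rdmol is None:
            raise ValueError(f"{path}: unparseable record at molecule index {idx}")
        if rdmol.GetNumConformers() == 0:
            raise ValueError(f"{path}: molecule index {idx} has no 3D coordinates")
        conf = rdmol.GetConformer()
        n = rdmol.GetNumAtoms()

        charges = None
        if rdmol.HasProp("PARTIAL_CHARGES"):
            vals = rdmol.GetProp("PARTIAL_CHARGES").split()
            if len(vals) == n:
                charges = [float(v) for v in vals]
        if charges is None and rdmol.GetNumAtoms() > 0:
            a0 = rdmol.GetAtomWithIdx(0)
            if a0.HasProp("_TriposPartialCharge"):
                charges = [
                    rdmol.GetAtomWithIdx(i).GetDoubleProp("_TriposPartialCharge")
                    for i in range(n)
                ]
        if charges is None:
            warnings.warn(f"{path}: molecule {idx} has no partial charges; assigning zeros")
            charges = [0.0] * n

        atoms = []
        for i in range(n):
            rdatom = rdmol.GetAtomWithIdx(i)
            pos = conf.GetAtomPosition(i)
            has_h = rdatom.GetTotalNumHs(includeNeighbors=True) > 0
            element = rdatom.GetSymbol()
            atoms.append(
                Atom(
                    element=element,
                    coords=np.array([pos.x, pos.y, pos.z]),
                    partial_charge=charges[i],
                    comsia_weights=default_comsia_weights(
                        element, charges[i], BONDI_RADII.get(element, 1.70), has_h
                    ),
                )
            )
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{idx}"
        molecules.append(Molecule(name=name or f"mol{idx}", atoms=atoms))

    if not molecules:
        warnings.warn(f"{path}: no molecules read")
    return molecules


def kabsch_superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray
) -> AlignmentResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R (det +1) and translation t minimising
    ||R x + t - y||; ``core_rmsd`` is the residual RMSD after the
    transform.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")

    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    a, b = mobile - mc, ref - rc
    # collinearity check: rank of centred point cloud
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")

    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return AlignmentResult(rotation=rot, translation=trans, core_rmsd=rmsd)


def align_series(
    molecules: Sequence[Molecule], template: Molecule
) -> tuple[list[Molecule], list[AlignmentResult]]:
    """Superpose each molecule's core atoms onto the template core.

    The core mapping is positional: the i-th entry of each molecule's
    ``core_atom_indices`` corresponds to the i-th template core atom.
    The template itself is not modified.
    """
    template_core = template.core_coords()
    aligned: list[Molecule] = []
    results: list[AlignmentResult] = []
    for mol in molecules:
        core = mol.core_coords()
        if core.shape != template_core.shape:
            raise ValueError(
                f"molecule {mol.name!r}: core size {core.shape[0]} does not match "
                f"template core size {template_core.shape[0]}"
            )
        res = kabsch_superpose(core, template_core)
        aligned.append(mol.transformed(res.rotation, res.translation))
        results.append(res)
        logger.debug("aligned %s: core RMSD %.4f A", mol.name, res.core_rmsd)
    return aligned, results
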