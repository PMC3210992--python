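"""Molecular interaction fields on a rectangular lattice.

Two descriptor families are computed for every aligned molecule on a
shared grid:

* CoMFA-style probe energies: a Lennard-Jones steric term
  ``eps_ij * [(R_ij/r)^12 - 2 (R_ij/r)^6]`` and a Coulomb electrostatic
  term ``332.0636 q_i q_probe / (eps(r) r)`` with the distance-dependent
  dielectric ``eps(r) = r`` (so the energy falls off as 1/r^2), both in
  kcal/mol.  Energies are truncated at a 30 kcal/mol cutoff to stop a few
  clashing lattice points from dominating the regression; at lattice
  points where the steric cutoff is hit, the electrostatic value is
  replaced by the column mean over non-clashing molecules during matrix
  assembly, so clash information is not encoded twice.

* CoMSIA-style similarity indices: for each physicochemical property k,
  ``A_k(q) = sum_i w_probe,k * w_ik * exp(-alpha * r_iq^2)`` with a unit
  probe and attenuation factor alpha (default 0.3).  The Gaussian decay
  needs no cutoff and gives smooth, dimensionless descriptors for five
  properties (steric, electrostatic, hydrophobic, H-bond donor, H-bond
  acceptor).

The probe is an sp3 carbon with +1 charge for the energy fields and a
unit-weight, 1 Angstrom atom for the similarity fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structures import COMSIA_PROPERTIES, Molecule

__all__ = [
    "GridSpec",
    "Probe",
    "FieldBlock",
    "COULOMB_CONSTANT",
    "ENERGY_CUTOFF",
    "COMFA_FIELDS",
    "FIELD_LETTERS",
    "parse_field_selection",
    "build_grid",
    "comfa_fields",
    "comsia_fields",
    "assemble_matrix",
    "comfa_block",
    "comsia_block",
]

#: kcal * Angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.0636
#: truncation for both probe energies, kcal/mol
ENERGY_CUTOFF = 30.0

COMFA_FIELDS = ("steric", "electrostatic")

FIELD_LETTERS = {
    "S": "steric",
    "E": "electrostatic",
    "H": "hydrophobic",
    "D": "donor",
    "A": "acceptor",
}

#: Lennard-Jones well depths per element, kcal/mol (Tripos-style defaults).
ELEMENT_LJ_EPS: dict[str, float] = {
    "H": 0.042, "C": 0.107, "N": 0.095, "O": 0.116, "F": 0.109,
    "P": 0.314, "S": 0.314, "Cl": 0.367, "Br": 0.434, "I": 0.623,
}
_DEFAULT_LJ_EPS = 0.107


def parse_field_selection(selection: str | Sequence[str]) -> tuple[str, ...]:
    """Normalise a field selection like ``"S,E,D,H"`` to full field names."""
    if isinstance(selection, str):
        parts = [p.strip() for p in selection.replace("+", ",").split(",") if p.strip()]
    else:
        parts = list(selection)
    out = []
    for p in parts:
        name = FIELD_LETTERS.get(p.upper(), p.lower()) if len(p) == 1 else p.lower()
        if name not in COMSIA_PROPERTIES:
            raise ValueError(f"unknown field {p!r}")
        out.append(name)
    if not out:
        raise ValueError("empty field selection")
    return tuple(out)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice: nodes at origin + spacing * index per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def nodes(self) -> np.ndarray:
        """All lattice node coordinates, shape (n_points, 3), x fastest."""
        nx, ny, nz = self.dims
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        # x fastest: flat index = ix + nx * (iy + ny * iz)
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return np.asarray(self.origin) + self.spacing * idx

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])


@dataclass(frozen=True)
class Probe:
    """Probe atom for both field families (defaults: sp3 C, +1 e)."""

    charge: float = 1.0
    vdw_radius: float = 1.70
    lj_well_depth: float = 0.107
    comsia_weights: Mapping[str, float] = dc_field(
        default_factory=lambda: {p: 1.0 for p in COMSIA_PROPERTIES}
    )
    comsia_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("probe vdw_radius must be positive")
        if not all(np.isfinite(list(self.comsia_weights.values()))):
            raise ValueError("probe comsia_weights must be finite")


@dataclass
class FieldBlock:
    """Compounds x (fields * grid nodes) descriptor matrix.

    Columns are ordered field-major: all nodes of the first field (x
    fastest within a field), then the next field.  ``column_meta`` holds
    one ``(field_name, node_index)`` pair per column.
    """

    matrix: np.ndarray
    column_meta: list[tuple[str, int]]
    grid: GridSpec
    fields: tuple[str, ...]
    compound_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("field matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length must match matrix columns")
        expected = len(self.fields) * self.grid.n_points
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"column count {self.matrix.shape[1]} != fields x nodes = {expected}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("field matrix contains NaN/Inf")

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]

    def field_slice(self, name: str) -> slice:
        n = self.grid.n_points
        i = self.fields.index(name)
        return slice(i * n, (i + 1) * n)

    def field_slices(self) -> dict[str, slice]:
        return {name: self.field_slice(name) for name in self.fields}

    # ---- persistence -------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` (matrix) and ``<prefix>.json`` (metadata)."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".csv"), self.matrix, delimiter=",")
        meta = {
            "fields": list(self.fields),
            "grid": {
                "origin": list(self.grid.origin),
                "spacing": self.grid.spacing,
                "dims": list(self.grid.dims),
            },
            "compound_names": self.compound_names,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "FieldBlock":
        prefix = Path(prefix)
        matrix = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        grid = GridSpec(
            origin=tuple(meta["grid"]["origin"]),
            spacing=meta["grid"]["spacing"],
            dims=tuple(meta["grid"]["dims"]),
        )
        fields = tuple(meta["fields"])
        n = grid.n_points
        meta_cols = [(f, q) for f in fields for q in range(n)]
        return cls(matrix, meta_cols, grid, fields, meta.get("compound_names"))


def build_grid(
    molecules: Sequence[Molecule], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Lattice enclosing every atom's vdW sphere plus ``margin`` on all sides.

    Node coordinates are snapped to integer multiples of ``spacing`` in
    the global frame, so any series occupying the same region yields the
    identical grid.
    """
    if not molecules or all(len(m.atoms) == 0 for m in molecules):
        raise ValueError("cannot build a grid for an empty series")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for mol in molecules:
        if not mol.atoms:
            continue
        xyz = mol.coords
        pad = mol.radii[:, None] + margin
        lo = np.minimum(lo, (xyz - pad).min(axis=0))
        hi = np.maximum(hi, (xyz + pad).max(axis=0))
    snap_tol = 1e-9  # treat hull bounds on a lattice plane as inside
    lo_idx = np.floor(lo / spacing + snap_tol).astype(int)
    hi_idx = np.ceil(hi / spacing - snap_tol).astype(int)
    origin = tuple(float(i) * spacing for i in lo_idx)
    dims = tuple(int(h - l) + 1 for l, h in zip(lo_idx, hi_idx))
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


def comfa_fields(
    molecule: Molecule, grid: GridSpec, probe: Probe = Probe()
) -> dict[str, np.ndarray]:
    """Probe interaction energies at every lattice node (kcal/mol).

    Returns ``steric`` (truncated at +30), ``electrostatic`` (truncated at
    +/-30) and the boolean ``steric_capped`` mask marking nodes where the
    steric cutoff was hit.
    """
    if probe.vdw_radius <= 0:
        raise ValueError("probe radius must be positive")
    nodes = grid.nodes()
    xyz = molecule.coords
    if xyz.shape[0] == 0:
        zeros = np.zeros(grid.n_points)
        return {"steric": zeros, "electrostatic": zeros.copy(),
                "steric_capped": np.zeros(grid.n_points, bool)}
    r = cdist(nodes, xyz)
    r = np.maximum(r, 1e-6)  # clash energies are truncated anyway

    eps_atoms = np.array(
        [ELEMENT_LJ_EPS.get(a.element, _DEFAULT_LJ_EPS) for a in molecule.atoms]
    )
    eps_ij = np.sqrt(eps_atoms * probe.lj_well_depth)
    r_min = molecule.radii + probe.vdw_radius
    with np.errstate(over="ignore"):
        frac6 = (r_min[None, :] / r) ** 6
        steric_raw = (eps_ij[None, :] * (frac6 * frac6 - 2.0 * frac6)).sum(axis=1)
    capped = steric_raw > ENERGY_CUTOFF
    steric = np.minimum(steric_raw, ENERGY_CUTOFF)

    q = molecule.charges
    # eps(r) = r  =>  E = k q_i q_p / r^2
    elec_raw = (COULOMB_CONSTANT * probe.charge * q[None, :] / (r * r)).sum(axis=1)
    electrostatic = np.clip(elec_raw, -ENERGY_CUTOFF, ENERGY_CUTOFF)
    return {"steric": steric, "electrostatic": electrostatic, "steric_capped": capped}


def comsia_fields(
    molecule: Molecule,
    grid: GridSpec,
    probe: Probe = Probe(),
    alpha: float = 0.3,
    properties: Sequence[str] = COMSIA_PROPERTIES,
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices for the requested properties at every node."""
    if alpha <= 0:
        raise ValueError("attenuation factor alpha must be positive")
    nodes = grid.nodes()
    xyz = molecule.coords
    if xyz.shape[0] == 0:
        return {p: np.zeros(grid.n_points) for p in properties}
    r2 = cdist(nodes, xyz, metric="sqeuclidean")
    g = np.exp(-alpha * r2)
    out = {}
    for prop in properties:
        w = molecule.weights(prop)
        out[prop] = float(probe.comsia_weights[prop]) * (g @ w)
    return out


def assemble_matrix(
    per_molecule_maps: Sequence[Mapping[str, np.ndarray]],
    fields: str | Sequence[str],
    grid: GridSpec,
    compound_names: list[str] | None = None,
) -> FieldBlock:
    """Concatenate per-molecule field maps into a descriptor matrix.

    Columns run field-major in the declared order, node index (x fastest)
    within each field.  For electrostatic columns of CoMFA maps (maps
    carrying a ``steric_capped`` mask), entries at sterically clashing
    nodes are replaced by the column mean over the non-clashing molecules.
    """
    field_names = parse_field_selection(fields)
    n_nodes = grid.n_points
    n_mol = len(per_molecule_maps)
    if n_mol == 0:
        raise ValueError("no molecules to assemble")
    for m in per_molecule_maps:
        for f in field_names:
            if f not in m:
                raise ValueError(f"field {f!r} missing from a molecule's maps")
            if len(np.asarray(m[f])) != n_nodes:
                raise ValueError("grid mismatch between molecules")

    blocks = []
    for f in field_names:
        col = np.vstack([np.asarray(m[f], dtype=float) for m in per_molecule_maps])
        if f == "electrostatic" and all("steric_capped" in m for m in per_molecule_maps):
            capped = np.vstack([m["steric_capped"] for m in per_molecule_maps])
            if capped.any():
                col = col.copy()
                ok = ~capped
                # column mean over non-clashing molecules; all-clash -> overall cap value mean
                with np.errstate(invalid="ignore"):
                    col_mean = np.where(
                        ok.sum(axis=0) > 0,
                        np.divide(
                            (col * ok).sum(axis=0),
                            np.maximum(ok.sum(axis=0), 1),
                        ),
                        0.0,
                    )
                col[capped] = np.broadcast_to(col_mean, col.shape)[capped]
        blocks.append(col)
    matrix = np.hstack(blocks)
    meta = [(f, q) for f in field_names for q in range(n_nodes)]
    return FieldBlock(matrix, meta, grid, field_names, compound_names)


def comfa_block(
    molecules: Sequence[Molecule],
    grid: GridSpec | None = None,
    probe: Probe = Probe(),
    spacing: float = 2.0,
    margin: float = 4.0,
) -> FieldBlock:
    """Convenience: CoMFA steric + electrostatic block for a series."""
    if grid is None:
        grid = build_grid(molecules, spacing=spacing, margin=margin)
    maps = [comfa_fields(m, grid, probe) for m in molecules]
    return assemble_matrix(maps, COMFA_FIELDS, grid, [m.name for m in molecules])


def comsia_block(
    molecules: Sequence[Molecule],
    fields: str | Sequence[str] = COMSIA_PROPERTIES,
    grid: GridSpec | None = None,
    probe: Probe = Probe(),
    alpha: float = 0.3,
    spacing: float = 2.0,
    margin: float = 4.0,
) -> FieldBlock:
    """Convenience: CoMSIA similarity block for a series."""
    field_names = parse_field_selection(fields)
    if grid is None:
        grid = build_grid(molecules, spacing=spacing, margin=margin)
    maps = [comsia_fields(m, grid, probe, alpha, field_names) for m in molecules]
    return assemble_matrix(maps, field_names, grid, [m.name for m in molecules])
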