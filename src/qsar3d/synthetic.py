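"""Synthetic congeneric series with a known field-to-activity ground truth.

Real 3D-QSAR inputs are proprietary aligned structures; this module
stands in for them with a rigid shared core plus a handful of fixed
substituent sites whose occupancy, element and partial charge vary
randomly from molecule to molecule — the synthetic analogue of an
R-group series.  Activities are generated as a sparse linear function of
the series' own lattice field values plus Gaussian noise, so every
downstream stage (fields, PLS, validation, contour maps) can be tested
against a known ground truth: the models should recover close to the
planted q^2 and the contour maps should rank the planted effect nodes
correctly.

Defaults emulate the reference study's conditions: 40 molecules, three
active lattice nodes, activity noise 0.1 pEC50 units, activities spanning
about 3 log units around pEC50 6.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .contours import ContourMap
from .fields import FieldBlock, GridSpec, Probe, build_grid, comsia_block
from .structures import Atom, Molecule, default_comsia_weights

__all__ = [
    "SyntheticSpec",
    "generate_series",
    "series_block",
    "recovery_score",
    "export_series",
]

_PALETTE = ("H", "C", "N", "O", "Cl")
_PALETTE_RADIUS = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "Cl": 1.75}

# rigid core: a puckered 8-atom scaffold (ring + two exocyclic atoms)
_CORE_ELEMENTS = ("C", "C", "N", "C", "S", "O", "C", "N")
_CORE_COORDS = np.array(
    [
        [0.00, 0.00, 0.00],
        [1.40, 0.30, 0.00],
        [2.10, -0.60, 0.80],
        [1.40, -1.70, 1.10],
        [-0.20, -1.50, 0.70],
        [1.95, -2.75, 1.60],
        [-1.05, 1.05, -0.45],
        [3.50, -0.45, 1.05],
    ]
)
_CORE_CHARGES = (0.05, -0.02, -0.30, 0.25, -0.10, -0.45, 0.02, -0.35)

# fixed substituent positions around the core (Angstrom)
_DEFAULT_SITES = np.array(
    [
        [-2.45, 1.90, -0.90],
        [2.05, 1.55, -0.55],
        [4.60, 0.65, 0.90],
        [1.05, -3.95, 2.05],
        [-1.55, -2.45, 1.15],
    ]
)


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic series."""

    n_molecules: int = 40
    core_elements: Sequence[str] = _CORE_ELEMENTS
    core_coords: np.ndarray = dc_field(default_factory=lambda: _CORE_COORDS.copy())
    core_charges: Sequence[float] = _CORE_CHARGES
    substituent_sites: np.ndarray = dc_field(default_factory=lambda: _DEFAULT_SITES.copy())
    site_occupancy: float = 0.75
    effect_weights: dict[tuple[str, int], float] | None = None  # None -> pick 3 nodes
    n_active_nodes: int = 3
    noise_sd: float = 0.1
    intercept: float = 6.5
    activity_span: float = 3.0
    fields: Sequence[str] = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")
    alpha: float = 0.3
    spacing: float = 2.0
    margin: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 8:
            raise ValueError("need at least 8 molecules")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_weights is not None and not any(
            w != 0 for w in self.effect_weights.values()
        ):
            raise ValueError("effect_weights must contain a nonzero weight")
        self.core_coords = np.asarray(self.core_coords, float)
        self.substituent_sites = np.asarray(self.substituent_sites, float)
        from scipy.spatial.distance import cdist

        d = cdist(self.substituent_sites, self.core_coords)
        if (d < 1.0).any():
            bad = int(np.argwhere(d < 1.0)[0][0])
            raise ValueError(f"substituent site {bad} collides with the core (< 1 A)")

    def grid(self) -> GridSpec:
        """Series grid, independent of which sites end up occupied."""
        phantom = Molecule(
            "hull",
            [Atom("C", c) for c in self.core_coords]
            + [Atom("Cl", s) for s in self.substituent_sites],
        )
        return build_grid([phantom], spacing=self.spacing, margin=self.margin)


def _make_molecule(spec: SyntheticSpec, rng: np.random.Generator, name: str) -> Molecule:
    atoms = []
    for el, xyz, q in zip(spec.core_elements, spec.core_coords, spec.core_charges):
        atoms.append(
            Atom(el, xyz, partial_charge=q,
                 comsia_weights=default_comsia_weights(el, q, None, has_h=el in ("N", "O")))
        )
    for site in spec.substituent_sites:
        if rng.random() >= spec.site_occupancy:
            continue
        el = str(rng.choice(_PALETTE))
        q = float(np.clip(rng.normal(0.0, 0.25), -0.8, 0.8))
        atoms.append(
            Atom(el, site, partial_charge=q, vdw_radius=_PALETTE_RADIUS[el],
                 comsia_weights=default_comsia_weights(
                     el, q, _PALETTE_RADIUS[el], has_h=el in ("N", "O")))
        )
    return Molecule(name, atoms, core_atom_indices=list(range(len(spec.core_elements))))


def series_block(spec: SyntheticSpec, molecules: Sequence[Molecule]) -> FieldBlock:
    """Similarity-field block of a generated series on the spec's grid."""
    return comsia_block(
        molecules, fields=spec.fields, grid=spec.grid(), probe=Probe(), alpha=spec.alpha
    )


def _pick_effect_columns(
    block: FieldBlock, n_active: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Greedily pick high-variance, mutually distant lattice columns."""
    sd = block.matrix.std(axis=0, ddof=1)
    order = np.argsort(sd)[::-1]
    nodes = block.grid.nodes()
    chosen: list[int] = []
    for col in order:
        if len(chosen) == n_active:
            break
        f_new, q_new = block.column_meta[col]
        ok = True
        for prev in chosen:
            f_old, q_old = block.column_meta[prev]
            if np.linalg.norm(nodes[q_new] - nodes[q_old]) < 2 * block.grid.spacing:
                ok = False
                break
        if ok and sd[col] > 0:
            chosen.append(int(col))
    if len(chosen) < n_active:
        raise ValueError("could not find enough well-separated active columns")
    return [block.column_meta[c] for c in chosen]


def generate_series(
    spec: SyntheticSpec,
) -> tuple[list[Molecule], np.ndarray, dict[tuple[str, int], float]]:
    """Generate molecules, activities and the planted effect weights.

    activity_i = intercept + sum_(f,q) w_(f,q) * A_f(q; molecule i)
                 + N(0, noise_sd)

    Planted weights are scaled so the noiseless signal spans
    ``activity_span`` pEC50 units across the series; the same seed always
    reproduces the identical series.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = [_make_molecule(spec, rng, f"synth{i + 1:03d}") for i in range(spec.n_molecules)]
    block = series_block(spec, molecules)

    if spec.effect_weights is None:
        cols = _pick_effect_columns(block, spec.n_active_nodes, rng)
        base = [1.0, -0.7, 0.45, 0.3, -0.2, 0.15]
        weights = {
            key: base[i % len(base)] for i, key in enumerate(cols)
        }
    else:
        weights = dict(spec.effect_weights)

    col_index = {meta: j for j, meta in enumerate(block.column_meta)}
    signal = np.zeros(spec.n_molecules)
    for key, w in weights.items():
        if key not in col_index:
            raise ValueError(f"effect weight {key} is not a column of the series block")
        signal += w * block.matrix[:, col_index[key]]

    span = float(np.ptp(signal))
    if span > 0 and spec.effect_weights is None:
        scale = spec.activity_span / span
        weights = {k: w * scale for k, w in weights.items()}
        signal = signal * scale
    activities = spec.intercept + (signal - signal.mean())
    activities = activities + rng.normal(0.0, spec.noise_sd, spec.n_molecules)
    return molecules, activities, weights


def recovery_score(
    true_weights: Mapping[tuple[str, int], float],
    maps: Mapping[str, ContourMap],
) -> float:
    """Spearman rank correlation between |planted weight| and |map value|.

    Evaluated over the lattice nodes with nonzero planted weight; raises
    when the maps are zero everywhere the truth is nonzero (rank
    undefined).
    """
    truth, got = [], []
    for (field_name, node), w in true_weights.items():
        if w == 0:
            continue
        if field_name not in maps:
            raise ValueError(f"no contour map for field {field_name!r}")
        truth.append(abs(w))
        got.append(abs(float(maps[field_name].values[node])))
    if not truth:
        raise ValueError("no nonzero true weights")
    if all(v == 0 for v in got):
        raise ValueError("contour maps are zero at every true-effect node")
    if len(truth) == 1:
        return 1.0 if got[0] != 0 else 0.0
    rho = spearmanr(truth, got).statistic
    if np.isnan(rho):  # constant vector on either side
        raise ValueError("rank correlation undefined (constant values)")
    return float(rho)


def export_series(
    molecules: Sequence[Molecule],
    activities: np.ndarray,
    out_dir: str | Path,
    basename: str = "synthetic_series",
) -> tuple[Path, Path]:
    """Write the series as an SDF (with PARTIAL_CHARGES) plus activity CSV.

    The files round-trip through :func:`qsar3d.structures.read_structures`
    and :func:`qsar3d.dataset.load_activity_table`, so synthetic and real
    input follow the same path into the pipeline.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sdf_path = out_dir / f"{basename}.sdf"
    csv_path = out_dir / f"{basename}.csv"

    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(False)
    for mol in molecules:
        rw = Chem.RWMol()
        conf = Chem.Conformer(len(mol.atoms))
        for i, atom in enumerate(mol.atoms):
            a = Chem.Atom(atom.element)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
            conf.SetAtomPosition(i, Point3D(*atom.coords))
        rw.AddConformer(conf)
        m = rw.GetMol()
        m.SetProp("_Name", mol.name)
        m.SetProp("PARTIAL_CHARGES", " ".join(f"{a.partial_charge:.4f}" for a in mol.atoms))
        writer.write(m)
    writer.close()

    with open(csv_path, "w") as fh:
        fh.write("id,exp_pec50,role\n")
        for i, act in enumerate(activities):
            fh.write(f"{i + 1},{act:.4f},train\n")
    return sdf_path, csv_path
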