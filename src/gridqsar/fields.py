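"""Grid-based molecular interaction fields.

CoMFA-style steric (Lennard-Jones 6-12) and electrostatic (Coulomb with
distance-dependent dielectric) probe energies, and CoMSIA-style
Gaussian-attenuated similarity indices, evaluated on a shared rectangular
lattice and assembled into a filtered, block-scaled descriptor matrix.

Lattice iteration order is x fastest, then y, then z; this order is recorded
in the column metadata and honoured by the contour exporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .chem_dataset import Molecule, MoleculeSet

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "DescriptorBlock",
    "load_vdw_params",
    "make_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "inside_envelope",
    "comsia_field",
    "comsia_weights",
    "assemble_block",
    "COULOMB_CONSTANT",
    "COMSIA_KINDS",
]

COULOMB_CONSTANT = 332.0  # kcal*A/(mol*e^2)
COMSIA_KINDS = ("S", "E", "H", "D", "A")

_HYDROPHOBIC_ELEMENTS = {"C", "Cl", "Br", "I"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice: ``origin + spacing * (ix, iy, iz)``."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(c < 1 for c in self.counts):
            raise ValueError("grid counts must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(o[d] + self.spacing * np.arange(self.counts[d]) for d in range(3))

    def points(self) -> np.ndarray:
        """All lattice points, flat index running x fastest, then y, then z."""
        ax, ay, az = self.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack(
            [X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")]
        )

    def flat_to_ijk(self, idx: np.ndarray) -> np.ndarray:
        nx, ny, _ = self.counts
        idx = np.asarray(idx)
        return np.column_stack([idx % nx, (idx // nx) % ny, idx // (nx * ny)])

    def to_3d(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat lattice vector to an (nx, ny, nz) array."""
        return np.asarray(flat).reshape(self.counts, order="F")

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "counts": list(self.counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["origin"]), float(d["spacing"]), tuple(d["counts"]))


@dataclass(frozen=True)
class ProbeSpec:
    """CoMFA/CoMSIA probe: sp3 carbon, +1 charge, unit CoMSIA weights."""

    r_star: float = 1.70
    epsilon: float = 0.107
    charge: float = 1.0
    radius: float = 1.0
    hydrophobicity: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0


def load_vdw_params(path: str | Path | None = None) -> dict:
    """Element -> {r_star, epsilon} table plus probe parameters."""
    if path is None:
        path = Path(resources.files("gridqsar.data") / "vdw_params.yaml")
    with open(path) as fh:
        params = yaml.safe_load(fh)
    return params


_DEFAULT_PARAMS = load_vdw_params()


def _element_param(element: str, key: str, params: dict) -> float:
    try:
        return float(params["elements"][element][key])
    except KeyError:
        raise KeyError(f"no van der Waals parameters for element {element!r}") from None


def make_grid(molset: MoleculeSet, spacing: float = 2.0, padding: float = 4.0) -> GridSpec:
    """Lattice enclosing the union bounding box of an aligned set plus padding."""
    if len(molset) == 0:
        raise ValueError("cannot build a grid for an empty molecule set")
    coords = molset.all_coords()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    counts = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), counts=counts)


def _distances(mol: Molecule, grid) -> np.ndarray:
    # field kernels depend on positions only through distances, so they also
    # accept a raw (m, 3) point array in place of a GridSpec
    pts = grid.points() if isinstance(grid, GridSpec) else np.asarray(grid, dtype=float)
    diff = pts[:, None, :] - mol.coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_steric(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    cutoff: float = 30.0,
    params: dict | None = None,
    *,
    clamp: bool = True,
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy at every lattice point (kcal/mol).

    ``E = sum_i eps_ij * ((R_ij/r)^12 - 2 (R_ij/r)^6)`` with additive R*
    and geometric-mean epsilon combination, clamped to ``[-cutoff, +cutoff]``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    params = params or _DEFAULT_PARAMS
    r_star = np.array([_element_param(e, "r_star", params) for e in mol.elements])
    eps = np.array([_element_param(e, "epsilon", params) for e in mol.elements])
    rij = r_star + probe.r_star
    eij = np.sqrt(eps * probe.epsilon)
    r = np.maximum(_distances(mol, grid), 1e-12)
    ratio6 = (rij[None, :] / r) ** 6
    energy = np.sum(eij[None, :] * (ratio6 * ratio6 - 2.0 * ratio6), axis=1)
    if clamp:
        energy = np.clip(energy, -cutoff, cutoff)
    return energy


def comfa_electrostatic(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    cutoff: float = 30.0,
    dielectric: str = "distance",
    *,
    clamp: bool = True,
) -> np.ndarray:
    """Coulomb probe energy at every lattice point (kcal/mol).

    ``E = sum_i 332.0 q_i q_probe / (D(r) r)`` with distance-dependent
    dielectric ``D(r) = r`` (or constant ``D = 1``), clamped to
    ``[-cutoff, +cutoff]``. Zero interatomic distances clamp rather than
    diverge.
    """
    if mol.charges is None:
        raise ValueError(f"molecule {mol.id}: electrostatic field needs partial charges")
    if dielectric not in ("distance", "constant"):
        raise ValueError(f"unknown dielectric model {dielectric!r}")
    r = np.maximum(_distances(mol, grid), 1e-12)
    denom = r * r if dielectric == "distance" else r
    energy = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges[None, :] / denom, axis=1)
    if clamp:
        energy = np.clip(energy, -cutoff, cutoff)
    return energy


def inside_envelope(mol: Molecule, grid: GridSpec, params: dict | None = None) -> np.ndarray:
    """Boolean mask of lattice points inside any atom's van der Waals sphere."""
    params = params or _DEFAULT_PARAMS
    radii = np.array([_element_param(e, "r_star", params) for e in mol.elements])
    r = _distances(mol, grid)
    return np.any(r < radii[None, :], axis=1)


def comsia_weights(mol: Molecule, kind: str, params: dict | None = None) -> np.ndarray:
    """Per-atom weights for a CoMSIA field kind.

    S: vdW radius cubed; E: partial charge; H: 1 for hydrophobic elements
    (C, halogens except F); D: 1 on N/O heavy atoms bearing a hydrogen;
    A: 1 on N/O with an available lone pair. Rule-based typing needs an
    RDKit graph; molecules may instead carry precomputed ``comsia_weights``.
    """
    if kind not in COMSIA_KINDS:
        raise ValueError(f"unknown CoMSIA field kind {kind!r}")
    if mol.comsia_weights is not None and kind in mol.comsia_weights:
        return np.asarray(mol.comsia_weights[kind], dtype=float)
    params = params or _DEFAULT_PARAMS
    if kind == "S":
        radii = np.array([_element_param(e, "r_star", params) for e in mol.elements])
        return radii**3
    if kind == "E":
        if mol.charges is None:
            raise ValueError(f"molecule {mol.id}: CoMSIA E field needs partial charges")
        return np.asarray(mol.charges, dtype=float)
    if kind == "H":
        return np.array([1.0 if e in _HYDROPHOBIC_ELEMENTS else 0.0 for e in mol.elements])
    if mol.rdmol is None:
        raise ValueError(
            f"molecule {mol.id}: donor/acceptor typing needs a chemical graph "
            "or precomputed comsia_weights"
        )
    w = np.zeros(mol.n_atoms)
    for atom in mol.rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _ACCEPTOR_ELEMENTS:
            continue
        if kind == "D":
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                w[atom.GetIdx()] = 1.0
        else:  # A
            if atom.GetFormalCharge() <= 0 and atom.GetTotalValence() <= 3:
                w[atom.GetIdx()] = 1.0
    return w


def comsia_field(
    mol: Molecule,
    grid: GridSpec,
    kind: str,
    alpha: float = 0.3,
    probe: ProbeSpec = ProbeSpec(),
    params: dict | None = None,
) -> np.ndarray:
    """Gaussian-attenuated similarity index at every lattice point.

    ``value(q) = -sum_i w_probe * w_i * exp(-alpha * r_iq^2)`` — the negated
    similarity convention, so attractive similarity contributions are <= 0
    for positive atom weights. Singularity-free everywhere.
    """
    w = comsia_weights(mol, kind, params)
    w_probe = {
        "S": probe.radius**3,
        "E": probe.charge,
        "H": probe.hydrophobicity,
        "D": probe.donor,
        "A": probe.acceptor,
    }[kind]
    r = _distances(mol, grid)
    return -w_probe * np.sum(w[None, :] * np.exp(-alpha * r * r), axis=1)


@dataclass
class DescriptorBlock:
    """Compound x (lattice point, field kind) descriptor matrix.

    ``X`` holds the retained, scaled columns; ``kept`` flags which raw
    columns survived the minimum-sigma filter. ``field_kinds``/``lattice_idx``
    describe the retained columns.
    """

    X: np.ndarray
    compound_ids: list[str]
    field_kinds: np.ndarray  # (n_cols,) str
    lattice_idx: np.ndarray  # (n_cols,) int, x-fastest flat index
    kept: np.ndarray  # (n_raw_cols,) bool
    grid: GridSpec
    fields: tuple[str, ...]
    scales: dict[str, float] = field(default_factory=dict)
    min_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("descriptor block contains non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column_sd(self, ddof: int = 1) -> np.ndarray:
        return self.X.std(axis=0, ddof=ddof)

    def columns_for(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.field_kinds == kind)


def _raw_field_matrix(
    molset: MoleculeSet,
    grid: GridSpec,
    spec: str,
    cutoff: float,
    alpha: float,
    dielectric: str,
    es_inside: str,
    probe: ProbeSpec,
    params: dict | None,
) -> np.ndarray:
    rows = []
    if spec == "comfa_S":
        for mol in molset:
            rows.append(comfa_steric(mol, grid, probe, cutoff, params))
        return np.vstack(rows)
    if spec == "comfa_E":
        masks = []
        for mol in molset:
            rows.append(comfa_electrostatic(mol, grid, probe, cutoff, dielectric))
            masks.append(inside_envelope(mol, grid, params))
        M = np.vstack(rows)
        if es_inside == "mean":
            # SYBYL-style: replace values inside the vdW envelope by the
            # column mean of the outside values
            inside = np.vstack(masks)
            with np.errstate(invalid="ignore"):
                outside_mean = np.where(
                    (~inside).sum(axis=0) > 0,
                    np.nansum(np.where(inside, np.nan, M), axis=0)
                    / np.maximum((~inside).sum(axis=0), 1),
                    0.0,
                )
            M = np.where(inside, outside_mean[None, :], M)
        elif es_inside != "clamp":
            raise ValueError(f"unknown in-sphere handling {es_inside!r}")
        return M
    if spec.startswith("comsia_"):
        kind = spec.split("_", 1)[1]
        for mol in molset:
            rows.append(comsia_field(mol, grid, kind, alpha, probe, params))
        return np.vstack(rows)
    raise ValueError(f"unknown field spec {spec!r}")


def assemble_block(
    molset: MoleculeSet,
    grid: GridSpec | None = None,
    fields: tuple[str, ...] = ("comfa_S", "comfa_E"),
    min_sigma: float = 2.0,
    scaling: str = "comfa_std",
    *,
    cutoff: float = 30.0,
    alpha: float = 0.3,
    dielectric: str = "distance",
    es_inside: str = "mean",
    probe: ProbeSpec = ProbeSpec(),
    params: dict | None = None,
    spacing: float = 2.0,
    padding: float = 4.0,
) -> DescriptorBlock:
    """Compute, filter and scale the descriptor block for an aligned set.

    Field specs: ``comfa_S``, ``comfa_E``, ``comsia_S|E|H|D|A``. Columns with
    standard deviation below ``min_sigma`` are dropped; ``comfa_std`` scaling
    then rescales each field kind to equal total column variance.
    """
    if grid is None:
        grid = make_grid(molset, spacing=spacing, padding=padding)
    n_pts = grid.n_points
    blocks, kinds, lidx = [], [], []
    for spec in fields:
        M = _raw_field_matrix(
            molset, grid, spec, cutoff, alpha, dielectric, es_inside, probe, params
        )
        blocks.append(M)
        kinds.append(np.full(n_pts, spec))
        lidx.append(np.arange(n_pts))
    X = np.hstack(blocks)
    field_kinds = np.concatenate(kinds)
    lattice_idx = np.concatenate(lidx)

    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    kept = sd >= min_sigma if min_sigma > 0 else np.ones(X.shape[1], bool)
    if not kept.any():
        raise ValueError(
            f"minimum-sigma filter ({min_sigma}) dropped every column; lower min_sigma"
        )
    X = X[:, kept]
    field_kinds = field_kinds[kept]
    lattice_idx = lattice_idx[kept]

    scales: dict[str, float] = {}
    if scaling == "comfa_std":
        for spec in fields:
            cols = field_kinds == spec
            if not cols.any():
                continue
            total_var = float(np.sum(X[:, cols].var(axis=0, ddof=1)))
            s = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
            X[:, cols] *= s
            scales[spec] = s
    elif scaling != "none":
        raise ValueError(f"unknown scaling mode {scaling!r}")

    return DescriptorBlock(
        X=X,
        compound_ids=list(molset.ids),
        field_kinds=field_kinds,
        lattice_idx=lattice_idx,
        kept=kept,
        grid=grid,
        fields=tuple(fields),
        scales=scales,
        min_sigma=min_sigma,
    )
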