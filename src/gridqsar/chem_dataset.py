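"""Molecule sets, activity tables and the packaged 71-compound thiourea series.

Molecules are lightweight records (elements, coordinates, partial charges)
optionally backed by an RDKit ``Mol`` when built from a chemical file format
or SMILES. Structure-free pseudo-molecules (see :mod:`gridqsar.synthetic_data`)
use the same type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Molecule",
    "MoleculeSet",
    "SeriesDefinition",
    "load_molecules",
    "write_sdf",
    "assign_charges",
    "build_thiourea_series",
    "split_dataset",
    "load_packaged_series",
    "load_packaged_activity",
    "load_activity_table",
    "pic50_from_ic50",
]

_EMBED_SEED = 20120608  # fixed: keeps 3D embedding deterministic
_CHARGE_TOL = 1e-3

# Common substructure of the packaged series: thiourea linker + aminopyrazine.
# Reconstructed, configurable — see the alignment CLI options.
SCAFFOLD_SMARTS = "Nc1nccnc1NC(=S)N"


@dataclass
class Molecule:
    """An identified set of atoms with coordinates and optional charges."""

    id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) in Angstrom
    charges: np.ndarray | None = None  # elementary charge units
    rdmol: Chem.Mol | None = None
    scaffold_atom_map: dict[int, int] | None = None
    comsia_weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(f"molecule {self.id}: element/coordinate length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id}: non-finite coordinates")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if not np.all(np.isfinite(self.charges)):
                raise ValueError(f"molecule {self.id}: non-finite partial charges")
        if self.scaffold_atom_map is not None:
            n = len(self.coords)
            for pos, idx in self.scaffold_atom_map.items():
                if not 0 <= idx < n:
                    raise ValueError(
                        f"molecule {self.id}: scaffold map entry {pos}->{idx} out of range"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.rdmol) if self.rdmol is not None else 0

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of this molecule with replaced coordinates (rdmol conformer updated)."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        rdmol = self.rdmol
        if rdmol is not None and rdmol.GetNumConformers():
            rdmol = Chem.Mol(rdmol)
            conf = rdmol.GetConformer()
            for i, xyz in enumerate(coords):
                conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        return replace(self, coords=coords, rdmol=rdmol)


def _from_rdkit(mol: Chem.Mol, mol_id: str) -> Molecule:
    if mol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol_id} has no 3D conformer")
    coords = mol.GetConformer().GetPositions()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = None
    if all(a.HasProp("_GasteigerCharge") for a in mol.GetAtoms()):
        charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    return Molecule(id=mol_id, elements=elements, coords=coords, charges=charges, rdmol=mol)


class MoleculeSet:
    """Ordered collection of molecules with unique ids."""

    def __init__(self, molecules: Sequence[Molecule] = ()):
        self.molecules: list[Molecule] = list(molecules)
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in set")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, key: int | str) -> Molecule:
        if isinstance(key, str):
            for m in self.molecules:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.molecules[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def all_coords(self) -> np.ndarray:
        return np.vstack([m.coords for m in self.molecules])


@dataclass
class SeriesDefinition:
    """Scaffold templates + R-group lookup + compound rows for a congeneric series.

    Scaffold templates are SMILES strings with ``{rp}``/``{rn}`` placeholders
    that substituent SMILES fragments are spliced into (fragments in the two
    namespaces use disjoint ring-closure digits so splicing is safe).
    """

    scaffolds: dict[str, str]
    rgroups: dict[tuple[str, str], str]  # (position, name) -> SMILES fragment
    compounds: list[dict] = field(default_factory=list)

    def smiles_for(self, row: dict) -> str:
        template = self.scaffolds[row["scaffold"]]
        out = template
        for pos in ("rp", "rn"):
            if "{%s}" % pos in out:
                key = (pos, row[pos])
                if key not in self.rgroups:
                    raise KeyError(
                        f"compound {row['compound_id']}: unresolved R-group "
                        f"{row[pos]!r} at position {pos}"
                    )
                out = out.replace("{%s}" % pos, self.rgroups[key])
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _embed_3d(mol: Chem.Mol, mol_id: str) -> Chem.Mol:
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        # retry with random coords before giving up
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(f"molecule {mol_id}: no embeddable 3D conformer")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    return mol


def load_molecules(path: str | Path, format: str = "sdf") -> MoleculeSet:
    """Read molecules from ``sdf`` | ``mol2`` | ``smiles`` files.

    SMILES input (one record per line, optional id after whitespace) is
    embedded to 3D and force-field minimized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mols: list[Molecule] = []
    if format == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        except OSError as exc:  # RDKit rejects empty/invalid files at open time
            raise ValueError(f"no records found in {path}: {exc}") from None
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparseable SDF record at index {i} in {path}")
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            mols.append(_from_rdkit(mol, mol_id))
    elif format == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, removeHs=False)
            if mol is None:
                raise ValueError(f"unparseable MOL2 record at index {i} in {path}")
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i}"
            mols.append(_from_rdkit(mol, mol_id))
    elif format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise ValueError(f"unparseable SMILES record at index {i} in {path}")
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol_{i}"
            mols.append(_from_rdkit(_embed_3d(mol, mol_id), mol_id))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not mols:
        raise ValueError(f"no records found in {path}")
    return MoleculeSet(mols)


def _bondless_rdmol(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for el in mol.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    conf = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    out = rw.GetMol()
    out.AddConformer(conf)
    out.SetProp("_Name", mol.id)
    return out


def write_sdf(molset: MoleculeSet, path: str | Path) -> None:
    """Write a molecule set as SDF (V2000). Bond-less records are written
    with zero bonds (synthetic pseudo-molecules)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molset:
            rdmol = mol.rdmol if mol.rdmol is not None else _bondless_rdmol(mol)
            rdmol.SetProp("_Name", mol.id)
            if mol.charges is not None:
                rdmol.SetProp("partial_charges", " ".join(f"{q:.6f}" for q in mol.charges))
            writer.write(rdmol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# charges


def assign_charges(mol: Molecule, method: str = "gasteiger") -> Molecule:
    """Assign Gasteiger partial charges (iterative partial equalization).

    Requires an RDKit-backed, valence-complete molecule with explicit
    hydrogens. Charges sum to the formal charge within 1e-3.
    """
    if method != "gasteiger":
        raise ValueError(f"unsupported charge method {method!r}")
    if mol.rdmol is None:
        raise ValueError(f"molecule {mol.id}: charge assignment needs a chemical graph")
    rdmol = Chem.Mol(mol.rdmol)
    for atom in rdmol.GetAtoms():
        if atom.GetNumRadicalElectrons():
            raise ValueError(
                f"molecule {mol.id}: radical atom index {atom.GetIdx()} "
                f"({atom.GetSymbol()}) unsupported"
            )
    AllChem.ComputeGasteigerCharges(rdmol, throwOnParamFailure=True)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        bad = int(np.flatnonzero(~np.isfinite(charges))[0])
        raise ValueError(f"molecule {mol.id}: non-finite charge at atom {bad}")
    total = Chem.GetFormalCharge(rdmol)
    if abs(charges.sum() - total) > _CHARGE_TOL:
        raise ValueError(
            f"molecule {mol.id}: charges sum {charges.sum():.4f} != formal charge {total}"
        )
    return replace(mol, charges=charges, rdmol=rdmol)


# ---------------------------------------------------------------------------
# packaged series


def _data_path(name: str) -> Path:
    return Path(resources.files("gridqsar.data") / name)


def load_packaged_series() -> SeriesDefinition:
    defn = SeriesDefinition(scaffolds={}, rgroups={})
    with open(_data_path("thiourea_series.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            kind = row["record"]
            if kind == "scaffold":
                defn.scaffolds[row["f1"]] = row["f2"]
            elif kind == "rgroup":
                defn.rgroups[(row["f2"], row["f1"])] = row["f3"]
            elif kind == "compound":
                defn.compounds.append(
                    {"compound_id": row["f1"], "scaffold": row["f2"],
                     "rp": row["f3"], "rn": row["f4"]}
                )
    return defn


def load_activity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "pIC50", "set_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["pIC50"])):
        raise ValueError("non-finite pIC50 values")
    return df


def load_packaged_activity() -> pd.DataFrame:
    """The packaged experimental/predicted activity table (71 rows, 53+18 split)."""
    return load_activity_table(_data_path("thiourea_activity.csv"))


def pic50_from_ic50(ic50_molar: float) -> float:
    """pIC50 = -log10 of the molar IC50."""
    if ic50_molar <= 0:
        raise ValueError("IC50 must be positive")
    return -float(np.log10(ic50_molar))


def build_thiourea_series(
    defn: SeriesDefinition | None = None,
    *,
    embed: bool = True,
    charges: bool = True,
) -> tuple[MoleculeSet, pd.DataFrame]:
    """Build the packaged 71-compound thiourea series and its activity table.

    With ``embed=False`` molecules carry a chemical graph but no 3D
    coordinates (cheap; sufficient for substructure work).
    """
    if defn is None:
        defn = load_packaged_series()
    activity = load_packaged_activity()
    mols: list[Molecule] = []
    for row in defn.compounds:
        smi = defn.smiles_for(row)
        rdmol = Chem.MolFromSmiles(smi)
        if rdmol is None:
            raise ValueError(f"compound {row['compound_id']}: invalid assembled SMILES {smi!r}")
        mol_id = row["compound_id"]
        if embed:
            rdmol = _embed_3d(rdmol, mol_id)
            mol = _from_rdkit(rdmol, mol_id)
            if charges:
                mol = assign_charges(mol)
        else:
            rdmol = Chem.AddHs(rdmol)
            rdmol.SetProp("_Name", mol_id)
            mol = Molecule(
                id=mol_id,
                elements=[a.GetSymbol() for a in rdmol.GetAtoms()],
                coords=np.zeros((rdmol.GetNumAtoms(), 3)),
                rdmol=rdmol,
            )
        mols.append(mol)
    molset = MoleculeSet(mols)
    if set(molset.ids) != set(activity["compound_id"]):
        raise ValueError("series definition and activity table disagree on compound ids")
    return molset, activity


# ---------------------------------------------------------------------------
# train/test splitting


def split_dataset(
    activity: pd.DataFrame,
    mode: str = "printed",
    seed: int | None = None,
    *,
    test_fraction: float | None = None,
    descriptors: np.ndarray | None = None,
) -> tuple[list[str], list[str]]:
    """Partition compounds into (train ids, test ids).

    ``printed`` returns the packaged split from the ``set_label`` column.
    ``rational`` spreads test compounds over the first two principal
    components of a supplied descriptor matrix using max-min selection;
    duplicated descriptor rows are never split across sets (ties broken by
    ascending compound id).
    """
    ids = [str(i) for i in activity["compound_id"]]
    if mode == "printed":
        if "set_label" not in activity.columns or activity["set_label"].isna().any():
            raise ValueError("printed mode requires a complete set_label column")
        train = [i for i, s in zip(ids, activity["set_label"]) if s == "train"]
        test = [i for i, s in zip(ids, activity["set_label"]) if s == "test"]
        if sorted(train + test) != sorted(ids):
            raise ValueError("set_label column contains labels other than train/test")
        return train, test
    if mode != "rational":
        raise ValueError(f"unknown split mode {mode!r}")
    if descriptors is None:
        raise ValueError("rational mode requires a descriptor matrix")
    X = np.asarray(descriptors, dtype=float)
    if len(X) != len(ids) or len(ids) < 2:
        raise ValueError("descriptor matrix must have one row per compound (>=2)")
    frac = test_fraction if test_fraction is not None else 18 / 71
    n_test = int(round(frac * len(ids)))
    if n_test == 0:
        return list(ids), []

    # project onto the first two principal components
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xc = Xc[:, sd > 0] / sd[sd > 0]
    if Xc.shape[1] == 0:
        scores = np.zeros((len(ids), 2))
    else:
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[: min(2, vt.shape[0])].T
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(ids))])

    # group duplicate descriptor rows so they land in the same set
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    groups: dict[bytes, list[int]] = {}
    for i in order:
        groups.setdefault(np.round(X[i], 12).tobytes(), []).append(i)
    reps = sorted(groups.values(), key=lambda g: ids[g[0]])

    # max-min spread over PC space, seeded start at the point farthest from center
    centroid = scores.mean(axis=0)
    d0 = np.linalg.norm(scores[[g[0] for g in reps]] - centroid, axis=1)
    chosen: list[int] = []
    test_idx: list[int] = []
    remaining = list(range(len(reps)))
    first = max(remaining, key=lambda g: (d0[g], [-ord(c) for c in ids[reps[g][0]]]))
    while remaining and len(test_idx) < n_test:
        if not chosen:
            pick = first
        else:
            def score(g: int) -> float:
                return min(
                    float(np.linalg.norm(scores[reps[g][0]] - scores[reps[c][0]]))
                    for c in chosen
                )
            pick = max(remaining, key=lambda g: (score(g), [-ord(c) for c in ids[reps[g][0]]]))
        chosen.append(pick)
        remaining.remove(pick)
        test_idx.extend(reps[pick])
    test_ids = sorted((ids[i] for i in test_idx), key=lambda s: (len(s), s))
    train_ids = [i for i in ids if i not in set(test_ids)]
    return train_ids, test_ids
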