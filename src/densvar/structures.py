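"""Atomic-model data types, PDB I/O, superposition and RMSD."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

# Electron counts for elements that occur in protein models.
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
    "SE": 34, "BR": 35, "I": 53,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ModelMismatchError(ValueError):
    """Two conformers do not share the same atom identities/ordering."""


@dataclass
class Atom:
    """One atom of a coordinate model.

    Coordinates in Å, ``b_iso`` in Å² (B = 8π²⟨u²⟩), ``occupancy`` in [0, 1].
    """

    element: str
    name: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 30.0
    residue_index: int = 1
    residue_name: str = "ALA"
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso <= 0:
            raise ValueError(f"b_iso must be positive, got {self.b_iso}")
        if self.element.upper() not in ELECTRON_COUNTS:
            raise ValueError(f"element {self.element!r} has no defined electron count")

    @property
    def electron_count(self) -> int:
        return ELECTRON_COUNTS[self.element.upper()]

    @property
    def key(self) -> tuple:
        """Identity used to match atoms across ensemble members."""
        return (self.chain_id, self.residue_index, self.name)


@dataclass
class Conformer:
    """An ordered atomic model; the unit of ensemble membership."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a Conformer needs at least one atom")
        # residue indices must be nondecreasing within each chain
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise ValueError(
                    f"residue_index decreases along chain {a.chain_id!r} "
                    f"({prev} -> {a.residue_index})"
                )
            last[a.chain_id] = a.residue_index

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def keys(self) -> list[tuple]:
        return [a.key for a in self.atoms]

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Conformer":
        """Copy of this conformer with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = []
        for a, xyz in zip(self.atoms, coords):
            b = copy.copy(a)
            b.position = np.array(xyz, dtype=float)
            atoms.append(b)
        return Conformer(atoms, label if label is not None else self.label)

    def translated(self, shift: np.ndarray, label: str | None = None) -> "Conformer":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float), label)

    def select(self, names: tuple[str, ...] | None) -> np.ndarray:
        """Boolean mask of atoms whose name is in ``names`` (None = all)."""
        if names is None:
            return np.ones(len(self.atoms), dtype=bool)
        nameset = set(names)
        return np.array([a.name in nameset for a in self.atoms], dtype=bool)


@dataclass
class Ensemble:
    """A base conformer plus members sharing its atom identities and order.

    ``truth_labels`` (fixture-only) tags each member "noise" or "variable".
    """

    members: list[Conformer]
    base: Conformer
    truth_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        base_keys = self.base.keys
        for m in self.members:
            if m.keys != base_keys:
                raise ModelMismatchError(
                    f"member {m.label!r} does not match the base model's atom "
                    "identities/ordering (chain, residue_index, atom name)"
                )
        if self.truth_labels is not None and len(self.truth_labels) != len(self.members):
            raise ValueError("truth_labels length must equal number of members")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column wwPDB v3.3 via biotite)
# ---------------------------------------------------------------------------

def _conformer_from_atom_array(arr: struc.AtomArray, label: str) -> Conformer:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        if not element:
            # infer from the first letter of the atom name (protein atoms)
            element = str(arr.atom_name[i]).strip()[0]
        atoms.append(
            Atom(
                element=element,
                name=str(arr.atom_name[i]).strip(),
                position=np.array(arr.coord[i], dtype=float),
                occupancy=float(arr.occupancy[i]),
                b_iso=float(arr.b_factor[i]),
                residue_index=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]).strip(),
                chain_id=str(arr.chain_id[i]).strip() or "A",
            )
        )
    return Conformer(atoms, label=label)


def read_pdb(path: str | Path, model: int | None = None) -> Conformer:
    """Read a single-conformation PDB file into a :class:`Conformer`.

    Parameters
    ----------
    path : file path
    model : which MODEL to read from a multi-model file. ``None`` (default)
        raises on multi-model input; pass ``1`` to take the first model.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, zero atoms, multi-model input without ``model``, or
        alternate-location records with partial occupancy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = pdb_io.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    if n_models > 1 and model is None:
        raise ValueError(
            f"{path}: {n_models} MODELs present; pass model=1 to take the first"
        )
    arr = pdb_file.get_structure(
        model=model or 1, altloc="all", extra_fields=["occupancy", "b_factor"]
    )
    if arr.array_length() == 0:
        raise ValueError(f"{path}: zero atoms parsed")
    altloc = getattr(arr, "altloc_id", None)
    if altloc is not None:
        has_alt = np.array([str(a).strip() not in ("", ".") for a in altloc])
        if np.any(has_alt & (arr.occupancy < 1.0)):
            raise ValueError(
                f"{path}: alternate locations with occupancy < 1 are not "
                "supported; supply a single-conformation model"
            )
    return _conformer_from_atom_array(arr, label=path.stem)


def write_pdb(c: Conformer, path: str | Path) -> None:
    """Write ``c`` as fixed-column PDB (coords %.3f, occupancy/B %.2f).

    Atom names longer than 4 characters are rejected (no silent truncation).
    """
    for a in c.atoms:
        if len(a.name) > 4:
            raise ValueError(f"atom name {a.name!r} exceeds the 4-character PDB field")
    n = len(c.atoms)
    arr = struc.AtomArray(n)
    arr.coord = c.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in c.atoms])
    arr.res_id = np.array([a.residue_index for a in c.atoms])
    arr.res_name = np.array([a.residue_name for a in c.atoms])
    arr.atom_name = np.array([a.name for a in c.atoms])
    arr.element = np.array([a.element.upper() for a in c.atoms])
    arr.set_annotation("occupancy", np.array([a.occupancy for a in c.atoms]))
    arr.set_annotation("b_factor", np.array([a.b_iso for a in c.atoms]))
    arr.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _matched_coords(
    a: Conformer, b: Conformer, selection: tuple[str, ...] | None
) -> tuple[np.ndarray, np.ndarray]:
    mask_a = a.select(selection)
    mask_b = b.select(selection)
    keys_a = [k for k, m in zip(a.keys, mask_a) if m]
    keys_b = [k for k, m in zip(b.keys, mask_b) if m]
    if keys_a != keys_b:
        raise ModelMismatchError("selections do not match between the two conformers")
    if len(keys_a) == 0:
        raise ValueError("empty atom selection")
    return a.coords[mask_a], b.coords[mask_b]


def superpose(
    a: Conformer, b: Conformer, selection: tuple[str, ...] | None = BACKBONE_ATOMS
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) superposition of ``b`` onto ``a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x_b + translation ≈ x_a`` minimizes the RMSD over the
    selected atoms. The rotation is proper (det = +1).
    """
    xa, xb = _matched_coords(a, b, selection)
    if len(xa) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    # scipy's align_vectors solves the constrained (proper-rotation) Procrustes
    # problem; recompute the residual explicitly (its rssd loses precision to
    # cancellation near zero).
    from scipy.spatial.transform import Rotation

    rot, _ = Rotation.align_vectors(xa - ca, xb - cb)
    rotation = rot.as_matrix()
    translation = ca - rotation @ cb
    resid = xa - (xb @ rotation.T + translation)
    rmsd_val = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rotation, translation, rmsd_val


def rmsd(
    a: Conformer,
    b: Conformer,
    selection: tuple[str, ...] | None = BACKBONE_ATOMS,
    fit: bool = True,
) -> float:
    """RMSD between matched conformers, optionally after best-fit superposition."""
    if fit:
        return superpose(a, b, selection)[2]
    xa, xb = _matched_coords(a, b, selection)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
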