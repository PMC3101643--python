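"""Baseline comparators: per-residue RMSD, normalized RMSD, B-factor profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from densvar.structures import BACKBONE_ATOMS, Conformer, rmsd, superpose


@dataclass
class ResidueProfile:
    """One nonnegative value per residue, tagged with what it measures."""

    residues: np.ndarray
    values: np.ndarray
    kind: str  # "rmsd" (Å) | "bfactor" (Å²) | "normalized_rmsd"

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residues) != len(self.values):
            raise ValueError("residues and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("profile values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "value": self.values, "kind": self.kind}
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["value"] = df["value"].map(lambda v: float(f"{v:.6g}"))
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResidueProfile":
        df = pd.read_csv(path)
        return cls(df["residue"].to_numpy(), df["value"].to_numpy(), str(df["kind"].iloc[0]))


def residue_rmsd_profile(
    base: Conformer, member: Conformer, fit: bool = True
) -> ResidueProfile:
    """Per-residue backbone RMSD after one optional global superposition."""
    if base.keys != member.keys:
        raise ValueError("base and member must share atom identities and order")
    coords_m = member.coords
    if fit:
        rotation, translation, _ = superpose(base, member, BACKBONE_ATOMS)
        coords_m = coords_m @ rotation.T + translation
    coords_b = base.coords
    mask = base.select(BACKBONE_ATOMS)
    ridx = base.residue_indices
    residues = np.unique(ridx)
    values = []
    for r in residues:
        sel = mask & (ridx == r)
        d2 = np.sum((coords_b[sel] - coords_m[sel]) ** 2, axis=1)
        values.append(np.sqrt(d2.mean()))
    return ResidueProfile(residues, np.array(values), kind="rmsd")


def normalized_rmsd(
    member: Conformer, base: Conformer, reference_alt: Conformer
) -> float:
    """Best-fit RMSD to the base, scaled by the alternate's RMSD to the base.

    Values near 1 indicate the member sits near the alternate conformation;
    values near 0, near the base.
    """
    denom = rmsd(reference_alt, base, fit=True)
    if denom <= 1e-8:
        raise ValueError("reference alternate coincides with the base (zero denominator)")
    return rmsd(member, base, fit=True) / denom


def bfactor_profile(c: Conformer) -> ResidueProfile:
    """Per-residue mean of atomic isotropic B-factors."""
    ridx = c.residue_indices
    b = np.array([a.b_iso for a in c.atoms])
    residues = np.unique(ridx)
    values = np.array([b[ridx == r].mean() for r in residues])
    return ResidueProfile(residues, values, kind="bfactor")
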