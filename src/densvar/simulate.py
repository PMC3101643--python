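"""Synthetic fixtures: toy proteins, two-conformer crystals, labeled ensembles.

This is the desk-scale stand-in for the full ensemble-generation pipeline
(backbone neighborhood sampling, side-chain building, refinement): a seeded
Cartesian sampler with bond-length regularization, a simulated crystal whose
structure factors average two conformers, and ensembles with known truth
labels for validating the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from densvar.structures import (
    Atom,
    Conformer,
    Ensemble,
    ModelMismatchError,
    rmsd,
    write_pdb,
)
from densvar.density import (
    UnitCell,
    DensityGrid,
    ReflectionSet,
    auto_cell,
    density_map,
    grid_shape_for,
    map_from_reflections,
    mix_structure_factors,
    r_factors,
    structure_factors,
    write_reflections_csv,
)

# Ideal backbone geometry (Engh-Huber-style values), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
DIHEDRAL_CB = -122.6  # improper C-N-CA-CB for L-amino acids
OMEGA_TRANS = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Seeded isotropic Gaussian coordinate noise (per-axis σ, Å)."""

    sigma_cart: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cart < 0:
            raise ValueError("sigma_cart must be nonnegative")


@dataclass
class CrystalFixture:
    """A simulated two-conformer crystal.

    ``base`` and ``alternate`` are translated into the cell frame; the mixed
    reflections are the weighted complex average of their structure factors
    and ``mixed_map`` is the Fourier synthesis of that average.
    """

    base: Conformer
    alternate: Conformer
    mixed_reflections: ReflectionSet
    mixed_map: DensityGrid
    cell: UnitCell
    d_min: float
    spacing: float
    weights: tuple[float, float] = (0.5, 0.5)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position a fourth atom from three reference atoms (internal coords)."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_toy_protein(
    n_residues: int,
    geometry: str = "helix",
    seed: int = 0,
    b_iso: float = 30.0,
    chain_id: str = "A",
) -> Conformer:
    """Ideal-geometry poly-alanine backbone (N, CA, C, O, CB per residue).

    ``geometry`` is "helix", "strand", or "coil" (seeded dihedral draw).
    All occupancies are 1 and all B-factors default to 30 Å².
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry not in ("helix", "strand", "coil"):
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    if geometry == "coil":
        phis = rng.uniform(-150.0, -60.0, size=n_residues)
        psis = rng.uniform(-60.0, 150.0, size=n_residues)
    else:
        phi0, psi0 = PHI_PSI[geometry]
        phis = np.full(n_residues, phi0)
        psis = np.full(n_residues, psi0)

    n_pos: list[np.ndarray] = []
    ca_pos: list[np.ndarray] = []
    c_pos: list[np.ndarray] = []
    o_pos: list[np.ndarray] = []
    cb_pos: list[np.ndarray] = []

    # First residue laid down explicitly.
    n_pos.append(np.zeros(3))
    ca_pos.append(np.array([BOND_N_CA, 0.0, 0.0]))
    ang = np.radians(ANGLE_N_CA_C)
    c_pos.append(ca_pos[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))

    for i in range(1, n_residues):
        n_i = _place_atom(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_pos[i - 1], c_pos[i - 1], n_i,
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = _place_atom(c_pos[i - 1], n_i, ca_i,
                          BOND_CA_C, ANGLE_N_CA_C, phis[i])
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    for i in range(n_residues):
        # carbonyl O is anti to the next N (dihedral ψ + 180)
        o_pos.append(_place_atom(n_pos[i], ca_pos[i], c_pos[i],
                                 BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0))
        cb_pos.append(_place_atom(c_pos[i], n_pos[i], ca_pos[i],
                                  BOND_CA_CB, ANGLE_N_CA_CB, DIHEDRAL_CB))

    atoms: list[Atom] = []
    for i in range(n_residues):
        for name, elem, pos in (
            ("N", "N", n_pos[i]),
            ("CA", "C", ca_pos[i]),
            ("C", "C", c_pos[i]),
            ("O", "O", o_pos[i]),
            ("CB", "C", cb_pos[i]),
        ):
            atoms.append(
                Atom(element=elem, name=name, position=pos, occupancy=1.0,
                     b_iso=b_iso, residue_index=i + 1, residue_name="ALA",
                     chain_id=chain_id)
            )
    return Conformer(atoms, label=f"toy_{geometry}_{n_residues}")


def _bond_pairs(c: Conformer) -> list[tuple[int, int]]:
    """Covalent bond index pairs for the toy backbone topology."""
    index = {a.key: i for i, a in enumerate(c.atoms)}
    pairs: list[tuple[int, int]] = []
    residues = sorted({(a.chain_id, a.residue_index) for a in c.atoms})
    for chain, res in residues:
        def at(name: str, r: int = res):
            return index.get((chain, r, name))
        for x, y in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
            i, j = at(x), at(y)
            if i is not None and j is not None:
                pairs.append((i, j))
        i, j = at("C"), index.get((chain, res + 1, "N"))
        if i is not None and j is not None:
            pairs.append((i, j))
    return pairs


def _regularize_bonds(
    coords: np.ndarray, pairs: list[tuple[int, int]], targets: np.ndarray,
    n_iter: int = 60,
) -> np.ndarray:
    """Gauss-Seidel projection of bond lengths toward their targets."""
    out = coords.copy()
    for _ in range(n_iter):
        worst = 0.0
        for (i, j), L in zip(pairs, targets):
            d = out[j] - out[i]
            dist = np.linalg.norm(d)
            if dist < 1e-12:
                continue
            err = (dist - L) / dist
            worst = max(worst, abs(dist - L) / L)
            shift = 0.5 * err * d
            out[i] += shift
            out[j] -= shift
        if worst < 1e-3:
            break
    return out


def perturb_conformer(c: Conformer, noise: NoiseModel) -> Conformer:
    """Displace every coordinate by independent N(0, sigma_cart²)."""
    rng = np.random.default_rng(noise.seed)
    return _perturb_with_rng(c, noise.sigma_cart, rng)


def _perturb_with_rng(c: Conformer, sigma: float, rng: np.random.Generator) -> Conformer:
    disp = rng.normal(0.0, sigma, size=(len(c), 3)) if sigma > 0 else np.zeros((len(c), 3))
    return c.with_coords(c.coords + disp)


def sample_neighborhood(
    base: Conformer,
    rmsd_range: tuple[float, float],
    n: int,
    seed: int = 0,
    max_attempts: int = 50,
) -> list[Conformer]:
    """Sample conformers with best-fit backbone RMSD to ``base`` in a range.

    Seeded Cartesian perturbation, iterative bond-length regularization,
    and displacement rescaling to land inside ``rmsd_range`` (upper bound
    capped at 2 Å). Bond lengths stay within 10% of the base model's.
    """
    lo, hi = rmsd_range
    if not (0 <= lo < hi <= 2.0):
        raise ValueError("rmsd_range must satisfy 0 <= lo < hi <= 2")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    pairs = _bond_pairs(base)
    base_coords = base.coords
    targets = np.array([np.linalg.norm(base_coords[j] - base_coords[i]) for i, j in pairs])
    out: list[Conformer] = []
    for k in range(n):
        target = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
        ok = False
        for _ in range(max_attempts):
            coords = base_coords + rng.normal(0.0, target / np.sqrt(3.0), size=base_coords.shape)
            for _ in range(8):
                coords = _regularize_bonds(coords, pairs, targets)
                cand = base.with_coords(coords, label=f"sample_{k}")
                r = rmsd(base, cand, fit=True)
                if r < 1e-6:
                    break
                coords = base_coords + (coords - base_coords) * (target / r)
            cand = base.with_coords(_regularize_bonds(coords, pairs, targets),
                                    label=f"sample_{k}")
            r = rmsd(base, cand, fit=True)
            lengths = np.array(
                [np.linalg.norm(cand.coords[j] - cand.coords[i]) for i, j in pairs]
            )
            if lo <= r <= hi and np.all(np.abs(lengths - targets) <= 0.1 * targets):
                out.append(cand)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not reach RMSD range {rmsd_range} after {max_attempts} attempts"
            )
    return out


def assign_free_flags(
    r: ReflectionSet, fraction: float = 0.1, seed: int = 0
) -> ReflectionSet:
    """Flag a seeded uniform fraction of reflections as the free set."""
    rng = np.random.default_rng(seed)
    free = rng.random(len(r)) < fraction
    free[np.all(r.hkl == 0, axis=1)] = False
    return ReflectionSet(hkl=r.hkl.copy(), f=r.f.copy(), d_min=r.d_min, free_flag=free)


def make_two_conformer_crystal(
    base: Conformer,
    alternate: Conformer,
    d_min: float = 2.0,
    weights: tuple[float, float] = (0.5, 0.5),
    padding: float = 10.0,
    spacing: float | None = None,
    free_fraction: float = 0.1,
    seed: int = 0,
) -> CrystalFixture:
    """Simulate a crystal whose diffraction averages two conformations.

    Per-conformer structure factors to ``d_min`` are complex-averaged by
    ``weights``; the mixed map is their Fourier synthesis. Both conformers
    are translated into an auto-sized orthorhombic P1 cell.
    """
    if base.keys != alternate.keys:
        raise ModelMismatchError("base and alternate must share atom ordering")
    if spacing is None:
        spacing = d_min / 3.0
    cell, shift = auto_cell([base, alternate], padding=padding)
    base_c = base.translated(shift, label=base.label or "conformer1")
    alt_c = alternate.translated(shift, label=alternate.label or "conformer2")
    f1 = structure_factors(base_c, cell, d_min)
    f2 = structure_factors(alt_c, cell, d_min)
    mixed = mix_structure_factors([f1, f2], list(weights))
    mixed = assign_free_flags(mixed, fraction=free_fraction, seed=seed)
    shape = grid_shape_for(cell, spacing)
    mixed_map = map_from_reflections(mixed, cell, shape)
    return CrystalFixture(
        base=base_c, alternate=alt_c, mixed_reflections=mixed,
        mixed_map=mixed_map, cell=cell, d_min=d_min, spacing=spacing,
        weights=weights,
    )


def make_labeled_ensemble(
    fixture: CrystalFixture,
    n_noise: int,
    n_variable: int,
    noise: NoiseModel,
) -> Ensemble:
    """Ensemble of perturbed copies of the fixture's two conformers.

    ``n_noise`` members are noise-perturbed copies of the base (truth label
    "noise"); ``n_variable`` are perturbed copies of the alternate ("variable").
    """
    if n_noise < 0 or n_variable < 0:
        raise ValueError("counts must be nonnegative")
    if n_noise + n_variable == 0:
        raise ValueError("ensemble needs at least one member")
    seeds = np.random.SeedSequence(noise.seed).spawn(n_noise + n_variable)
    members: list[Conformer] = []
    labels: list[str] = []
    for i in range(n_noise):
        m = _perturb_with_rng(fixture.base, noise.sigma_cart, np.random.default_rng(seeds[i]))
        m.label = f"noise_{i}"
        members.append(m)
        labels.append("noise")
    for i in range(n_variable):
        m = _perturb_with_rng(
            fixture.alternate, noise.sigma_cart,
            np.random.default_rng(seeds[n_noise + i]),
        )
        m.label = f"variable_{i}"
        members.append(m)
        labels.append("variable")
    return Ensemble(members=members, base=fixture.base, truth_labels=labels)


def filter_by_fit(
    e: Ensemble,
    obs: ReflectionSet,
    cell: UnitCell,
    tolerance: float = 0.02,
) -> Ensemble:
    """Keep members whose R_free against ``obs`` is ≤ base R_free + tolerance."""
    if obs.free_flag is None:
        raise ValueError("observed reflections need free flags")

    def member_r_free(c: Conformer) -> float:
        calc = structure_factors(c, cell, obs.d_min)
        if not calc.same_indices(obs):
            idx = calc.hkl_index()
            order = np.array([idx[tuple(h)] for h in obs.hkl])
            calc = ReflectionSet(hkl=obs.hkl.copy(), f=calc.f[order], d_min=obs.d_min)
        return r_factors(obs, calc).r_free

    base_r_free = member_r_free(e.base)
    keep = [member_r_free(m) <= base_r_free + tolerance for m in e.members]
    members = [m for m, k in zip(e.members, keep) if k]
    labels = None
    if e.truth_labels is not None:
        labels = [t for t, k in zip(e.truth_labels, keep) if k]
    if not members:
        import warnings

        warnings.warn("filter_by_fit removed every member", stacklevel=2)
        return Ensemble(members=[e.base], base=e.base, truth_labels=None)
    return Ensemble(members=members, base=e.base, truth_labels=labels)


def deduplicate(e: Ensemble, rmsd_tol: float = 0.1) -> Ensemble:
    """Greedy redundancy pruning by best-fit backbone RMSD, in member order."""
    if rmsd_tol < 0:
        raise ValueError("rmsd_tol must be nonnegative")
    kept: list[int] = []
    for i, m in enumerate(e.members):
        if all(rmsd(e.members[j], m, fit=True) > rmsd_tol for j in kept):
            kept.append(i)
    labels = None if e.truth_labels is None else [e.truth_labels[i] for i in kept]
    return Ensemble(members=[e.members[i] for i in kept], base=e.base, truth_labels=labels)


def write_fixture(fixture: CrystalFixture, ensemble: Ensemble, out_dir: str | Path) -> None:
    """Emit the fixture as the file set the CLI classify command consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(fixture.base, out / "base.pdb")
    write_pdb(fixture.alternate, out / "alternate.pdb")
    members_dir = out / "members"
    members_dir.mkdir(exist_ok=True)
    for i, m in enumerate(ensemble.members):
        write_pdb(m, members_dir / f"member_{i:02d}.pdb")
    write_reflections_csv(fixture.mixed_reflections, out / "reflections.csv")
    if ensemble.truth_labels is not None:
        labels = {f"member_{i:02d}": t for i, t in enumerate(ensemble.truth_labels)}
        (out / "truth_labels.json").write_text(json.dumps(labels, indent=2) + "\n")
    meta = {
        "cell": [fixture.cell.a, fixture.cell.b, fixture.cell.c],
        "d_min": fixture.d_min,
        "spacing": fixture.spacing,
        "weights": list(fixture.weights),
    }
    (out / "fixture.json").write_text(json.dumps(meta, indent=2) + "\n")
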