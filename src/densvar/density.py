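"""Electron-density synthesis, structure factors, R-factors, grid regions.

Conventions: space group P1; orthorhombic cells (all angles 90°) for grid
operations; B = 8π²⟨u²⟩ so an atom of B-factor B is rendered as a normalized
isotropic Gaussian of per-axis variance σ² = B/(8π²); structure factors use
F(h) = Σ_j f_j exp(+2πi h·x_frac_j) and density synthesis is
ρ(x) = (1/V) Σ_h F(h) exp(−2πi h·x).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from densvar.structures import Conformer

FOUR_PI_SQ = 4.0 * np.pi**2
EIGHT_PI_SQ = 8.0 * np.pi**2


@dataclass(frozen=True)
class UnitCell:
    """P1 unit cell. Grid operations require an orthorhombic cell."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def is_orthorhombic(self) -> bool:
        return all(abs(ang - 90.0) < 1e-9 for ang in (self.alpha, self.beta, self.gamma))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return float(
            self.a * self.b * self.c
            * np.sqrt(max(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg, 0.0))
        )

    def require_orthorhombic(self) -> None:
        if not self.is_orthorhombic:
            raise NotImplementedError("only orthorhombic (P1, 90° angles) cells are supported here")

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of reflections, (M, 3) integer array."""
        self.require_orthorhombic()
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = (hkl[:, 0] / self.a) ** 2 + (hkl[:, 1] / self.b) ** 2 + (hkl[:, 2] / self.c) ** 2
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)


@dataclass
class DensityGrid:
    """Real scalar field ρ (e/Å³) on a regular grid over a unit cell."""

    cell: UnitCell
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    @property
    def spacings(self) -> np.ndarray:
        return self.cell.lengths / np.array(self.shape)

    def total_electrons(self) -> float:
        """∫ρ dV over the cell."""
        return float(self.values.sum() * self.voxel_volume)

    def same_layout(self, other: "DensityGrid") -> bool:
        return self.shape == other.shape and self.cell == other.cell


@dataclass
class ReflectionSet:
    """Complex structure factors on Miller indices, with free-set flags."""

    hkl: np.ndarray  # (M, 3) int
    f: np.ndarray  # (M,) complex, electrons
    d_min: float
    free_flag: np.ndarray | None = None  # (M,) bool

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=complex).reshape(-1)
        if len(self.hkl) != len(self.f):
            raise ValueError("hkl and f length mismatch")
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate Miller indices")
        if self.free_flag is not None:
            self.free_flag = np.asarray(self.free_flag, dtype=bool).reshape(-1)
            if len(self.free_flag) != len(self.f):
                raise ValueError("free_flag length mismatch")

    def __len__(self) -> int:
        return len(self.f)

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    def hkl_index(self) -> dict[tuple, int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def same_indices(self, other: "ReflectionSet") -> bool:
        return self.hkl.shape == other.hkl.shape and bool(np.all(self.hkl == other.hkl))


@dataclass
class GridRegion:
    """Ordered (lexicographic) subset of a grid's points, as flat indices."""

    shape: tuple[int, int, int]
    flat_indices: np.ndarray

    def __post_init__(self) -> None:
        self.flat_indices = np.asarray(self.flat_indices, dtype=np.int64).reshape(-1)
        n = int(np.prod(self.shape))
        if len(self.flat_indices) == 0:
            raise ValueError("empty grid region")
        if self.flat_indices.min() < 0 or self.flat_indices.max() >= n:
            raise IndexError("region index out of range for grid shape")
        self.flat_indices = np.unique(self.flat_indices)  # sorted == lexicographic

    def __len__(self) -> int:
        return len(self.flat_indices)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "GridRegion":
        return cls(shape, np.arange(int(np.prod(shape)), dtype=np.int64))


@dataclass
class FitStatistics:
    """R / R_free and the amplitude scale applied to the calculated set."""

    r: float
    r_free: float
    scale: float


# ---------------------------------------------------------------------------
# Cell and grid helpers
# ---------------------------------------------------------------------------

def auto_cell(conformers: list[Conformer], padding: float = 10.0) -> tuple[UnitCell, np.ndarray]:
    """Orthorhombic cell enclosing all conformers with ``padding`` Å of slack.

    Returns the cell and the translation that moves the joint bounding box
    to ``padding/2`` from the origin; apply the same shift to every model
    that will be rendered in this cell.
    """
    coords = np.vstack([c.coords for c in conformers])
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo + padding
    shift = padding / 2.0 - lo
    return UnitCell(*extent), shift


def grid_shape_for(cell: UnitCell, spacing: float) -> tuple[int, int, int]:
    """Smallest grid with voxel edge ≤ ``spacing`` along every cell axis."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return tuple(int(np.ceil(L / spacing)) for L in cell.lengths)


# ---------------------------------------------------------------------------
# Density synthesis from coordinates
# ---------------------------------------------------------------------------

def density_map(
    c: Conformer,
    cell: UnitCell,
    spacing: float,
    b_added: float = 0.0,
    shape: tuple[int, int, int] | None = None,
) -> DensityGrid:
    """Render a conformer as a sum of normalized atomic Gaussians.

    Each atom contributes ``occupancy × Z`` electrons as an isotropic 3-D
    Gaussian with per-axis variance ``(b_iso + b_added) / (8π²)``. Tails are
    wrapped periodically (evaluated to 4σ). Atoms may sit anywhere; their
    fractional coordinates are wrapped into the cell.
    """
    cell.require_orthorhombic()
    if shape is None:
        shape = grid_shape_for(cell, spacing)
    nx, ny, nz = shape
    lengths = cell.lengths
    values = np.zeros(shape)
    axes = [np.arange(n) * L / n for n, L in zip(shape, lengths)]

    for atom in c.atoms:
        b_total = atom.b_iso + b_added
        sigma = np.sqrt(b_total / EIGHT_PI_SQ)
        cut = 4.0 * sigma
        if 2 * cut >= min(lengths):
            raise ValueError(
                f"Gaussian footprint (8σ = {2*cut:.1f} Å) exceeds a cell edge; "
                "enlarge the cell or reduce B"
            )
        weight = atom.occupancy * atom.electron_count
        pos = np.mod(atom.position, lengths)  # wrap into the cell
        gauss_1d = []
        index_1d = []
        for axis in range(3):
            n, L = shape[axis], lengths[axis]
            step = L / n
            lo = int(np.floor((pos[axis] - cut) / step))
            hi = int(np.ceil((pos[axis] + cut) / step))
            idx = np.arange(lo, hi + 1)
            x = idx * step - pos[axis]
            g = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
            index_1d.append(np.mod(idx, n))
            gauss_1d.append(g)
        contrib = weight * np.einsum("i,j,k->ijk", *gauss_1d)
        values[np.ix_(*index_1d)] += contrib
    return DensityGrid(cell, values)


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def miller_indices(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller triples (full sphere, including 000) with d(hkl) ≥ d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv_d2 = (
        (hkl[:, 0] / cell.a) ** 2 + (hkl[:, 1] / cell.b) ** 2 + (hkl[:, 2] / cell.c) ** 2
    )
    keep = inv_d2 <= 1.0 / d_min**2 + 1e-12
    hkl = hkl[keep]
    # deterministic lexicographic order
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def structure_factors(
    c: Conformer, cell: UnitCell, d_min: float, b_added: float = 0.0
) -> ReflectionSet:
    """Direct-summation structure factors of the Gaussian-atom model.

    F(hkl) = Σ_j occ_j Z_j exp(−(B_j + b_added) s²/4) exp(2πi h·x_frac,j),
    s = 1/d(hkl). Exact Fourier transform of the continuous Gaussian model.
    """
    cell.require_orthorhombic()
    hkl = miller_indices(cell, d_min)
    s2 = (
        (hkl[:, 0] / cell.a) ** 2 + (hkl[:, 1] / cell.b) ** 2 + (hkl[:, 2] / cell.c) ** 2
    )
    frac = c.coords / cell.lengths  # (N, 3)
    occ_z = np.array([a.occupancy * a.electron_count for a in c.atoms])
    b = np.array([a.b_iso + b_added for a in c.atoms])
    # (M, N) Debye-Waller × phase, summed over atoms
    dw = np.exp(-np.outer(s2, b) / 4.0)
    phase = np.exp(2j * np.pi * (hkl @ frac.T))
    f = np.einsum("mn,mn,n->m", dw, phase, occ_z, optimize=True)
    return ReflectionSet(hkl=hkl, f=f, d_min=d_min)


def reflections_from_map(grid: DensityGrid, d_min: float | None = None) -> ReflectionSet:
    """Structure factors of a sampled map by forward FFT.

    With ``d_min=None`` the complete grid-Nyquist set is returned, making
    ``map_from_reflections`` an exact inverse.
    """
    nx, ny, nz = grid.shape
    fgrid = np.fft.ifftn(grid.values) * grid.cell.volume  # F(h) = (V/N) Σ ρ e^{+2πi h·x}
    hs = [np.fft.fftfreq(n, 1.0 / n).astype(int) for n in grid.shape]
    h, k, l = np.meshgrid(*hs, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    f = fgrid.ravel()
    if d_min is not None:
        d = grid.cell.d_spacing(hkl)
        keep = d >= d_min - 1e-12
        hkl, f = hkl[keep], f[keep]
        eff_d_min = d_min
    else:
        eff_d_min = float(min(2 * s for s in grid.spacings))
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return ReflectionSet(hkl=hkl[order], f=f[order], d_min=eff_d_min)


def map_from_reflections(
    r: ReflectionSet, cell: UnitCell, shape: tuple[int, int, int]
) -> DensityGrid:
    """Inverse Fourier synthesis ρ(x) = (1/V) Σ F(h) exp(−2πi h·x) on a grid."""
    cell.require_orthorhombic()
    nx, ny, nz = shape
    limits = np.array([nx, ny, nz])
    # one index per DFT bin: -n//2 ≤ h ≤ (n-1)//2 along each axis
    if np.any(r.hkl > (limits - 1) // 2) or np.any(r.hkl < -(limits // 2)):
        raise ValueError("grid shape too coarse for the reflection set (aliasing)")
    fgrid = np.zeros(shape, dtype=complex)
    fgrid[r.hkl[:, 0] % nx, r.hkl[:, 1] % ny, r.hkl[:, 2] % nz] = r.f
    rho = np.fft.fftn(fgrid) / cell.volume
    return DensityGrid(cell, rho.real)


def mix_structure_factors(
    sets: list[ReflectionSet], weights: list[float]
) -> ReflectionSet:
    """Complex-valued weighted average of structure-factor sets."""
    if len(sets) == 0:
        raise ValueError("no reflection sets")
    if len(weights) != len(sets):
        raise ValueError("one weight per set required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    first = sets[0]
    for s in sets[1:]:
        if not first.same_indices(s) or abs(s.d_min - first.d_min) > 1e-9:
            raise ValueError("reflection sets must share hkl list and d_min")
    f = sum(wi * s.f for wi, s in zip(w, sets))
    return ReflectionSet(hkl=first.hkl.copy(), f=f, d_min=first.d_min,
                         free_flag=None if first.free_flag is None else first.free_flag.copy())


# ---------------------------------------------------------------------------
# R-factors
# ---------------------------------------------------------------------------

def r_factors(obs: ReflectionSet, calc: ReflectionSet) -> FitStatistics:
    """R (work) and R_free with a single least-squares amplitude scale.

    R = Σ_work | |F_obs| − k|F_calc| | / Σ_work |F_obs|, with
    k = argmin Σ_work (|F_obs| − k|F_calc|)² fit on the work set and reused
    for the free set. F(000) is excluded.
    """
    if obs.free_flag is None:
        raise ValueError("observed set must carry free flags")
    if not obs.same_indices(calc):
        raise ValueError("observed and calculated sets must share hkl lists")
    not_origin = np.any(obs.hkl != 0, axis=1)
    free = obs.free_flag & not_origin
    work = (~obs.free_flag) & not_origin
    if work.sum() == 0 or free.sum() == 0:
        raise ValueError("work and free sets must both be nonempty")
    fo, fc = obs.amplitudes(), calc.amplitudes()
    k = float(np.dot(fo[work], fc[work]) / np.dot(fc[work], fc[work]))
    r = float(np.abs(fo[work] - k * fc[work]).sum() / fo[work].sum())
    r_free = float(np.abs(fo[free] - k * fc[free]).sum() / fo[free].sum())
    return FitStatistics(r=r, r_free=r_free, scale=k)


# ---------------------------------------------------------------------------
# Grid regions
# ---------------------------------------------------------------------------

def fragment_box(
    c: Conformer,
    residues: tuple[int, int],
    margin: float,
    grid: DensityGrid,
) -> GridRegion:
    """Axis-aligned bounding box (plus margin) around a residue range.

    ``residues`` is an inclusive (first, last) residue-index range. Grid
    points with coordinates inside the expanded box are returned; a box
    thinner than one voxel still yields the nearest grid plane.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    lo_res, hi_res = residues
    ridx = c.residue_indices
    sel = (ridx >= lo_res) & (ridx <= hi_res)
    if not np.any(sel):
        raise ValueError(f"no atoms in residue range {residues}")
    coords = c.coords[sel]
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    nx, ny, nz = grid.shape
    lengths = grid.cell.lengths
    index_1d = []
    for axis, n in enumerate((nx, ny, nz)):
        step = lengths[axis] / n
        i_lo = int(np.ceil(lo[axis] / step - 1e-9))
        i_hi = int(np.floor(hi[axis] / step + 1e-9))
        if i_hi < i_lo:  # box thinner than a voxel: take nearest plane
            i_lo = i_hi = int(round(0.5 * (lo[axis] + hi[axis]) / step))
        idx = np.unique(np.clip(np.arange(i_lo, i_hi + 1), 0, n - 1))
        index_1d.append(idx)
    ii, jj, kk = np.meshgrid(*index_1d, indexing="ij")
    flat = (ii * ny + jj) * nz + kk
    return GridRegion(shape=grid.shape, flat_indices=flat.ravel())


def extract_density(grid: DensityGrid, region: GridRegion) -> np.ndarray:
    """Density values over a region, in lexicographic grid-index order."""
    if region.shape != grid.shape:
        raise ValueError("region was built for a different grid shape")
    return grid.values.ravel()[region.flat_indices]


# ---------------------------------------------------------------------------
# File formats: reflection CSV and CCP4/MRC map export
# ---------------------------------------------------------------------------

REFLECTION_COLUMNS = ["h", "k", "l", "F_real", "F_imag", "free"]


def write_reflections_csv(r: ReflectionSet, path: str | Path) -> None:
    free = r.free_flag if r.free_flag is not None else np.zeros(len(r), dtype=bool)
    df = pd.DataFrame(
        {
            "h": r.hkl[:, 0],
            "k": r.hkl[:, 1],
            "l": r.hkl[:, 2],
            "F_real": r.f.real,
            "F_imag": r.f.imag,
            "free": free.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_reflections_csv(path: str | Path, d_min: float) -> ReflectionSet:
    df = pd.read_csv(path)
    missing = [c for c in REFLECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reflection CSV missing columns: {missing}")
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    f = df["F_real"].to_numpy() + 1j * df["F_imag"].to_numpy()
    free = df["free"].to_numpy().astype(bool)
    return ReflectionSet(hkl=hkl, f=f, d_min=d_min, free_flag=free)


def write_ccp4_map(grid: DensityGrid, path: str | Path) -> None:
    """Minimal CCP4/MRC mode-2 (float32) map with a P1 header."""
    nx, ny, nz = grid.shape
    cell = grid.cell
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nz, ny, nx)  # NC, NR, NS (section = slowest = x)
    struct.pack_into("<i", header, 12, 2)  # MODE 2: float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # start
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # sampling intervals
    struct.pack_into("<6f", header, 40, cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    struct.pack_into("<3i", header, 64, 3, 2, 1)  # MAPC, MAPR, MAPS: col=z fastest
    vals = grid.values.astype(np.float32)
    struct.pack_into("<3f", header, 76, float(vals.min()), float(vals.max()), float(vals.mean()))
    struct.pack_into("<i", header, 88, 1)  # ISPG = P1
    header[208:212] = b"MAP "
    struct.pack_into("<4B", header, 212, 0x44, 0x44, 0, 0)  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(vals.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # x slowest, z fastest matches the C-order ravel of values[ix, iy, iz]
        fh.write(vals.tobytes(order="C"))
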