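"""Density-map and atomic-model I/O, pixel-size relabeling, and restraint topology.

Maps are stored on a regular orthogonal grid, index order (ix, iy, iz) with x
fastest in memory-layout terms of the MRC convention; ``grid[i, j, k]`` is the
density at the center of voxel (i, j, k), i.e. at physical position
``origin + (index + 0.5) * voxel_size``.  MRC/CCP4 axis-order permutations are
normalized on read.  Atomic models are plain coordinate/attribute arrays read
from and written to PDB.

The restraint topology is a structure-based (elastic-network-like) potential
derived from the starting geometry: bonds between heavy atoms within a cutoff
at their observed lengths, angles between connected bond pairs at their
observed values, and a soft steric repulsion for everything not covalently
coupled.  It stands in for a molecular-mechanics force field at pseudo-atom
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from densfit._elements import (
    element_mass,
    element_number,
    element_radius,
    is_known,
)
from densfit.exceptions import (
    DegenerateInputError,
    MapFormatError,
    ModelFormatError,
)

__all__ = [
    "DensityMap",
    "AtomicModel",
    "Topology",
    "read_map",
    "write_map",
    "relabel_pixel_size",
    "normalize_map",
    "read_model",
    "write_model",
    "build_topology",
]

DEFAULT_BOND_CUTOFF = 1.9  # Å, covers C-S single bonds
MAX_VALENCE = 6
DEFAULT_K_BOND = 1000.0  # kJ/mol/Å²
DEFAULT_K_ANGLE = 100.0  # kJ/mol/rad²


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DensityMap:
    """A 3D scalar density on a regular grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Density values; ``grid[i, j, k]`` samples the center of voxel (i,j,k).
    voxel_size : ndarray, shape (3,)
        Å per voxel along x, y, z.
    origin : ndarray, shape (3,)
        Å position of the corner of voxel (0, 0, 0).
    label : str
        Free-text provenance label.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        if any(n < 2 for n in self.grid.shape):
            raise ValueError(f"grid must have >= 2 voxels per axis, got {self.grid.shape}")
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical box size in Å along each axis (always N_i * p_i)."""
        return np.asarray(self.grid.shape) * self.voxel_size

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D arrays of voxel-center coordinates along x, y, z (Å)."""
        return tuple(
            self.origin[a] + (np.arange(self.grid.shape[a]) + 0.5) * self.voxel_size[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(),
                          self.origin.copy(), self.label)


@dataclass
class AtomicModel:
    """An ordered set of atoms with coordinates and per-atom attributes.

    Atom order is stable under read -> write round-trips.  ``amplitude`` is
    the unitless weight each atom carries in the Gaussian forward model
    (default: atomic number).
    """

    coords: np.ndarray                     # (n, 3) Å
    elements: list[str]
    masses: np.ndarray                     # (n,) amu
    amplitudes: np.ndarray                 # (n,) unitless
    atom_names: list[str]
    residue_ids: np.ndarray                # (n,) int
    chain_ids: list[str]
    is_heavy: np.ndarray                   # (n,) bool
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        self.masses = np.asarray(self.masses, dtype=np.float64).reshape(n)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64).reshape(n)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64).reshape(n)
        self.is_heavy = np.asarray(self.is_heavy, dtype=bool).reshape(n)
        if self.residue_names is None:
            self.residue_names = ["UNK"] * n
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not np.all(self.masses > 0):
            raise ValueError("atom masses must be positive")
        if not np.all(self.amplitudes > 0):
            raise ValueError("atom amplitudes must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """A shallow copy of the model sharing attributes but with new coordinates."""
        return replace(self, coords=np.asarray(coords, dtype=np.float64).copy())

    def copy(self) -> "AtomicModel":
        return replace(
            self,
            coords=self.coords.copy(),
            elements=list(self.elements),
            masses=self.masses.copy(),
            amplitudes=self.amplitudes.copy(),
            atom_names=list(self.atom_names),
            residue_ids=self.residue_ids.copy(),
            chain_ids=list(self.chain_ids),
            is_heavy=self.is_heavy.copy(),
            residue_names=list(self.residue_names or []),
        )


@dataclass
class Topology:
    """Structure-based restraint lists for an :class:`AtomicModel`.

    bonds: (nb, 2) atom indices, reference lengths b0 (Å), stiffness k_b
    (kJ/mol/Å²); angles: (na, 3) indices i-j-k with j the vertex, reference
    angles theta0 (rad), stiffness k_theta (kJ/mol/rad²); excluded_pairs:
    1-2 and 1-3 pairs exempt from steric repulsion; repulsion_radius: per-atom
    radii (Å) for the clash/repulsion terms.
    """

    bonds: np.ndarray
    b0: np.ndarray
    k_b: np.ndarray
    angles: np.ndarray
    theta0: np.ndarray
    k_theta: np.ndarray
    excluded_pairs: set
    repulsion_radius: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.b0 = np.asarray(self.b0, dtype=np.float64).reshape(-1)
        self.k_b = np.asarray(self.k_b, dtype=np.float64).reshape(-1)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.theta0 = np.asarray(self.theta0, dtype=np.float64).reshape(-1)
        self.k_theta = np.asarray(self.k_theta, dtype=np.float64).reshape(-1)
        self.repulsion_radius = np.asarray(self.repulsion_radius, dtype=np.float64)
        idx = np.concatenate([self.bonds.ravel(), self.angles.ravel()]) \
            if len(self.bonds) or len(self.angles) else np.empty(0, dtype=np.int64)
        if len(idx) and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise ValueError("topology indices out of range for the model")
        if np.any(self.b0 <= 0):
            raise ValueError("bond reference lengths must be positive")
        if np.any(self.theta0 <= 0) or np.any(self.theta0 > np.pi):
            raise ValueError("angle references must lie in (0, pi]")
        if np.any(self.k_b < 0) or np.any(self.k_theta < 0):
            raise ValueError("force constants must be non-negative")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_angles(self) -> int:
        return len(self.angles)


# ---------------------------------------------------------------------------
# map I/O


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 volume into a :class:`DensityMap`.

    Axis-order permutations recorded in the header are normalized so the
    returned grid is indexed (ix, iy, iz).  The origin is taken from the
    MRC2014 ORIGIN record when set, otherwise from NxSTART * voxel size.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(0.0, gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc
    grid = np.array(ccp4.grid.array, dtype=np.float64)
    spacing = np.array(ccp4.grid.spacing, dtype=np.float64)
    if not np.all(spacing > 0):
        raise MapFormatError(f"non-positive voxel size in header of {path!r}")
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        warnings.warn(
            f"anisotropic voxel size {spacing} preserved from {path!r}",
            stacklevel=2,
        )
    origin = np.array(
        [ccp4.header_float(w) for w in (50, 51, 52)], dtype=np.float64
    )
    if np.all(origin == 0):
        nstart = np.array(
            [ccp4.header_i32(w) for w in (5, 6, 7)], dtype=np.float64
        )
        origin = nstart * spacing
    return DensityMap(grid, spacing, origin, label=str(path))


def write_map(m: DensityMap, path) -> str:
    """Write a :class:`DensityMap` as a standard MRC file (mode 2, 32-bit real)."""
    if not np.all(np.isfinite(m.grid)):
        raise ValueError("map contains non-finite values; refusing to write")
    g = gemmi.FloatGrid(*m.grid.shape)
    np.asarray(g.array)[:] = m.grid.astype(np.float32)
    ext = m.extent
    g.unit_cell = gemmi.UnitCell(ext[0], ext[1], ext[2], 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))
    return str(path)


def relabel_pixel_size(m: DensityMap, new_p: float) -> DensityMap:
    """Relabel the voxel size of a map without touching any voxel value.

    This is a header-only operation: the same reconstruction is declared at a
    different Å/pixel, so every physical length in the map — extent and origin
    — scales by ``new_p / old_p`` per axis.  No interpolation is performed.
    """
    if new_p <= 0:
        raise ValueError(f"pixel size must be positive, got {new_p}")
    ratio = new_p / m.voxel_size
    return DensityMap(
        m.grid.copy(),
        np.full(3, float(new_p)),
        m.origin * ratio,
        label=m.label,
    )


def normalize_map(m: DensityMap, mask: np.ndarray | None = None) -> DensityMap:
    """Return a copy with zero mean and unit standard deviation.

    When ``mask`` is given, the mean and standard deviation are computed over
    masked voxels only, but the affine transform is applied everywhere.
    """
    values = m.grid[mask] if mask is not None else m.grid
    mu = float(values.mean())
    sd = float(values.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot normalize a constant density map")
    return DensityMap((m.grid - mu) / sd, m.voxel_size.copy(), m.origin.copy(),
                      label=m.label)


# ---------------------------------------------------------------------------
# model I/O


def read_model(path, default_amplitude: str = "atomic_number") -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel` preserving atom order.

    Masses come from a fixed internal element table; unknown elements get a
    carbon-like default with a warning.  Heavy-atom flags mark non-hydrogens.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelFormatError(f"cannot read model {path!r}: {exc}") from exc
    coords, elements, names, res_ids, res_names, chain_ids = [], [], [], [], [], []
    if len(st) == 0:
        raise ModelFormatError(f"no models in {path!r}")
    for chain in st[0]:
        for res in chain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                sym = atom.element.name.upper() if atom.element.name else ""
                if not sym or not is_known(sym):
                    warnings.warn(
                        f"unknown element {sym!r} for atom {atom.name}; "
                        "using default mass/amplitude",
                        stacklevel=2,
                    )
                    sym = sym or "X"
                elements.append(sym)
                names.append(atom.name)
                res_ids.append(res.seqid.num)
                res_names.append(res.name)
                chain_ids.append(chain.name)
    if not coords:
        raise ModelFormatError(f"no atoms in {path!r}")
    masses = np.array([element_mass(e) for e in elements])
    amps = np.array([float(element_number(e)) for e in elements])
    heavy = np.array([e != "H" for e in elements])
    return AtomicModel(
        np.array(coords), elements, masses, amps, names,
        np.array(res_ids), chain_ids, heavy, residue_names=res_names,
    )


def write_model(model: AtomicModel, path, chain_filter: str | None = None) -> str:
    """Write an :class:`AtomicModel` to PDB, preserving atom order.

    ``chain_filter`` restricts output to a single chain id (used when scoring
    one chain with an external tool).
    """
    st = gemmi.Structure()
    st.add_model(gemmi.Model(1))
    cur_chain = None
    cur_res_key = None
    chain_obj = None
    res_obj = None
    res_names = model.residue_names or ["UNK"] * model.n_atoms
    for i in range(model.n_atoms):
        if chain_filter is not None and model.chain_ids[i] != chain_filter:
            continue
        if model.chain_ids[i] != cur_chain:
            chain_obj = gemmi.Chain(model.chain_ids[i])
            st[0].add_chain(chain_obj)
            chain_obj = st[0][-1]
            cur_chain = model.chain_ids[i]
            cur_res_key = None
        res_key = (model.chain_ids[i], int(model.residue_ids[i]), res_names[i])
        if res_key != cur_res_key:
            res_obj = gemmi.Residue()
            res_obj.name = res_names[i]
            res_obj.seqid = gemmi.SeqId(int(model.residue_ids[i]), " ")
            res_obj.het_flag = "A"
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[-1]
            cur_res_key = res_key
        atom = gemmi.Atom()
        atom.name = model.atom_names[i]
        atom.element = gemmi.Element(model.elements[i].capitalize())
        atom.pos = gemmi.Position(*model.coords[i])
        atom.occ = 1.0
        atom.b_iso = 0.0
        res_obj.add_atom(atom)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
    return str(path)


# ---------------------------------------------------------------------------
# restraint topology


def build_topology(
    model: AtomicModel,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
    k_bond: float = DEFAULT_K_BOND,
    k_angle: float = DEFAULT_K_ANGLE,
    max_valence: int = MAX_VALENCE,
) -> Topology:
    """Derive a structure-based restraint topology from the input geometry.

    Bonds are heavy-atom pairs within ``bond_cutoff`` at their observed
    distance; angles come from connected bond pairs at their observed value;
    1-2 and 1-3 pairs are excluded from steric repulsion.
    """
    n = model.n_atoms
    heavy_idx = np.flatnonzero(model.is_heavy)
    bonds: list[tuple[int, int]] = []
    if len(heavy_idx) >= 2:
        tree = cKDTree(model.coords[heavy_idx])
        for a, b in tree.query_pairs(bond_cutoff):
            i, j = int(heavy_idx[a]), int(heavy_idx[b])
            bonds.append((min(i, j), max(i, j)))
    bonds.sort()
    bond_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    b0 = (
        np.linalg.norm(model.coords[bond_arr[:, 0]] - model.coords[bond_arr[:, 1]], axis=1)
        if len(bond_arr)
        else np.empty(0)
    )

    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for i, nb in neighbors.items():
        if len(nb) > max_valence:
            warnings.warn(
                f"atom {i} has {len(nb)} bonds (> max valence {max_valence}); "
                "check bond_cutoff",
                stacklevel=2,
            )

    angles: list[tuple[int, int, int]] = []
    for j in sorted(neighbors):
        nb = sorted(neighbors[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angle_arr = np.array(angles, dtype=np.int64).reshape(-1, 3)
    if len(angle_arr):
        v1 = model.coords[angle_arr[:, 0]] - model.coords[angle_arr[:, 1]]
        v2 = model.coords[angle_arr[:, 2]] - model.coords[angle_arr[:, 1]]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        theta0 = np.arccos(np.clip(cosang, -1.0, 1.0))
        theta0 = np.clip(theta0, 1e-6, np.pi)
    else:
        theta0 = np.empty(0)

    excluded = {(i, j) for i, j in bonds}
    for i, j, k in angles:
        excluded.add((min(i, k), max(i, k)))

    radii = np.array([element_radius(e) for e in model.elements])
    return Topology(
        bonds=bond_arr,
        b0=b0,
        k_b=np.full(len(bond_arr), k_bond),
        angles=angle_arr,
        theta0=theta0,
        k_theta=np.full(len(angle_arr), k_angle),
        excluded_pairs=excluded,
        repulsion_radius=radii,
        n_atoms=n,
    )
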