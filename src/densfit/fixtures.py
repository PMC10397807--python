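"""Deterministic synthetic test systems: toy barrels, perturbations, target maps.

The toy β-barrel places one pseudo-atom (CA-like bead) per residue on a
tilted-strand cylinder, mimicking the architecture of β-barrel membrane
channels at coarse resolution: strands run roughly along the cylinder axis
(the membrane normal), so per-axis radii of gyration are anisotropic just as
for a real barrel.  Target and half-maps are forward-modeled from a model
with controlled Gaussian voxel noise; half-maps carry independent noise
inflated by sqrt(2) so that averaging them reproduces the full map's noise
level in expectation.

Everything is bit-reproducible from (spec, seed): the same FixtureSpec always
yields the same atoms and the same maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from densfit.forward_model import SpreadParams, model_to_map
from densfit.map_model_io import AtomicModel, DensityMap, Topology, build_topology

__all__ = ["FixtureSpec", "make_toy_barrel", "make_toy_coil", "perturb_model",
           "make_target_maps"]

MIN_STRAND_SEPARATION = 4.2  # Å arc spacing below which strands would fuse
# elastic-network stiffness of the pseudo-atom restraints (kJ/mol/Å², /rad²)
ENM_K_BOND = 200.0
ENM_K_ANGLE = 40.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic test system.

    kind: barrel (tilted strands on a cylinder), coil (self-avoiding random
    chain) or dimer (two barrels, chains A and B).  noise_sd is the map noise
    standard deviation relative to the noiseless density's voxel standard
    deviation.
    """

    kind: str = "barrel"
    n_strands: int = 8
    strand_length: int = 10
    radius: float = 6.0          # Å, cylinder radius (~4.7 Å strand spacing)
    spacing: float = 3.8         # Å, intra-strand bead spacing (CA-like)
    tilt: float = 0.15           # rad of azimuthal advance per bead (strand tilt)
    topology_cutoff: float = 5.0  # Å, elastic-network bond cutoff
    pixel_size: float = 0.84     # Å per voxel of generated maps
    box: int = 48                # voxels per axis of generated maps
    noise_sd: float = 0.05       # relative map noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("barrel", "coil", "dimer"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.pixel_size <= 0 or self.box < 8:
            raise ValueError("invalid map geometry in fixture spec")


def _bead_model(coords: np.ndarray, chain_ids: list[str],
                amplitude_seed: int = 0,
                amplitude_variation: float = 0.7) -> AtomicModel:
    n = len(coords)
    # residue-specific spreading weights (side-chain size proxy; real
    # residues span roughly glycine to tryptophan, a ~3.5x electron-count
    # range): without contrast the density is invariant under bead
    # permutation and fits can settle in register-shifted states
    rng = np.random.default_rng(amplitude_seed)
    amplitudes = 6.0 * (1.0 + amplitude_variation * rng.uniform(-1, 1, n))
    return AtomicModel(
        coords=coords,
        elements=["C"] * n,
        masses=np.full(n, 12.011),
        amplitudes=amplitudes,
        atom_names=["CA"] * n,
        residue_ids=np.arange(1, n + 1),
        chain_ids=chain_ids,
        is_heavy=np.ones(n, dtype=bool),
        residue_names=["ALA"] * n,
    )


def _barrel_coords(spec: FixtureSpec, phase: float = 0.0) -> np.ndarray:
    if spec.n_strands < 4 or spec.strand_length < 4:
        raise ValueError("barrel needs >= 4 strands of >= 4 residues")
    arc = 2 * np.pi * spec.radius / spec.n_strands
    if arc < MIN_STRAND_SEPARATION:
        raise ValueError(
            f"radius {spec.radius} Å gives {arc:.2f} Å strand separation; "
            f"increase radius or reduce n_strands (need >= {MIN_STRAND_SEPARATION} Å)"
        )
    chord = 2 * spec.radius * np.sin(spec.tilt / 2.0)
    if chord >= spec.spacing:
        raise ValueError("tilt too large for the requested bead spacing")
    dz = np.sqrt(spec.spacing**2 - chord**2)
    coords = []
    t_idx = np.arange(spec.strand_length)
    z = (t_idx - (spec.strand_length - 1) / 2.0) * dz
    for s in range(spec.n_strands):
        # uniform tilt keeps inter-strand separation constant along the barrel
        phi = phase + 2 * np.pi * s / spec.n_strands + spec.tilt * t_idx
        coords.append(np.column_stack([
            spec.radius * np.cos(phi),
            spec.radius * np.sin(phi),
            z,
        ]))
    return np.concatenate(coords)


def make_toy_barrel(spec: FixtureSpec) -> tuple[AtomicModel, Topology]:
    """Pseudo-atom barrel (or barrel dimer) centered at the origin, with topology.

    Atom count is n_strands * strand_length per barrel; the cylinder axis is
    z, playing the role of the membrane normal.
    """
    if spec.kind == "coil":
        return make_toy_coil(spec)
    coords = _barrel_coords(spec)
    chains = ["A"] * len(coords)
    if spec.kind == "dimer":
        offset = np.array([2 * spec.radius + 8.0, 0.0, 0.0])
        coords = np.concatenate([coords, _barrel_coords(spec) + offset])
        chains = chains + ["B"] * (len(coords) - len(chains))
        coords = coords - coords.mean(axis=0)
    model = _bead_model(coords, chains, amplitude_seed=spec.seed)
    topo = build_topology(model, bond_cutoff=spec.topology_cutoff,
                          k_bond=ENM_K_BOND, k_angle=ENM_K_ANGLE)
    return model, topo


def make_toy_coil(spec: FixtureSpec) -> tuple[AtomicModel, Topology]:
    """Self-avoiding random chain of beads with the spec's spacing."""
    n = spec.n_strands * spec.strand_length
    rng = np.random.default_rng(spec.seed)
    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(200):
            step = rng.standard_normal(3)
            step *= spec.spacing / np.linalg.norm(step)
            cand = coords[-1] + step
            prev = np.array(coords[:-1]) if len(coords) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) > 3.9:
                coords.append(cand)
                break
        else:
            raise RuntimeError("random coil generation got stuck; change seed")
    coords = np.array(coords) - np.mean(coords, axis=0)
    model = _bead_model(coords, ["A"] * n, amplitude_seed=spec.seed)
    topo = build_topology(model, bond_cutoff=spec.spacing * 1.05,
                          k_bond=ENM_K_BOND, k_angle=ENM_K_ANGLE)
    return model, topo


def perturb_model(model: AtomicModel, rmsd_target: float, seed: int,
                  correlation_length: float = 12.0) -> AtomicModel:
    """Seeded random heavy-atom displacement with an exact RMSD to the input.

    The displacement field is spatially smooth (a sum of random sinusoidal
    modes with wavelengths around ``correlation_length`` plus a small
    uncorrelated part), emulating a conformational offset between a starting
    model and the target state rather than white-noise damage to local
    geometry.  ``correlation_length = 0`` gives independent per-atom
    displacements.  The field is rescaled so the RMSD over all atoms equals
    ``rmsd_target``.
    """
    if rmsd_target < 0:
        raise ValueError("rmsd_target must be non-negative")
    if rmsd_target == 0:
        return model.copy()
    rng = np.random.default_rng(seed)
    heavy = model.is_heavy
    n_heavy = int(heavy.sum())
    disp = np.zeros_like(model.coords)
    if correlation_length > 0:
        x = model.coords[heavy]
        field = np.zeros((n_heavy, 3))
        for _ in range(6):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            wavevec = rng.standard_normal(3)
            wavevec *= 2 * np.pi / (correlation_length *
                                    np.linalg.norm(wavevec))
            phase = rng.uniform(0, 2 * np.pi)
            field += np.sin(x @ wavevec + phase)[:, None] * direction
        field += 0.2 * rng.standard_normal((n_heavy, 3))
        disp[heavy] = field
    else:
        disp[heavy] = rng.standard_normal((n_heavy, 3))
    # project out the net rigid-body component (Kabsch superposition) so the
    # perturbation is pure deformation; rigid placement is the alignment
    # stage's job, not the perturbation's
    from scipy.spatial.transform import Rotation
    moved = model.coords + disp
    com_ref = model.coords.mean(axis=0)
    com_mov = moved.mean(axis=0)
    rot, _ = Rotation.align_vectors(model.coords - com_ref, moved - com_mov)
    superposed = (moved - com_mov) @ rot.as_matrix().T + com_ref
    disp = superposed - model.coords
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    disp *= rmsd_target / rms
    return model.with_coords(model.coords + disp)


def _grid_spec(model: AtomicModel, spec: FixtureSpec) -> DensityMap:
    n = spec.box
    p = spec.pixel_size
    com = model.center_of_mass()
    origin = com - n * p / 2.0
    return DensityMap(np.zeros((n, n, n)), np.full(3, p), origin,
                      label="fixture grid")


def make_target_maps(model: AtomicModel, spec: FixtureSpec
                     ) -> tuple[DensityMap, DensityMap, DensityMap]:
    """Forward-model full and half target maps with controlled noise.

    full = density + noise of sd ``noise_sd * sd(density)``; half1/half2 add
    independent noise of sd ``noise_sd * sqrt(2) * sd(density)`` so that
    (half1 + half2) / 2 matches the full map's noise level in expectation.
    The map box is centered on the model's center of mass.
    """
    grid_spec = _grid_spec(model, spec)
    params = SpreadParams.for_pixel_size(spec.pixel_size)
    margin = 2.0 * params.sigma
    lo = grid_spec.origin + margin
    hi = grid_spec.origin + grid_spec.extent - margin
    if np.any(model.coords < lo) or np.any(model.coords > hi):
        raise ValueError(
            f"model does not fit in the {spec.box}^3 box at "
            f"{spec.pixel_size} Å/voxel with a {margin:.2f} Å margin"
        )
    density = model_to_map(model, grid_spec, params)
    base_sd = float(density.grid.std())
    rng = np.random.default_rng(spec.seed)
    shape = density.shape

    def with_noise(scale: float, label: str) -> DensityMap:
        noise = rng.standard_normal(shape) * (scale * base_sd) if scale > 0 \
            else 0.0
        return DensityMap(density.grid + noise, density.voxel_size.copy(),
                          density.origin.copy(), label=label)

    full = with_noise(spec.noise_sd, "fixture full map")
    half1 = with_noise(spec.noise_sd * np.sqrt(2.0), "fixture half map 1")
    half2 = with_noise(spec.noise_sd * np.sqrt(2.0), "fixture half map 2")
    return full, half1, half2
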