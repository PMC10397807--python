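"""Density-guided fitting: alignment, adaptive-force dynamics, minimization.

The engine integrates overdamped Langevin dynamics on the combined energy

    E(x) = E_restraint(x; topology) - k * S(rho_model(x), rho_target)

where S is the normalized cross-correlation between the forward-modeled
density of the current coordinates and the target map.  The bias force
constant k follows adaptive force scaling: every feedback interval, k grows
by a factor exp(dt_fb / tau) while the similarity stalls and shrinks by the
inverse factor while it improves.  This drives the model into the map with
the gentlest force that still makes progress, and terminates the run when
the force constant saturates (excess adapted forces), when the maximum time
is reached, or when forces blow up.

Frames are recorded on a fixed evaluation stride with the similarity,
FSC-average against the target at the configured resolution threshold, the
stereochemical quality total, and the current k — the series that frame
selection consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from densfit.exceptions import AlignmentError, MinimizationError
from densfit.forward_model import (
    SpreadParams,
    Spreader,
    model_to_map,
    similarity_and_force,
)
from densfit.map_model_io import AtomicModel, DensityMap, Topology
from densfit.metrics import cross_correlation, fsc_average_maps, stereo_score

__all__ = [
    "FitConfig", "FitFrame", "FitTrajectory",
    "rigid_body_align", "adaptive_force_update", "run_fit", "energy_minimize",
    "restraint_energy_forces", "write_trajectory_pdb",
]

KB = 0.0083144621  # kJ/mol/K
K_REPULSION = 200.0  # kJ/mol/Å², soft steric repulsion stiffness
CLASH_GAP = 0.4  # Å, same convention as the clash metric


@dataclass
class FitConfig:
    """Parameters of a density-guided fitting run.

    Defaults follow the protocol's standard conditions: bias force constant
    starting at 10 kJ/mol with a feedback time constant of 4 ps, metric
    evaluation every 2 ps, 300 K, FSC-average threshold 2.88 Å, and a 3 ns
    time limit.  ``seed`` is required; all stochastic draws of a run flow
    from it.
    """

    seed: int
    k_start: float = 10.0            # kJ/mol
    tau: float = 4.0                 # ps, feedback time constant
    feedback_interval: float = 2.0   # ps between adaptive-force updates
    eval_stride: float = 2.0         # ps between recorded frames
    temperature: float = 300.0       # K
    timestep: float = 0.002          # ps
    max_time: float = 3000.0         # ps
    k_cap: float = 1.0e6             # kJ/mol, saturation of the adaptive force
    resolution_threshold: float = 2.88  # Å, FSC-average threshold
    mobility: float = 0.05           # Å²/(kJ/mol·ps), overdamped mobility
    max_step: float = 0.25           # Å, per-step displacement clamp
    quality_weights: tuple[float, float, float] = (10.0, 5.0, 0.1)

    def __post_init__(self) -> None:
        for name in ("tau", "feedback_interval", "eval_stride", "timestep",
                     "max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_start <= 0:
            raise ValueError("k_start must be positive")
        if self.k_cap <= self.k_start:
            raise ValueError("k_cap must exceed k_start")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class FitFrame:
    """One recorded snapshot of a fitting trajectory."""

    time: float            # ps
    coords: np.ndarray     # (n, 3) Å
    similarity: float      # normalized cross-correlation
    fsc_avg: float
    quality: float         # stereochemical score total (lower = better)
    k: float               # kJ/mol


@dataclass
class FitTrajectory:
    """Ordered frames of a fitting run plus its configuration and outcome."""

    frames: list
    config: FitConfig
    termination_reason: str  # max_time | k_cap | force_blowup | user

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory must contain at least one frame")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def metric_table(self) -> np.ndarray:
        """(n_frames, 5) array of time, similarity, fsc_avg, quality, k."""
        return np.array([
            [f.time, f.similarity, f.fsc_avg, f.quality, f.k]
            for f in self.frames
        ])

    def to_tsv(self, path) -> str:
        with open(path, "w") as fh:
            fh.write("time_ps\tsimilarity\tfsc_avg\tquality\tk\n")
            for f in self.frames:
                fh.write(f"{f.time:.6g}\t{f.similarity:.8g}\t{f.fsc_avg:.8g}\t"
                         f"{f.quality:.8g}\t{f.k:.8g}\n")
        return str(path)


# ---------------------------------------------------------------------------
# restraint potential


def _prepare_repulsion_pairs(topo: Topology, is_heavy: np.ndarray):
    """Precompute non-excluded heavy-atom pairs and their contact distances."""
    heavy = np.flatnonzero(is_heavy)
    ii, jj = np.triu_indices(len(heavy), k=1)
    i_idx = heavy[ii]
    j_idx = heavy[jj]
    keep = np.array([
        (min(i, j), max(i, j)) not in topo.excluded_pairs
        for i, j in zip(i_idx, j_idx)
    ], dtype=bool) if len(i_idx) else np.empty(0, dtype=bool)
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    d_min = topo.repulsion_radius[i_idx] + topo.repulsion_radius[j_idx] - CLASH_GAP
    return i_idx, j_idx, d_min


def restraint_energy_forces(coords: np.ndarray, topo: Topology,
                            repulsion_pairs=None, is_heavy=None):
    """Energy (kJ/mol) and forces (kJ/mol/Å) of the structure-based potential.

    Harmonic bonds and angles at their reference geometry plus a one-sided
    harmonic repulsion between non-excluded heavy-atom pairs below contact
    distance.
    """
    x = coords
    energy = 0.0
    forces = np.zeros_like(x)

    if topo.n_bonds:
        i, j = topo.bonds[:, 0], topo.bonds[:, 1]
        dv = x[i] - x[j]
        d = np.linalg.norm(dv, axis=1)
        delta = d - topo.b0
        energy += 0.5 * float(topo.k_b @ delta**2)
        f = (-(topo.k_b * delta) / np.maximum(d, 1e-12))[:, None] * dv
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    if topo.n_angles:
        ai, aj, ak = topo.angles[:, 0], topo.angles[:, 1], topo.angles[:, 2]
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
        dE = topo.k_theta * (theta - topo.theta0)
        energy += 0.5 * float(topo.k_theta @ (theta - topo.theta0) ** 2)
        dthe_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
        dthe_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
        fi = -dE[:, None] * dthe_di
        fk = -dE[:, None] * dthe_dk
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))

    if repulsion_pairs is None:
        if is_heavy is None:
            is_heavy = np.ones(len(x), dtype=bool)
        repulsion_pairs = _prepare_repulsion_pairs(topo, is_heavy)
    i_idx, j_idx, d_min = repulsion_pairs
    if len(i_idx):
        dv = x[i_idx] - x[j_idx]
        d = np.linalg.norm(dv, axis=1)
        overlap = d_min - d
        active = overlap > 0
        if np.any(active):
            ov = overlap[active]
            energy += 0.5 * K_REPULSION * float(ov @ ov)
            f = (K_REPULSION * ov / np.maximum(d[active], 1e-12))[:, None] * dv[active]
            np.add.at(forces, i_idx[active], f)
            np.add.at(forces, j_idx[active], -f)

    return energy, forces


# ---------------------------------------------------------------------------
# rigid-body pre-alignment


def _apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray,
                     pivot: np.ndarray) -> np.ndarray:
    return (coords - pivot) @ rot.T + pivot + trans


def rigid_body_align(model: AtomicModel, target: DensityMap,
                     params: SpreadParams, n_orientations: int = 300,
                     seed: int = 0, coarse: bool = True):
    """Rigid-body fit of a model into a map by cross-correlation.

    A coarse orientation search (quasi-uniform random rotations about the
    model's center of mass, each with an FFT translational scan) seeds a
    local 6-parameter refinement of the cross-correlation between the
    forward-modeled density and the target.  The returned transform maps
    input coordinates as ``x' = R (x - com) + com + t``.  The aligned model
    never scores below the input model.
    """
    pivot = model.center_of_mass()
    target_grid_fft = np.fft.fftn(target.grid)
    tc = target.grid - target.grid.mean()
    t_norm = float(np.sqrt(np.sum(tc**2)))
    if t_norm == 0:
        raise AlignmentError("target map is constant")

    def cc_of(coords: np.ndarray) -> float:
        mm = model_to_map(model.with_coords(coords), target, params)
        if mm.grid.std() == 0:
            return -np.inf
        return cross_correlation(mm, target)

    cc_input = cc_of(model.coords)

    # density centroid (positive part) for initial centering
    w = np.clip(target.grid, 0.0, None)
    if w.sum() == 0:
        w = target.grid - target.grid.min()
    xs, ys, zs = (np.arange(n) for n in target.shape)
    cx = np.array([
        (w.sum(axis=(1, 2)) @ (xs + 0.5)) / w.sum(),
        (w.sum(axis=(0, 2)) @ (ys + 0.5)) / w.sum(),
        (w.sum(axis=(0, 1)) @ (zs + 0.5)) / w.sum(),
    ]) * target.voxel_size + target.origin
    center_shift = cx - pivot

    rng = np.random.default_rng(seed)
    if coarse:
        rots = [Rotation.identity()] + list(Rotation.random(n_orientations, rng))
    else:
        rots = [Rotation.identity()]

    best = (-np.inf, np.eye(3), np.zeros(3))
    voxel = target.voxel_size
    for rot in rots:
        R = rot.as_matrix()
        coords0 = _apply_transform(model.coords, R, center_shift, pivot)
        mm = model_to_map(model.with_coords(coords0), target, params)
        if mm.grid.std() == 0:
            continue
        # FFT translational scan (circular; maps are zero-padded in practice)
        corr = np.fft.ifftn(np.conj(np.fft.fftn(mm.grid)) * target_grid_fft).real
        shift_vox = np.array(np.unravel_index(np.argmax(corr), corr.shape))
        shift_vox = np.where(shift_vox > np.array(corr.shape) // 2,
                             shift_vox - np.array(corr.shape), shift_vox)
        t = center_shift + shift_vox * voxel
        cc = cc_of(_apply_transform(model.coords, R, t, pivot))
        if cc > best[0]:
            best = (cc, R, t)

    if not np.isfinite(best[0]):
        raise AlignmentError(
            "no orientation produced overlap between the model density and "
            "the map; check that the model lies inside the map box"
        )

    # local refinement over rotation vector + translation
    r0 = Rotation.from_matrix(best[1]).as_rotvec()
    x0 = np.concatenate([r0, best[2]])

    def objective(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        return -cc_of(_apply_transform(model.coords, R, p[3:], pivot))

    res = minimize(objective, x0, method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000})
    cc_ref = -res.fun
    if cc_ref > best[0]:
        best = (cc_ref, Rotation.from_rotvec(res.x[:3]).as_matrix(), res.x[3:])

    if best[0] < cc_input:
        # never degrade the input placement
        best = (cc_input, np.eye(3), np.zeros(3))
    R, t = best[1], best[2]
    aligned = model.with_coords(_apply_transform(model.coords, R, t, pivot))
    return R, t, aligned


# ---------------------------------------------------------------------------
# adaptive force scaling


def adaptive_force_update(k: float, similarity_now: float,
                          similarity_prev: float, config: FitConfig) -> float:
    """One multiplicative adaptive-force-scaling update.

    If the similarity did not increase over the feedback interval the force
    constant grows by exp(dt_fb / tau); if it improved, it shrinks by the
    inverse factor.  The result is clamped to (0, k_cap].
    """
    if k <= 0:
        raise ValueError("force constant must be positive")
    factor = np.exp(config.feedback_interval / config.tau)
    k_new = k * factor if similarity_now <= similarity_prev else k / factor
    return float(min(k_new, config.k_cap))


# ---------------------------------------------------------------------------
# density-guided dynamics


def run_fit(model: AtomicModel, topo: Topology, target: DensityMap,
            config: FitConfig, params: SpreadParams | None = None,
            k_frozen: float | None = None) -> FitTrajectory:
    """Density-guided overdamped Langevin fitting of a model into a map.

    Integrates Euler-Maruyama dynamics at ``config.temperature`` on the
    restraint potential plus the density bias -k*S, with k adapted every
    feedback interval.  Frames are recorded every ``eval_stride`` ps with
    similarity, FSC-average at the resolution threshold, and stereochemical
    quality.  Runs are bit-reproducible for a given seed.

    ``k_frozen`` pins the bias constant (0.0 disables the bias entirely,
    reducing the run to pure restraint relaxation); adaptive scaling is then
    bypassed.
    """
    if params is None:
        params = SpreadParams.for_pixel_size(float(target.voxel_size[0]))
    g = target.grid
    if abs(g.mean()) > 1e-6 or abs(g.std() - 1.0) > 1e-3:
        warnings.warn("target map does not look normalized "
                      "(normalize_map is expected upstream)", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    n_steps = int(round(config.max_time / dt))
    fb_every = max(int(round(config.feedback_interval / dt)), 1)
    eval_every = max(int(round(config.eval_stride / dt)), 1)

    x = model.coords.copy()
    k = config.k_start if k_frozen is None else float(k_frozen)
    rep_pairs = _prepare_repulsion_pairs(topo, model.is_heavy)
    spreader = Spreader(target, params, model.amplitudes)
    noise_scale = np.sqrt(2.0 * config.mobility * KB * config.temperature * dt)

    frames: list[FitFrame] = []
    reason = "max_time"

    def wrap_map(grid: np.ndarray) -> DensityMap:
        return DensityMap(grid, target.voxel_size.copy(),
                          target.origin.copy(), label="model density")

    def record(step: int, s: float, model_grid: np.ndarray) -> None:
        fsc = fsc_average_maps(wrap_map(model_grid), target,
                               config.resolution_threshold)
        q = stereo_score(model, topo, weights=config.quality_weights,
                         coords=x).total
        frames.append(FitFrame(step * dt, x.copy(), s, fsc, q, k))

    s, f_bias, model_grid = spreader.density_and_force(x, k, target.grid)
    s_prev = s
    record(0, s, model_grid)

    step = 0
    while step < n_steps:
        step += 1
        _, f_rest = restraint_energy_forces(x, topo, rep_pairs, model.is_heavy)
        total = f_rest + f_bias
        if not np.all(np.isfinite(total)):
            reason = "force_blowup"
            break
        dx = config.mobility * total * dt
        if config.temperature > 0:
            dx = dx + noise_scale * rng.standard_normal(x.shape)
        # trust-radius clamp keeps large adapted forces integrable
        norms = np.linalg.norm(dx, axis=1)
        too_big = norms > config.max_step
        if np.any(too_big):
            dx[too_big] *= (config.max_step / norms[too_big])[:, None]
        x = x + dx

        s, f_bias, model_grid = spreader.density_and_force(x, k, target.grid)
        if k_frozen is None and step % fb_every == 0:
            k = adaptive_force_update(k, s, s_prev, config)
            s_prev = s
            if k >= config.k_cap:
                reason = "k_cap"
                break
        if step % eval_every == 0:
            record(step, s, model_grid)

    if step > 0 and (not frames or frames[-1].time < step * dt):
        # always record the terminal state
        record(step, s, model_grid)
    return FitTrajectory(frames, config, reason)


# ---------------------------------------------------------------------------
# energy minimization


def energy_minimize(model: AtomicModel, topo: Topology,
                    restrain_heavy: bool = False,
                    force_tol: float = 1e-4,
                    k_pos: float = 1000.0,
                    max_iter: int = 20000) -> AtomicModel:
    """Steepest-descent minimization of the restraint potential.

    Runs with backtracking line search until the maximum per-atom force drops
    below ``force_tol`` (kJ/mol/Å) or the step size underflows.  With
    ``restrain_heavy``, harmonic positional restraints of stiffness ``k_pos``
    hold heavy atoms near their input positions — the final annealing step
    after frame selection, which relaxes stereochemistry without letting the
    model drift off the map.
    """
    x = model.coords.copy()
    x0 = model.coords.copy()
    heavy = model.is_heavy
    rep_pairs = _prepare_repulsion_pairs(topo, heavy)

    def energy_forces(xx):
        e, f = restraint_energy_forces(xx, topo, rep_pairs, heavy)
        if restrain_heavy:
            disp = xx[heavy] - x0[heavy]
            e += 0.5 * k_pos * float(np.sum(disp**2))
            f[heavy] -= k_pos * disp
        return e, f

    e, f = energy_forces(x)
    if not np.isfinite(e):
        raise MinimizationError("non-finite energy at input coordinates")
    max_f = float(np.max(np.linalg.norm(f, axis=1))) if len(f) else 0.0
    alpha = 0.01 / max(max_f, 1e-12)
    for _ in range(max_iter):
        if max_f < force_tol:
            break
        x_try = x + alpha * f
        e_try, f_try = energy_forces(x_try)
        if np.isfinite(e_try) and e_try <= e:
            x, e, f = x_try, e_try, f_try
            max_f = float(np.max(np.linalg.norm(f, axis=1)))
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha * max_f < 1e-14:
                break  # step-size underflow: converged to line-search precision
    else:
        warnings.warn(
            f"minimization stopped at max_iter={max_iter} with max force "
            f"{max_f:.3g} kJ/mol/Å", stacklevel=2)
    return model.with_coords(x)


# ---------------------------------------------------------------------------
# trajectory export


def write_trajectory_pdb(traj: FitTrajectory, model: AtomicModel, path) -> str:
    """Write trajectory frames as a multi-model PDB."""
    st = gemmi.Structure()
    res_names = model.residue_names or ["UNK"] * model.n_atoms
    for im, frame in enumerate(traj.frames, start=1):
        st.add_model(gemmi.Model(im))
        gm = st[im - 1]
        cur_chain = None
        cur_res_key = None
        chain_obj = None
        res_obj = None
        for i in range(model.n_atoms):
            if model.chain_ids[i] != cur_chain:
                gm.add_chain(gemmi.Chain(model.chain_ids[i]))
                chain_obj = gm[-1]
                cur_chain = model.chain_ids[i]
                cur_res_key = None
            key = (model.chain_ids[i], int(model.residue_ids[i]))
            if key != cur_res_key:
                r = gemmi.Residue()
                r.name = res_names[i]
                r.seqid = gemmi.SeqId(int(model.residue_ids[i]), " ")
                r.het_flag = "A"
                chain_obj.add_residue(r)
                res_obj = chain_obj[-1]
                cur_res_key = key
            a = gemmi.Atom()
            a.name = model.atom_names[i]
            a.element = gemmi.Element(model.elements[i].capitalize())
            a.pos = gemmi.Position(*frame.coords[i])
            a.occ = 1.0
            a.b_iso = 0.0
            res_obj.add_atom(a)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
    return str(path)
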