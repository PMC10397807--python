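"""Map- and model-quality metrics.

Implements the similarity and selection metrics used throughout the fitting
protocol: voxel-wise normalized cross-correlation, Fourier shell correlation
(FSC) curves and their mean up to a resolution threshold, a simplified
windowed local-quality score in the spirit of FSC-Q (model-to-map agreement
minus half-map reproducibility per local window), a stereochemical quality
score that plays the role of a knowledge-based potential (lower = better),
and per-axis radii of gyration for the anisotropy diagnostic.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from densfit.exceptions import DegenerateInputError, OptionalDependencyError
from densfit.map_model_io import AtomicModel, DensityMap, Topology, write_model

__all__ = [
    "FSCCurve", "QualityScore", "LocalQualityResult",
    "cross_correlation", "fsc_curve", "fsc_average", "fsc_average_maps",
    "local_quality", "stereo_score", "external_goap", "rg_about_axis",
]

DEFAULT_WEIGHTS = (10.0, 5.0, 0.1)  # (per Å, per rad, per clash/1000)
CLASH_GAP = 0.4  # Å subtracted from summed radii, clashscore-style


@dataclass
class FSCCurve:
    """Fourier shell correlation per spherical frequency shell.

    shell_freq is the shell-center spatial frequency (1/Å), strictly
    increasing from ~0; fsc the per-shell normalized correlation in [-1, 1];
    n_voxels the number of Fourier voxels in each shell.
    """

    shell_freq: np.ndarray
    fsc: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=np.float64)
        self.fsc = np.asarray(self.fsc, dtype=np.float64)
        self.n_voxels = np.asarray(self.n_voxels, dtype=np.int64)
        if np.any(np.diff(self.shell_freq) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")
        if np.any(np.abs(self.fsc) > 1 + 1e-9):
            raise ValueError("FSC values must lie in [-1, 1]")

    def to_tsv(self, path) -> str:
        header = "shell_freq\tfsc\tn_voxels\n"
        with open(path, "w") as fh:
            fh.write(header)
            for f, c, n in zip(self.shell_freq, self.fsc, self.n_voxels):
                fh.write(f"{f:.8g}\t{c:.8g}\t{n}\n")
        return str(path)

    @classmethod
    def from_tsv(cls, path) -> "FSCCurve":
        data = np.loadtxt(path, skiprows=1)
        data = np.atleast_2d(data)
        return cls(data[:, 0], data[:, 1], data[:, 2].astype(np.int64))


@dataclass
class QualityScore:
    """Stereochemical quality score; lower is better.

    total = w_b * bond_rms + w_a * angle_rms + w_c * clash_per_1000.  This is
    the built-in stand-in for an external knowledge-based model-quality
    potential: it penalizes the same degradations (stretched bonds, distorted
    angles, steric clashes) that increasing fitting forces produce.
    """

    bond_rms: float
    angle_rms: float
    clash_per_1000: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.bond_rms, self.angle_rms, self.clash_per_1000) < 0:
            raise ValueError("quality components must be non-negative")
        w_b, w_a, w_c = self.weights
        self.total = (w_b * self.bond_rms + w_a * self.angle_rms
                      + w_c * self.clash_per_1000)


@dataclass
class LocalQualityResult:
    """Windowed local-quality scores (simplified FSC-Q-style analog).

    q per window = mean windowed FSC(model map, full map) minus mean windowed
    FSC(half1, half2).  q near 0 means the model explains the map about as
    well as the half-maps reproduce each other; q < -0.5 flags regions where
    the model disagrees with reproducible signal, q > +0.5 regions where the
    model matches better than the half-map noise floor supports.  The sign
    bands mirror the +-0.5 interpretive convention of FSC-Q but this windowed
    variant is not the published FSC-Q algorithm.
    """

    window: int
    tile_q: np.ndarray
    voxel_q: np.ndarray
    mean_q: float
    frac_above: float   # fraction of windows with q > +0.5
    frac_below: float   # fraction of windows with q < -0.5
    atom_q: np.ndarray | None = None


# ---------------------------------------------------------------------------


def cross_correlation(a: DensityMap, b: DensityMap) -> float:
    """Pearson correlation of voxel values of two maps on the same grid."""
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    x = a.grid.ravel()
    y = b.grid.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("cross-correlation undefined for a constant map")
    return float(xc @ yc) / np.sqrt(vx * vy)


@lru_cache(maxsize=8)
def _shell_index(n: int):
    """Integer shell index per Fourier voxel of an n^3 grid, plus shell sizes."""
    k = np.fft.fftfreq(n) * n  # integer lattice frequencies
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    idx = np.rint(r).astype(np.int64)
    n_shells = n // 2 + 1
    mask = idx < n_shells
    counts = np.bincount(idx[mask].ravel(), minlength=n_shells)
    return idx, mask, n_shells, counts


def fsc_curve(a: DensityMap, b: DensityMap) -> FSCCurve:
    """Fourier shell correlation between two maps on the same cubic grid.

    Shells are unit-width bins on the integer frequency lattice; shell s has
    center frequency s / (N * p) in 1/Å.  Shells where both maps carry zero
    power are reported as FSC = 1 (nothing to disagree about); shells where
    only one map has power as FSC = 0.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if not (a.shape[1] == n and a.shape[2] == n):
        raise ValueError(f"FSC requires a cubic grid, got {a.shape}; pad upstream")
    if not np.allclose(a.voxel_size, b.voxel_size, rtol=1e-6):
        raise ValueError("voxel sizes differ between maps")
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    idx, mask, n_shells, counts = _shell_index(n)
    flat_idx = idx[mask].ravel()
    num = np.bincount(flat_idx, weights=(fa[mask] * np.conj(fb[mask])).real.ravel(),
                      minlength=n_shells)
    pa = np.bincount(flat_idx, weights=(np.abs(fa[mask]) ** 2).ravel(),
                     minlength=n_shells)
    pb = np.bincount(flat_idx, weights=(np.abs(fb[mask]) ** 2).ravel(),
                     minlength=n_shells)
    denom = np.sqrt(pa * pb)
    scale = float(max(pa.max(), pb.max(), 1.0))
    tiny = 1e-14 * scale
    fsc = np.zeros(n_shells)
    good = denom > tiny
    fsc[good] = num[good] / denom[good]
    both_empty = (pa <= tiny) & (pb <= tiny)
    fsc[both_empty] = 1.0
    np.clip(fsc, -1.0, 1.0, out=fsc)
    p = float(a.voxel_size[0])
    freqs = np.arange(n_shells) / (n * p)
    # shell 0 center frequency is exactly 0; nudge for strict monotonicity
    return FSCCurve(freqs + 1e-12, fsc, counts)


def fsc_average(curve: FSCCurve, resolution_threshold: float | None = None) -> float:
    """Arithmetic mean of FSC over shells up to 1/resolution_threshold.

    With no threshold, averages all shells.  The threshold must lie within
    the Nyquist range of the curve.
    """
    if resolution_threshold is None:
        return float(curve.fsc.mean())
    if resolution_threshold <= 0:
        raise ValueError("resolution threshold must be positive")
    f_max = 1.0 / resolution_threshold
    if f_max > curve.shell_freq[-1] * (1 + 1e-9):
        raise ValueError(
            f"threshold {resolution_threshold} Å is beyond Nyquist "
            f"({1.0 / curve.shell_freq[-1]:.3f} Å)"
        )
    included = curve.shell_freq <= f_max
    return float(curve.fsc[included].mean())


def fsc_average_maps(a: DensityMap, b: DensityMap,
                     resolution_threshold: float | None = None) -> float:
    """Convenience: FSC-average between two maps at a resolution threshold."""
    return fsc_average(fsc_curve(a, b), resolution_threshold)


def _window_fsc_mean(a: np.ndarray, b: np.ndarray, p: float) -> float:
    """Mean FSC over all shells of a small cubic window; robust to empties."""
    if np.array_equal(a, b):
        return 1.0
    da = DensityMap(a, np.full(3, p))
    db = DensityMap(b, np.full(3, p))
    return fsc_average(fsc_curve(da, db))


def local_quality(model_map: DensityMap, full_map: DensityMap,
                  half1: DensityMap, half2: DensityMap,
                  window: int = 15,
                  model: AtomicModel | None = None) -> LocalQualityResult:
    """Windowed local quality: model-vs-map FSC minus half-map FSC, per window.

    The grid is tiled with non-overlapping cubic windows of the given odd
    size (edge voxels join the nearest tile); within each window the mean FSC
    over all shells of the subvolume is computed for (model map, full map)
    and for (half1, half2), and their difference q is the window's score.
    Fractions of windows beyond +-0.5 are reported; atoms, if a model is
    given, inherit the q of the window containing their nearest voxel.
    """
    for other in (full_map, half1, half2):
        if other.shape != model_map.shape:
            raise ValueError("all maps must share the same grid")
    if window % 2 == 0 or window < 5:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    shape = model_map.shape
    if window > min(shape):
        raise ValueError(f"window {window} exceeds grid extent {shape}")
    p = float(model_map.voxel_size[0])
    nt = [max(s // window, 1) for s in shape]
    tile_q = np.zeros(nt)
    for ti in range(nt[0]):
        for tj in range(nt[1]):
            for tk in range(nt[2]):
                sl = tuple(
                    slice(t * window,
                          (t + 1) * window if t < n - 1 else None)
                    for t, n in zip((ti, tj, tk), nt)
                )
                # clip edge tiles back to a cube for the FSC
                cube = tuple(
                    slice(s.start, s.start + window) if (s.stop is None or
                          s.stop - s.start != window) else s
                    for s in sl
                )
                cube = tuple(
                    slice(min(c.start, dim - window), min(c.start, dim - window) + window)
                    for c, dim in zip(cube, shape)
                )
                q = (_window_fsc_mean(model_map.grid[cube], full_map.grid[cube], p)
                     - _window_fsc_mean(half1.grid[cube], half2.grid[cube], p))
                tile_q[ti, tj, tk] = q
    ii = np.minimum(np.arange(shape[0]) // window, nt[0] - 1)
    jj = np.minimum(np.arange(shape[1]) // window, nt[1] - 1)
    kk = np.minimum(np.arange(shape[2]) // window, nt[2] - 1)
    voxel_q = tile_q[np.ix_(ii, jj, kk)]
    atom_q = None
    if model is not None:
        idx = np.floor((model.coords - model_map.origin) / model_map.voxel_size).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        atom_q = voxel_q[idx[:, 0], idx[:, 1], idx[:, 2]]
    flat = tile_q.ravel()
    return LocalQualityResult(
        window=window,
        tile_q=tile_q,
        voxel_q=voxel_q,
        mean_q=float(flat.mean()),
        frac_above=float(np.mean(flat > 0.5)),
        frac_below=float(np.mean(flat < -0.5)),
        atom_q=atom_q,
    )


# ---------------------------------------------------------------------------


def count_clashes(model: AtomicModel, topo: Topology,
                  coords: np.ndarray | None = None) -> int:
    """Non-excluded heavy-atom pairs closer than r_i + r_j - 0.4 Å."""
    xyz = model.coords if coords is None else coords
    heavy = np.flatnonzero(model.is_heavy)
    if len(heavy) < 2:
        return 0
    radii = topo.repulsion_radius[heavy]
    max_d = float(2 * radii.max() - CLASH_GAP)
    tree = cKDTree(xyz[heavy])
    n_clash = 0
    for a, b in tree.query_pairs(max_d):
        i, j = int(heavy[a]), int(heavy[b])
        if (min(i, j), max(i, j)) in topo.excluded_pairs:
            continue
        d = np.linalg.norm(xyz[i] - xyz[j])
        if d < topo.repulsion_radius[i] + topo.repulsion_radius[j] - CLASH_GAP:
            n_clash += 1
    return n_clash


def stereo_score(model: AtomicModel, topo: Topology,
                 weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                 coords: np.ndarray | None = None) -> QualityScore:
    """Stereochemical quality of a model against its restraint topology.

    bond_rms is the RMS deviation of bond lengths from their reference;
    angle_rms the RMS angle deviation (rad); clash_per_1000 the number of
    steric clashes per 1000 atoms.  Lower total is better; an undistorted
    model scores 0.
    """
    xyz = model.coords if coords is None else coords
    if topo.n_bonds == 0 and topo.n_angles == 0:
        warnings.warn("empty topology: quality components are all zero",
                      stacklevel=2)
        return QualityScore(0.0, 0.0, 0.0, weights)
    if topo.n_bonds:
        d = np.linalg.norm(xyz[topo.bonds[:, 0]] - xyz[topo.bonds[:, 1]], axis=1)
        bond_rms = float(np.sqrt(np.mean((d - topo.b0) ** 2)))
    else:
        bond_rms = 0.0
    if topo.n_angles:
        v1 = xyz[topo.angles[:, 0]] - xyz[topo.angles[:, 1]]
        v2 = xyz[topo.angles[:, 2]] - xyz[topo.angles[:, 1]]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        angle_rms = float(np.sqrt(np.mean((theta - topo.theta0) ** 2)))
    else:
        angle_rms = 0.0
    clashes = count_clashes(model, topo, coords=xyz)
    return QualityScore(bond_rms, angle_rms,
                        1000.0 * clashes / model.n_atoms, weights)


def external_goap(model_file, goap_executable,
                  model: AtomicModel | None = None,
                  chain: str | None = None) -> float:
    """Score a model with an external GOAP-style executable (optional hook).

    If ``model`` and ``chain`` are given, only that chain is written to
    ``model_file`` before scoring.  The executable is called with the PDB
    path as its sole argument and must print a scalar score (lower = better).
    Raises :class:`OptionalDependencyError` when the executable is absent so
    callers can fall back to :func:`stereo_score`.
    """
    exe = shutil.which(str(goap_executable)) or (
        str(goap_executable) if shutil.os.path.isfile(str(goap_executable)) else None
    )
    if exe is None:
        raise OptionalDependencyError(
            f"external scorer {goap_executable!r} not found; "
            "the built-in stereo_score is the default quality metric"
        )
    if model is not None:
        write_model(model, model_file, chain_filter=chain)
    out = subprocess.run([exe, str(model_file)], capture_output=True, text=True,
                         check=True)
    for tok in out.stdout.split():
        try:
            return float(tok)
        except ValueError:
            continue
    raise OptionalDependencyError(
        f"could not parse a score from {goap_executable!r} output"
    )


def rg_about_axis(model: AtomicModel, axis: np.ndarray,
                  coords: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration about an axis through the COM (Å).

    sqrt( sum_i m_i d_i^2 / sum_i m_i ) with d_i the perpendicular distance
    of atom i from the axis.  Per-axis ratios against a reference model form
    the anisotropic stretch/compression diagnostic for pixel-size errors.
    """
    xyz = model.coords if coords is None else coords
    if len(xyz) == 0:
        raise ValueError("model has no atoms")
    axis = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    u = axis / norm
    total_mass = model.masses.sum()
    if total_mass <= 0:
        raise ValueError("total mass must be positive")
    rel = xyz - (model.masses @ xyz) / total_mass
    par = rel @ u
    d2 = np.sum(rel**2, axis=1) - par**2
    d2 = np.maximum(d2, 0.0)
    return float(np.sqrt(model.masses @ d2 / total_mass))
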