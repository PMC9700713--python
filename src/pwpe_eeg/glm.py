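"""Scalp x time volumes and first-level (per-subject) trial-wise GLMs.

Single-trial epochs are linearly interpolated from the electrode
positions onto a regular 2D scalp lattice (left-right x
posterior-anterior, default voxel 4.25 mm x 5.38 mm) for every
timepoint in the 100-400 ms post-stimulus analysis window (2 ms steps),
smoothed with a spatial Gaussian kernel (default FWHM 16 mm x 16 mm,
renormalised inside the scalp mask, no smoothing along time), and each
voxel's trial series is regressed on an intercept plus one z-scored HGF
regressor by ordinary least squares — the mass-univariate sensor-space
analogue of a first-level fMRI analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, QhullError

from ._exceptions import AlignmentError, DesignError, ProjectionError
from .containers import EpochSet
from .hgf import TrajectorySet

__all__ = ["Grid", "make_grid", "project_epochs", "smooth_volumes",
           "DesignMatrix", "build_design", "BetaMap", "first_level_fit",
           "volume_to_nifti"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Grid:
    """Regular scalp x time lattice with a channel->voxel projection."""

    x: np.ndarray            # (nx,) mm, left -> right
    y: np.ndarray            # (ny,) mm, posterior -> anterior
    times: np.ndarray        # (nt,) ms inside the analysis window
    mask: np.ndarray         # (nx, ny) bool, inside the electrode hull
    weights: np.ndarray      # (n_mask_voxels, n_scalp_channels)
    scalp_idx: np.ndarray    # channel indices projected
    time_idx: np.ndarray     # sample indices into the epoch time axis
    voxel: tuple[float, float, float]  # (mm, mm, ms)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.times.size)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())


def make_grid(epochs: EpochSet, voxel: tuple[float, float] = (4.25, 5.38),
              window: tuple[float, float] = (100.0, 400.0),
              time_step: float | None = None, margin: float = 2.0) -> Grid:
    """Build the lattice and barycentric interpolation weights.

    ``time_step`` (ms) coarser than the sampling step subsamples the
    time axis (used for scaled-down simulation studies); the default
    keeps every sample in the window.
    """
    ch = epochs.channels
    scalp_idx = np.flatnonzero(ch.scalp)
    if scalp_idx.size < 4:
        raise ProjectionError("need at least 4 scalp channels to project")
    pts = ch.pos[scalp_idx]
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ProjectionError(f"degenerate montage geometry: {err}") from err

    dx, dy = voxel
    x = np.arange(pts[:, 0].min() - margin, pts[:, 0].max() + margin + dx, dx)
    y = np.arange(pts[:, 1].min() - margin, pts[:, 1].max() + margin + dy, dy)
    gx, gy = np.meshgrid(x, y, indexing="ij")
    q = np.column_stack([gx.ravel(), gy.ravel()])
    simplex = tri.find_simplex(q)
    inside = simplex >= 0
    mask = inside.reshape(len(x), len(y))
    if not mask.any():
        raise ProjectionError("empty scalp mask")

    # barycentric weights of each in-mask voxel w.r.t. its triangle vertices
    sim = simplex[inside]
    T = tri.transform[sim]                       # (m, 3, 2)
    r = q[inside] - T[:, 2]
    bary = np.einsum("mij,mj->mi", T[:, :2], r)
    bary = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
    verts = tri.simplices[sim]                   # (m, 3) into pts
    W = np.zeros((int(inside.sum()), scalp_idx.size))
    rows = np.repeat(np.arange(W.shape[0]), 3)
    W[rows, verts.ravel()] = bary.ravel()

    tsel = (epochs.times >= window[0]) & (epochs.times <= window[1])
    time_idx = np.flatnonzero(tsel)
    srate_step = 1000.0 / epochs.srate
    if time_step is not None and time_step > srate_step:
        decim = int(round(time_step / srate_step))
        time_idx = time_idx[::decim]
    if time_idx.size == 0:
        raise ProjectionError(f"analysis window {window} outside epoch times")
    t_ms = epochs.times[time_idx]
    vt = float(t_ms[1] - t_ms[0]) if t_ms.size > 1 else srate_step
    return Grid(x=x, y=y, times=t_ms, mask=mask, weights=W,
                scalp_idx=scalp_idx, time_idx=time_idx, voxel=(dx, dy, vt))


def project_epochs(epochs: EpochSet, grid: Grid, kept_only: bool = True,
                   trials: np.ndarray | None = None) -> np.ndarray:
    """Per-trial volumes (n_trials, nx, ny, nt); voxels outside the mask are 0."""
    if trials is None:
        trials = np.flatnonzero(epochs.kept) if kept_only else \
            np.arange(epochs.n_trials)
    else:
        trials = np.asarray(trials, int)
    sub = epochs.data[np.ix_(trials, grid.scalp_idx, grid.time_idx)]
    flat = (sub.transpose(0, 2, 1) @ grid.weights.T).transpose(0, 2, 1)
    nx, ny, nt = grid.shape
    out = np.zeros((trials.size, nx, ny, nt))
    out.reshape(trials.size, nx * ny, nt)[:, grid.mask.ravel(), :] = flat
    return out


def smooth_volumes(volumes: np.ndarray, grid: Grid,
                   fwhm: tuple[float, float] = (16.0, 16.0)) -> np.ndarray:
    """Spatial-only Gaussian smoothing, kernel renormalised inside the mask.

    The masked mean of each volume is preserved exactly by an additive
    correction (normalised convolution preserves constants but not, in
    general, the masked mean near the hull boundary).
    """
    sx = fwhm[0] * FWHM_TO_SIGMA / grid.voxel[0]
    sy = fwhm[1] * FWHM_TO_SIGMA / grid.voxel[1]
    m = grid.mask.astype(float)
    denom = gaussian_filter(m, (sx, sy), mode="constant")
    denom[denom < 1e-12] = np.inf
    single = volumes.ndim == 3
    vols = volumes[None] if single else volumes
    mask4 = grid.mask[None, :, :, None]
    n_mask = grid.mask.sum() * vols.shape[-1]
    num = gaussian_filter(vols * mask4, (0, sx, sy, 0), mode="constant")
    out = np.where(mask4, num / denom[None, :, :, None], 0.0)
    # restore each volume's masked mean (normalised convolution preserves
    # constants but leaks mass at the hull boundary)
    shift = ((vols * mask4).sum(axis=(1, 2, 3))
             - (out * mask4).sum(axis=(1, 2, 3))) / n_mask
    out += shift[:, None, None, None] * mask4
    return out[0] if single else out


@dataclass
class DesignMatrix:
    """Intercept + one (z-scored) trial-wise regressor, kept trials only."""

    X: np.ndarray            # (n_kept, 2)
    regressor: str
    trial_index: np.ndarray  # original trial indices of the rows

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(traj: TrajectorySet, epochs: EpochSet, regressor: str,
                 zscore: bool = True, rectify: bool = False) -> DesignMatrix:
    """Design matrix aligned with the kept trials of ``epochs``."""
    if len(traj) != epochs.n_trials:
        raise AlignmentError(
            f"trajectories ({len(traj)}) not aligned with epochs "
            f"({epochs.n_trials})")
    kept = np.flatnonzero(epochs.kept)
    x = traj.regressor(regressor, rectify=rectify)[kept].astype(float)
    sd = x.std()
    if sd == 0:
        raise DesignError(f"regressor {regressor!r} has zero variance "
                          "over the kept trials")
    if zscore:
        x = (x - x.mean()) / sd
    X = np.column_stack([np.ones(x.size), x])
    return DesignMatrix(X=X, regressor=regressor, trial_index=kept)


@dataclass
class BetaMap:
    """Per-voxel first-level slope estimate and residual variance."""

    beta: np.ndarray          # (nx, ny, nt) slope of the regressor
    intercept: np.ndarray
    resvar: np.ndarray        # residual variance (df-adjusted)
    df: int                   # n_kept_trials - 2
    xtx_inv_slope: float      # [ (X'X)^-1 ]_{11} for slope SEs
    grid: Grid
    regressor: str
    subject: str = ""

    def slope_se(self) -> np.ndarray:
        return np.sqrt(self.resvar * self.xtx_inv_slope)


def first_level_fit(volumes: np.ndarray, design: DesignMatrix, grid: Grid,
                    subject: str = "") -> BetaMap:
    """Voxelwise OLS of trial amplitude on [1, regressor]."""
    n = volumes.shape[0]
    if n != design.n:
        raise AlignmentError(
            f"{n} volumes vs {design.n} design rows")
    if n < 10:
        raise DesignError(f"need >= 10 kept trials for a stable fit (got {n})")
    X = design.X
    Y = volumes.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df = n - X.shape[1]
    resvar = (resid ** 2).sum(axis=0) / df
    shape = volumes.shape[1:]
    xtx_inv = np.linalg.inv(X.T @ X)
    return BetaMap(beta=coef[1].reshape(shape),
                   intercept=coef[0].reshape(shape),
                   resvar=resvar.reshape(shape), df=df,
                   xtx_inv_slope=float(xtx_inv[1, 1]), grid=grid,
                   regressor=design.regressor, subject=subject)


def first_level_fit_multi(epochs: EpochSet, designs: dict[str, DesignMatrix],
                          grid: Grid, fwhm: tuple[float, float] = (16.0, 16.0),
                          chunk_size: int = 128, subject: str = "",
                          ) -> dict[str, BetaMap]:
    """Fit one GLM per design while streaming trials in chunks.

    Projection and smoothing are done chunk-wise and only the normal-
    equation accumulators (X'Y per design, diag(Y'Y) shared) are kept,
    so full-resolution lattices never materialise the complete
    per-trial volume stack. Results match :func:`first_level_fit` on
    the in-memory path to numerical precision.
    """
    kept = np.flatnonzero(epochs.kept)
    n = kept.size
    for name, d in designs.items():
        if d.n != n:
            raise AlignmentError(f"design {name!r}: {d.n} rows vs {n} "
                                 "kept trials")
    if n < 10:
        raise DesignError(f"need >= 10 kept trials for a stable fit (got {n})")
    n_vox = int(np.prod(grid.shape))
    xty = {name: np.zeros((2, n_vox)) for name in designs}
    yty = np.zeros(n_vox)
    for start in range(0, n, chunk_size):
        idx = kept[start:start + chunk_size]
        vols = smooth_volumes(project_epochs(epochs, grid, trials=idx),
                              grid, fwhm)
        Y = vols.reshape(idx.size, -1)
        yty += (Y ** 2).sum(axis=0)
        for name, d in designs.items():
            xty[name] += d.X[start:start + chunk_size].T @ Y
    out = {}
    shape = grid.shape
    for name, d in designs.items():
        xtx_inv = np.linalg.inv(d.X.T @ d.X)
        coef = xtx_inv @ xty[name]
        rss = np.maximum(yty - (coef * xty[name]).sum(axis=0), 0.0)
        df = n - 2
        out[name] = BetaMap(beta=coef[1].reshape(shape),
                            intercept=coef[0].reshape(shape),
                            resvar=(rss / df).reshape(shape), df=df,
                            xtx_inv_slope=float(xtx_inv[1, 1]), grid=grid,
                            regressor=name, subject=subject)
    return out


def volume_to_nifti(data: np.ndarray, grid: Grid, path) -> None:
    """Export an (nx, ny, nt) volume as NIfTI with voxel sizes in the header."""
    import nibabel as nib

    affine = np.diag([grid.voxel[0], grid.voxel[1], grid.voxel[2], 1.0])
    affine[0, 3], affine[1, 3], affine[2, 3] = grid.x[0], grid.y[0], \
        grid.times[0]
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    img.header.set_zooms(grid.voxel)
    nib.save(img, str(path))
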