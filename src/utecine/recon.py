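"""3D radial cine reconstruction.

Pipeline per frame and coil: select the frame's projections, weight samples
by the radial density-compensation function, grid them onto a 2x-oversampled
Cartesian grid with a Kaiser-Bessel kernel, apply a centered inverse FFT,
divide out the kernel's image-domain apodization, crop to the nominal
matrix, and take the magnitude; the per-coil magnitude volumes are combined
by sum-of-squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridding import GriddingConfig, kb_spread, nufft_adjoint, _apodization_3d
from .schedule import BinningMode, bin_frames
from .forward_sim import RawDataset

__all__ = ["CineVolume", "density_compensation", "grid_adjoint",
           "finalize_image", "coil_combine_sos", "reconstruct_cine",
           "GriddingConfig"]


@dataclass(frozen=True)
class CineVolume:
    """Reconstructed 4D magnitude cine: (frame, x, y, z)."""

    data: np.ndarray
    voxel_size_um: float
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def density_compensation(radii) -> np.ndarray:
    """Radial density-compensation weights for one center-out spoke.

    Each sample is weighted by the k-space volume of its spherical shell
    (4/3 pi [(r + d/2)^3 - (r - d/2)^3] for shell half-width d/2); the r = 0
    sample gets the innermost-shell limit (4/3 pi (d/2)^3).  The weights sum
    to the k-volume of the ball covered by the spoke's radii; dividing by the
    number of spokes (done in :func:`reconstruct_cine`) yields each sample's
    share of k-space volume.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0):
        raise ValueError("radii must be non-negative")
    if radii.size == 1 or np.ptp(radii) == 0:
        return np.ones_like(radii)
    d = np.median(np.diff(radii))
    outer = radii + d / 2.0
    inner = np.maximum(radii - d / 2.0, 0.0)
    return 4.0 / 3.0 * np.pi * (outer ** 3 - inner ** 3)


def grid_adjoint(values, k_coords, cfg: GriddingConfig, matrix: int) -> np.ndarray:
    """Grid (already density-weighted) samples onto the oversampled grid.

    Returns the complex (oversampling * matrix)^3 DC-centered k-space grid.
    """
    M = int(round(cfg.oversampling * matrix))
    u = np.asarray(k_coords, dtype=float).reshape(-1, 3) * (M / matrix)
    return kb_spread(values, u, M, cfg)


def finalize_image(grid: np.ndarray, cfg: GriddingConfig, matrix: int,
                   deapodize: bool = True) -> np.ndarray:
    """Centered inverse FFT, deapodization, central crop, magnitude."""
    M = grid.shape[0]
    g = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * (M ** 3)
    lo = M // 2 - matrix // 2
    g = g[lo:lo + matrix, lo:lo + matrix, lo:lo + matrix]
    if deapodize:
        g = g / _apodization_3d(matrix, M, cfg)
    return np.abs(g)


def coil_combine_sos(volumes) -> np.ndarray:
    """Voxelwise root-sum-of-squares over per-coil magnitude volumes."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("expected a stack of 3D volumes (coil, x, y, z)")
    return np.sqrt(np.sum(volumes ** 2, axis=0))


def _recon_one(samples, coords, weights, cfg, matrix, n_coils,
               deapodize=True) -> np.ndarray:
    per_coil = []
    for c in range(n_coils):
        img = nufft_adjoint(samples[..., c].ravel() * weights, coords, matrix,
                            cfg, deapodize=deapodize)
        per_coil.append(np.abs(img))
    return coil_combine_sos(per_coil)


def reconstruct_cine(raw: RawDataset, mode: BinningMode | str,
                     cfg: GriddingConfig | None = None,
                     density_compensate: bool = True,
                     deapodize: bool = True) -> CineVolume:
    """Reconstruct an HSR or HTR cine from a RawDataset.

    HSR: one frame per HSR window, all projections.  HTR: block_size x more
    frames, each from one block slot's projections (block_size x fewer).
    """
    mode = BinningMode(mode)
    cfg = cfg or GriddingConfig()
    spokes = raw.spokes
    matrix = int(raw.meta.get("matrix", int(2 * spokes.k_max)))
    dcf = density_compensation(spokes.sample_radii) if density_compensate \
        else np.ones(spokes.n_readout)

    if raw.schedule is None:
        if mode is BinningMode.HTR:
            raise ValueError("HTR reconstruction requires a gated acquisition")
        frame_sets = [(0, np.arange(spokes.n_spokes))]
        frame_times = np.array([0.0])
    else:
        sched = raw.schedule
        binning = bin_frames(sched, mode)
        if mode is BinningMode.HSR:
            frame_sets = [(f, binning.projections(f)) for f in range(binning.n_frames)]
            frame_times = np.array([sched.frame_mid_time(f)
                                    for f in range(binning.n_frames)])
        else:
            frame_sets = [(t // sched.block_size, binning.projections(t))
                          for t in range(binning.n_frames)]
            frame_times = np.array([sched.htr_frame_time(t)
                                    for t in range(binning.n_frames)])

    vols = []
    norm = matrix ** 3
    for raw_frame, proj in frame_sets:
        coords = spokes.sample_coordinates(proj).reshape(-1, 3)
        samples = raw.samples[raw_frame, proj]  # (n_proj, n_readout, n_coils)
        weights = np.broadcast_to(dcf, samples.shape[:2]).ravel() / (len(proj) * norm)
        vols.append(_recon_one(samples, coords, weights, cfg, matrix,
                               raw.n_coils, deapodize=deapodize))
    fov_mm = float(raw.meta.get("fov_mm", matrix))
    return CineVolume(data=np.stack(vols), voxel_size_um=fov_mm / matrix * 1000.0,
                      frame_times=frame_times)
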