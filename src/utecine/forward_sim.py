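"""Raw k-space acquisition simulator.

Each cine frame freezes the phantom at the frame's mid-time (quasi-static
approximation: signal evolution within one <=1.3 ms readout is ignored and
T2* decay enters analytically at the nominal TE).  Per-coil samples are the
non-uniform Fourier transform of the coil-weighted signal map at the spoke
sample locations, plus i.i.d. complex Gaussian noise whose standard
deviation ``noise_sigma`` applies to the real and imaginary parts separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .gridding import GriddingConfig, nufft_forward
from .phantom import DynamicPhantom, rasterize_frame
from .schedule import AcquisitionSchedule, GatingParams, build_schedule
from .trajectory import SpokeSet

__all__ = ["CoilModel", "RawDataset", "simulate_coil_maps", "acquire",
           "save_raw", "load_raw"]


@dataclass(frozen=True)
class CoilModel:
    """Receiver sensitivities: (n_coils, N, N, N) complex maps."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def __post_init__(self):
        sos = np.sum(np.abs(self.maps) ** 2, axis=0)
        if not np.all(sos > 0):
            raise ValueError("coil sensitivities vanish somewhere inside the FOV")


def simulate_coil_maps(n_coils: int, matrix: int) -> CoilModel:
    """Deterministic coil sensitivity maps.

    1 coil: uniform volume coil.  4 coils: a 2x2 surface array on the +z face
    of the FOV, each element a smooth Gaussian profile centered on its
    quadrant and decaying into the volume.
    """
    if n_coils == 1:
        return CoilModel(maps=np.ones((1, matrix, matrix, matrix), dtype=complex))
    if n_coils != 4:
        raise ValueError("supported coil counts are 1 (volume) and 4 (2x2 array)")
    n = matrix
    ax = np.arange(n) - n / 2
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    centers = [(-n / 4, -n / 4), (-n / 4, n / 4), (n / 4, -n / 4), (n / 4, n / 4)]
    sigma_t = 0.35 * n      # transverse extent of one element
    decay = 0.8 * n         # depth decay from the +z face
    maps = np.empty((4, n, n, n), dtype=complex)
    for i, (cx, cy) in enumerate(centers):
        profile = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_t ** 2)))
        depth = np.exp(-(zz - n / 2) ** 2 / (2 * decay ** 2))
        maps[i] = profile * depth
    # Floor keeps the sum-of-squares strictly positive everywhere.
    maps += 0.02
    return CoilModel(maps=maps)


@dataclass(frozen=True)
class RawDataset:
    """Per-coil complex k-space samples of a cine acquisition.

    samples : (n_frames, n_projections, n_readout, n_coils) complex array;
    frame index is the HSR frame position within the R-R interval (a single
    frame for non-gated scans).
    """

    samples: np.ndarray
    spokes: SpokeSet
    schedule: AcquisitionSchedule | None
    noise_sigma: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[3]


def acquire(ph: DynamicPhantom, sched: AcquisitionSchedule | None,
            spokes: SpokeSet, coils: CoilModel, noise_sigma: float,
            seed: int, field_strength: float, dose_umol_per_kg: float,
            tr: float, te: float, flip_deg: float,
            gridding: GriddingConfig | None = None,
            supersample: int = 1) -> RawDataset:
    """Simulate the prospectively gated acquisition.

    For each HSR frame window the phantom is rasterized at the window's
    mid-time and all scheduled projections are sampled; ungated acquisitions
    (``sched=None``) produce a single static frame.
    """
    if coils.maps.shape[1] != ph.matrix:
        raise ValueError("coil maps and phantom matrix disagree")
    if sched is not None and spokes.n_spokes != sched.n_total:
        raise ValueError("trajectory and schedule disagree on projection count")
    rng = np.random.default_rng(seed)
    n_frames = 1 if sched is None else sched.n_hsr_frames
    coords = spokes.sample_coordinates().reshape(-1, 3)
    n_samp = coords.shape[0]
    out = np.empty((n_frames, spokes.n_spokes, spokes.n_readout, coils.n_coils),
                   dtype=complex)
    for f in range(n_frames):
        t = 0.0 if sched is None else sched.frame_mid_time(f)
        signal, _ = rasterize_frame(ph, t, field_strength, dose_umol_per_kg,
                                    tr, te, flip_deg, supersample=supersample)
        for c in range(coils.n_coils):
            vals = nufft_forward(signal * coils.maps[c], coords, gridding)
            if noise_sigma > 0:
                vals = vals + noise_sigma * (rng.standard_normal(n_samp)
                                             + 1j * rng.standard_normal(n_samp))
            out[f, :, :, c] = vals.reshape(spokes.n_spokes, spokes.n_readout)
    meta = {"field": field_strength, "dose": dose_umol_per_kg, "tr": tr,
            "te": te, "flip_deg": flip_deg, "matrix": ph.matrix,
            "fov_mm": ph.fov_mm}
    return RawDataset(samples=out, spokes=spokes, schedule=sched,
                      noise_sigma=noise_sigma, seed=seed, meta=meta)


def save_raw(raw: RawDataset, path) -> None:
    """Persist a RawDataset to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=raw.samples.astype(np.complex64))
        f.create_dataset("trajectory/directions", data=raw.spokes.directions)
        f.create_dataset("trajectory/sample_radii", data=raw.spokes.sample_radii)
        f.attrs["k_max"] = raw.spokes.k_max
        f.attrs["n_readout"] = raw.spokes.n_readout
        f.attrs["noise_sigma"] = raw.noise_sigma
        f.attrs["seed"] = raw.seed
        for k, v in raw.meta.items():
            f.attrs[f"meta_{k}"] = v
        if raw.schedule is not None:
            g = f.create_group("schedule")
            g.attrs["n_total"] = raw.schedule.n_total
            g.attrs["n_hsr_frames"] = raw.schedule.n_hsr_frames
            g.attrs["rr_interval"] = raw.schedule.gating.rr_interval
            g.attrs["tr"] = raw.schedule.gating.tr
            g.attrs["block_size"] = raw.schedule.gating.block_size


def load_raw(path) -> RawDataset:
    """Load a RawDataset written by :func:`save_raw`."""
    with h5py.File(path, "r") as f:
        samples = f["samples"][...].astype(complex)
        spokes = SpokeSet(directions=f["trajectory/directions"][...],
                          n_readout=int(f.attrs["n_readout"]),
                          k_max=float(f.attrs["k_max"]),
                          sample_radii=f["trajectory/sample_radii"][...])
        sched = None
        if "schedule" in f:
            g = f["schedule"]
            gating = GatingParams(rr_interval=float(g.attrs["rr_interval"]),
                                  tr=float(g.attrs["tr"]),
                                  block_size=int(g.attrs["block_size"]))
            sched = build_schedule(int(g.attrs["n_total"]), gating)
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return RawDataset(samples=samples, spokes=spokes, schedule=sched,
                          noise_sigma=float(f.attrs["noise_sigma"]),
                          seed=int(f.attrs["seed"]), meta=meta)
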