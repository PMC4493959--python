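"""Prospective ECG-gated block-of-4 cine encoding.

After each ECG trigger, one block of `block_size` consecutive half-projections
(projections 1-2-3-4 in the first R-R interval, 5-6-7-8 in the second, ...) is
played out repeatedly, once per cine frame, until the R-R interval is filled.
The same raw data can then be binned two ways:

* HSR (high spatial resolution): each of the n_hsr frames combines *all*
  projections acquired at that frame position across every heartbeat.
* HTR (high temporal resolution): each block slot becomes its own frame,
  giving block_size x n_hsr frames with block_size times fewer projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "GatingParams",
    "AcquisitionSchedule",
    "FrameBinning",
    "BinningMode",
    "frame_counts",
    "build_schedule",
    "bin_frames",
    "predicted_scan_time",
]


class BinningMode(str, Enum):
    HSR = "hsr"
    HTR = "htr"


@dataclass(frozen=True)
class GatingParams:
    """Cardiac gating parameters. Times in seconds."""

    rr_interval: float = 0.150
    tr: float = 0.0035
    block_size: int = 4
    gated: bool = True

    def __post_init__(self):
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def frame_counts(g: GatingParams) -> tuple[int, int]:
    """Number of (HSR, HTR) cine frames fitting in one R-R interval.

    n_hsr = floor(rr / (block_size * tr)); the block is the atomic repeat
    unit, so n_htr = block_size * n_hsr.
    """
    if not g.gated:
        raise ValueError("frame counts are undefined without cardiac gating")
    n_hsr = int(g.rr_interval // (g.block_size * g.tr))
    if n_hsr < 1:
        raise ValueError("R-R interval shorter than one block")
    return n_hsr, g.block_size * n_hsr


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Mapping (heartbeat, frame, slot) -> projection index.

    Heartbeat h acquires the block {block_size*h, ..., block_size*h +
    block_size - 1}, repeated once per HSR frame position.  Projection
    indices are 0-based.
    """

    n_total: int
    gating: GatingParams
    n_hsr_frames: int

    @property
    def block_size(self) -> int:
        return self.gating.block_size

    @property
    def n_heartbeats(self) -> int:
        return self.n_total // self.block_size

    @property
    def n_htr_frames(self) -> int:
        return self.block_size * self.n_hsr_frames

    def projection(self, heartbeat: int, frame: int, slot: int) -> int:
        if not (0 <= heartbeat < self.n_heartbeats):
            raise ValueError("heartbeat out of range")
        if not (0 <= frame < self.n_hsr_frames):
            raise ValueError("frame out of range")
        if not (0 <= slot < self.block_size):
            raise ValueError("slot out of range")
        return self.block_size * heartbeat + slot

    def acquisition_time(self, heartbeat: int, frame: int, slot: int) -> float:
        """Seconds after the trigger of the given heartbeat."""
        self.projection(heartbeat, frame, slot)  # bounds check
        return (frame * self.block_size + slot) * self.gating.tr

    def frame_mid_time(self, frame: int) -> float:
        """Mid-time of an HSR frame window within the R-R interval, seconds."""
        return (frame + 0.5) * self.block_size * self.gating.tr

    def htr_frame_time(self, htr_frame: int) -> float:
        """Mid-time of an HTR frame (one TR wide), seconds post-trigger."""
        return (htr_frame + 0.5) * self.gating.tr


def build_schedule(n_total: int, g: GatingParams) -> AcquisitionSchedule:
    """Build the prospective block schedule for ``n_total`` half-projections."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_total % g.block_size != 0:
        raise ValueError(
            f"n_total ({n_total}) must be divisible by block_size ({g.block_size})"
        )
    n_hsr, _ = frame_counts(g)
    return AcquisitionSchedule(n_total=n_total, gating=g, n_hsr_frames=n_hsr)


@dataclass(frozen=True)
class FrameBinning:
    """Frame index -> set of projection indices for one reconstruction mode."""

    mode: BinningMode
    frames: tuple  # tuple of np.ndarray of projection indices

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def projections(self, frame: int) -> np.ndarray:
        return self.frames[frame]


def bin_frames(s: AcquisitionSchedule, mode: BinningMode | str) -> FrameBinning:
    """Assign projections to cine frames for HSR or HTR reconstruction.

    HSR: every frame uses the full projection set (maximum sphere coverage).
    HTR: frame f*block_size + s uses projections {block_size*h + s} over all
    heartbeats h; the block_size HTR children of one HSR frame partition the
    full set.
    """
    mode = BinningMode(mode)
    all_proj = np.arange(s.n_total)
    if mode is BinningMode.HSR:
        frames = tuple(all_proj for _ in range(s.n_hsr_frames))
    else:
        frames = []
        for f in range(s.n_hsr_frames):
            for slot in range(s.block_size):
                frames.append(np.arange(slot, s.n_total, s.block_size))
        frames = tuple(frames)
    return FrameBinning(mode=mode, frames=frames)


def predicted_scan_time(n_total: int, g: GatingParams, n_excitations: int = 1) -> float:
    """Total acquisition time in seconds.

    Gated: one heartbeat per block, so (n_total / block_size) * R-R.
    Non-gated: back-to-back TRs, n_total * TR.
    """
    if n_total < 0 or n_excitations < 0:
        raise ValueError("n_total and n_excitations must be non-negative")
    if g.gated:
        if n_total % g.block_size != 0:
            raise ValueError("gated scans require n_total divisible by block_size")
        return (n_total // g.block_size) * g.rr_interval * n_excitations
    return n_total * g.tr * n_excitations
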