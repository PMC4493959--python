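"""Sequence and field-strength configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

__all__ = ["SequenceConfig", "config_hash"]


@dataclass(frozen=True)
class SequenceConfig:
    """Acquisition parameters of one UTE protocol.

    Times in seconds, flip angle in degrees, FOV in mm.
    """

    tr: float
    te: float
    flip_deg: float
    fov_mm: float
    matrix: int
    n_projections: int
    bandwidth_hz_per_pixel: float = 781.0
    gated: bool = True
    rr_interval: float = 0.150
    block_size: int = 4
    n_excitations: int = 1

    def __post_init__(self):
        if self.tr <= 0 or self.te < 0:
            raise ValueError("tr must be > 0 and te >= 0")
        if self.matrix < 2:
            raise ValueError("matrix must be >= 2")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")

    @property
    def voxel_size_um(self) -> float:
        """Isotropic voxel size in micrometres (FOV/matrix)."""
        return self.fov_mm / self.matrix * 1000.0

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(obj) -> str:
    """Deterministic short hash of a configuration mapping or dataclass."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
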