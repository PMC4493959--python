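"""3D radial (koosh-ball) trajectory generation.

Half-projections are center-out radial spokes whose end points lie on the
unit sphere.  Directions follow a generalized (Archimedean) spiral that
starts at the north pole and winds down to the south pole as the scan
progresses, which distributes the projection end points nearly uniformly
over the sphere surface.  Each spoke is sampled from k = 0 outward, which
is what makes the echo time ultra-short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpokeSet", "generate_spiral_directions", "spoke_samples"]

# Saff–Kuijlaars constant for the unit-speed generalized spiral on the sphere.
_SPIRAL_C = 3.6


@dataclass(frozen=True)
class SpokeSet:
    """Ordered half-projection directions plus radial sampling geometry.

    Attributes
    ----------
    directions : (n, 3) array of unit vectors, pole-to-pole ordered.
    n_readout : samples per spoke (center-out).
    k_max : maximum k-space radius in cycles/FOV (= matrix/2).
    """

    directions: np.ndarray
    n_readout: int = 0
    k_max: float = 0.0
    sample_radii: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        if self.n_readout and self.sample_radii is None:
            radii = np.linspace(0.0, self.k_max, self.n_readout)
            object.__setattr__(self, "sample_radii", radii)

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    def sample_coordinates(self, indices=None) -> np.ndarray:
        """k-space sample locations, shape (n_spokes, n_readout, 3), cycles/FOV.

        ``indices`` optionally selects a subset of spokes.
        """
        dirs = self.directions if indices is None else self.directions[indices]
        return dirs[:, None, :] * self.sample_radii[None, :, None]


def generate_spiral_directions(n: int) -> np.ndarray:
    """Generate ``n`` unit vectors on a pole-to-pole spiral.

    The polar coordinate z is uniformly spaced over [+1, -1] (endpoints
    included), and the azimuth advances by c / sqrt(n (1 - z^2)) so that the
    traversal speed along the spiral is approximately uniform, giving a
    homogeneous surface distribution.  Deterministic for fixed ``n``.

    Parameters
    ----------
    n : number of half-projections, >= 1.

    Returns
    -------
    (n, 3) float array of unit vectors, z monotonically non-increasing.
    """
    if n < 1:
        raise ValueError(f"number of directions must be >= 1, got {n}")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    z = 1.0 - 2.0 * np.arange(n) / (n - 1)
    z = np.clip(z, -1.0, 1.0)
    sin_theta = np.sqrt(1.0 - z * z)
    # Azimuth increment; zero at the poles where the spiral is degenerate.
    with np.errstate(divide="ignore"):
        dphi = np.where(sin_theta > 0, _SPIRAL_C / (np.sqrt(n) * np.where(sin_theta > 0, sin_theta, 1.0)), 0.0)
    phi = np.cumsum(dphi)
    out = np.empty((n, 3))
    out[:, 0] = sin_theta * np.cos(phi)
    out[:, 1] = sin_theta * np.sin(phi)
    out[:, 2] = z
    # Renormalize to kill rounding drift.
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def spoke_samples(direction: np.ndarray, n_readout: int, k_max: float) -> np.ndarray:
    """k-space coordinates along one center-out half-projection.

    Sample j sits at radius j * k_max / (n_readout - 1); the first sample is
    exactly at the origin.

    Returns (n_readout, 3) array in cycles/FOV.
    """
    if n_readout < 2:
        raise ValueError(f"n_readout must be >= 2, got {n_readout}")
    direction = np.asarray(direction, dtype=float)
    radii = np.linspace(0.0, k_max, n_readout)
    return radii[:, None] * direction[None, :]


def make_spoke_set(n_spokes: int, matrix: int, readout_oversampling: float = 2.0) -> SpokeSet:
    """Convenience constructor: spiral directions + radial sampling for a matrix.

    k_max = matrix/2 cycles/FOV; default readout has 2x radial oversampling
    (n_readout = matrix/2 * readout_oversampling samples from 0 to k_max).
    """
    k_max = matrix / 2.0
    n_readout = max(2, int(round(matrix / 2 * readout_oversampling)))
    return SpokeSet(generate_spiral_directions(n_spokes), n_readout=n_readout, k_max=k_max)
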