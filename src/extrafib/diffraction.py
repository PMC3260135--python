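"""Orientation texture of the mineral c-axes and 00l diffraction arcs.

Hydroxyapatite c-axes follow the long axes of the mineral plates, which
scatter within a small half-angle of the fibril axis.  The 00l reflections
of a longitudinal view therefore concentrate into two arcs whose subtended
angle equals the full angular spread of the c-axes, while a view down the
fibril axis puts the c-axes out of plane and extinguishes the 00l
reflections.  Arcs are treated purely geometrically (orientation
statistics); no structure-factor physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import VoxelScene

__all__ = ["OrientationDistribution", "arc_extent", "projected_00l_visibility"]


@dataclass(frozen=True)
class OrientationDistribution:
    """c-axis tilt angles (deg, in [-90, 90]) about a reference fibril axis."""

    axis_angles: np.ndarray
    reference_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        angles = np.asarray(self.axis_angles, dtype=float)
        if angles.ndim != 1:
            raise ValueError("axis_angles must be a 1D sequence of degrees")
        if angles.size and (np.abs(angles) > 90).any():
            raise ValueError("axis angles must lie in [-90, 90] degrees")
        object.__setattr__(self, "axis_angles", angles)

    @classmethod
    def uniform(cls, half_angle: float, n: int = 1001) -> "OrientationDistribution":
        """Even coverage of [-half_angle, +half_angle], endpoints included."""
        return cls(axis_angles=np.linspace(-half_angle, half_angle, n))

    @classmethod
    def from_scene(cls, scene: VoxelScene) -> "OrientationDistribution":
        """Long-axis angles of the plates actually placed in a scene."""
        return cls(axis_angles=np.array([p.angle_deg for p in scene.plates]))


def arc_extent(dist: OrientationDistribution, coverage: float = 1.0) -> float:
    """Angle (deg) subtended by a 00l arc containing ``coverage`` of the axes.

    The arc is symmetric about the reference axis; at full coverage it is
    twice the largest absolute tilt, so a uniform +-18 deg dispersion gives
    a 36 deg arc.
    """
    if dist.axis_angles.size == 0:
        raise ValueError("empty orientation distribution")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    half = float(np.quantile(np.abs(dist.axis_angles), coverage))
    return 2.0 * half


def projected_00l_visibility(
    dist: OrientationDistribution,
    view_axis,
    in_plane_tolerance: float = 5.0,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Fraction of c-axes able to satisfy the in-plane 00l Bragg condition.

    A c-axis contributes a 00l reflection only if it lies within
    ``in_plane_tolerance`` degrees of the plane normal to the viewing
    direction.  Azimuths about the fibril axis are uniform (only the polar
    tilt is textured); the fraction is evaluated by Monte Carlo with
    ``n_draws`` orientation samples.

    For a tightly dispersed texture this is ~1 viewed perpendicular to the
    fibrils and ~0 viewed down the fibril axis, matching the absence of
    00l reflections in cross-section patterns.
    """
    if dist.axis_angles.size == 0:
        raise ValueError("empty orientation distribution")
    v = np.asarray(view_axis, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("view axis must be a nonzero vector")
    v = v / norm

    rng = np.random.default_rng(seed)
    alpha = np.radians(rng.choice(dist.axis_angles, size=n_draws, replace=True))
    phi = rng.uniform(0.0, 2 * np.pi, size=n_draws)

    # reference axis defines the polar direction of the texture
    ref = np.asarray(dist.reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, ref)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ref, e1)

    sin_a = np.sin(alpha)
    c_axes = (
        sin_a[:, None] * np.cos(phi)[:, None] * e1[None, :]
        + sin_a[:, None] * np.sin(phi)[:, None] * e2[None, :]
        + np.cos(alpha)[:, None] * ref[None, :]
    )
    out_of_plane = np.degrees(np.arcsin(np.clip(np.abs(c_axes @ v), 0.0, 1.0)))
    return float(np.mean(out_of_plane <= in_plane_tolerance))
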