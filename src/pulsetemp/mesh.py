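"""Axisymmetric (r, z) tensor-product meshes for the phantom solvers.

Node-centered finite volumes on a nonuniform tensor grid.  Material
labels are assigned both to nodes (for heat capacity, Dirichlet sets and
source terms) and to face midpoints (for flux coefficients), so that
nodes sitting exactly on a material interface carry the boundary
condition while fluxes see the material actually present between nodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import NumericsConfig, PhantomGeometry, ProbeGeometry

__all__ = ["AxiMesh", "AGAR_NODE", "ELECTRODE_ACTIVE", "ELECTRODE_GROUND",
           "INSULATOR_NODE", "build_phantom_mesh", "build_coaxial_mesh"]

AGAR_NODE = 0
ELECTRODE_ACTIVE = 1
ELECTRODE_GROUND = 2
INSULATOR_NODE = 3

_TOL = 1e-9


def _segment(start: float, stop: float, target: float) -> np.ndarray:
    """Uniform subdivision of [start, stop] with spacing near ``target``."""
    n = max(1, int(round((stop - start) / target)))
    return np.linspace(start, stop, n + 1)


def _join(segments: list[np.ndarray]) -> np.ndarray:
    pts = [segments[0]]
    for seg in segments[1:]:
        pts.append(seg[1:])
    return np.concatenate(pts)


@dataclass
class AxiMesh:
    """Tensor grid in (r, z) with node and face material labels.

    ``labels`` is (nr, nz); ``face_label_r[i, j]`` labels the face between
    nodes (i, j) and (i+1, j); ``face_label_z[i, j]`` between (i, j) and
    (i, j+1).  ``volumes`` are control-volume measures including the 2*pi
    revolution factor; ``area_r``/``area_z`` are the matching face areas.
    ``convective`` marks exterior sides ("outer", "top", "bottom") that
    exchange heat with ambient air.
    """

    r: np.ndarray
    z: np.ndarray
    labels: np.ndarray
    face_label_r: np.ndarray
    face_label_z: np.ndarray
    convective: tuple[str, ...] = ("outer", "top", "bottom")

    def __post_init__(self) -> None:
        if np.any(self.r < -_TOL):
            raise ValueError("radial coordinates must be non-negative")
        nr, nz = self.shape
        if self.labels.shape != (nr, nz):
            raise ValueError("label grid shape mismatch")
        # control-volume half-boundaries
        r, z = self.r, self.z
        r_half = np.empty(nr + 1)
        r_half[1:-1] = 0.5 * (r[:-1] + r[1:])
        r_half[0], r_half[-1] = r[0], r[-1]
        z_half = np.empty(nz + 1)
        z_half[1:-1] = 0.5 * (z[:-1] + z[1:])
        z_half[0], z_half[-1] = z[0], z[-1]
        self._r_half, self._z_half = r_half, z_half
        ring = np.pi * (r_half[1:] ** 2 - r_half[:-1] ** 2)  # (nr,)
        dz_cv = z_half[1:] - z_half[:-1]                     # (nz,)
        self.volumes = ring[:, None] * dz_cv[None, :]
        self.area_r = 2.0 * np.pi * r_half[1:-1, None] * dz_cv[None, :]
        self.area_z = np.repeat(ring[:, None], nz - 1, axis=1)
        self.dr = np.diff(r)
        self.dz = np.diff(z)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.r), len(self.z)

    @property
    def n_nodes(self) -> int:
        return len(self.r) * len(self.z)

    def outer_area(self, side: str) -> np.ndarray:
        """Exterior face areas for one side of the domain boundary."""
        dz_cv = self._z_half[1:] - self._z_half[:-1]
        ring = np.pi * (self._r_half[1:] ** 2 - self._r_half[:-1] ** 2)
        if side == "outer":
            return 2.0 * np.pi * self.r[-1] * dz_cv
        if side == "inner":
            return 2.0 * np.pi * self.r[0] * dz_cv
        if side in ("top", "bottom"):
            return ring
        raise ValueError(f"unknown side {side!r}")

    def interpolate(self, field: np.ndarray, r: float, z: float) -> float:
        """Bilinear interpolation of a nodal field at a point."""
        if not (self.r[0] - _TOL <= r <= self.r[-1] + _TOL
                and self.z[0] - _TOL <= z <= self.z[-1] + _TOL):
            raise ValueError(f"point (r={r}, z={z}) outside mesh")
        i = int(np.clip(np.searchsorted(self.r, r) - 1, 0, len(self.r) - 2))
        j = int(np.clip(np.searchsorted(self.z, z) - 1, 0, len(self.z) - 2))
        tr = (r - self.r[i]) / (self.r[i + 1] - self.r[i])
        tz = (z - self.z[j]) / (self.z[j + 1] - self.z[j])
        tr, tz = np.clip(tr, 0.0, 1.0), np.clip(tz, 0.0, 1.0)
        return float((1 - tr) * (1 - tz) * field[i, j]
                     + tr * (1 - tz) * field[i + 1, j]
                     + (1 - tr) * tz * field[i, j + 1]
                     + tr * tz * field[i + 1, j + 1])


def _label_grids(r: np.ndarray, z: np.ndarray,
                 material_at: Callable[[float, float], int]):
    nr, nz = len(r), len(z)
    labels = np.empty((nr, nz), dtype=np.int8)
    for i in range(nr):
        for j in range(nz):
            labels[i, j] = material_at(r[i], z[j])
    rm = 0.5 * (r[:-1] + r[1:])
    zm = 0.5 * (z[:-1] + z[1:])
    face_r = np.empty((nr - 1, nz), dtype=np.int8)
    for i in range(nr - 1):
        for j in range(nz):
            face_r[i, j] = material_at(rm[i], z[j])
    face_z = np.empty((nr, nz - 1), dtype=np.int8)
    for i in range(nr):
        for j in range(nz - 1):
            face_z[i, j] = material_at(r[i], zm[j])
    return labels, face_r, face_z


def build_phantom_mesh(probe: ProbeGeometry, phantom: PhantomGeometry,
                       numerics: NumericsConfig | None = None) -> AxiMesh:
    """Mesh the phantom cylinder with the bipolar probe on its axis.

    The probe occupies r <= shaft_radius from the top surface down to the
    insertion depth.  From the tip upward: ground electrode, insulating
    gap, active electrode, insulated shaft.  Grid lines are placed exactly
    on every material boundary; spacing is ``fine_spacing`` near the probe
    and sensors and ``coarse_spacing`` in the far field.
    """
    num = numerics or NumericsConfig()
    rs = probe.shaft_radius
    h = phantom.height
    z_tip = h - probe.insertion_depth
    z_g_top = z_tip + probe.electrode_exposure
    z_i_top = z_g_top + probe.insulation_gap
    z_a_top = z_i_top + probe.electrode_exposure
    if z_tip <= 0:
        raise ValueError("probe insertion exceeds phantom height")
    r_fine_end = min(rs + num.fine_extent, phantom.radius)
    if r_fine_end < rs + max(probe.sensor_offsets):
        raise ValueError("fine region must cover the sensor radii")
    if phantom.radius <= rs + max(probe.sensor_offsets):
        raise ValueError("phantom radius must exceed outermost sensor")

    r = _join([
        _segment(0.0, rs, min(num.fine_spacing, rs / 2)),
        _segment(rs, r_fine_end, num.fine_spacing),
        _segment(r_fine_end, phantom.radius, num.coarse_spacing),
    ])
    z_fine_start = max(0.0, z_tip - num.fine_extent / 2)
    z_segs = []
    if z_fine_start > _TOL:
        z_segs.append(_segment(0.0, z_fine_start, num.coarse_spacing))
    z_segs += [
        _segment(z_fine_start, z_tip, num.fine_spacing),
        _segment(z_tip, z_g_top, num.fine_spacing),
        _segment(z_g_top, z_i_top, num.fine_spacing),
        _segment(z_i_top, z_a_top, num.fine_spacing),
        _segment(z_a_top, h, num.fine_spacing),
    ]
    z = _join(z_segs)

    def material_at(rr: float, zz: float) -> int:
        if rr <= rs + _TOL and zz >= z_tip - _TOL:
            if zz <= z_g_top + _TOL:
                return ELECTRODE_GROUND
            if z_i_top - _TOL <= zz <= z_a_top + _TOL:
                return ELECTRODE_ACTIVE
            return INSULATOR_NODE
        return AGAR_NODE

    labels, face_r, face_z = _label_grids(r, z, material_at)
    mesh = AxiMesh(r, z, labels, face_r, face_z)
    # sensor sampling location: level with the active electrode midpoint
    mesh.sensor_z = 0.5 * (z_i_top + z_a_top)
    mesh.sensor_r = tuple(rs + off for off in probe.sensor_offsets)
    return mesh


def build_coaxial_mesh(inner_radius: float, outer_radius: float,
                       length: float, n_radial: int = 32,
                       n_axial: int = 8) -> AxiMesh:
    """Coaxial-cylinder test geometry with a known analytic resistance.

    Inner surface is the energized electrode, outer surface the ground;
    top and bottom are insulating.  For uniform conductivity sigma the
    exact resistance is ln(b/a) / (2*pi*sigma*length).
    """
    r = np.linspace(inner_radius, outer_radius, n_radial + 1)
    z = np.linspace(0.0, length, n_axial + 1)

    def material_at(rr: float, zz: float) -> int:
        if rr <= inner_radius + _TOL:
            return ELECTRODE_ACTIVE
        if rr >= outer_radius - _TOL:
            return ELECTRODE_GROUND
        return AGAR_NODE

    labels, face_r, face_z = _label_grids(r, z, material_at)
    return AxiMesh(r, z, labels, face_r, face_z, convective=())
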