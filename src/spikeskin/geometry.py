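"""Conical skin geometry, sensor layout and the somatotopic output grid.

The e-skin wraps a forearm-like surface that is modelled as a sector of a
truncated cone.  Points on the surface are addressed by cylindrical
coordinates ``(theta, z)``: azimuth in radians and height along the cone
axis in millimetres.  Because a cone is a developable surface, geodesic
distances are computed exactly by unrolling the sector onto a plane: a
point at slant height ``s`` and azimuth ``theta`` maps to planar polar
coordinates ``(r=s, phi=theta*sin(alpha))`` where ``alpha`` is the apex
half-angle.  All distances are in mm, areas in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SkinGeometry", "OutputGrid", "cone_distance"]


@dataclass(frozen=True)
class SkinGeometry:
    """Sector of a truncated cone carrying the 21 FBG sensors.

    Parameters
    ----------
    sin_alpha : sine of the apex half-angle (dimensionless).
    s_min, s_max : slant-height interval of the region of interest (mm).
    theta_span : angular sector covered by the ROI (rad), centred on 0.
    n_sensors : number of FBG transducers embedded under the ROI.
    """

    sin_alpha: float = 0.2
    s_min: float = 200.0
    s_max: float = 320.0
    theta_span: float = 2.1635
    n_sensors: int = 21

    # --- coordinate transforms -------------------------------------------
    def slant(self, z: np.ndarray | float) -> np.ndarray | float:
        """Slant height of a point with axial coordinate ``z``."""
        cos_alpha = np.sqrt(1.0 - self.sin_alpha**2)
        return np.asarray(z) / cos_alpha

    def z_of_slant(self, s: np.ndarray | float) -> np.ndarray | float:
        cos_alpha = np.sqrt(1.0 - self.sin_alpha**2)
        return np.asarray(s) * cos_alpha

    @property
    def z_min(self) -> float:
        return float(self.z_of_slant(self.s_min))

    @property
    def z_max(self) -> float:
        return float(self.z_of_slant(self.s_max))

    def unroll(self, theta, z):
        """Map surface points to planar Cartesian coordinates (mm).

        Unrolling is an isometry for a cone, so planar Euclidean distance
        between unrolled points equals the surface geodesic distance.
        """
        theta = np.asarray(theta, dtype=float)
        s = np.asarray(self.slant(z), dtype=float)
        phi = theta * self.sin_alpha
        return np.stack([s * np.sin(phi), s * np.cos(phi)], axis=-1)

    def embed3d(self, theta, z):
        """Map surface points to 3-D Cartesian coordinates (mm)."""
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        r = np.asarray(self.slant(z)) * self.sin_alpha
        return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=-1)

    # --- derived quantities ----------------------------------------------
    @property
    def area_cm2(self) -> float:
        """ROI area: ``theta_span*sin(alpha)*(s_max^2-s_min^2)/2`` (cm^2)."""
        a_mm2 = self.theta_span * self.sin_alpha * (self.s_max**2 - self.s_min**2) / 2.0
        return a_mm2 / 100.0

    @property
    def center(self) -> tuple[float, float]:
        """(theta, z) of the ROI centre (used as the miss penalty point)."""
        s_mid = 0.5 * (self.s_min + self.s_max)
        return 0.0, float(self.z_of_slant(s_mid))

    def contains(self, theta, z) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        s = np.asarray(self.slant(z), dtype=float)
        half = self.theta_span / 2.0
        return (np.abs(theta) <= half + 1e-9) & (s >= self.s_min - 1e-9) & (s <= self.s_max + 1e-9)

    def sensor_positions(self) -> np.ndarray:
        """(theta, z) of the FBG sensors: a 7 x 3 staggered serpentine grid.

        The single optical fibre snakes along three rows of seven gratings;
        odd rows are shifted by half a column, mimicking the interleaved
        layout of the physical patch.  Rows/columns are inset from the ROI
        border so every receptive field lies inside it.
        """
        n_col, n_row = 7, 3
        half = self.theta_span / 2.0
        th_edge = 0.88 * half
        cols = np.linspace(-th_edge, th_edge, n_col)
        s_lo = self.s_min + 0.18 * (self.s_max - self.s_min)
        s_hi = self.s_max - 0.18 * (self.s_max - self.s_min)
        rows = np.linspace(s_lo, s_hi, n_row)
        pts = []
        d_th = (cols[1] - cols[0]) / 2.0
        for j, s in enumerate(rows):
            shift = d_th / 2.0 if j % 2 == 1 else -d_th / 2.0
            for th in cols:
                pts.append((np.clip(th + shift, -half, half), self.z_of_slant(s)))
        out = np.array(pts)[: self.n_sensors]
        return out

    def sensor_spacing(self) -> float:
        """Median nearest-neighbour geodesic spacing of the sensors (mm)."""
        pos = self.sensor_positions()
        d = cone_distance(pos[:, None, :], pos[None, :, :], self)
        d = d + np.eye(len(pos)) * 1e9
        return float(np.median(d.min(axis=1)))

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly (by surface area) over the ROI."""
        half = self.theta_span / 2.0
        theta = rng.uniform(-half, half, n)
        # area element ~ s ds -> inverse-CDF sampling of slant height
        u = rng.uniform(0.0, 1.0, n)
        s = np.sqrt(self.s_min**2 + u * (self.s_max**2 - self.s_min**2))
        return np.stack([theta, np.asarray(self.z_of_slant(s))], axis=-1)


def cone_distance(p1, p2, geometry: SkinGeometry):
    """Geodesic distance (mm) between surface points ``(theta, z)``.

    Exact for a cone: the sector is unrolled to the plane (an isometry) and
    the planar Euclidean distance is returned, i.e.
    ``sqrt(s1^2 + s2^2 - 2 s1 s2 cos(dtheta * sin(alpha)))``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    u1 = geometry.unroll(p1[..., 0], p1[..., 1])
    u2 = geometry.unroll(p2[..., 0], p2[..., 1])
    return np.linalg.norm(u1 - u2, axis=-1)


@dataclass(frozen=True)
class OutputGrid:
    """Regular (theta, z) lattice of output-neuron positions.

    Each output neuron is pinned to a lattice site; the decoded contact
    position is the activity-weighted barycentre of these sites, which is
    what makes localization finer than both the sensor spacing and the
    lattice spacing (super-resolution).
    """

    geometry: SkinGeometry = field(default_factory=SkinGeometry)
    n_theta: int = 12
    n_z: int = 9

    @property
    def n_neurons(self) -> int:
        return self.n_theta * self.n_z

    @property
    def density(self) -> float:
        """Output neurons per cm^2 of ROI."""
        return self.n_neurons / self.geometry.area_cm2

    def positions(self) -> np.ndarray:
        """(n_neurons, 2) array of (theta, z), row-major over (z, theta)."""
        g = self.geometry
        half = g.theta_span / 2.0
        th = np.linspace(-half, half, self.n_theta)
        s = np.linspace(g.s_min, g.s_max, self.n_z)
        tt, ss = np.meshgrid(th, s)
        return np.stack([tt.ravel(), np.asarray(g.z_of_slant(ss.ravel()))], axis=-1)

    def unrolled(self) -> np.ndarray:
        pos = self.positions()
        return self.geometry.unroll(pos[:, 0], pos[:, 1])

    def spacing(self) -> float:
        """Median nearest-neighbour lattice spacing (mm)."""
        u = self.unrolled()
        d = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
        d = d + np.eye(len(u)) * 1e9
        return float(np.median(d.min(axis=1)))

    def nearest_neighbors(self, k: int = 4) -> np.ndarray:
        """(n_neurons, k) indices of the k nearest neighbours (self excluded).

        Neighbours are ranked by unrolled planar distance, so border sites
        pick up the nearest available sites even when not axis-adjacent.
        """
        u = self.unrolled()
        d = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return np.argsort(d, axis=1)[:, :k]
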