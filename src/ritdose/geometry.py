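"""Lattice tumour / lung-shell geometry and concentric tally shells.

The tumour is a sphere of radius ``tumour_radius`` subdivided into spherical
cell clusters of radius 250 um whose centres sit on a simple cubic lattice
(spacing = one cluster diameter).  The surrounding lung is a concentric
shell, 4 cm thick by default, subdivided into functional subunits (FSUs) on
the same lattice.  Energy is tallied on concentric spherical shells of
0.05 cm thickness spanning tumour plus lung.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ESCAPED",
    "ShellGrid",
    "TissueModel",
    "build_tissue_model",
    "shell_index",
    "cells_per_cluster",
]

#: sentinel returned by :func:`shell_index` for points beyond the outer edge
ESCAPED = -1

DEFAULT_CLUSTER_RADIUS_CM = 0.025
DEFAULT_LUNG_THICKNESS_CM = 4.0
DEFAULT_SHELL_THICKNESS_CM = 0.05
#: ICRU-44 soft tissue / inflated lung densities [g/cm^3]
DEFAULT_DENSITY_TUMOUR = 1.06
DEFAULT_DENSITY_LUNG = 0.26


@dataclass(frozen=True)
class ShellGrid:
    """Concentric spherical tally shells with half-open radial bins."""

    edges: np.ndarray  # ordered radii [cm], edges[0] == 0

    @classmethod
    def from_extent(cls, outer_radius: float,
                    shell_thickness: float = DEFAULT_SHELL_THICKNESS_CM) -> "ShellGrid":
        if outer_radius <= 0 or shell_thickness <= 0:
            raise ValueError("outer radius and shell thickness must be positive")
        n = max(1, int(math.ceil(outer_radius / shell_thickness - 1e-12)))
        return cls(edges=np.linspace(0.0, n * shell_thickness, n + 1))

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def outer_radius(self) -> float:
        return float(self.edges[-1])

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    @property
    def volumes(self) -> np.ndarray:
        """Analytic spherical-shell volumes [cm^3]."""
        return 4.0 / 3.0 * np.pi * (self.edges[1:] ** 3 - self.edges[:-1] ** 3)


def shell_index_of_radius(r, grid: ShellGrid):
    """Radial shell index for radii ``r`` [cm].

    Binning is half-open, ``[edge_i, edge_{i+1})``; radii at or beyond the
    outermost edge map to the sentinel :data:`ESCAPED`.
    """
    scalar = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    idx = np.searchsorted(grid.edges, r, side="right") - 1
    idx[r >= grid.outer_radius] = ESCAPED
    return int(idx[0]) if scalar else idx


def shell_index(points, grid: ShellGrid):
    """Shell index of Cartesian ``points`` with shape ``(..., 3)``."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (..., 3)")
    return shell_index_of_radius(np.linalg.norm(pts, axis=-1), grid)


def cells_per_cluster(density: float, cluster_radius: float) -> float:
    """Cells in one cluster: density x (4/3) pi r^3, real-valued."""
    if density <= 0:
        raise ValueError("cell density must be positive")
    return density * 4.0 / 3.0 * math.pi * cluster_radius ** 3


def _lattice_centres(max_radius: float, spacing: float,
                     registration: str) -> np.ndarray:
    """All cubic-lattice points with |c| <= max_radius (registration rule)."""
    if registration not in ("origin", "half"):
        raise ValueError("registration must be 'origin' or 'half'")
    offset = 0.0 if registration == "origin" else 0.5
    n = int(math.floor(max_radius / spacing - offset)) + 1
    axis = (np.arange(-n, n + 1) + offset) * spacing
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r2 = np.einsum("ij,ij->i", pts, pts)
    return pts[r2 <= max_radius ** 2 * (1 + 1e-12)]


@dataclass(frozen=True)
class TissueModel:
    """Tumour sphere of cell clusters plus lung shell of FSUs."""

    tumour_radius: float  # [cm]
    cluster_radius: float  # [cm]
    lung_shell_thickness: float  # [cm]
    density_tumour: float  # [g/cm^3]
    density_lung: float  # [g/cm^3]
    cluster_centres_tumour: np.ndarray  # (n, 3) [cm]
    cluster_centres_lung: np.ndarray  # (m, 3) [cm]
    registration: str = "origin"
    shell_thickness: float = DEFAULT_SHELL_THICKNESS_CM
    grid: ShellGrid = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "grid",
            ShellGrid.from_extent(self.tumour_radius + self.lung_shell_thickness
                                  if self.lung_shell_thickness > 0 else self.tumour_radius,
                                  self.shell_thickness),
        )

    @property
    def n_tumour_clusters(self) -> int:
        return len(self.cluster_centres_tumour)

    @property
    def n_lung_clusters(self) -> int:
        return len(self.cluster_centres_lung)

    @property
    def outer_radius(self) -> float:
        return self.tumour_radius + self.lung_shell_thickness

    @property
    def cluster_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.cluster_radius ** 3

    @property
    def tumour_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.tumour_radius ** 3

    @property
    def tumour_mass(self) -> float:
        """[g]"""
        return self.tumour_volume * self.density_tumour

    @property
    def lung_mass(self) -> float:
        """[g] mass of the surrounding lung shell."""
        v = 4.0 / 3.0 * math.pi * (self.outer_radius ** 3 - self.tumour_radius ** 3)
        return v * self.density_lung

    def medium_of_radius(self, r) -> np.ndarray:
        """0 = tumour (soft tissue), 1 = lung, for radii ``r`` [cm]."""
        return (np.asarray(r) > self.tumour_radius).astype(np.int8)

    def shell_media(self) -> np.ndarray:
        """Medium code per tally shell, decided at the shell centre."""
        return self.medium_of_radius(self.grid.centres)

    def tumour_cluster_shell_counts(self) -> np.ndarray:
        """K_r: tumour clusters per tally shell (cluster-centre binning)."""
        counts = np.zeros(self.grid.n_shells, dtype=np.int64)
        idx = shell_index(self.cluster_centres_tumour, self.grid)
        np.add.at(counts, idx[idx >= 0], 1)
        return counts

    def lung_cluster_shell_counts(self) -> np.ndarray:
        """FSU count per tally shell (cluster-centre binning).

        Centres sitting exactly on the outer edge belong to the last shell:
        the shell interval there is closed on the outside so that the FSU
        partition is exhaustive.
        """
        counts = np.zeros(self.grid.n_shells, dtype=np.int64)
        if self.n_lung_clusters:
            idx = shell_index(self.cluster_centres_lung, self.grid)
            idx[idx == ESCAPED] = self.grid.n_shells - 1
            np.add.at(counts, idx, 1)
        return counts


def build_tissue_model(
    tumour_radius: float,
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS_CM,
    lung_shell_thickness: float = DEFAULT_LUNG_THICKNESS_CM,
    density_tumour: float = DEFAULT_DENSITY_TUMOUR,
    density_lung: float = DEFAULT_DENSITY_LUNG,
    shell_thickness: float = DEFAULT_SHELL_THICKNESS_CM,
    registration: str = "origin",
) -> TissueModel:
    """Enumerate cluster centres and build the tissue model.

    A cluster belongs to the tumour if its centre lies within
    ``tumour_radius`` (centre-in-sphere rule); lung FSUs are the lattice
    points with centres in ``(tumour_radius, tumour_radius + thickness]``.
    ``registration='origin'`` places a cluster centre at the origin;
    ``'half'`` shifts the lattice by half a spacing on each axis.
    """
    if tumour_radius <= 2 * cluster_radius:
        raise ValueError(
            f"tumour radius {tumour_radius} cm must exceed the cluster diameter "
            f"{2 * cluster_radius} cm"
        )
    spacing = 2.0 * cluster_radius
    outer = tumour_radius + lung_shell_thickness
    pts = _lattice_centres(outer, spacing, registration)
    r2 = np.einsum("ij,ij->i", pts, pts)
    in_tumour = r2 <= tumour_radius ** 2 * (1 + 1e-12)
    return TissueModel(
        tumour_radius=tumour_radius,
        cluster_radius=cluster_radius,
        lung_shell_thickness=lung_shell_thickness,
        density_tumour=density_tumour,
        density_lung=density_lung,
        cluster_centres_tumour=pts[in_tumour],
        cluster_centres_lung=pts[~in_tumour],
        registration=registration,
        shell_thickness=shell_thickness,
    )
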