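"""Cylindrical (r, z) computational grid.

The explant is a cylinder treated with rotational symmetry, so the
computational domain is the rectangle ``[0, r_max] x [0, z_max]`` in the
radial/depth plane.  Nodes are cell-centred on both axes: node ``i`` along
``r`` sits at ``(i + 1/2) * dr``.  Cell centring keeps every radial node
strictly off the ``r = 0`` axis (no coordinate-singularity special case) and
makes the finite-volume no-flux discretisation conserve the ``r``-weighted
integral exactly: the flux through the axis face carries a factor ``r = 0``
and the outer faces carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred grid on ``[0, r_max] x [0, z_max]``.

    Parameters
    ----------
    r_max, z_max
        Domain extents in cm (defaults: 1.25 cm radius -- the right half of
        a 2.5 cm wide section -- and 1.0 cm depth).
    n_r, n_z
        Number of cells along each axis.
    """

    r_max: float = 1.25
    z_max: float = 1.0
    n_r: int = 51
    n_z: int = 41

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.z_max <= 0:
            raise ValueError("domain extents must be positive")
        if self.n_r < 2 or self.n_z < 2:
            raise ValueError("need at least 2 cells per axis")

    @property
    def dr(self) -> float:
        return self.r_max / self.n_r

    @property
    def dz(self) -> float:
        return self.z_max / self.n_z

    @property
    def r(self) -> np.ndarray:
        """Radial node coordinates, shape ``(n_r,)``, all strictly positive."""
        return (np.arange(self.n_r) + 0.5) * self.dr

    @property
    def z(self) -> np.ndarray:
        """Depth node coordinates, shape ``(n_z,)``; z grows from the fixed
        bottom face (z = 0) to the impacted surface (z = z_max)."""
        return (np.arange(self.n_z) + 0.5) * self.dz

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_r, self.n_z)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """``(R, Z)`` coordinate arrays of shape ``(n_r, n_z)``."""
        return np.meshgrid(self.r, self.z, indexing="ij")

    def cell_volumes(self) -> np.ndarray:
        """Cylindrical-shell cell volumes ``2*pi*r_i*dr*dz``, shape (n_r, n_z)."""
        return (2.0 * np.pi * self.r * self.dr * self.dz)[:, None] * np.ones(
            (1, self.n_z)
        )

    def integrate(self, f: np.ndarray) -> float:
        """Volume integral of a nodal field over the cylinder."""
        f = np.asarray(f)
        if f.shape != self.shape:
            raise ValueError(f"field shape {f.shape} != grid shape {self.shape}")
        return float(np.sum(f * self.cell_volumes()))

    def refined(self, factor: int = 2) -> "Grid":
        """Grid with each cell split ``factor`` times per axis."""
        return Grid(self.r_max, self.z_max, self.n_r * factor, self.n_z * factor)


def restrict_to_coarse(fine: np.ndarray, factor: int = 2) -> np.ndarray:
    """Restrict a fine-grid field to the coarse grid by block averaging.

    With cell-centred nodes the coarse node is the centroid of its
    ``factor x factor`` fine sub-cells, so the block mean reproduces the
    coarse nodal value exactly for fields linear in (r, z) and to second
    order otherwise.
    """
    fine = np.asarray(fine)
    nr, nz = fine.shape
    if nr % factor or nz % factor:
        raise ValueError("fine grid shape not divisible by refinement factor")
    return fine.reshape(nr // factor, factor, nz // factor, factor).mean(axis=(1, 3))
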