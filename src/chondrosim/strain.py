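"""Strain-field ingestion and synthesis.

The biochemical model is seeded by the axial (vertical) compressive strain
left in the tissue by the impact.  Two sources are supported:

* a displacement deck exported from an external finite-element solve of the
  indenter impact -- three columns (horizontal position x, vertical position
  z, axial displacement U2, all in cm) -- converted to percent strain by the
  ratio rule ``eps = 100 * |U2| / z`` and mapped onto the model grid by
  exact nearest-neighbour lookup;
* a deterministic synthetic field emulating the indenter footprint: peak
  strain under the indenter, Gaussian decay radially beyond the footprint
  and with distance from the sub-surface strain maximum.

Strain is carried in percent throughout (the necrosis map expects percent).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .grid import Grid

#: Records at or below this depth (cm) are dropped: the ratio rule divides by
#: the vertical position, which is ill-defined on the fixed bottom face.
Z_FLOOR = 1e-3


@dataclass(frozen=True)
class DisplacementDeck:
    """Axial displacement records from an external FE impact solve."""

    x: np.ndarray  # horizontal position, cm
    z: np.ndarray  # vertical position, cm (measured up from the fixed base)
    u2: np.ndarray  # axial displacement, cm (negative = compression)

    def __post_init__(self) -> None:
        for name in ("x", "z", "u2"):
            arr = getattr(self, name)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"deck column {name!r} must be a nonempty 1-D array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"deck column {name!r} contains non-finite values")
        if not (self.x.size == self.z.size == self.u2.size):
            raise ValueError("deck columns have mismatched lengths")
        if not np.any(self.z > 0):
            raise ValueError("deck has no records above the base (z > 0)")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class StrainRecords:
    """Scattered strain samples (r, z, eps%) prior to gridding."""

    r: np.ndarray
    z: np.ndarray
    eps: np.ndarray


@dataclass(frozen=True)
class StrainField:
    """Axial strain magnitude in percent on the model grid."""

    grid: Grid
    eps: np.ndarray  # shape grid.shape, percent, >= 0

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != self.grid.shape:
            raise ValueError(
                f"strain shape {eps.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(eps)):
            raise ValueError("strain field contains non-finite values")
        if np.any(eps < 0):
            raise ValueError("strain magnitude must be nonnegative")


@dataclass(frozen=True)
class SyntheticStrainParams:
    """Parameters of the deterministic synthetic impact strain field.

    ``eps_peak`` is the peak compressive axial strain in percent; ``r_ind``
    the indenter half-width footprint (cm, default 0.275 = half a 5.5 mm
    indenter line); ``ell_r``/``ell_z`` Gaussian decay lengths (cm);
    ``z_peak`` the depth of maximum strain (cm above the base; values just
    below the surface mimic the sub-surface maximum seen in dynamic FE
    impact output).
    """

    eps_peak: float = 60.0
    r_ind: float = 0.275
    ell_r: float = 0.4
    ell_z: float = 0.5
    z_peak: float = 0.85

    def __post_init__(self) -> None:
        if self.eps_peak < 0:
            raise ValueError("eps_peak must be nonnegative")
        if self.ell_r <= 0 or self.ell_z <= 0 or self.r_ind <= 0:
            raise ValueError("length scales must be positive")


def read_displacement_deck(path: str | Path) -> DisplacementDeck:
    """Read a three-column (x, z, U2) displacement deck.

    Comma- or whitespace-delimited text, units cm, one optional header line.
    A line that does not parse as three numbers raises an error naming the
    line number.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # single header line
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {raw.rstrip()!r} as three numbers"
                ) from None
            if len(vals) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(vals)}"
                )
            rows.append((vals[0], vals[1], vals[2]))
    if not rows:
        raise ValueError(f"{path}: no displacement records found")
    arr = np.asarray(rows, dtype=float)
    return DisplacementDeck(x=arr[:, 0], z=arr[:, 1], u2=arr[:, 2])


def strain_from_displacement(
    deck: DisplacementDeck, z_floor: float = Z_FLOOR
) -> StrainRecords:
    """Convert displacements to percent axial strain by the ratio rule.

    ``eps = 100 * |U2| / z`` per record; records with ``z <= z_floor`` are
    dropped (the base is fixed, so the ratio is ill-defined there).
    """
    keep = deck.z > z_floor
    if not np.any(keep):
        raise ValueError("all records at or below z_floor; no strain computable")
    z = deck.z[keep]
    eps = 100.0 * np.abs(deck.u2[keep]) / z
    return StrainRecords(r=deck.x[keep].copy(), z=z.copy(), eps=eps)


def mirror_half_symmetry(records: StrainRecords, x_center: float = 0.0) -> StrainRecords:
    """Fold a full-width deck about ``x_center`` into radial coordinates.

    Records to the right of the centre map to ``r = x - x_center``; a
    full-width deck is folded by averaging each mirror pair (matched on
    ``(r, z)`` to 1e-9 cm).  A right-half deck passes through with only the
    coordinate shift.
    """
    r = records.r - x_center
    right = r >= 0
    if np.all(right):
        return StrainRecords(r=r, z=records.z.copy(), eps=records.eps.copy())
    # fold: average left/right mirror pairs
    key = {}
    for ri, zi, ei in zip(np.abs(r), records.z, records.eps):
        k = (round(ri / 1e-9), round(zi / 1e-9))
        if k in key:
            acc = key[k]
            acc[0] += ei
            acc[1] += 1
        else:
            key[k] = [ei, 1]
    out_r = np.empty(len(key))
    out_z = np.empty(len(key))
    out_e = np.empty(len(key))
    for i, ((kr, kz), (s, n)) in enumerate(sorted(key.items())):
        out_r[i] = kr * 1e-9
        out_z[i] = kz * 1e-9
        out_e[i] = s / n
    return StrainRecords(r=out_r, z=out_z, eps=out_e)


def nearest_strain(records: StrainRecords, grid: Grid) -> StrainField:
    """Sample scattered strain records onto the grid by exact nearest
    neighbour (Euclidean); equidistant ties break to the lowest record index."""
    if records.r.size == 0:
        raise ValueError("no strain records")
    pts = np.column_stack([records.r, records.z])
    tree = cKDTree(pts)
    R, Z = grid.meshgrid()
    query = np.column_stack([R.ravel(), Z.ravel()])
    dist, idx = tree.query(query, k=1)
    # resolve ties deterministically: among records at the minimal distance,
    # take the lowest index
    ties_possible = tree.query_ball_point(query, r=dist * (1 + 1e-12))
    for q, cand in enumerate(ties_possible):
        if len(cand) > 1:
            d = np.hypot(pts[cand, 0] - query[q, 0], pts[cand, 1] - query[q, 1])
            close = [c for c, dd in zip(cand, d) if dd <= dist[q] * (1 + 1e-12)]
            idx[q] = min(close)
    eps = records.eps[idx].reshape(grid.shape)
    return StrainField(grid=grid, eps=eps)


def synthetic_strain(params: SyntheticStrainParams, r, z) -> np.ndarray:
    """Evaluate the synthetic strain profile at arbitrary (r, z) in percent.

    ``eps = eps_peak * radial(r) * depth(z)`` with ``radial = 1`` inside the
    indenter footprint and a Gaussian tail beyond it, and a Gaussian depth
    profile centred at ``z_peak``.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    radial = np.where(
        r <= params.r_ind,
        1.0,
        np.exp(-(((r - params.r_ind) / params.ell_r) ** 2)),
    )
    depth = np.exp(-(((z - params.z_peak) / params.ell_z) ** 2))
    return params.eps_peak * radial * depth


def synthetic_strain_field(
    params: SyntheticStrainParams, grid: Grid
) -> StrainField:
    """Deterministic synthetic impact strain field on the model grid.

    The depth profile is normalised to 1 at its maximum within the domain,
    so the field maximum equals ``eps_peak`` when ``z_peak`` lies inside
    ``[0, z_max]``.
    """
    R, Z = grid.meshgrid()
    eps = synthetic_strain(params, R, Z)
    # normalise the continuous depth profile over [0, z_max]
    z_star = min(max(params.z_peak, 0.0), grid.z_max)
    depth_max = float(np.exp(-(((z_star - params.z_peak) / params.ell_z) ** 2)))
    if depth_max > 0:
        eps = eps / depth_max
    return StrainField(grid=grid, eps=eps)


def zero_strain_field(grid: Grid) -> StrainField:
    """All-zero strain (no impact); the model is quiescent under it."""
    return StrainField(grid=grid, eps=np.zeros(grid.shape))


def uniform_strain_field(grid: Grid, eps: float) -> StrainField:
    """Spatially uniform strain in percent (used for 0-D cross-checks)."""
    return StrainField(grid=grid, eps=np.full(grid.shape, float(eps)))


def write_strain_field(field: StrainField, path: str | Path) -> None:
    """Write a strain field as a CSV grid (r, z, eps) with a metadata header."""
    g = field.grid
    R, Z = g.meshgrid()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# strain-field r_max={g.r_max!r} z_max={g.z_max!r} "
            f"n_r={g.n_r} n_z={g.n_z} units=percent\n"
        )
        fh.write("r_cm,z_cm,eps_percent\n")
        for ri, zi, ei in zip(R.ravel(), Z.ravel(), field.eps.ravel()):
            fh.write(f"{float(ri)!r},{float(zi)!r},{float(ei)!r}\n")


def read_strain_field(path: str | Path) -> StrainField:
    """Read a strain field written by :func:`write_strain_field` (bit-exact)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# strain-field"):
            raise ValueError(f"{path}: not a strain-field file")
        meta = dict(
            tok.split("=", 1) for tok in header[len("# strain-field") :].split()
            if "=" in tok
        )
        grid = Grid(
            r_max=float(meta["r_max"]),
            z_max=float(meta["z_max"]),
            n_r=int(meta["n_r"]),
            n_z=int(meta["n_z"]),
        )
        body = fh.read()
    data = np.loadtxt(io.StringIO(body), delimiter=",", skiprows=1)
    eps = data[:, 2].reshape(grid.shape)
    return StrainField(grid=grid, eps=eps)
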